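"""Synthetic amphidiploid genomes, BAC libraries and pool-screen signals.

Everything the screening pipeline consumes can be generated here with full
ground truth retained: a pair of diverged progenitor regions, the
amphidiploid carrying both homoeologs plus accession-level SNPs, a gridded
clone library with ~10x coverage, the seven-dimension pooling design, an
intergenomic-SNP assay panel with the five category pathologies, noisy
per-pool R/Theta signals, reference-panel genotype evidence, and a
validation oracle standing in for PCR-amplicon analysis of single clones.

All randomness flows from a single seed through per-stage substreams, so
any stage is replayable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import NoiseModel, SimulationConfig
from .pooling import PoolingDesign, build_pooling_design

BASES = np.array(list("ACGT"))
GAP = 4

SUBGENOMES = ("A", "C")


def _decode_base(code: int) -> str:
    return str(BASES[code])


# ---------------------------------------------------------------------------
# progenitor pair


@dataclass
class ProgenitorPair:
    """Two progenitor region sequences and their true alignment.

    ``aln_a`` / ``aln_c`` are aligned base-code arrays (0-3 = ACGT,
    4 = gap) of equal length; ungapped sequences and coordinate maps are
    derived views.
    """

    aln_a: np.ndarray
    aln_c: np.ndarray
    substitution_cols: np.ndarray

    def __post_init__(self):
        self.seq_a = self.aln_a[self.aln_a != GAP]
        self.seq_c = self.aln_c[self.aln_c != GAP]
        # position of each alignment column on each sequence (-1 in gaps)
        self.pos_a = np.where(self.aln_a != GAP,
                              np.cumsum(self.aln_a != GAP) - 1, -1)
        self.pos_c = np.where(self.aln_c != GAP,
                              np.cumsum(self.aln_c != GAP) - 1, -1)

    @property
    def n_columns(self) -> int:
        return len(self.aln_a)

    def identity(self) -> float:
        """Fraction of alignment columns with identical bases (gaps count
        as non-matching, as in an HSP percent identity)."""
        matches = np.count_nonzero(
            (self.aln_a == self.aln_c) & (self.aln_a != GAP))
        return matches / self.n_columns


def simulate_progenitor_pair(config: SimulationConfig,
                             rng: Optional[np.random.Generator] = None
                             ) -> ProgenitorPair:
    """Generate two progenitor sequences related by substitutions and indels.

    Substitutions are uniform over the three alternative nucleotides;
    indel lengths are geometric with mean ``config.indel_mean_len``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.region_length_bp
    seq_a = rng.integers(0, 4, size=L, dtype=np.int8)

    sub_mask = rng.random(L) < config.divergence_rate
    shift = rng.integers(1, 4, size=L, dtype=np.int8)
    seq_c_base = np.where(sub_mask, (seq_a + shift) % 4, seq_a).astype(np.int8)

    indel_sites = np.flatnonzero(rng.random(L) < config.indel_rate)
    seg_a: List[np.ndarray] = []
    seg_c: List[np.ndarray] = []
    cursor = 0
    for p in indel_sites:
        if p < cursor:
            continue
        seg_a.append(seq_a[cursor:p])
        seg_c.append(seq_c_base[cursor:p])
        length = int(rng.geometric(1.0 / config.indel_mean_len))
        if rng.random() < 0.5:   # deletion in C
            length = min(length, L - p)
            seg_a.append(seq_a[p:p + length])
            seg_c.append(np.full(length, GAP, dtype=np.int8))
            cursor = p + length
        else:                    # insertion in C
            seg_a.append(np.full(length, GAP, dtype=np.int8))
            seg_c.append(rng.integers(0, 4, size=length, dtype=np.int8))
            cursor = p
    seg_a.append(seq_a[cursor:])
    seg_c.append(seq_c_base[cursor:])
    aln_a = np.concatenate(seg_a)
    aln_c = np.concatenate(seg_c)
    subs = np.flatnonzero((aln_a != aln_c) & (aln_a != GAP) & (aln_c != GAP))
    return ProgenitorPair(aln_a, aln_c, subs)


# ---------------------------------------------------------------------------
# amphidiploid


@dataclass
class Amphidiploid:
    """Both subgenome copies of the region plus the intergenomic SNP truth.

    ``snp_truth`` has one row per progenitor intergenomic SNP with its
    position on each subgenome, the progenitor alleles, the (possibly
    accession-mutated) amphidiploid alleles, and flags for sites that
    became monomorphic or changed in the amphidiploid.
    """

    pair: ProgenitorPair
    sub_a: np.ndarray
    sub_c: np.ndarray
    rate_a: float
    rate_c: float
    mutated_a: np.ndarray
    mutated_c: np.ndarray
    snp_truth: pd.DataFrame = field(default=None, repr=False)

    def refresh_snp_truth(self) -> None:
        cols = self.pair.substitution_cols
        pos_a = self.pair.pos_a[cols]
        pos_c = self.pair.pos_c[cols]
        prog_a = self.pair.aln_a[cols]
        prog_c = self.pair.aln_c[cols]
        amph_a = self.sub_a[pos_a]
        amph_c = self.sub_c[pos_c]
        self.snp_truth = pd.DataFrame({
            "aln_col": cols,
            "pos_a": pos_a,
            "pos_c": pos_c,
            "prog_a": BASES[prog_a],
            "prog_c": BASES[prog_c],
            "amph_a": BASES[amph_a],
            "amph_c": BASES[amph_c],
        })
        self.snp_truth["monomorphic"] = (
            self.snp_truth.amph_a == self.snp_truth.amph_c)
        self.snp_truth["conserved"] = (
            (self.snp_truth.amph_a == self.snp_truth.prog_a)
            & (self.snp_truth.amph_c == self.snp_truth.prog_c))


def derive_amphidiploid(pair: ProgenitorPair,
                        accession_snp_rate_range: Tuple[float, float],
                        rng: np.random.Generator) -> Amphidiploid:
    """Derive the two amphidiploid subgenomes from the progenitor pair.

    Each subgenome differs from its progenitor by a per-site substitution
    rate drawn uniformly from ``accession_snp_rate_range`` (accession-level
    divergence between the amphidiploid and the sequenced progenitors).
    """
    lo, hi = accession_snp_rate_range
    sub = {}
    rates = {}
    mutated = {}
    for key, seq in (("A", pair.seq_a), ("C", pair.seq_c)):
        rate = float(rng.uniform(lo, hi))
        mask = rng.random(len(seq)) < rate
        shift = rng.integers(1, 4, size=len(seq), dtype=np.int8)
        sub[key] = np.where(mask, (seq + shift) % 4, seq).astype(np.int8)
        rates[key] = rate
        mutated[key] = np.flatnonzero(mask)
    amph = Amphidiploid(pair, sub["A"], sub["C"], rates["A"], rates["C"],
                        mutated["A"], mutated["C"])
    amph.refresh_snp_truth()
    return amph


# ---------------------------------------------------------------------------
# BAC library


@dataclass
class Library:
    """A gridded clone library with truth intervals.

    Clones live on three "chromosomes": the A-region chromosome (the
    region embedded in background margins), the C-region chromosome, and a
    background chromosome absorbing the rest of the genome.  ``region_start``
    / ``region_end`` give each clone's interval in region coordinates of
    its subgenome (meaningful only where ``subgenome`` is A or C).
    """

    n_plates: int
    rows: int
    cols: int
    chrom: np.ndarray          # 0=A-chromosome, 1=C-chromosome, 2=background
    start: np.ndarray
    length: np.ndarray
    subgenome: np.ndarray      # 'A', 'C' or 'bg'
    region_start: np.ndarray
    region_end: np.ndarray
    genome_total: int
    margin: int
    chrom_lens: np.ndarray = field(
        default_factory=lambda: np.zeros(3, dtype=np.int64))

    @property
    def size(self) -> int:
        return len(self.start)

    def coordinates(self) -> pd.DataFrame:
        idx = np.arange(self.size)
        plate, rest = np.divmod(idx, self.rows * self.cols)
        row, col = np.divmod(rest, self.cols)
        return pd.DataFrame({
            "linear_index": idx, "plate": plate, "row": row, "col": col,
            "subgenome": self.subgenome,
            "region_start": self.region_start,
            "region_end": self.region_end,
            "length": self.length,
        })

    def clones_covering(self, subgenome: str, pos: int) -> np.ndarray:
        """Linear indices of clones of one subgenome covering a region
        position."""
        mask = ((self.subgenome == subgenome)
                & (self.region_start <= pos) & (pos < self.region_end))
        return np.flatnonzero(mask)

    def covers(self, linear_index: int, subgenome: str, pos: int) -> bool:
        return (self.subgenome[linear_index] == subgenome
                and self.region_start[linear_index] <= pos
                < self.region_end[linear_index])


def simulate_bac_library(amph: Amphidiploid, config: SimulationConfig,
                         rng: np.random.Generator) -> Library:
    """Draw one clone per library coordinate, uniformly over the genome.

    ``genome_length_bp`` is rescaled so that
    ``library_size * insert_mean / genome_total == coverage_target``;
    the realised value is stored on the returned library.
    """
    size = config.library_size
    len_a = len(amph.sub_a)
    len_c = len(amph.sub_c)
    if size == 0:
        empty = np.empty(0, dtype=np.int64)
        return Library(config.n_plates, config.rows_per_plate,
                       config.cols_per_plate, empty, empty, empty,
                       np.empty(0, dtype=object), empty, empty,
                       config.genome_length_bp, config.insert_size_mean_bp,
                       np.zeros(3, dtype=np.int64))
    genome_total = int(round(size * config.insert_size_mean_bp
                             / config.coverage_target))
    margin = config.insert_size_mean_bp
    chrom_a = len_a + 2 * margin
    chrom_c = len_c + 2 * margin
    chrom_bg = genome_total - chrom_a - chrom_c
    if chrom_bg < 0:
        raise ValueError(
            "regions of interest do not fit the genome implied by library "
            f"size, insert size and coverage target (total {genome_total} bp)")

    lengths = rng.normal(config.insert_size_mean_bp,
                         config.insert_size_sd_bp, size)
    lengths = np.maximum(lengths, config.insert_size_min_bp).astype(np.int64)

    chrom_lens = np.array([chrom_a, chrom_c, chrom_bg], dtype=np.float64)
    chrom = rng.choice(3, size=size, p=chrom_lens / chrom_lens.sum())
    u = rng.random(size)
    start = (u * (chrom_lens[chrom] - 1)).astype(np.int64)
    end = np.minimum(start + lengths, chrom_lens[chrom].astype(np.int64))
    lengths = end - start

    region_start = start - margin
    region_end = end - margin
    region_len = np.where(chrom == 0, len_a, len_c)
    overlaps = (chrom < 2) & (region_end > 0) & (region_start < region_len)
    subgenome = np.where(overlaps & (chrom == 0), "A",
                         np.where(overlaps & (chrom == 1), "C", "bg"))
    region_start = np.where(subgenome == "bg", -1, region_start)
    region_end = np.where(subgenome == "bg", -1, region_end)

    return Library(config.n_plates, config.rows_per_plate,
                   config.cols_per_plate, chrom.astype(np.int8), start,
                   lengths, subgenome.astype(object), region_start,
                   region_end, genome_total, margin,
                   chrom_lens.astype(np.int64))


# ---------------------------------------------------------------------------
# assay panel


@dataclass
class AssayDefinition:
    """One intergenomic SNP assay.

    ``allele1`` is the progenitor-A nucleotide at the site, ``allele2``
    the progenitor-C nucleotide.  ``channel_a`` / ``channel_c`` give the
    assay nucleotide (1 or 2) that clones of each subgenome elicit, or 0
    where the assay cannot detect that subgenome (interfering
    polymorphism, category-4 pathology).
    """

    assay_id: str
    order_index: int
    pos_a: int
    pos_c: int
    allele1: str
    allele2: str
    category_true: int
    channel_a: int
    channel_c: int
    off_target_pos: int = -1     # position on the background chromosome
    conflict_side: str = ""      # evidence pathology: "", "rapa", "oleracea", "both"
    flank_left: str = ""
    flank_right: str = ""


def _category_counts(mix: Tuple[float, ...], n: int) -> List[int]:
    raw = [m * n for m in mix]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def simulate_assay_panel(amph: Amphidiploid, config: SimulationConfig,
                         rng: np.random.Generator,
                         footprint: int = 25) -> List[AssayDefinition]:
    """Place ``n_assays`` assays on truth-known intergenomic SNP sites.

    Sites are chosen evenly across the region among conserved SNPs with a
    clean oligonucleotide footprint, then the configured category mix is
    imposed: categories 1-3 keep the clean site (their pathologies live in
    the reference evidence), category 4 receives an interfering
    substitution within the footprint of one subgenome, and category 5
    sites are made monomorphic in the amphidiploid.
    """
    truth = amph.snp_truth
    clean = truth[truth.conserved].reset_index(drop=True)
    # demand an isolated site: no other intergenomic SNP within the footprint
    pos = clean.pos_a.to_numpy()
    isolated = np.ones(len(clean), dtype=bool)
    if len(clean) > 1:
        gap_prev = np.diff(pos, prepend=pos[0] - 10 * footprint)
        gap_next = np.diff(pos, append=pos[-1] + 10 * footprint)
        isolated = (gap_prev > footprint) & (gap_next > footprint)
    clean = clean[isolated].reset_index(drop=True)
    if len(clean) < config.n_assays:
        raise ValueError(
            f"only {len(clean)} usable intergenomic SNP sites for "
            f"{config.n_assays} assays; increase region length or divergence")

    pick = np.unique(np.linspace(0, len(clean) - 1,
                                 config.n_assays).round().astype(int))
    while len(pick) < config.n_assays:   # collisions at tiny n
        extra = rng.integers(0, len(clean))
        pick = np.unique(np.append(pick, extra))
    sites = clean.iloc[pick[:config.n_assays]].sort_values("pos_a")

    counts = _category_counts(config.assay_category_mix, config.n_assays)
    categories = np.repeat(np.arange(1, 6), counts)
    categories = rng.permutation(categories)

    assays: List[AssayDefinition] = []
    sub_a, sub_c = amph.sub_a, amph.sub_c
    for order, ((_, row), cat) in enumerate(zip(sites.iterrows(), categories)):
        pa, pc = int(row.pos_a), int(row.pos_c)
        a1, a2 = row.prog_a, row.prog_c
        channel_a, channel_c = 1, 2
        conflict = ""
        if cat == 2:
            conflict = "rapa" if rng.random() < 0.5 else "oleracea"
        elif cat == 3:
            conflict = "both"
        elif cat == 4:
            # interfering substitution within the oligo footprint of one
            # subgenome: that subgenome escapes detection
            if rng.random() < 0.5:
                channel_c = 0
                off = int(rng.integers(5, footprint))
                p = min(pc + off, len(sub_c) - 1)
                sub_c[p] = (sub_c[p] + rng.integers(1, 4)) % 4
            else:
                channel_a = 0
                off = int(rng.integers(5, footprint))
                p = min(pa + off, len(sub_a) - 1)
                sub_a[p] = (sub_a[p] + rng.integers(1, 4)) % 4
        elif cat == 5:
            # monomorphic in the amphidiploid: both subgenomes carry allele1
            sub_c[pc] = int(np.flatnonzero(BASES == a1)[0])
            channel_a = channel_c = 1
        off_pos = -1
        if rng.random() < config.off_target_fraction:
            off_pos = int(rng.integers(0, 10**9))
        fl = BASES[sub_a[max(0, pa - 60):pa]]
        fr = BASES[sub_a[pa + 1:pa + 61]]
        assays.append(AssayDefinition(
            assay_id=f"a{order + 1:02d}", order_index=order,
            pos_a=pa, pos_c=pc, allele1=a1, allele2=a2,
            category_true=int(cat), channel_a=channel_a, channel_c=channel_c,
            off_target_pos=off_pos, conflict_side=conflict,
            flank_left="".join(fl), flank_right="".join(fr)))
    amph.refresh_snp_truth()
    return assays


def assay_table(assays: List[AssayDefinition]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in assays])


# ---------------------------------------------------------------------------
# pool signals


def positive_clones(assay: AssayDefinition, library: Library
                    ) -> Dict[int, np.ndarray]:
    """Truth: linear indices of clones responding on each assay nucleotide."""
    out = {1: [], 2: []}
    if assay.channel_a:
        out[assay.channel_a].append(library.clones_covering("A", assay.pos_a))
    if assay.channel_c:
        out[assay.channel_c].append(library.clones_covering("C", assay.pos_c))
    if assay.off_target_pos >= 0 and library.chrom_lens[2] > 0:
        # off-target homologous locus on the background chromosome
        pos = assay.off_target_pos % int(library.chrom_lens[2])
        mask = ((library.chrom == 2) & (library.start <= pos)
                & (pos < library.start + library.length))
        out[1].append(np.flatnonzero(mask))
    return {k: (np.unique(np.concatenate(v)) if v else
                np.empty(0, dtype=np.int64)) for k, v in out.items()}


def simulate_pool_signals(assays: List[AssayDefinition], library: Library,
                          design: PoolingDesign, noise: NoiseModel,
                          rng: np.random.Generator
                          ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pool normalised R / Theta signals for every assay.

    Returns ``(signals, pool_truth)``: the noisy signal table and the
    ideal (pre-noise) call of every (assay, pool).  Pools containing
    clones of only one assay nucleotide sit at Theta ~0 (nucleotide 1) or
    ~1 (nucleotide 2); pools containing both sit midway; empty pools draw
    a residual intensity.  Dropout replaces a positive pool's intensity by
    a residual draw; a nucleotide flip mirrors Theta.
    """
    noise.validate()
    n_pools = design.n_pools
    frames = []
    truth_frames = []
    for assay in assays:
        pos = positive_clones(assay, library)
        has1 = np.zeros(n_pools, dtype=bool)
        has2 = np.zeros(n_pools, dtype=bool)
        if len(pos[1]):
            has1[np.unique(design.membership[pos[1]])] = True
        if len(pos[2]):
            has2[np.unique(design.membership[pos[2]])] = True

        true_call = np.full(n_pools, "negative", dtype=object)
        true_call[has1 & ~has2] = "allele1"
        true_call[~has1 & has2] = "allele2"
        true_call[has1 & has2] = "both"

        positive = has1 | has2
        theta = rng.random(n_pools)          # meaningless for negatives
        theta[has1 & ~has2] = 0.0
        theta[~has1 & has2] = 1.0
        theta[has1 & has2] = 0.5

        flip = positive & (rng.random(n_pools) < noise.nucleotide_flip_prob)
        theta[flip] = 1.0 - theta[flip]

        jitter = rng.normal(0.0, noise.theta_jitter_sd, n_pools)
        theta = np.where(positive, theta + jitter, theta)
        both_mask = has1 & has2
        theta[both_mask] = np.clip(theta[both_mask], 0.10, 0.90)
        theta = np.clip(theta, 0.0, 1.0)

        r = np.maximum(rng.normal(*noise.residual_r, n_pools), 0.0)
        r_pos = np.maximum(rng.normal(*noise.positive_r, n_pools), 0.2)
        dropout = positive & (rng.random(n_pools) < noise.pool_dropout_prob)
        live = positive & ~dropout
        r = np.where(live, r_pos, r)

        pools = np.arange(n_pools)
        frames.append(pd.DataFrame({
            "assay_id": assay.assay_id, "pool": pools,
            "norm_R": r, "norm_theta": theta}))
        truth_frames.append(pd.DataFrame({
            "assay_id": assay.assay_id, "pool": pools,
            "true_call": true_call, "dropout": dropout, "flip": flip}))
    signals = pd.concat(frames, ignore_index=True)
    pool_truth = pd.concat(truth_frames, ignore_index=True)
    return signals, pool_truth


# ---------------------------------------------------------------------------
# reference panel evidence and validation oracle

EVIDENCE_SOURCES = ["rapa_acc1", "rapa_acc2", "rapa_wgs",
                    "oleracea_acc1", "oleracea_acc2", "oleracea_wgs",
                    "oleracea_gss", "express_call", "express_amplicon"]


def simulate_reference_panel(assays: List[AssayDefinition],
                             rng: np.random.Generator,
                             gss_missing_prob: float = 0.3) -> pd.DataFrame:
    """Genotype evidence for each assay from reference accessions.

    Clean assays show allele1 across all A-progenitor sources and allele2
    across C-progenitor sources.  Category-2 assays carry one conflicting
    accession on one side, category-3 assays on both sides.  The
    amphidiploid ("express") genotyping call shows both nucleotides except
    for category-4 (one detectable nucleotide) and category-5 (site
    monomorphic, amplicon shows a single base) assays.
    """
    rows = []
    for a in assays:
        a1, a2 = a.allele1, a.allele2
        other1 = _other_base(a1, rng)
        other2 = _other_base(a2, rng)
        row = {
            "assay_id": a.assay_id,
            "rapa_acc1": a1, "rapa_acc2": a1, "rapa_wgs": a1,
            "oleracea_acc1": a2, "oleracea_acc2": a2, "oleracea_wgs": a2,
            "oleracea_gss": a2 if rng.random() > gss_missing_prob else "",
            "express_call": f"{a1}/{a2}",
            "express_amplicon": f"{a1}/{a2}",
        }
        if a.conflict_side in ("rapa", "both"):
            row[f"rapa_acc{rng.integers(1, 3)}"] = other1
        if a.conflict_side in ("oleracea", "both"):
            row[f"oleracea_acc{rng.integers(1, 3)}"] = other2
        if a.category_true == 4:
            detected = a1 if (a.channel_a == 1 or a.channel_c == 1) else a2
            row["express_call"] = detected
            # the amplicon still spans both subgenome copies
            row["express_amplicon"] = f"{a1}/{a2}"
        elif a.category_true == 5:
            row["express_call"] = a1
            row["express_amplicon"] = a1   # monomorphic amplicon
        rows.append(row)
    return pd.DataFrame(rows)


def _other_base(base: str, rng: np.random.Generator) -> str:
    alternatives = [b for b in "ACGT" if b != base]
    return alternatives[int(rng.integers(0, 3))]


class ValidationOracle:
    """Ground-truth stand-in for PCR-amplicon validation of single clones.

    ``test(linear_index, assay_id)`` returns ``("present", subgenome)`` if
    the clone's insert spans the assay site on its subgenome, otherwise
    ``("absent", None)``.  Amplicons listed in ``masked`` are
    subgenome-specific: presence of the other subgenome's copy cannot be
    tested and ``("untestable", None)`` is returned.
    """

    def __init__(self, library: Library, assays: List[AssayDefinition],
                 masked: Optional[Dict[str, str]] = None):
        self.library = library
        self.assays = {a.assay_id: a for a in assays}
        self.masked = dict(masked or {})
        self.n_queries = 0

    def test(self, linear_index: int, assay_id: str
             ) -> Tuple[str, Optional[str]]:
        if assay_id not in self.assays:
            raise KeyError(f"unknown assay id {assay_id!r}")
        if not (0 <= linear_index < self.library.size):
            raise KeyError(f"unknown clone index {linear_index}")
        self.n_queries += 1
        a = self.assays[assay_id]
        sub = self.library.subgenome[linear_index]
        testable = self.masked.get(assay_id)   # subgenome the amplicon amplifies
        if sub in SUBGENOMES:
            pos = a.pos_a if sub == "A" else a.pos_c
            if self.library.covers(linear_index, sub, pos):
                if testable is not None and sub != testable:
                    return "untestable", None
                return "present", sub
        if testable is not None:
            # a subgenome-specific amplicon cannot prove absence of the
            # other subgenome's copy
            return "untestable", None
        return "absent", None


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class Simulation:
    """One fully generated synthetic screening experiment with truth."""

    config: SimulationConfig
    pair: ProgenitorPair
    amph: Amphidiploid
    library: Library
    design: PoolingDesign
    assays: List[AssayDefinition]
    signals: pd.DataFrame
    pool_truth: pd.DataFrame
    evidence: pd.DataFrame
    oracle: ValidationOracle

    @classmethod
    def generate(cls, config: SimulationConfig) -> "Simulation":
        config.validate()
        streams = np.random.SeedSequence(config.seed).spawn(6)
        rngs = [np.random.default_rng(s) for s in streams]
        pair = simulate_progenitor_pair(config, rngs[0])
        amph = derive_amphidiploid(pair, config.accession_snp_rate_range,
                                   rngs[1])
        assays = simulate_assay_panel(amph, config, rngs[2])
        library = simulate_bac_library(amph, config, rngs[3])
        design = build_pooling_design(config.n_plates, config.rows_per_plate,
                                      config.cols_per_plate,
                                      config.diagonal_modulus)
        signals, pool_truth = simulate_pool_signals(
            assays, library, design, config.noise, rngs[4])
        evidence = simulate_reference_panel(assays, rngs[5])
        masked = {}
        maskable = [a for a in assays if a.category_true in (1, 2)]
        for a in maskable[:config.n_masked_amplicons]:
            masked[a.assay_id] = "C"   # amplicon amplifies only the C copy
        oracle = ValidationOracle(library, assays, masked)
        return cls(config, pair, amph, library, design, assays, signals,
                   pool_truth, evidence, oracle)

    # -- truth accessors ---------------------------------------------------

    def truth_scores(self) -> pd.DataFrame:
        """All detectable truth scores: (clone, assay, nucleotide class)."""
        rows = []
        for a in self.assays:
            pos = positive_clones(a, self.library)
            both = np.intersect1d(pos[1], pos[2])
            for nt in (1, 2):
                only = np.setdiff1d(pos[nt], both)
                for li in only:
                    rows.append((int(li), a.assay_id, f"allele{nt}"))
            for li in both:
                rows.append((int(li), a.assay_id, "both"))
        return pd.DataFrame(rows, columns=["linear_index", "assay_id",
                                           "call_class"])

    def truth_presence(self) -> pd.DataFrame:
        """All (region clone, assay) presences, independent of
        detectability — what exhaustive amplicon validation would find."""
        rows = []
        for a in self.assays:
            for sub, pos in (("A", a.pos_a), ("C", a.pos_c)):
                for li in self.library.clones_covering(sub, pos):
                    rows.append((int(li), a.assay_id, sub))
        return pd.DataFrame(rows, columns=["linear_index", "assay_id",
                                           "subgenome"])

    def region_clones(self) -> pd.DataFrame:
        """Clones overlapping at least one assay site, with subgenome."""
        pres = self.truth_presence()
        return (pres.groupby("linear_index")
                .agg(subgenome=("subgenome", "first"),
                     n_markers=("assay_id", "nunique"))
                .reset_index())
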