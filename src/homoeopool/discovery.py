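"""Discovery of intergenomic SNP assay sites from progenitor alignments.

Covers the alignment-region suitability filters (HSP length/identity with
off-target exclusion), the conservative assembly of survey-sequence
contigs (masking every column on which overlapping reads disagree), the
per-column assay-site rules on a pairwise alignment, and verification of
candidate sites in the amphidiploid subgenomes.

Alignment computation itself is injectable: real data enters as tabular
hits and gapped sequences, synthetic data as the simulator's recorded
alignment truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .simulate import Amphidiploid

logger = logging.getLogger(__name__)

DNA = set("ACGT")


# ---------------------------------------------------------------------------
# HSP filtering


@dataclass(frozen=True)
class Hsp:
    """A local alignment block (high-scoring segment pair).

    Spans are 0-based half-open on query and subject.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    length_bp: int
    identity_pct: float

    def in_region(self, region: Tuple[str, int, int]) -> bool:
        sid, start, end = region
        return (self.subject_id == sid
                and self.subject_start >= start and self.subject_end <= end)


def filter_hsps(hsps: Sequence[Hsp], target_region: Tuple[str, int, int],
                min_len: int = 500, min_id: float = 95.0,
                off_len: int = 150, off_id: float = 90.0) -> List[Hsp]:
    """Keep HSPs suitable for intergenomic SNP assay design.

    An HSP passes iff it spans at least ``min_len`` bp at >= ``min_id`` %
    identity, lies within the target region on the subject genome, and its
    query has no other hit of >= ``off_len`` bp at >= ``off_id`` %
    identity outside the target region (off-target exclusion).
    """
    off_target: Dict[str, bool] = {}
    for h in hsps:
        if (not h.in_region(target_region) and h.length_bp >= off_len
                and h.identity_pct >= off_id):
            off_target[h.query_id] = True
    return [h for h in hsps
            if h.length_bp >= min_len and h.identity_pct >= min_id
            and h.in_region(target_region)
            and not off_target.get(h.query_id, False)]


# ---------------------------------------------------------------------------
# GSS contig assembly


@dataclass
class GssContig:
    """A survey-sequence contig retaining only bases on which all covering
    reads agree; disagreements are masked with ``N``."""

    member_read_ids: List[str]
    consensus: str
    masked_positions: List[int] = field(default_factory=list)


def assemble_gss_contigs(reads: Dict[str, str],
                         overlaps: Iterable[Tuple[str, str, int]]
                         ) -> List[GssContig]:
    """Merge overlapping reads into contigs by identical-base retention.

    ``overlaps`` are coordinate offsets: ``(r1, r2, offset)`` places the
    start of ``r2`` at position ``offset`` of ``r1``.  An offset that
    implies no actual overlap, or offsets that disagree along different
    paths of the overlap graph, raise ``ValueError``.
    """
    adj: Dict[str, List[Tuple[str, int]]] = {r: [] for r in reads}
    for r1, r2, off in overlaps:
        if r1 not in reads or r2 not in reads:
            raise ValueError(f"overlap references unknown read ({r1}, {r2})")
        if off >= len(reads[r1]) or off + len(reads[r2]) <= 0:
            raise ValueError(
                f"offset {off} implies no overlap between {r1} and {r2}")
        adj[r1].append((r2, off))
        adj[r2].append((r1, -off))

    position: Dict[str, int] = {}
    contigs: List[GssContig] = []
    for root in reads:
        if root in position:
            continue
        comp = [root]
        position[root] = 0
        stack = [root]
        while stack:
            cur = stack.pop()
            for nxt, off in adj[cur]:
                want = position[cur] + off
                if nxt in position:
                    if position[nxt] != want:
                        raise ValueError(
                            f"inconsistent overlap offsets for read {nxt}")
                    continue
                position[nxt] = want
                comp.append(nxt)
                stack.append(nxt)
        base = min(position[r] for r in comp)
        span = max(position[r] + len(reads[r]) for r in comp) - base
        cols: List[set] = [set() for _ in range(span)]
        for r in comp:
            p0 = position[r] - base
            for i, ch in enumerate(reads[r]):
                cols[p0 + i].add(ch)
        consensus = []
        masked = []
        for i, col in enumerate(cols):
            if len(col) == 1:
                consensus.append(next(iter(col)))
            else:
                consensus.append("N")
                masked.append(i)
        contigs.append(GssContig(sorted(comp), "".join(consensus), masked))
    return contigs


# ---------------------------------------------------------------------------
# assay-site selection on a pairwise alignment


@dataclass
class AssayCandidate:
    """A candidate intergenomic SNP assay site on a pairwise alignment."""

    site_pos1: int
    site_pos2: int
    nucleotide_1: str
    nucleotide_2: str
    flank_left: str
    flank_right: str
    flank_identity_len: int
    designability: float
    uniqueness_ok: bool = True


def designability_surrogate(window_seq: str, homopolymer_min: int = 6,
                            gc_window: int = 21,
                            gc_range: Tuple[float, float] = (0.25, 0.75)
                            ) -> float:
    """Replaceable stand-in for a vendor oligo-designability score.

    Scores 1 minus the fraction of window bases that sit in a homopolymer
    run of >= ``homopolymer_min`` or in a ``gc_window``-base neighbourhood
    whose GC content falls outside ``gc_range``.
    """
    n = len(window_seq)
    if n == 0:
        return 0.0
    seq = np.frombuffer(window_seq.encode(), dtype="S1")
    bad = np.zeros(n, dtype=bool)
    run_start = 0
    for i in range(1, n + 1):
        if i == n or seq[i] != seq[run_start]:
            if i - run_start >= homopolymer_min:
                bad[run_start:i] = True
            run_start = i
    gc = np.isin(seq, [b"G", b"C"]).astype(float)
    half = gc_window // 2
    csum = np.concatenate([[0.0], np.cumsum(gc)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        frac = (csum[hi] - csum[lo]) / (hi - lo)
        if not (gc_range[0] <= frac <= gc_range[1]):
            bad[i] = True
    return 1.0 - bad.mean()


def find_assay_sites(aln1: str, aln2: str, flank_min: int = 20,
                     flank_max: int = 25, mismatch_clearance: int = 15,
                     window: int = 60,
                     designability_min: float = 0.6
                     ) -> List[AssayCandidate]:
    """Emit assay candidates at suitable substitution columns.

    A column qualifies when the two sequences differ by a substitution,
    no gap occurs within ``flank_max`` columns on either side, flanks are
    identical over at least ``flank_min`` bases, at most one mismatch
    falls within the ``flank_max`` windows and only at a distance greater
    than both ``mismatch_clearance`` and ``flank_min``, a full ``window``
    bases are extractable on each side of both sequences, and the
    designability surrogate exceeds ``designability_min``.
    """
    if len(aln1) != len(aln2):
        raise ValueError("aligned sequences must have equal length")
    a1 = np.frombuffer(aln1.upper().encode(), dtype="S1")
    a2 = np.frombuffer(aln2.upper().encode(), dtype="S1")
    n = len(a1)
    gap1 = a1 == b"-"
    gap2 = a2 == b"-"
    gap = gap1 | gap2
    mismatch = (a1 != a2) & ~gap
    pos1 = np.cumsum(~gap1) - 1
    pos2 = np.cumsum(~gap2) - 1
    seq1 = aln1.upper().replace("-", "")
    seq2 = aln2.upper().replace("-", "")

    out: List[AssayCandidate] = []
    for i in np.flatnonzero(mismatch):
        b1 = chr(a1[i][0]) if isinstance(a1[i], bytes) else a1[i].decode()
        b2 = a2[i].decode()
        if b1 not in DNA or b2 not in DNA:
            logger.info("skipping candidate at column %d: ambiguity code", i)
            continue
        lo = i - flank_max
        hi = i + flank_max + 1
        if lo < 0 or hi > n:
            continue
        if gap[lo:hi].any():
            continue
        dists = []
        ok = True
        for j in range(1, flank_max + 1):
            if mismatch[i - j]:
                dists.append(j)
            if mismatch[i + j]:
                dists.append(j)
        if len(dists) > 1:
            ok = False
        elif dists and (dists[0] <= mismatch_clearance
                        or dists[0] <= flank_min):
            ok = False
        if not ok:
            continue
        p1, p2 = int(pos1[i]), int(pos2[i])
        if (p1 < window or p1 + window >= len(seq1)
                or p2 < window or p2 + window >= len(seq2)):
            continue
        win = seq1[p1 - window:p1 + window + 1]
        score = designability_surrogate(win)
        if score <= designability_min:
            continue
        ident = dists[0] - 1 if dists else flank_max
        out.append(AssayCandidate(
            site_pos1=p1, site_pos2=p2, nucleotide_1=b1, nucleotide_2=b2,
            flank_left=seq1[p1 - window:p1], flank_right=seq1[p1 + 1:p1 + window + 1],
            flank_identity_len=ident, designability=score))
    return out


# ---------------------------------------------------------------------------
# verification in the amphidiploid


def verify_in_amphidiploid(candidate: AssayCandidate, amph: Amphidiploid,
                           footprint: int = 25) -> str:
    """Check a progenitor-derived candidate against the amphidiploid.

    Returns one of ``conserved`` (both alleles present, clean footprints),
    ``changed`` (site polymorphic with different alleles), ``monomorphic``
    (subgenome copies identical at the site), ``interfering`` (extra
    polymorphism within the oligonucleotide footprint of one subgenome) or
    ``unmappable``.
    """
    from .simulate import BASES

    p1, p2 = candidate.site_pos1, candidate.site_pos2
    if not (0 <= p1 < len(amph.sub_a) and 0 <= p2 < len(amph.sub_c)):
        return "unmappable"
    x = str(BASES[amph.sub_a[p1]])
    y = str(BASES[amph.sub_c[p2]])
    if x == y:
        return "monomorphic"
    if {x, y} != {candidate.nucleotide_1, candidate.nucleotide_2}:
        return "changed"
    for sub, prog, p in ((amph.sub_a, amph.pair.seq_a, p1),
                         (amph.sub_c, amph.pair.seq_c, p2)):
        lo = max(0, p - footprint)
        hi = min(len(sub), p + footprint + 1)
        diff = np.flatnonzero(sub[lo:hi] != prog[lo:hi]) + lo
        if len(np.setdiff1d(diff, [p])) > 0:
            return "interfering"
    return "conserved"
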