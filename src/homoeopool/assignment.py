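"""Assignment of assay nucleotides and clones to the A and C subgenomes.

Evidence from reference accessions of both progenitors, plus the
amphidiploid genotyping call and amplicon sequence, sorts every assay
into one of five categories:

1. both nucleotides consistently assigned by the progenitor panels;
2. one nucleotide's sources concordant, the other side conflicting (the
   concordant side fixes both assignments);
3. neither side concordant — assignments inferred from the subgenome
   labels of co-identified clones;
4. only one nucleotide detected in the amphidiploid (interfering
   polymorphism) — the detected nucleotide inferred from co-identified
   clones;
5. site monomorphic in the amphidiploid — no assignment is made.

Clones then receive the consensus subgenome of their category-1..4
scores; mixed implications are reported as conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

RAPA_SOURCES = ["rapa_acc1", "rapa_acc2", "rapa_wgs"]
OLERACEA_SOURCES = ["oleracea_acc1", "oleracea_acc2", "oleracea_wgs",
                    "oleracea_gss"]
MISSING = {"", "-", "nd", "na", None}


@dataclass
class AssayCategory:
    """Category and nucleotide-to-subgenome map of one assay.

    ``category`` is 1-5, or ``"pending3"`` / ``"pending4"`` before clone
    inference, or ``"unassigned"``.  ``nt_map`` maps nucleotide bases to
    "A"/"C"; categories 1-3 map both, 4 exactly one, 5 none.
    """

    assay_id: str
    category: object
    nt_map: Dict[str, str] = field(default_factory=dict)
    note: str = ""


def _informative(value: object) -> Optional[str]:
    """Single-base evidence value, or None for missing/heterozygous."""
    if value is None or not isinstance(value, str):
        return None
    v = value.strip().upper()
    if v in {m.upper() for m in MISSING if isinstance(m, str)} or v == "":
        return None
    if "/" in v or v not in set("ACGT"):
        return None
    return v


def _side_consensus(row: Mapping, sources: Sequence[str]) -> Optional[str]:
    """Consensus base of one progenitor's sources.

    Returns the base if all informative sources agree, ``"conflict"`` if
    they disagree, and ``None`` if no source is informative.
    """
    values = {v for v in (_informative(row.get(s)) for s in sources)
              if v is not None}
    if not values:
        return None
    if len(values) == 1:
        return values.pop()
    return "conflict"


def _express_alleles(value: object) -> List[str]:
    if not isinstance(value, str):
        return []
    v = value.strip().upper()
    if v in ("", "UNREADABLE", "ND", "-"):
        return []
    parts = [p for p in v.split("/") if p in set("ACGT")]
    return parts


def classify_assay(row: Mapping,
                   alignment_only: Optional[Dict[str, str]] = None
                   ) -> AssayCategory:
    """Pre-inference classification of one assay's evidence row.

    ``row`` carries the evidence sources (``rapa_acc1`` ... ``express_call``,
    ``express_amplicon``); ``alignment_only`` optionally maps nucleotides
    directly for assays whose genotyping data are unusable.
    """
    aid = row["assay_id"] if "assay_id" in row else "?"
    express = _express_alleles(row.get("express_call"))
    amplicon = _express_alleles(row.get("express_amplicon"))

    if not express:
        if alignment_only:
            return AssayCategory(aid, "unassigned", dict(alignment_only),
                                 note="alignment-only assignment")
        return AssayCategory(aid, "unassigned",
                             note="no usable amphidiploid call")

    if len(express) == 1:
        if len(amplicon) == 1:
            # subgenome copies identical in the assayed region
            return AssayCategory(aid, 5)
        return AssayCategory(aid, "pending4")

    allele_set = set(express)
    rapa = _side_consensus(row, RAPA_SOURCES)
    oler = _side_consensus(row, OLERACEA_SOURCES)
    rapa_base = rapa if rapa not in (None, "conflict") else None
    oler_base = oler if oler not in (None, "conflict") else None

    if rapa_base and oler_base:
        if rapa_base == oler_base:
            return AssayCategory(
                aid, "unassigned",
                note="both progenitors claim the same nucleotide")
        if rapa_base in allele_set and oler_base in allele_set:
            return AssayCategory(aid, 1,
                                 {rapa_base: "A", oler_base: "C"})
        return AssayCategory(aid, "unassigned",
                             note="progenitor nucleotides do not match "
                                  "the amphidiploid call")
    if rapa_base and rapa_base in allele_set:
        other = (allele_set - {rapa_base}).pop()
        return AssayCategory(aid, 2, {rapa_base: "A", other: "C"})
    if oler_base and oler_base in allele_set:
        other = (allele_set - {oler_base}).pop()
        return AssayCategory(aid, 2, {other: "A", oler_base: "C"})
    return AssayCategory(aid, "pending3")


def classify_panel(evidence: pd.DataFrame,
                   alignment_only: Optional[Dict[str, Dict[str, str]]] = None
                   ) -> List[AssayCategory]:
    alignment_only = alignment_only or {}
    return [classify_assay(row, alignment_only.get(row["assay_id"]))
            for _, row in evidence.iterrows()]


# ---------------------------------------------------------------------------
# inference from co-identified clones


def _clone_labels_from(categories: Sequence[AssayCategory],
                       score_table: pd.DataFrame,
                       assay_alleles: Mapping[str, Dict[str, str]],
                       use_categories=(1, 2)) -> Dict[int, str]:
    """Unanimous subgenome labels of clones from selected categories."""
    nt_maps = {c.assay_id: c.nt_map for c in categories
               if c.category in use_categories}
    votes: Dict[int, set] = {}
    for li, aid, cls in score_table[
            ["linear_index", "assay_id", "call_class"]].itertuples(index=False):
        if aid not in nt_maps or cls == "both":
            continue
        base = assay_alleles[aid].get(cls)
        sub = nt_maps[aid].get(base)
        if sub:
            votes.setdefault(li, set()).add(sub)
    return {li: v.pop() for li, v in votes.items() if len(v) == 1}


def infer_pending(categories: Sequence[AssayCategory],
                  score_table: pd.DataFrame,
                  assay_alleles: Mapping[str, Dict[str, str]],
                  quorum: float = 0.8, min_informative: int = 3
                  ) -> List[AssayCategory]:
    """Resolve pending assays from clones co-identified by category-1/2
    markers.

    ``assay_alleles`` maps assay id -> {"allele1": base, "allele2": base}.
    For each pending assay and nucleotide, the subgenome labels of the
    clones that nucleotide identified are tallied; the majority subgenome
    is assigned when its fraction reaches ``quorum`` over at least
    ``min_informative`` labelled clones.  Category-1/2/5 assignments are
    never altered; the function is idempotent.
    """
    labels = _clone_labels_from(categories, score_table, assay_alleles)
    out: List[AssayCategory] = []
    for cat in categories:
        if cat.category not in ("pending3", "pending4"):
            out.append(cat)
            continue
        sub_for: Dict[str, str] = {}
        scores = score_table[score_table.assay_id == cat.assay_id]
        for cls in ("allele1", "allele2"):
            clones = scores.loc[scores.call_class == cls, "linear_index"]
            tally: Dict[str, int] = {}
            for li in clones:
                lab = labels.get(li)
                if lab:
                    tally[lab] = tally.get(lab, 0) + 1
            total = sum(tally.values())
            if total >= min_informative:
                sub, n = max(tally.items(), key=lambda kv: kv[1])
                if n / total >= quorum:
                    base = assay_alleles[cat.assay_id][cls]
                    sub_for[base] = sub
        if cat.category == "pending3":
            if (len(sub_for) == 2
                    and len(set(sub_for.values())) == 2):
                out.append(AssayCategory(cat.assay_id, 3, sub_for))
            else:
                out.append(AssayCategory(cat.assay_id, "unassigned",
                                         note="clone inference inconclusive"))
        else:
            if len(sub_for) == 1:
                out.append(AssayCategory(cat.assay_id, 4, sub_for))
            else:
                out.append(AssayCategory(cat.assay_id, "unassigned",
                                         note="clone inference inconclusive"))
    return out


# ---------------------------------------------------------------------------
# clone assignment


def assign_clones(score_table: pd.DataFrame,
                  categories: Sequence[AssayCategory],
                  assay_alleles: Mapping[str, Dict[str, str]]
                  ) -> pd.DataFrame:
    """Per-clone subgenome labels with a conflict report.

    Every category-1..4 score implies a subgenome for its clone through
    the assay's nucleotide map; category-5 scores and ambiguous (``both``)
    scores never contribute.  Returns one row per scored clone with the
    vote counts, the consensus label (``None`` on a tie) and a conflict
    flag for mixed implications.
    """
    nt_maps = {c.assay_id: c.nt_map for c in categories
               if c.category in (1, 2, 3, 4)}
    rows: Dict[int, Dict[str, int]] = {}
    for li, aid, cls in score_table[
            ["linear_index", "assay_id", "call_class"]].itertuples(index=False):
        rows.setdefault(li, {"A": 0, "C": 0})
        if aid not in nt_maps or cls == "both":
            continue
        base = assay_alleles[aid].get(cls)
        sub = nt_maps[aid].get(base)
        if sub:
            rows[li][sub] += 1
    out = []
    for li, v in rows.items():
        total = v["A"] + v["C"]
        if v["A"] > v["C"]:
            label = "A"
        elif v["C"] > v["A"]:
            label = "C"
        else:
            label = None
        out.append((li, v["A"], v["C"], total, label,
                    v["A"] > 0 and v["C"] > 0))
    df = pd.DataFrame(out, columns=["linear_index", "votes_A", "votes_C",
                                    "n_votes", "subgenome", "conflict"])
    return df.sort_values("linear_index").reset_index(drop=True)


def conflict_rate(labels: pd.DataFrame, min_votes: int = 2) -> float:
    """Fraction of clones with >= ``min_votes`` implied-subgenome votes
    that show mixed implications."""
    multi = labels[labels.n_votes >= min_votes]
    if len(multi) == 0:
        return 0.0
    return float(multi.conflict.mean())
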