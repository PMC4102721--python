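"""Decoding positive pools into putative clone coordinates.

A coordinate is reported for assay nucleotide k iff all seven of its
pools are positive for k, where a pool is positive for k when its call is
``allele-k`` or ``both`` (a pool holding clones of both subgenomes elicits
both fluorescences).  Coordinates satisfying the rule for both nucleotides
are flagged ambiguous and emitted once with class ``both``.

The optimised decoder intersects per-dimension candidate sets via the
precomputed membership matrix; :func:`decode_exhaustive` recomputes every
coordinate's pools arithmetically and serves as the definitional oracle.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .pooling import PoolingDesign

SCORE_COLUMNS = ["linear_index", "assay_id", "call_class"]


def _positive_masks(calls: pd.DataFrame, design: PoolingDesign
                    ) -> Tuple[np.ndarray, np.ndarray]:
    pools = calls["pool"].to_numpy()
    if pools.size and (pools.min() < 0 or pools.max() >= design.n_pools):
        bad = pools[(pools < 0) | (pools >= design.n_pools)][0]
        raise ValueError(f"call references unknown pool {bad}")
    call = calls["call"].to_numpy()
    pos1 = np.zeros(design.n_pools, dtype=bool)
    pos2 = np.zeros(design.n_pools, dtype=bool)
    pos1[pools[(call == "allele1") | (call == "both")]] = True
    pos2[pools[(call == "allele2") | (call == "both")]] = True
    return pos1, pos2


def decode(assay_calls: pd.DataFrame, design: PoolingDesign
           ) -> Dict[str, np.ndarray]:
    """Decode one assay's pool calls into per-nucleotide coordinate sets.

    Returns ``{"allele1": idx, "allele2": idx, "ambiguous": idx}`` of
    linear coordinate indices; the per-nucleotide sets include the
    ambiguous coordinates.
    """
    pos1, pos2 = _positive_masks(assay_calls, design)
    M = design.membership
    hit1 = pos1[M].all(axis=1)
    hit2 = pos2[M].all(axis=1)
    return {
        "allele1": np.flatnonzero(hit1),
        "allele2": np.flatnonzero(hit2),
        "ambiguous": np.flatnonzero(hit1 & hit2),
    }


def decode_exhaustive(assay_calls: pd.DataFrame, design: PoolingDesign
                      ) -> Dict[str, np.ndarray]:
    """Definitional oracle: evaluate every library coordinate one by one."""
    pos1, pos2 = _positive_masks(assay_calls, design)
    hits1: List[int] = []
    hits2: List[int] = []
    rows, cols = design.rows, design.cols
    i = 0
    for plate in range(design.n_plates):
        for row in range(rows):
            for col in range(cols):
                pools = design.pools_of_scalar(plate, row, col)
                if all(pos1[p] for p in pools):
                    hits1.append(i)
                if all(pos2[p] for p in pools):
                    hits2.append(i)
                i += 1
    h1 = np.asarray(hits1, dtype=np.int64)
    h2 = np.asarray(hits2, dtype=np.int64)
    return {"allele1": h1, "allele2": h2,
            "ambiguous": np.intersect1d(h1, h2)}


def score_rows(assay_id: str, decoded: Dict[str, np.ndarray]) -> pd.DataFrame:
    amb = set(decoded["ambiguous"].tolist())
    rows = []
    for li in decoded["allele1"]:
        if int(li) not in amb:
            rows.append((int(li), assay_id, "allele1"))
    for li in decoded["allele2"]:
        if int(li) not in amb:
            rows.append((int(li), assay_id, "allele2"))
    for li in sorted(amb):
        rows.append((int(li), assay_id, "both"))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def screen_all(calls: pd.DataFrame, design: PoolingDesign,
               assay_ids: Iterable[str] | None = None
               ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Decode every assay and aggregate a score table plus hit counts.

    Returns ``(score_table, per_assay)`` where ``per_assay`` mirrors a
    library-screen summary table: total putative clones and counts per
    assay nucleotide (ambiguous coordinates counted once in the total).
    """
    if assay_ids is None:
        assay_ids = list(pd.unique(calls["assay_id"]))
    frames = []
    summary = []
    for aid in assay_ids:
        decoded = decode(calls[calls["assay_id"] == aid], design)
        frames.append(score_rows(aid, decoded))
        n1 = len(decoded["allele1"])
        n2 = len(decoded["allele2"])
        namb = len(decoded["ambiguous"])
        summary.append((aid, n1 + n2 - namb, n1, n2, namb))
    score_table = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame(columns=SCORE_COLUMNS))
    per_assay = pd.DataFrame(
        summary, columns=["assay_id", "n_clones", "n_allele1", "n_allele2",
                          "n_ambiguous"])
    return score_table, per_assay
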