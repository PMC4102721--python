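"""Clone selection, validation, contig assembly, refinement and bridging.

Putative clones from the screen are selected for validation by three
criteria (A: enough independent assay scores; B: two scores well
separated in marker order; C: the block of markers at a region end),
checked clone-by-clone against a validation oracle (amplicon analysis),
assembled per subgenome into contigs connected by shared confirmed
markers, refined by testing predicted-but-unscored markers (recovering
false negatives), and finally bridged across gaps by re-examining
unselected candidates scored near contig ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd


class MarkerOrder:
    """Assay order along the reference progenitor genome."""

    def __init__(self, assay_ids: Sequence[str]):
        self.ids = list(assay_ids)
        self.position = {aid: i for i, aid in enumerate(self.ids)}
        if len(self.position) != len(self.ids):
            raise ValueError("duplicate assay ids in marker order")

    def __len__(self) -> int:
        return len(self.ids)

    def separation(self, a: str, b: str) -> int:
        """Number of markers between two assays."""
        return abs(self.position[a] - self.position[b]) - 1

    def end_blocks(self, count: int) -> Tuple[Set[str], Set[str]]:
        return set(self.ids[:count]), set(self.ids[-count:])


# ---------------------------------------------------------------------------
# selection


@dataclass
class SelectionParams:
    min_assays: int = 4
    promiscuity_limit: int = 3000
    separation_min: int = 2
    end_marker_count: int = 3


def select_candidates(score_table: pd.DataFrame, marker_order: MarkerOrder,
                      params: SelectionParams = SelectionParams()
                      ) -> pd.DataFrame:
    """Select putative clones for validation.

    Criterion A: scored by >= ``min_assays`` distinct assays, not counting
    assays whose total hit count exceeds ``promiscuity_limit``.
    Criterion B (clones failing A): two countable scores separated by at
    least ``separation_min`` intervening markers.  Criterion C: scored by
    all ``end_marker_count`` markers at one end of the region.  Returns
    one row per selected clone with boolean provenance labels and the
    primary criterion (first met in A > B > C order).
    """
    per_assay = score_table.groupby("assay_id").size()
    promiscuous = set(per_assay[per_assay > params.promiscuity_limit].index)
    first_block, last_block = marker_order.end_blocks(params.end_marker_count)

    rows = []
    for li, grp in score_table.groupby("linear_index"):
        assays = set(grp.assay_id)
        countable = assays - promiscuous
        positions = sorted(marker_order.position[a] for a in countable)
        crit_a = len(countable) >= params.min_assays
        crit_b = (len(positions) >= 2
                  and positions[-1] - positions[0] - 1 >= params.separation_min)
        crit_c = first_block <= countable or last_block <= countable
        if crit_a or (crit_b and not crit_a) or crit_c:
            primary = "A" if crit_a else ("B" if crit_b else "C")
            rows.append((li, crit_a, crit_b and not crit_a, crit_c, primary,
                         len(countable)))
    return pd.DataFrame(rows, columns=["linear_index", "criterion_a",
                                       "criterion_b", "criterion_c",
                                       "primary", "n_countable"])


# ---------------------------------------------------------------------------
# validation


def validate(selected: Iterable[int], score_table: pd.DataFrame, oracle
             ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Check every score of the selected clones against the oracle.

    Returns ``(records, confirmed, false_positives)``.  Untestable
    amplicon results neither confirm nor refute a score and are excluded
    from the false-positive denominator.
    """
    selected = set(int(s) for s in selected)
    sub = score_table[score_table.linear_index.isin(selected)]
    records = []
    for li, aid, cls in sub[["linear_index", "assay_id",
                             "call_class"]].itertuples(index=False):
        outcome, subgenome = oracle.test(int(li), aid)
        records.append((int(li), aid, cls, outcome, subgenome))
    rec = pd.DataFrame(records, columns=["linear_index", "assay_id",
                                         "call_class", "outcome",
                                         "subgenome"])
    confirmed = rec[rec.outcome == "present"].copy()
    false_pos = rec[rec.outcome == "absent"].copy()
    return rec, confirmed, false_pos


# ---------------------------------------------------------------------------
# contigs


@dataclass
class Contig:
    """An ordered set of confirmed clones covering a marker interval."""

    subgenome: str
    clone_markers: Dict[int, Set[int]]   # linear_index -> marker positions
    contig_id: str = ""
    untestable_markers: Dict[int, Set[int]] = field(default_factory=dict)

    @property
    def members(self) -> List[int]:
        def key(li):
            ms = self.clone_markers[li]
            return (min(ms), max(ms), li)
        return sorted(self.clone_markers, key=key)

    @property
    def marker_set(self) -> Set[int]:
        out: Set[int] = set()
        for ms in self.clone_markers.values():
            out |= ms
        return out

    @property
    def span(self) -> Tuple[int, int]:
        ms = self.marker_set
        return (min(ms), max(ms))


def _connected_contigs(subgenome: str,
                       clone_markers: Dict[int, Set[int]]) -> List[Contig]:
    """Connected components under the shared-confirmed-marker relation."""
    parent = {li: li for li in clone_markers}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    by_marker: Dict[int, List[int]] = {}
    for li, ms in clone_markers.items():
        for m in ms:
            by_marker.setdefault(m, []).append(li)
    for clones in by_marker.values():
        for other in clones[1:]:
            union(clones[0], other)

    groups: Dict[int, Dict[int, Set[int]]] = {}
    for li in clone_markers:
        groups.setdefault(find(li), {})[li] = set(clone_markers[li])
    contigs = [Contig(subgenome, g) for g in groups.values()]
    contigs.sort(key=lambda c: c.span)
    for i, c in enumerate(contigs):
        c.contig_id = f"{subgenome}-{i + 1}"
    return contigs


def build_contigs(confirmed: pd.DataFrame, marker_order: MarkerOrder,
                  clone_subgenomes: Mapping[int, str]
                  ) -> Tuple[Dict[str, List[Contig]], pd.DataFrame]:
    """Assemble per-subgenome contigs from confirmed scores.

    Clones with no confirmed marker are dropped (logged in the violation
    report); clones whose confirmed markers skip internal markers are
    reported as marker-order violations for refinement to resolve.
    """
    per_sub: Dict[str, Dict[int, Set[int]]] = {}
    violations = []
    for li, grp in confirmed.groupby("linear_index"):
        sub = clone_subgenomes.get(int(li))
        if sub not in ("A", "C"):
            continue
        markers = {marker_order.position[a] for a in grp.assay_id}
        if not markers:
            continue
        per_sub.setdefault(sub, {})[int(li)] = markers
        if max(markers) - min(markers) + 1 != len(markers):
            missing = sorted(set(range(min(markers), max(markers) + 1))
                             - markers)
            violations.append((int(li), sub, str(missing)))
    contigs = {sub: _connected_contigs(sub, cm)
               for sub, cm in per_sub.items()}
    report = pd.DataFrame(violations, columns=["linear_index", "subgenome",
                                               "skipped_markers"])
    return contigs, report


# ---------------------------------------------------------------------------
# refinement


def _refine_clone(li: int, markers: Set[int], untestable: Set[int],
                  subgenome: str, marker_order: MarkerOrder, oracle,
                  tested: Dict[Tuple[int, int], str]) -> List[int]:
    """Fixed-point refinement of one clone: interior markers first, then
    end extension.  Returns the positions newly confirmed."""

    def test(pos: int) -> str:
        key = (li, pos)
        if key not in tested:
            outcome, _ = oracle.test(li, marker_order.ids[pos])
            tested[key] = outcome
        return tested[key]

    recovered = []
    while True:
        grew = False
        lo, hi = min(markers), max(markers)
        for pos in range(lo + 1, hi):
            if pos in markers or pos in untestable:
                continue
            outcome = test(pos)
            if outcome == "present":
                markers.add(pos)
                recovered.append(pos)
            elif outcome == "untestable":
                untestable.add(pos)
        for pos in (lo - 1, hi + 1):
            while 0 <= pos < len(marker_order):
                outcome = test(pos)
                if outcome == "present":
                    markers.add(pos)
                    recovered.append(pos)
                    grew = True
                    pos += -1 if pos < lo else 1
                elif outcome == "untestable":
                    untestable.add(pos)
                    pos += -1 if pos < lo else 1
                else:
                    break
        if not grew:
            break
    return recovered


def refine_contigs(contigs: Dict[str, List[Contig]],
                   marker_order: MarkerOrder, oracle
                   ) -> Tuple[Dict[str, List[Contig]], pd.DataFrame]:
    """Establish the full extent of every clone with the oracle.

    Tests markers interior to each clone's confirmed interval and markers
    adjacent to its ends until no interval grows; every recovered
    presence is a false-negative score of the original screen.
    Connectivity is rebuilt afterwards (recoveries may merge contigs).
    """
    fn_rows = []
    refined: Dict[str, List[Contig]] = {}
    tested: Dict[Tuple[int, int], str] = {}
    for sub, contig_list in contigs.items():
        merged_markers: Dict[int, Set[int]] = {}
        for contig in contig_list:
            for li, markers in contig.clone_markers.items():
                markers = set(markers)
                untestable = set(contig.untestable_markers.get(li, set()))
                for pos in _refine_clone(li, markers, untestable, sub,
                                         marker_order, oracle, tested):
                    fn_rows.append((li, marker_order.ids[pos], sub))
                merged_markers[li] = markers
        refined[sub] = _connected_contigs(sub, merged_markers)
    fns = pd.DataFrame(fn_rows, columns=["linear_index", "assay_id",
                                         "subgenome"])
    return refined, fns


# ---------------------------------------------------------------------------
# bridging


def bridge_contigs(contigs: Dict[str, List[Contig]],
                   score_table: pd.DataFrame, marker_order: MarkerOrder,
                   oracle, clone_subgenomes: Mapping[int, str],
                   end_marker_window: int = 3
                   ) -> Tuple[Dict[str, List[Contig]], pd.DataFrame]:
    """Link and extend contigs through additional putative clones.

    Putative clones that were not validated before but are scored by
    markers within ``end_marker_window`` of a contig end (a gap-facing
    end or the outer end of a contig) are tested with the oracle.  A
    confirmed clone sharing markers with two contigs merges them; a
    confirmed clone sharing markers with one contig extends it.
    Unbridged gaps are reported with their marker interval and whether
    candidates existed.
    """
    report = []
    out: Dict[str, List[Contig]] = {}
    tested: Dict[Tuple[int, int], str] = {}
    score_pos = score_table.assign(
        pos=score_table.assay_id.map(marker_order.position))

    def confirm_candidate(sub, li, positions) -> Set[int]:
        confirmed: Set[int] = set()
        for pos in sorted(positions):
            key = (li, pos)
            if key not in tested:
                outcome, osub = oracle.test(li, marker_order.ids[pos])
                tested[key] = outcome if osub in (None, sub) else "absent"
            if tested[key] == "present":
                confirmed.add(pos)
        if confirmed:
            _refine_clone(li, confirmed, set(), sub, marker_order, oracle,
                          tested)
        return confirmed

    for sub, contig_list in contigs.items():
        contig_list = sorted(contig_list, key=lambda c: c.span)
        members = set()
        clone_markers: Dict[int, Set[int]] = {}
        for c in contig_list:
            members |= set(c.clone_markers)
            clone_markers.update({li: set(ms)
                                  for li, ms in c.clone_markers.items()})
        # gap bridging between consecutive contigs
        for left, right in zip(contig_list, contig_list[1:]):
            gap_lo = left.span[1]
            gap_hi = right.span[0]
            window_pos = set(range(gap_lo - end_marker_window + 1,
                                   gap_lo + end_marker_window + 1))
            window_pos |= set(range(gap_hi - end_marker_window,
                                    gap_hi + end_marker_window))
            cand = score_pos[score_pos.pos.isin(window_pos)
                             & ~score_pos.linear_index.isin(members)]
            cand_ids = sorted(set(int(i) for i in cand.linear_index))
            bridge_clone = None
            for li in cand_ids:
                confirmed = confirm_candidate(
                    sub, li, set(cand.loc[cand.linear_index == li, "pos"]))
                if not confirmed:
                    continue
                if (confirmed & left.marker_set
                        and confirmed & right.marker_set):
                    bridge_clone = li
                    clone_markers[li] = confirmed
                    members.add(li)
                    break
                # not a bridge, but a confirmed extension of one contig
                if confirmed & (left.marker_set | right.marker_set):
                    clone_markers[li] = confirmed
                    members.add(li)
            report.append((sub, left.contig_id, right.contig_id,
                           gap_lo, gap_hi, len(cand_ids),
                           bridge_clone is not None, bridge_clone))
        # outer-end extension of every contig
        for contig in contig_list:
            lo, hi = contig.span
            window_pos = set(range(lo, lo + end_marker_window))
            window_pos |= set(range(hi - end_marker_window + 1, hi + 1))
            cand = score_pos[score_pos.pos.isin(window_pos)
                             & ~score_pos.linear_index.isin(members)]
            for li in sorted(set(int(i) for i in cand.linear_index)):
                confirmed = confirm_candidate(
                    sub, li, set(cand.loc[cand.linear_index == li, "pos"]))
                if confirmed & contig.marker_set:
                    clone_markers[li] = confirmed
                    members.add(li)
        out[sub] = _connected_contigs(sub, clone_markers)
    rep = pd.DataFrame(report, columns=["subgenome", "left", "right",
                                        "gap_from", "gap_to", "n_candidates",
                                        "bridged", "bridge_clone"])
    return out, rep
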