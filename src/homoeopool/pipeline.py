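"""End-to-end screening pipeline on a synthetic experiment.

Chains signal calling, seven-dimension deconvolution, evidence
classification and clone-based inference, subgenome assignment, clone
selection, oracle validation, contig building, false-negative recovery
and contig bridging, and compares every stage against the retained ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .assignment import (AssayCategory, assign_clones, classify_panel,
                         conflict_rate, infer_pending)
from .calling import CallingParams, call_table
from .config import SimulationConfig
from .contigs import (Contig, MarkerOrder, SelectionParams, bridge_contigs,
                      build_contigs, refine_contigs, select_candidates,
                      validate, _connected_contigs)
from .deconvolution import screen_all
from .reporting import summarize_screen
from .simulate import Simulation


@dataclass
class PipelineResult:
    sim: Simulation
    calls: pd.DataFrame
    score_table: pd.DataFrame
    per_assay: pd.DataFrame
    categories: List[AssayCategory]
    clone_labels: pd.DataFrame
    marker_order: MarkerOrder
    selected: pd.DataFrame
    validation: pd.DataFrame
    confirmed: pd.DataFrame
    false_positives: pd.DataFrame
    contigs_initial: Dict[str, List[Contig]]
    order_violations: pd.DataFrame
    contigs_refined: Dict[str, List[Contig]]
    false_negatives: pd.DataFrame
    contigs_final: Dict[str, List[Contig]]
    bridge_report: pd.DataFrame
    metrics: Dict[str, float] = field(default_factory=dict)


def assay_allele_map(sim: Simulation) -> Dict[str, Dict[str, str]]:
    return {a.assay_id: {"allele1": a.allele1, "allele2": a.allele2}
            for a in sim.assays}


def run_pipeline(sim: Simulation,
                 calling_params: CallingParams = CallingParams(),
                 selection_params: SelectionParams = SelectionParams(),
                 quorum: float = 0.8, min_informative: int = 3,
                 end_marker_window: int = 3) -> PipelineResult:
    """Run the full screen-to-contig pipeline and score it against truth."""
    calls = call_table(sim.signals, calling_params)
    assay_ids = [a.assay_id for a in sim.assays]
    score_table, per_assay = screen_all(calls, sim.design, assay_ids)

    alleles = assay_allele_map(sim)
    categories = classify_panel(sim.evidence)
    categories = infer_pending(categories, score_table, alleles,
                               quorum=quorum, min_informative=min_informative)
    clone_labels = assign_clones(score_table, categories, alleles)

    marker_order = MarkerOrder(
        [a.assay_id for a in sorted(sim.assays, key=lambda x: x.order_index)])
    selected = select_candidates(score_table, marker_order, selection_params)
    validation, confirmed, false_pos = validate(
        selected.linear_index, score_table, sim.oracle)

    label_map = dict(zip(clone_labels.linear_index, clone_labels.subgenome))
    for li, grp in confirmed.groupby("linear_index"):
        subs = set(grp.subgenome)
        if len(subs) == 1:
            label_map[int(li)] = subs.pop()

    contigs0, violations = build_contigs(confirmed, marker_order, label_map)
    contigs1, fns = refine_contigs(contigs0, marker_order, sim.oracle)
    contigs2, bridge_rep = bridge_contigs(
        contigs1, score_table, marker_order, sim.oracle, label_map,
        end_marker_window=end_marker_window)

    result = PipelineResult(
        sim, calls, score_table, per_assay, categories, clone_labels,
        marker_order, selected, validation, confirmed, false_pos,
        contigs0, violations, contigs1, fns, contigs2, bridge_rep)
    result.metrics = compute_metrics(result)
    return result


# ---------------------------------------------------------------------------
# truth comparison


def true_tiling(sim: Simulation, marker_order: MarkerOrder
                ) -> Dict[str, List[Contig]]:
    """Contigs implied by the ground truth clone/marker presences."""
    presence = sim.truth_presence()
    out: Dict[str, List[Contig]] = {}
    for sub, grp in presence.groupby("subgenome"):
        clone_markers = {
            int(li): {marker_order.position[a] for a in g.assay_id}
            for li, g in grp.groupby("linear_index")}
        out[sub] = _connected_contigs(sub, clone_markers)
    return out


def compute_metrics(result: PipelineResult) -> Dict[str, float]:
    sim = result.sim
    mo = result.marker_order

    truth = sim.truth_scores()
    truth_keys = set(zip(truth.linear_index, truth.assay_id))
    decoded_keys = set(zip(result.score_table.linear_index,
                           result.score_table.assay_id))
    n_truth = len(truth_keys)
    recovered = len(truth_keys & decoded_keys)
    fn_fraction = 1.0 - recovered / n_truth if n_truth else 0.0

    cls_truth = {a.assay_id: a.category_true for a in sim.assays}
    cat_ok = sum(1 for c in result.categories
                 if c.category == cls_truth[c.assay_id])
    cat_acc = cat_ok / len(result.categories)

    conf_rate = conflict_rate(result.clone_labels)

    masked = sim.oracle.masked
    presence = sim.truth_presence()
    testable = presence[[
        not (aid in masked and masked[aid] != sub)
        for aid, sub in zip(presence.assay_id, presence.subgenome)]]
    want = set((int(li), mo.position[aid])
               for li, aid in zip(testable.linear_index, testable.assay_id))
    got = set()
    for sub, contig_list in result.contigs_final.items():
        for c in contig_list:
            for li, ms in c.clone_markers.items():
                got |= {(li, m) for m in ms}
    tiling_recall = len(want & got) / len(want) if want else 1.0

    tt = true_tiling(sim, mo)
    metrics = {
        "n_scores": float(len(result.score_table)),
        "n_putative_clones": float(
            result.score_table.linear_index.nunique()),
        "n_truth_scores": float(n_truth),
        "fn_score_fraction": fn_fraction,
        "category_accuracy": cat_acc,
        "conflict_rate": conf_rate,
        "n_selected": float(len(result.selected)),
        "n_false_positive_scores": float(len(result.false_positives)),
        "n_recovered_false_negatives": float(len(result.false_negatives)),
        "tiling_recall": tiling_recall,
    }
    for sub in ("A", "C"):
        metrics[f"n_contigs_{sub}"] = float(
            len(result.contigs_final.get(sub, [])))
        metrics[f"n_true_contigs_{sub}"] = float(len(tt.get(sub, [])))
        metrics[f"n_confirmed_clones_{sub}"] = float(sum(
            len(c.clone_markers)
            for c in result.contigs_final.get(sub, [])))
    return metrics


# ---------------------------------------------------------------------------
# noise-propagation estimators (independent of the pipeline code path)


def expected_fn_fraction(dropout_prob: float, flip_prob: float = 0.0,
                         n_dims: int = 7) -> float:
    """Expected fraction of truth scores lost to pool noise.

    A coordinate requires a usable positive call in every screening
    dimension; each of its pools independently drops out or flips to the
    wrong nucleotide.  (Flips of pools containing both nucleotides are
    harmless; the estimate ignores this second-order effect.)
    """
    survive = (1.0 - dropout_prob) * (1.0 - flip_prob)
    return 1.0 - survive ** n_dims


def monte_carlo_conflict_rate(sim: Simulation, n_rep: int = 5,
                              seed: int = 12345,
                              min_votes: int = 2) -> Dict[str, float]:
    """Direct noise-propagation estimate of the subgenome-conflict rate.

    Replays dropout/flip noise on the ideal pool-call truth, decodes with
    the membership matrix, and labels clones with the *true*
    nucleotide-to-subgenome maps — bypassing signal synthesis, evidence
    classification and category inference.  Returns the mean conflict
    rate among clones with >= ``min_votes`` subgenome votes and a
    binomial standard error.
    """
    rng = np.random.default_rng(seed)
    design = sim.design
    noise = sim.config.noise
    sub_of = {}   # (assay_id, call_class) -> implied subgenome
    for a in sim.assays:
        if a.category_true == 5:
            continue
        if a.channel_a:
            sub_of[(a.assay_id, f"allele{a.channel_a}")] = "A"
        if a.channel_c:
            sub_of[(a.assay_id, f"allele{a.channel_c}")] = "C"

    rates = []
    totals = []
    for _ in range(n_rep):
        votes: Dict[int, Dict[str, int]] = {}
        for aid, grp in sim.pool_truth.groupby("assay_id"):
            call = grp.true_call.to_numpy().copy()
            pools = grp.pool.to_numpy()
            positive = call != "negative"
            flip = positive & (rng.random(len(call))
                               < noise.nucleotide_flip_prob)
            swap1 = flip & (call == "allele1")
            swap2 = flip & (call == "allele2")
            call[swap1] = "allele2"
            call[swap2] = "allele1"
            drop = positive & (rng.random(len(call))
                               < noise.pool_dropout_prob)
            call[drop] = "negative"
            pos1 = np.zeros(design.n_pools, dtype=bool)
            pos2 = np.zeros(design.n_pools, dtype=bool)
            pos1[pools[(call == "allele1") | (call == "both")]] = True
            pos2[pools[(call == "allele2") | (call == "both")]] = True
            M = design.membership
            hit1 = pos1[M].all(axis=1)
            hit2 = pos2[M].all(axis=1)
            amb = hit1 & hit2
            for nt, hits in (("allele1", hit1 & ~amb), ("allele2",
                                                        hit2 & ~amb)):
                sub = sub_of.get((aid, nt))
                if sub is None:
                    continue
                for li in np.flatnonzero(hits):
                    v = votes.setdefault(int(li), {"A": 0, "C": 0})
                    v[sub] += 1
        multi = [v for v in votes.values()
                 if v["A"] + v["C"] >= min_votes]
        n_conf = sum(1 for v in multi if v["A"] > 0 and v["C"] > 0)
        rates.append(n_conf / len(multi) if multi else 0.0)
        totals.append(len(multi))
    mean = float(np.mean(rates))
    n_eff = float(np.mean(totals)) * n_rep
    se = float(np.sqrt(max(mean * (1 - mean), 1e-12) / max(n_eff, 1.0)))
    return {"rate": mean, "se": se, "n_multi": float(np.mean(totals))}


def run_default(seed: int = 0,
                config: Optional[SimulationConfig] = None) -> PipelineResult:
    """Generate a default-scale experiment and run the full pipeline."""
    cfg = config or SimulationConfig(seed=seed)
    if config is not None:
        cfg.seed = seed
    sim = Simulation.generate(cfg)
    return run_pipeline(sim)


def screen_summary(result: PipelineResult):
    return summarize_screen(result.score_table)
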