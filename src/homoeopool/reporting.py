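"""Screen summary statistics, printed-precision rendering and fixture checks.

The multiplicity histogram (how many clones were identified by exactly k
assays) and its identities tie the per-assay hit counts to the distinct
clone count: sum(n_k) equals the number of distinct clones and
sum(k * n_k) equals the total score count.  The fixture checks recompute
these identities, and the derived percentages, from shipped
machine-readable copies of a published reference screen (52 intergenomic
SNP assays against an 82,944-clone amphidiploid BAC library).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Dict, Optional

import pandas as pd


@dataclass
class ScreenSummary:
    per_assay: pd.DataFrame          # assay_id, n_clones, n_allele1, ...
    histogram_all: pd.Series         # k -> number of clones with k assays
    histogram_filtered: pd.Series    # excluding promiscuous assays
    n_scores: int
    n_clones: int
    promiscuous_assays: tuple


def summarize_screen(score_table: pd.DataFrame,
                     promiscuity_limit: int = 3000) -> ScreenSummary:
    """Multiplicity histogram and per-assay counts with identity checks.

    The histogram is computed twice: over all assays and excluding assays
    whose total hit count exceeds ``promiscuity_limit``.  The identities
    linking histogram, per-assay totals and score counts are asserted; a
    violation indicates a decoding bug and raises ``RuntimeError``.
    """
    per_assay = (score_table.groupby("assay_id").size()
                 .rename("n_scores").reset_index())
    promiscuous = tuple(
        per_assay.loc[per_assay.n_scores > promiscuity_limit, "assay_id"])

    def histogram(table: pd.DataFrame) -> pd.Series:
        counts = table.groupby("linear_index")["assay_id"].nunique()
        return counts.value_counts().sort_index()

    hist_all = histogram(score_table)
    filtered = score_table[~score_table.assay_id.isin(promiscuous)]
    hist_filtered = histogram(filtered)

    n_scores = len(score_table)
    n_clones = score_table.linear_index.nunique()
    if int(hist_all.sum()) != n_clones:
        raise RuntimeError("histogram does not sum to the distinct clone "
                           "count — decoding inconsistency")
    if int((hist_all.index * hist_all).sum()) != n_scores:
        raise RuntimeError("sum of k * n_k does not equal the total score "
                           "count — decoding inconsistency")
    if int(per_assay.n_scores.sum()) != n_scores:
        raise RuntimeError("per-assay totals do not sum to the score count")
    return ScreenSummary(per_assay, hist_all, hist_filtered,
                         n_scores, n_clones, promiscuous)


def derived_stats(numerator: int, denominator: int) -> float:
    """Raw percentage ``100 * numerator / denominator``."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in derived statistic")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    return 100.0 * numerator / denominator


def render_percent(value: float, decimals: int = 1) -> str:
    """Round-half-up rendering at the requested precision (9.11 -> "9.1",
    6.896 -> "6.9", 72.03 -> "72" at 0 decimals); locale-independent."""
    q = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    d = Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)
    return format(d, "f")


# ---------------------------------------------------------------------------
# fixture checks


def _load_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("homoeopool.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_reference_tables() -> Dict[str, pd.DataFrame]:
    """The shipped reference-screen fixtures (per-assay hit counts,
    multiplicity histogram, printed headline statistics)."""
    stats = _load_fixture("reference_screen_stats.tsv")
    return {
        "table1": _load_fixture("reference_screen_table1.tsv"),
        "table2": _load_fixture("reference_screen_table2.tsv"),
        "stats": dict(zip(stats.name, stats.value)),
    }


def paper_fixture_checks(fixtures: Optional[Dict] = None) -> pd.DataFrame:
    """Recompute every derivable headline number of the reference screen.

    Each row reports the check name, the expected (printed) value, the
    value recomputed from the fixture tables, and a pass flag.
    """
    fx = fixtures or load_reference_tables()
    t1, t2, stats = fx["table1"], fx["table2"], fx["stats"]
    checks = []

    def check(name, expected, computed, ok=None):
        if ok is None:
            ok = expected == computed
        checks.append((name, expected, computed, bool(ok)))

    total = int(t1.n_total.sum())
    check("per_assay_totals_sum_to_score_count",
          int(stats["total_scores"]), total)
    check("assay_count", int(stats["n_assays"]), len(t1))
    check("max_single_assay_hits", int(stats["max_assay_hits"]),
          int(t1.n_total.max()))
    both = t1[(t1.nt1_count > 0) & (t1.nt2_count > 0)]
    check("assays_detecting_both_nucleotides",
          int(stats["n_both_nucleotide_assays"]), len(both))
    ambiguous = int((t1.nt1_count + t1.nt2_count - t1.n_total).sum())
    check("ambiguous_clones_from_double_counting",
          int(stats["n_ambiguous_clones"]), ambiguous)

    check("histogram_sums_to_distinct_clones",
          int(stats["distinct_clones"]), int(t2.n_clones_all.sum()))
    weighted = int((t2.n_assays * t2.n_clones_all).sum())
    check("weighted_histogram_equals_score_count",
          int(stats["total_scores"]), weighted)
    weighted_ex = int((t2.n_assays * t2.n_clones_excl).sum())
    check("weighted_histogram_excluding_promiscuous",
          int(stats["total_scores"]) - int(stats["max_assay_hits"]),
          weighted_ex)
    ge4_all = int(t2.loc[t2.n_assays >= 4, "n_clones_all"].sum())
    check("clones_with_4plus_assays_exceed_550", ">550", ge4_all,
          ok=ge4_all > 550)
    ge4_ex = int(t2.loc[t2.n_assays >= 4, "n_clones_excl"].sum())
    check("clones_with_4plus_countable_assays",
          int(stats["selection_criterion_a"]), ge4_ex)

    check("selected_fraction_pct",
          render_percent(float(stats["selected_pct"]), 1),
          render_percent(derived_stats(int(stats["selected_clones"]),
                                       int(stats["distinct_clones"])), 1))
    check("unambiguous_nucleotide_classification_pct",
          render_percent(float(stats["unambiguous_pct"]), 2),
          render_percent(derived_stats(int(stats["unambiguous_clones"]),
                                       int(stats["both_nucleotide_clones"])),
                         2))
    check("subgenome_conflict_pct",
          render_percent(float(stats["conflict_pct"]), 1),
          render_percent(derived_stats(int(stats["conflicting_clones"]),
                                       int(stats["multi_marker_clones"])), 1))
    fp_den = int(stats["confirmed_clone_scores"]) - int(
        stats["untestable_scores"])
    check("false_positive_score_pct",
          render_percent(float(stats["false_positive_pct"]), 1),
          render_percent(derived_stats(int(stats["false_positive_scores"]),
                                       fp_den), 1))
    return pd.DataFrame(checks, columns=["check", "expected", "computed",
                                         "passed"])
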