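import pandas as pd
import pytest

from homoeopool.contigs import (MarkerOrder, SelectionParams, bridge_contigs,
                                build_contigs, refine_contigs,
                                select_candidates, validate)

MARKERS = [f"m{i:02d}" for i in range(10)]


class FakeOracle:
    """Dict-backed amplicon oracle: truth maps clone -> {marker positions}."""

    def __init__(self, truth, subgenome="A", masked=()):
        self.truth = truth
        self.subgenome = subgenome
        self.masked = set(masked)

    def test(self, li, assay_id):
        pos = MARKERS.index(assay_id)
        if assay_id in self.masked:
            return "untestable", None
        if pos in self.truth.get(li, set()):
            return "present", self.subgenome
        return "absent", None


def scores(rows):
    return pd.DataFrame(rows, columns=["linear_index", "assay_id",
                                       "call_class"])


@pytest.fixture
def order():
    return MarkerOrder(MARKERS)


class TestSelection:
    def test_four_scores_meet_criterion_a(self, order):
        table = scores([(0, f"m0{i}", "allele1") for i in range(4)])
        sel = select_candidates(table, order)
        assert sel.linear_index.tolist() == [0]
        assert sel.primary.iloc[0] == "A"

    def test_promiscuous_assay_not_countable(self, order):
        rows = [(0, f"m0{i}", "allele1") for i in range(4)]
        # make m00 promiscuous: >3000 hits
        rows += [(li, "m00", "allele1") for li in range(10, 3300)]
        sel = select_candidates(scores(rows), order,
                                SelectionParams(separation_min=9))
        sel0 = sel[sel.linear_index == 0]
        assert sel0.empty or not sel0.criterion_a.iloc[0]

    def test_separated_pair_meets_criterion_b(self, order):
        table = scores([(0, "m03", "allele1"), (0, "m07", "allele2")])
        sel = select_candidates(table, order)
        assert sel.primary.tolist() == ["B"]

    def test_adjacent_pair_not_selected(self, order):
        table = scores([(0, "m04", "allele1"), (0, "m05", "allele1")])
        assert select_candidates(table, order).empty

    def test_end_block_meets_criterion_c(self, order):
        table = scores([(0, "m07", "allele1"), (0, "m08", "allele1"),
                        (0, "m09", "allele1")])
        sel = select_candidates(table, order,
                                SelectionParams(separation_min=5))
        assert sel.primary.tolist() == ["C"]

    def test_selection_monotone_in_scores(self, order):
        base = [(0, "m03", "allele1"), (0, "m07", "allele1")]
        more = base + [(0, "m05", "allele1"), (0, "m09", "allele1")]
        s1 = set(select_candidates(scores(base), order).linear_index)
        s2 = set(select_candidates(scores(more), order).linear_index)
        assert s1 <= s2


class TestValidation:
    def test_truth_backed_oracle_splits_scores(self, order):
        oracle = FakeOracle({0: {1, 2}, 1: set()})
        table = scores([(0, "m01", "allele1"), (0, "m03", "allele1"),
                        (1, "m01", "allele1")])
        rec, confirmed, fp = validate([0, 1], table, oracle)
        assert len(confirmed) == 1 and confirmed.assay_id.iloc[0] == "m01"
        assert set(zip(fp.linear_index, fp.assay_id)) == \
            {(0, "m03"), (1, "m01")}

    def test_all_absent_oracle_marks_everything_false(self, order):
        oracle = FakeOracle({})
        table = scores([(0, "m01", "allele1"), (0, "m02", "allele1")])
        _, confirmed, fp = validate([0], table, oracle)
        assert confirmed.empty and len(fp) == 2

    def test_masked_amplicon_neither_confirms_nor_refutes(self, order):
        oracle = FakeOracle({0: {1}}, masked={"m01"})
        rec, confirmed, fp = validate([0], scores([(0, "m01", "allele1")]),
                                      oracle)
        assert confirmed.empty and fp.empty
        assert rec.outcome.tolist() == ["untestable"]


def confirmed_frame(rows):
    return pd.DataFrame(rows, columns=["linear_index", "assay_id",
                                       "call_class", "outcome", "subgenome"])


class TestContigBuilding:
    def test_shared_marker_joins_clones(self, order):
        conf = confirmed_frame([
            (0, "m01", "allele1", "present", "A"),
            (0, "m02", "allele1", "present", "A"),
            (0, "m03", "allele1", "present", "A"),
            (1, "m03", "allele1", "present", "A"),
            (1, "m04", "allele1", "present", "A")])
        contigs, report = build_contigs(conf, order, {0: "A", 1: "A"})
        (c,) = contigs["A"]
        assert c.span == (1, 4) and set(c.clone_markers) == {0, 1}
        assert report.empty

    def test_disjoint_marker_sets_make_two_contigs(self, order):
        conf = confirmed_frame([
            (0, "m01", "allele1", "present", "A"),
            (0, "m02", "allele1", "present", "A"),
            (1, "m05", "allele1", "present", "A"),
            (1, "m06", "allele1", "present", "A")])
        contigs, _ = build_contigs(conf, order, {0: "A", 1: "A"})
        assert len(contigs["A"]) == 2

    def test_skipped_internal_marker_reported(self, order):
        conf = confirmed_frame([
            (0, "m01", "allele1", "present", "A"),
            (0, "m03", "allele1", "present", "A")])
        _, report = build_contigs(conf, order, {0: "A"})
        assert report.skipped_markers.tolist() == ["[2]"]


class TestRefinement:
    def test_interior_marker_recovered(self, order):
        oracle = FakeOracle({0: {2, 3, 4}})
        conf = confirmed_frame([
            (0, "m02", "allele1", "present", "A"),
            (0, "m04", "allele1", "present", "A")])
        contigs, _ = build_contigs(conf, order, {0: "A"})
        refined, fns = refine_contigs(contigs, order, oracle)
        assert set(zip(fns.linear_index, fns.assay_id)) == {(0, "m03")}
        (c,) = refined["A"]
        assert c.clone_markers[0] == {2, 3, 4}

    def test_end_extension_until_absent(self, order):
        oracle = FakeOracle({0: {2, 3, 4, 5, 6}})
        conf = confirmed_frame([(0, "m04", "allele1", "present", "A")])
        contigs, _ = build_contigs(conf, order, {0: "A"})
        refined, fns = refine_contigs(contigs, order, oracle)
        assert refined["A"][0].clone_markers[0] == {2, 3, 4, 5, 6}
        assert len(fns) == 4

    def test_refinement_merges_contigs(self, order):
        oracle = FakeOracle({0: {1, 2, 3}, 1: {3, 4, 5}})
        conf = confirmed_frame([
            (0, "m01", "allele1", "present", "A"),
            (0, "m02", "allele1", "present", "A"),
            (1, "m04", "allele1", "present", "A"),
            (1, "m05", "allele1", "present", "A")])
        contigs, _ = build_contigs(conf, order, {0: "A", 1: "A"})
        assert len(contigs["A"]) == 2
        refined, _ = refine_contigs(contigs, order, oracle)
        assert len(refined["A"]) == 1


class TestBridging:
    def test_planted_gap_spanner_recovered(self, order):
        # contigs [1-3] and [6-8]; clone 9 truly spans 3..6 but was
        # never selected; it is scored at m03 and m06
        oracle = FakeOracle({0: {1, 2, 3}, 1: {6, 7, 8},
                             9: {3, 4, 5, 6}})
        conf = confirmed_frame([
            (0, "m01", "allele1", "present", "A"),
            (0, "m02", "allele1", "present", "A"),
            (0, "m03", "allele1", "present", "A"),
            (1, "m06", "allele1", "present", "A"),
            (1, "m07", "allele1", "present", "A"),
            (1, "m08", "allele1", "present", "A")])
        table = scores([(9, "m03", "allele1"), (9, "m06", "allele1")])
        contigs, _ = build_contigs(conf, order, {0: "A", 1: "A"})
        assert len(contigs["A"]) == 2
        merged, report = bridge_contigs(contigs, table, order, oracle,
                                        {0: "A", 1: "A"})
        assert len(merged["A"]) == 1
        assert report.bridged.tolist() == [True]
        assert report.bridge_clone.tolist() == [9]

    def test_unbridgeable_gap_reported(self, order):
        oracle = FakeOracle({0: {1, 2}, 1: {6, 7}})
        conf = confirmed_frame([
            (0, "m01", "allele1", "present", "A"),
            (0, "m02", "allele1", "present", "A"),
            (1, "m06", "allele1", "present", "A"),
            (1, "m07", "allele1", "present", "A")])
        table = scores([(5, "m03", "allele1")])   # candidate maps elsewhere
        contigs, _ = build_contigs(conf, order, {0: "A", 1: "A"})
        merged, report = bridge_contigs(contigs, table, order, oracle,
                                        {0: "A", 1: "A"})
        assert len(merged["A"]) == 2
        row = report.iloc[0]
        assert not row.bridged and row.n_candidates == 1

    def test_merge_count_matches_bridges(self, order):
        # three contigs, one bridge between the first two
        oracle = FakeOracle({0: {0, 1}, 1: {3, 4}, 2: {7, 8},
                             9: {1, 2, 3}})
        conf = confirmed_frame([
            (0, "m00", "allele1", "present", "A"),
            (0, "m01", "allele1", "present", "A"),
            (1, "m03", "allele1", "present", "A"),
            (1, "m04", "allele1", "present", "A"),
            (2, "m07", "allele1", "present", "A"),
            (2, "m08", "allele1", "present", "A")])
        table = scores([(9, "m01", "allele1"), (9, "m03", "allele1")])
        contigs, _ = build_contigs(conf, order, {0: "A", 1: "A", 2: "A"})
        merged, report = bridge_contigs(contigs, table, order, oracle,
                                        {0: "A", 1: "A", 2: "A"})
        assert len(contigs["A"]) - len(merged["A"]) == \
            int(report.bridged.sum())
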