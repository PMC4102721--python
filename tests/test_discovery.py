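import numpy as np
import pytest

from homoeopool import (derive_amphidiploid, simulate_progenitor_pair,
                        verify_in_amphidiploid)
from homoeopool.discovery import (AssayCandidate, Hsp, assemble_gss_contigs,
                                  designability_surrogate, filter_hsps,
                                  find_assay_sites)

from conftest import small_config

REGION = ("C1", 1000, 50_000)


def hsp(q, length, ident, s_start=2000, subject="C1"):
    return Hsp(q, subject, 0, length, s_start, s_start + length, length,
               ident)


class TestHspFilters:
    def test_length_boundary(self):
        assert filter_hsps([hsp("q1", 499, 99.0)], REGION) == []
        kept = filter_hsps([hsp("q1", 500, 95.0)], REGION)
        assert len(kept) == 1

    def test_identity_boundary(self):
        assert filter_hsps([hsp("q1", 600, 94.9)], REGION) == []

    def test_off_target_sibling_rejects_query(self):
        good = hsp("q1", 600, 96.0)
        off = hsp("q1", 200, 92.0, s_start=70_000)  # outside region
        assert filter_hsps([good, off], REGION) == []
        weak_off = hsp("q1", 100, 92.0, s_start=70_000)  # below off_len
        assert filter_hsps([good, weak_off], REGION) == [good]

    def test_region_containment_required(self):
        outside = hsp("q1", 600, 96.0, s_start=60_000)
        assert filter_hsps([outside], REGION) == []

    def test_empty_input_gives_empty_output(self):
        assert filter_hsps([], REGION) == []

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        hsps = []
        for i in range(200):
            q = f"q{rng.integers(40)}"
            length = int(rng.integers(50, 1500))
            ident = float(rng.uniform(85, 100))
            s = int(rng.integers(0, 100_000))
            hsps.append(Hsp(q, "C1", 0, length, s, s + length, length, ident))

        def in_region(h):
            return h.subject_start >= 1000 and h.subject_end <= 50_000

        expected = []
        for h in hsps:
            if not (h.length_bp >= 500 and h.identity_pct >= 95.0
                    and in_region(h)):
                continue
            bad = any(o.query_id == h.query_id and not in_region(o)
                      and o.length_bp >= 150 and o.identity_pct >= 90.0
                      for o in hsps)
            if not bad:
                expected.append(h)
        assert filter_hsps(hsps, REGION) == expected

    def test_filters_are_monotone(self):
        rng = np.random.default_rng(4)
        hsps = [hsp(f"q{i}", int(rng.integers(100, 1200)),
                    float(rng.uniform(90, 100))) for i in range(50)]
        base = set(id(h) for h in filter_hsps(hsps, REGION))
        tighter = set(id(h) for h in filter_hsps(hsps, REGION,
                                                 min_len=700, min_id=97.0))
        assert tighter <= base


class TestGssContigs:
    def test_identical_reads_merge_without_masking(self):
        reads = {"r1": "ACGTACGT", "r2": "ACGTAAAA"}
        contigs = assemble_gss_contigs(reads, [("r1", "r2", 4)])
        (c,) = contigs
        assert c.consensus == "ACGTACGTAAAA"
        assert c.masked_positions == []

    def test_single_disagreement_masked(self):
        reads = {"r1": "ACGTACGT", "r2": "TCGTAAAA"}
        contigs = assemble_gss_contigs(reads, [("r1", "r2", 4)])
        (c,) = contigs
        assert c.consensus == "ACGTNCGTAAAA"
        assert c.masked_positions == [4]

    def test_planted_disagreements_recovered(self):
        rng = np.random.default_rng(5)
        template = "".join(rng.choice(list("ACGT"), 300))
        reads, offsets = {}, []
        prev = None
        for i, start in enumerate(range(0, 240, 40)):
            rid = f"r{i}"
            reads[rid] = template[start:start + 100]
            if prev is not None:
                offsets.append((prev, rid, 40))
            prev = rid
        # plant disagreements inside overlap of r1 (positions 40-139)
        planted = [50, 95]
        r1 = list(reads["r1"])
        for p in planted:
            local = p - 40
            r1[local] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r1[local]]
        reads["r1"] = "".join(r1)
        (contig,) = assemble_gss_contigs(reads, offsets)
        assert contig.masked_positions == planted

    def test_inconsistent_offset_rejected(self):
        reads = {"r1": "ACGT", "r2": "ACGT"}
        with pytest.raises(ValueError, match="no overlap"):
            assemble_gss_contigs(reads, [("r1", "r2", 10)])

    def test_disconnected_reads_make_separate_contigs(self):
        reads = {"r1": "AAAA", "r2": "CCCC"}
        assert len(assemble_gss_contigs(reads, [])) == 2


class TestAssaySites:
    def make_alignment(self, site=60, n=121):
        rng = np.random.default_rng(6)
        # alternate bases to avoid homopolymers and keep GC near 0.5
        seq = "".join("ACGT"[int(rng.integers(4))] for _ in range(n))
        seq = "".join("AC"[i % 2] if seq[i] * 6 in seq else seq[i]
                      for i in range(n))
        a = list(seq)
        b = list(seq)
        b[site] = "G" if a[site] != "G" else "T"
        return "".join(a), "".join(b)

    def test_clean_site_accepted(self):
        a, b = self.make_alignment()
        sites = find_assay_sites(a, b, window=30)
        assert [c.site_pos1 for c in sites] == [60]
        c = sites[0]
        assert c.nucleotide_1 != c.nucleotide_2
        assert len(c.flank_left) == 30 and len(c.flank_right) == 30

    def test_nearby_mismatch_rejected(self):
        a, b = self.make_alignment()
        b = list(b)
        b[50] = "G" if a[50] != "G" else "T"  # distance 10 < clearance
        sites = find_assay_sites(a, "".join(b), window=30)
        assert all(c.site_pos1 != 60 for c in sites)

    def test_nearby_gap_rejected(self):
        a, b = self.make_alignment()
        a = a[:40] + "-" + a[41:]
        sites = find_assay_sites(a, b, window=30)
        assert all(c.site_pos1 != 60 for c in sites)

    def test_zero_divergence_yields_no_candidates(self):
        a, _ = self.make_alignment()
        assert find_assay_sites(a, a) == []

    def test_matches_per_column_bruteforce(self):
        cfg = small_config(region_length_bp=12_000, indel_rate=0.001)
        pair = simulate_progenitor_pair(cfg, np.random.default_rng(7))
        from homoeopool.simulate import BASES
        a = "".join("-" if x == 4 else str(BASES[x]) for x in pair.aln_a)
        b = "".join("-" if x == 4 else str(BASES[x]) for x in pair.aln_c)
        got = {(c.site_pos1, c.site_pos2)
               for c in find_assay_sites(a, b)}

        # independent per-column evaluation
        fmin, fmax, clear, win = 20, 25, 15, 60
        expected = set()
        n = len(a)
        p1 = p2 = -1
        pos1 = []
        pos2 = []
        for i in range(n):
            if a[i] != "-":
                p1 += 1
            if b[i] != "-":
                p2 += 1
            pos1.append(p1)
            pos2.append(p2)
        ung1 = a.replace("-", "")
        ung2 = b.replace("-", "")
        for i in range(fmax, n - fmax):
            if a[i] == "-" or b[i] == "-" or a[i] == b[i]:
                continue
            ctx = range(i - fmax, i + fmax + 1)
            if any(a[j] == "-" or b[j] == "-" for j in ctx):
                continue
            mm = [abs(j - i) for j in ctx if j != i and a[j] != b[j]]
            if len(mm) > 1 or (mm and mm[0] <= max(clear, fmin)):
                continue
            q1, q2 = pos1[i], pos2[i]
            if (q1 < win or q1 + win >= len(ung1)
                    or q2 < win or q2 + win >= len(ung2)):
                continue
            window = ung1[q1 - win:q1 + win + 1]
            if designability_surrogate(window) <= 0.6:
                continue
            expected.add((q1, q2))
        assert got == expected


class TestDesignability:
    def test_homopolymer_rich_window_scores_low(self):
        assert designability_surrogate("A" * 60) == 0.0

    def test_balanced_window_scores_high(self):
        win = "ACGT" * 15
        assert designability_surrogate(win) > 0.9


@pytest.fixture(scope="module")
def amph():
    cfg = small_config(region_length_bp=40_000)
    pair = simulate_progenitor_pair(cfg, np.random.default_rng(8))
    return derive_amphidiploid(pair, (0.0, 0.0), np.random.default_rng(9))


class TestAmphidiploidVerification:
    def candidate(self, amph, col):
        pa = int(amph.pair.pos_a[col])
        pc = int(amph.pair.pos_c[col])
        from homoeopool.simulate import BASES
        return AssayCandidate(
            site_pos1=pa, site_pos2=pc,
            nucleotide_1=str(BASES[amph.pair.aln_a[col]]),
            nucleotide_2=str(BASES[amph.pair.aln_c[col]]),
            flank_left="", flank_right="", flank_identity_len=25,
            designability=1.0)

    def test_conserved(self, amph):
        col = int(amph.pair.substitution_cols[5])
        assert verify_in_amphidiploid(self.candidate(amph, col), amph) == \
            "conserved"

    def test_monomorphic(self, amph):
        col = int(amph.pair.substitution_cols[6])
        cand = self.candidate(amph, col)
        old = amph.sub_c[cand.site_pos2]
        amph.sub_c[cand.site_pos2] = amph.sub_a[cand.site_pos1]
        assert verify_in_amphidiploid(cand, amph) == "monomorphic"
        amph.sub_c[cand.site_pos2] = old

    def test_changed(self, amph):
        col = int(amph.pair.substitution_cols[7])
        cand = self.candidate(amph, col)
        old = amph.sub_a[cand.site_pos1]
        amph.sub_a[cand.site_pos1] = (old + 1) % 4
        if amph.sub_a[cand.site_pos1] == amph.sub_c[cand.site_pos2]:
            amph.sub_a[cand.site_pos1] = (old + 2) % 4
        assert verify_in_amphidiploid(cand, amph) == "changed"
        amph.sub_a[cand.site_pos1] = old

    def test_interfering(self, amph):
        col = int(amph.pair.substitution_cols[8])
        cand = self.candidate(amph, col)
        p = cand.site_pos2 + 7   # inside the footprint
        old = amph.sub_c[p]
        amph.sub_c[p] = (old + 1) % 4
        assert verify_in_amphidiploid(cand, amph) == "interfering"
        amph.sub_c[p] = old

    def test_unmappable(self, amph):
        cand = self.candidate(amph, int(amph.pair.substitution_cols[5]))
        cand.site_pos1 = 10**9
        assert verify_in_amphidiploid(cand, amph) == "unmappable"
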