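import numpy as np
import pytest

from snppanel import (
    GenotypeDataError,
    GenotypeMatrix,
    LocusInfo,
    MISSING,
    MinimalPanelSelector,
    SimConfig,
    build_fingerprints,
    concordance_rate,
    difference_matrix,
    exhaustive_minimum_set,
    minimal_discriminating_set,
    pair_distinguished,
    select_core,
    similarity_verdict,
    simulate,
    stats_table,
    toy_fixture,
)
from snppanel.panel import Fingerprint, VERDICT_DISTINCT, VERDICT_SIMILAR

from conftest import random_matrix


class TestPairDistinguished:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0, 1, True), (1, 1, False), (0, MISSING, False),
         (MISSING, MISSING, False), (0, 2, True)],
    )
    def test_rule(self, a, b, expected):
        assert pair_distinguished(a, b) is expected


def difference_matrix_oracle(matrix, panel):
    idx = matrix.locus_index(panel)
    n = matrix.n_varieties
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for k in range(n):
            out[i, k] = sum(
                pair_distinguished(int(matrix.calls[i, j]), int(matrix.calls[k, j]))
                for j in idx
            )
    np.fill_diagonal(out, 0)
    return out


class TestDifferenceMatrix:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        m = random_matrix(seed, n_varieties=20, n_loci=30)
        got = difference_matrix(m, m.locus_ids)
        assert np.array_equal(got, difference_matrix_oracle(m, m.locus_ids))

    def test_symmetric_zero_diagonal(self):
        m = random_matrix(9, n_varieties=15, n_loci=20)
        d = difference_matrix(m, m.locus_ids)
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_planted_duplicates_have_zero_distance(self, small_sim):
        m, truth, _ = small_sim
        d = difference_matrix(m, m.locus_ids)
        vi = {v: i for i, v in enumerate(m.varieties)}
        for a, b in truth.duplicate_pairs:
            assert d[vi[a], vi[b]] == 0

    def test_adding_a_marker_never_decreases_counts(self):
        m = random_matrix(3, n_varieties=10, n_loci=12)
        base = difference_matrix(m, m.locus_ids[:6])
        more = difference_matrix(m, m.locus_ids[:7])
        assert np.all(more >= base)

    def test_empty_panel_rejected(self):
        m = random_matrix(1)
        with pytest.raises(GenotypeDataError):
            difference_matrix(m, [])


class TestSelectCore:
    def test_chromosome_quota_honoured(self):
        m, _, _ = simulate(SimConfig(n_varieties=60, n_loci=240, missing_rate=0.0,
                                     cluster_fraction=0.0, seed=21))
        panel = select_core(m, m.locus_ids, 50)
        assert len(panel.marker_ids) == 50
        # every chromosome with >= 4 candidates contributes >= floor(50/12) = 4
        assert all(c >= 4 for c in panel.per_chrom_counts.values())

    def test_k_equals_survivors_returns_all(self):
        m = random_matrix(5, n_varieties=8, n_loci=10)
        panel = select_core(m, m.locus_ids, len(m.locus_ids), flank_bp=0)
        assert sorted(panel.marker_ids) == sorted(m.locus_ids)

    def test_equal_pic_tie_broken_by_smaller_position(self):
        loci = [LocusInfo("far", "chr1", 9000, "A", "G"),
                LocusInfo("near", "chr1", 1000, "C", "T")]
        col = [0] * 2 + [1] * 4 + [2] * 2
        m = GenotypeMatrix([f"v{i}" for i in range(8)], loci,
                           np.array([col, col], dtype=np.int8).T)
        panel = select_core(m, m.locus_ids, 1)
        assert panel.marker_ids == ["near"]

    def test_mutual_flank_distance_enforced(self):
        loci = [LocusInfo(f"m{i}", "chr1", 1000 + 50 * i, "A", "G") for i in range(4)]
        col = [0, 0, 1, 1, 1, 1, 2, 2]
        m = GenotypeMatrix([f"v{i}" for i in range(8)], loci,
                           np.array([col] * 4, dtype=np.int8).T)
        panel = select_core(m, m.locus_ids, 2, flank_bp=100)
        positions = sorted(l.pos for l in m.loci if l.id in panel.marker_ids)
        assert positions[1] - positions[0] > 100

    def test_accounting_covers_all_pairs(self):
        m, _, _ = simulate(SimConfig(n_varieties=30, n_loci=120, missing_rate=0.0, seed=8))
        panel = select_core(m, m.locus_ids, 24)
        n_pairs = 30 * 29 // 2
        assert panel.resolved_pairs + len(panel.unresolved_pairs) == n_pairs


class TestMinimalDiscriminatingSet:
    def test_two_locus_factorial_design_needs_both(self):
        loci = [LocusInfo("a", "chr1", 100, "A", "G"),
                LocusInfo("b", "chr1", 900, "C", "T")]
        calls = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        m = GenotypeMatrix(["w", "x", "y", "z"], loci, calls)
        panel = minimal_discriminating_set(m, m.locus_ids)
        assert sorted(panel.marker_ids) == ["a", "b"]
        assert panel.resolved_pairs == 6 and not panel.unresolved_pairs

    def test_identical_varieties_yield_empty_panel(self):
        loci = [LocusInfo("a", "chr1", 100, "A", "G")]
        m = GenotypeMatrix(["x", "y", "z"], loci, np.ones((3, 1), dtype=np.int8))
        panel = minimal_discriminating_set(m, m.locus_ids)
        assert panel.marker_ids == []
        assert len(panel.unresolved_pairs) == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_coverage_equals_exhaustive_optimum(self, seed):
        """Greedy may pick more markers but must match optimal coverage."""
        m = random_matrix(seed, n_varieties=15, n_loci=12)
        greedy = minimal_discriminating_set(m, m.locus_ids)
        optimum = exhaustive_minimum_set(m, m.locus_ids)
        assert greedy.resolved_pairs == optimum.resolved_pairs
        assert len(greedy.marker_ids) >= len(optimum.marker_ids)

    def test_toy_fixture_pinned_panel(self):
        m, survivors, expected_panel = toy_fixture()
        panel = minimal_discriminating_set(m, survivors)
        assert panel.marker_ids == expected_panel
        assert panel.resolved_pairs == 16 * 15 // 2
        optimum = exhaustive_minimum_set(m, survivors)
        assert len(panel.marker_ids) == len(optimum.marker_ids)

    def test_selector_estimator_wraps_search(self):
        m, survivors, expected_panel = toy_fixture()
        sel = MinimalPanelSelector().fit(m, candidates=survivors)
        assert sel.marker_ids_ == expected_panel
        # transform keeps the greedy selection order
        assert sel.transform(m).locus_ids == expected_panel


class TestFingerprints:
    def test_single_variety_rendering(self):
        loci = [LocusInfo("a", "chr1", 100, "A", "G"),
                LocusInfo("b", "chr1", 900, "C", "T")]
        calls = np.array([[0, 1]], dtype=np.int8)
        m = GenotypeMatrix(["v"], loci, calls)
        prints = build_fingerprints(m, ["a", "b"])
        assert prints[0].genotype == "A/A|C/T"

    def test_missing_rendered_as_NN_and_panel_in_position_order(self):
        loci = [LocusInfo("late", "chr2", 100, "A", "G"),
                LocusInfo("early", "chr1", 900, "C", "T")]
        calls = np.array([[MISSING, 2]], dtype=np.int8)
        m = GenotypeMatrix(["v"], loci, calls)
        prints = build_fingerprints(m, ["late", "early"])
        assert prints[0].genotype == "T/T|NN"

    def test_duplicates_share_strings_iff_zero_difference(self, small_sim):
        m, truth, _ = small_sim
        prints = {f.variety: f.genotype for f in build_fingerprints(m, m.locus_ids)}
        d = difference_matrix(m, m.locus_ids)
        vi = {v: i for i, v in enumerate(m.varieties)}
        for a in m.varieties[:10]:
            for b in m.varieties[:10]:
                if a < b:
                    assert (prints[a] != prints[b]) == (d[vi[a], vi[b]] > 0)
        for a, b in truth.duplicate_pairs:
            assert prints[a] == prints[b]


class TestSimilarityVerdict:
    @pytest.mark.parametrize("diff,expected", [
        (0, VERDICT_SIMILAR), (1, VERDICT_SIMILAR), (2, VERDICT_DISTINCT),
    ])
    def test_threshold_rule(self, diff, expected):
        assert similarity_verdict(diff) == expected

    def test_threshold_zero(self):
        assert similarity_verdict(1, threshold=0) == VERDICT_DISTINCT

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            similarity_verdict(-1)


class TestConcordanceRate:
    def fp(self, variety, cells):
        return Fingerprint(variety, "|".join(cells))

    def test_identical_sets_are_fully_concordant(self):
        a = [self.fp("v1", ["A/A", "C/T"]), self.fp("v2", ["A/G", "C/C"])]
        assert concordance_rate(a, a).rate == 1.0

    def test_four_discordant_of_150_cells(self):
        # 15 varieties x 10 loci = 150 cells, 4 flipped -> 146/150 = 97.33%
        rng = np.random.default_rng(0)
        cells = [["A/A"] * 10 for _ in range(15)]
        a = [self.fp(f"v{i}", c) for i, c in enumerate(cells)]
        flipped = [list(c) for c in cells]
        flat = [(i, j) for i in range(15) for j in range(10)]
        for i, j in [flat[k] for k in rng.choice(150, size=4, replace=False)]:
            flipped[i][j] = "A/G"
        b = [self.fp(f"v{i}", c) for i, c in enumerate(flipped)]
        result = concordance_rate(a, b)
        assert result.n_compared == 150 and result.n_concordant == 146
        assert round(100 * result.rate, 2) == 97.33

    def test_missing_cells_excluded(self):
        a = [self.fp("v", ["A/A", "NN", "C/C"])]
        b = [self.fp("v", ["A/A", "A/G", "NN"])]
        result = concordance_rate(a, b)
        assert result.n_compared == 1 and result.n_excluded_missing == 2

    def test_all_missing_side_warns_with_nan(self):
        a = [self.fp("v", ["NN", "NN"])]
        b = [self.fp("v", ["A/A", "A/G"])]
        with pytest.warns(UserWarning):
            result = concordance_rate(a, b)
        assert np.isnan(result.rate) and result.n_compared == 0

    def test_variety_mismatch_raises(self):
        with pytest.raises(GenotypeDataError):
            concordance_rate([self.fp("v1", ["A/A"])], [self.fp("v2", ["A/A"])])
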