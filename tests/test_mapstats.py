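"""Recombination accounting, binning, two-point linkage, Kosambi, distortion."""

import numpy as np
import pytest

from maskov import (
    HET,
    HOM,
    MISSING,
    GenotypeMatrix,
    LinkageGrouper,
    bin_markers,
    chi_square_scan,
    count_recombinations,
    group_markers,
    kosambi_cM,
    map_length_along_order,
    mean_recombinations,
    order_markers_greedy,
    percent_reduction,
    recombination_counts,
    two_point,
)
from maskov.mapstats import map_length_along_order as _mlen
from maskov.simulate import SimulationParams, simulate_clean


def _matrix_from_encoded(enc, lg="LG1"):
    """Encoded {1,0,-1} markers x individuals -> matrix under phase 1-."""
    enc = np.asarray(enc, dtype=np.int8)
    calls = np.where(enc == 1, HET, np.where(enc == -1, HOM, MISSING)).astype(np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        calls=calls,
        marker_ids=[f"M{i}" for i in range(n)],
        linkage_group=np.array([lg] * n, dtype=object),
        order_index=np.arange(n),
        individual_ids=[f"i{j}" for j in range(m)],
    )


class TestRecombinationCounts:
    @pytest.mark.parametrize(
        "v, expected",
        [([1, 1, -1, -1, 1], 2), ([1, 1, 1], 0), ([1, 0, -1], 1), ([], 0), ([0, 0], 0)],
    )
    def test_sign_changes(self, v, expected):
        assert count_recombinations(np.array(v, dtype=np.int8)) == expected

    def test_mean_over_individuals(self):
        enc = np.array([[1, 1], [-1, 1], [1, -1], [-1, -1]], dtype=np.int8)
        # ind1: 1,-1,1,-1 -> 3 changes; ind2: 1,1,-1,-1 -> 1 change
        m = _matrix_from_encoded(enc)
        counts = recombination_counts(m, np.ones(4, dtype=np.int8))
        assert counts.tolist() == [3, 1]
        assert mean_recombinations(m, np.ones(4, dtype=np.int8)) == 2.0

    def test_constant_matrix_zero(self):
        m = _matrix_from_encoded(np.ones((5, 3), dtype=np.int8))
        assert mean_recombinations(m, np.ones(5, dtype=np.int8)) == 0.0


class TestPercentReduction:
    def test_study_values(self):
        # the maternal map's printed 71.1% is 71.0 at full precision of the
        # printed means 22.45 and 6.5; the paternal 67% verifies exactly
        assert percent_reduction(22.45, 6.5) == pytest.approx(71.1, abs=0.1)
        assert percent_reduction(11.22, 3.7) == 67.0

    def test_no_change_and_bad_input(self):
        assert percent_reduction(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)


class TestBins:
    def test_identical_rows_share_a_bin(self):
        enc = np.array([[1, -1, 1], [1, -1, 1], [-1, 1, 1]], dtype=np.int8)
        bins = bin_markers(_matrix_from_encoded(enc), "LG1")
        assert len(bins) == 2
        assert bins[0].marker_ids == ["M0", "M1"]
        assert bins[0].representative == "M0"

    def test_all_distinct(self):
        enc = np.array([[1, 1], [1, -1], [-1, 1]], dtype=np.int8)
        assert len(bin_markers(_matrix_from_encoded(enc), "LG1")) == 3

    def test_partition_covers_all_markers_once(self):
        rng = np.random.default_rng(11)
        enc = rng.choice(np.array([1, -1], dtype=np.int8), size=(20, 8))
        m = _matrix_from_encoded(enc)
        bins = bin_markers(m, "LG1")
        members = [mid for b in bins for mid in b.marker_ids]
        assert sorted(members) == sorted(m.marker_ids)

    def test_missing_rejected(self):
        enc = np.array([[1, 0], [1, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="impute"):
            bin_markers(_matrix_from_encoded(enc), "LG1")


class TestTwoPoint:
    def test_identical_vectors_71(self):
        v = np.ones(71, dtype=np.int8)
        tp = two_point(v, v)
        assert tp.r_hat == 0.0
        assert tp.lod == pytest.approx(71 * np.log10(2), abs=1e-12)  # 21.37

    def test_half_recombinant_lod_zero(self):
        v1 = np.array([1, 1, -1, -1], dtype=np.int8)
        v2 = np.array([1, -1, 1, -1], dtype=np.int8)
        tp = two_point(v1, v2)
        assert tp.r_hat == 0.5 and tp.lod == 0.0

    def test_direct_ratio_with_missing_skipped(self):
        v1 = np.ones(52, dtype=np.int8)
        v2 = np.ones(52, dtype=np.int8)
        v2[:5] = -1
        v2[50:] = 0  # two uninformative pairs
        tp = two_point(v1, v2)
        assert tp.n_informative == 50 and tp.r_hat == pytest.approx(0.10)

    def test_opposite_phase_folded_and_flagged(self):
        v = np.ones(40, dtype=np.int8)
        tp = two_point(v, -v)
        assert tp.r_hat == 0.0 and tp.phase_flipped
        assert tp.lod == pytest.approx(40 * np.log10(2))

    def test_no_informative_pairs_flagged(self):
        tp = two_point(np.array([1, 0]), np.array([0, 1]))
        assert tp.undefined

    def test_lod_formula_against_likelihood_grid(self):
        # R=5, n=50: the closed form is the likelihood ratio at the MLE;
        # a brute-force grid over r must not beat it
        R, n = 5, 50
        v1 = np.ones(n, dtype=np.int8)
        v2 = v1.copy()
        v2[:R] = -1
        tp = two_point(v1, v2)
        grid = np.linspace(1e-6, 0.5, 20001)
        loglik = R * np.log10(grid) + (n - R) * np.log10(1 - grid) - n * np.log10(0.5)
        assert tp.lod == pytest.approx(loglik.max(), abs=1e-6)


class TestGrouping:
    def test_two_identical_markers_join(self):
        enc = np.ones((2, 71), dtype=np.int8)
        labels = group_markers(enc, min_lod=7.0)
        assert labels[0] == labels[1]

    def test_unlinked_markers_are_singletons(self):
        rng = np.random.default_rng(4)
        enc = rng.choice(np.array([1, -1], dtype=np.int8), size=(5, 71))
        labels = group_markers(enc, min_lod=7.0, max_r=0.35)
        assert len(set(labels)) == 5

    def test_simulated_groups_recovered(self):
        truth = simulate_clean(SimulationParams(markers_per_lg=30, seed=9))
        est = LinkageGrouper(min_lod=7.0, max_r=0.35)
        from maskov.model import _encode_calls

        est.fit(_encode_calls(truth.clean.calls, np.ones(truth.clean.n_markers, dtype=np.int8)))
        assert est.n_groups_ == 7
        # labels refine exactly onto the true groups
        for g in truth.clean.groups():
            rows = truth.clean.linkage_group == g
            assert len(set(est.labels_[rows])) == 1

    def test_raising_lod_never_merges(self):
        rng = np.random.default_rng(2)
        enc = rng.choice(np.array([1, -1], dtype=np.int8), size=(12, 40))
        lo = group_markers(enc, min_lod=3.0)
        hi = group_markers(enc, min_lod=8.0)
        # markers separated at low LOD stay separated at high LOD
        for i in range(12):
            for j in range(i):
                if lo[i] != lo[j]:
                    assert hi[i] != hi[j]


class TestKosambi:
    def test_closed_form_values(self):
        assert kosambi_cM(0.0) == 0.0
        assert kosambi_cM(0.25) == pytest.approx(25 * np.log(3), abs=1e-12)  # 27.47

    def test_small_r_linear_limit(self):
        for r in (0.01, 0.03, 0.05):
            assert kosambi_cM(r) == pytest.approx(100 * r, rel=0.01)

    def test_strictly_increasing_and_above_100r(self):
        rs = np.linspace(0.01, 0.49, 49)
        ds = kosambi_cM(rs)
        assert np.all(np.diff(ds) > 0)
        assert np.all(ds > 100 * rs)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            kosambi_cM(0.5)


class TestMapLength:
    def test_single_interval(self):
        n = 100
        enc = np.ones((2, n), dtype=np.int8)
        enc[1, :25] = -1  # r = 0.25
        m = _matrix_from_encoded(enc)
        bins = bin_markers(m, "LG1")
        s = map_length_along_order(bins, lg="LG1")
        assert s.length_cM == pytest.approx(25 * np.log(3), abs=1e-9)
        assert s.n_bins == 2 and s.cM_per_bin == pytest.approx(s.length_cM / 2)

    def test_single_bin_zero_length(self):
        enc = np.ones((3, 10), dtype=np.int8)
        m = _matrix_from_encoded(enc)
        bins = bin_markers(m, "LG1")
        assert len(bins) == 1
        assert map_length_along_order(bins).length_cM == 0.0

    def test_simulated_length_within_sampling_band(self):
        # 71 meioses on an 87.6 cM group: the summed adjacent-bin Kosambi
        # estimate has sd ~ sqrt(100^2 * L/100 / n) ~ 11 cM; assert 3 sd
        truth = simulate_clean(SimulationParams(markers_per_lg=300, lg_lengths_cM=(87.6,), seed=17))
        bins = bin_markers(truth.clean, "LG1")
        s = map_length_along_order(bins, lg="LG1")
        assert abs(s.length_cM - 87.6) < 35.0

    def test_density_arithmetic(self):
        # binning then summarising reproduces densities
        rng = np.random.default_rng(5)
        enc = np.cumprod(rng.choice([1, -1], size=(10, 60), p=[0.9, 0.1]), axis=0).astype(np.int8)
        m = _matrix_from_encoded(enc)
        bins = bin_markers(m, "LG1")
        s = map_length_along_order(bins, lg="LG1")
        assert s.cM_per_bin * s.n_bins == pytest.approx(s.length_cM, abs=1e-9)
        assert s.cM_per_marker * s.n_markers == pytest.approx(s.length_cM, abs=1e-9)


class TestChiSquareScan:
    def _scan_for_counts(self, a, b):
        enc = np.concatenate([np.ones(a, dtype=np.int8), -np.ones(b, dtype=np.int8)])
        return chi_square_scan(_matrix_from_encoded(enc[None, :])).iloc[0]

    def test_balanced_counts_not_significant(self):
        rec = self._scan_for_counts(35, 36)
        assert rec["chi2"] == pytest.approx(0.0141, abs=5e-4)
        assert rec["sig_level"] == ""

    def test_distorted_marker_significant_at_001(self):
        rec = self._scan_for_counts(50, 21)
        assert rec["chi2"] == pytest.approx(11.845, abs=5e-3)
        assert rec["chi2"] > 10.828
        assert rec["sig_level"] == "0.001"

    def test_equal_counts_zero(self):
        rec = self._scan_for_counts(30, 30)
        assert rec["chi2"] == 0.0 and rec["p"] == pytest.approx(1.0)

    def test_label_swap_invariance_and_monotonicity(self):
        a = self._scan_for_counts(40, 20)["chi2"]
        b = self._scan_for_counts(20, 40)["chi2"]
        assert a == b
        assert self._scan_for_counts(45, 15)["chi2"] > a

    def test_all_missing_marker_flagged(self):
        enc = np.zeros((1, 5), dtype=np.int8)
        rec = chi_square_scan(_matrix_from_encoded(enc)).iloc[0]
        assert rec["n"] == 0 and np.isnan(rec["chi2"])

    def test_ordered_by_position_when_given(self):
        enc = np.ones((3, 6), dtype=np.int8)
        m = _matrix_from_encoded(enc)
        df = chi_square_scan(m, positions_cM={"M0": 5.0, "M1": 1.0, "M2": 3.0})
        assert df["marker_id"].tolist() == ["M1", "M2", "M0"]


class TestGreedyOrdering:
    def test_two_bins_trivial(self):
        enc = np.array([[1, 1], [1, -1]], dtype=np.int8)
        assert order_markers_greedy(enc) in ([0, 1], [1, 0])

    def test_recovers_simulated_order_or_reversal(self):
        truth = simulate_clean(SimulationParams(markers_per_lg=40, lg_lengths_cM=(60.0,), seed=13))
        bins = bin_markers(truth.clean, "LG1")
        enc = np.array(
            [np.where(b.genotype == HET, 1, -1) for b in bins], dtype=np.int8
        )
        order = order_markers_greedy(enc)
        assert order == sorted(order) or order == sorted(order, reverse=True)

    def test_consistency_with_maskov_edge_count(self):
        # count_recombinations equals the edges a zero-error run reports
        from maskov import MaskovParams, impute_individual

        rng = np.random.default_rng(3)
        for _ in range(20):
            changes = rng.random(30) < 0.05
            v = np.cumprod(np.where(changes, -1, 1)).astype(np.int8)
            res = impute_individual(v, MaskovParams(E=1))
            if not res.skipped and np.array_equal(res.values, v):
                assert res.n_edges == count_recombinations(v)
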