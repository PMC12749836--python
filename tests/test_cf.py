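from fractions import Fraction
from math import comb

import numpy as np
import pytest

from conftest import toy_matrix
from nadscope.cf import (
    binomial_cdf,
    binomial_tail,
    call_nads,
    class_cf_distribution,
    contact_frequency,
    false_positive_model,
    implied_contamination,
    min_passing_count,
    per_cell_coverage,
    quintile_coverage_vs_cf,
    rpkm,
    signal_at_nad_classes,
)
from nadscope.genome import ValidationError


def exact_tail(k: int, n: int, p: Fraction) -> Fraction:
    """Arbitrary-precision P(X >= k), X ~ Binomial(n, p), by rational summation."""
    return sum(
        Fraction(comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


class TestContactFrequency:
    def test_cf_is_count_proportion(self, toy_bins):
        cols = [np.zeros(toy_bins.n_bins) for _ in range(4)]
        for c in cols[:3]:
            c[0] = 1
        m = toy_matrix(toy_bins, cols)
        cf = contact_frequency(m)
        assert cf.cf[0] == pytest.approx(0.75)
        assert cf.counts[0] == 3
        assert cf.cf[1:].sum() == 0

    def test_permutation_invariance(self, toy_bins):
        rng = np.random.default_rng(5)
        cols = [(rng.random(toy_bins.n_bins) < 0.3) for _ in range(6)]
        m = toy_matrix(toy_bins, cols)
        perm = toy_matrix(toy_bins, [cols[i] for i in [3, 1, 5, 0, 4, 2]])
        np.testing.assert_array_equal(contact_frequency(m).cf, contact_frequency(perm).cf)


class TestCallNads:
    def test_strict_inequality_at_threshold(self, toy_bins):
        # 11/53 passes the >0.20 cutoff, 10/53 does not, 0.20 exactly neither
        cols = [np.zeros(toy_bins.n_bins) for _ in range(53)]
        for c in cols[:11]:
            c[0] = 1
        for c in cols[:10]:
            c[1] = 1
        m = toy_matrix(toy_bins, cols)
        callset = call_nads(contact_frequency(m), 0.20)
        assert callset.flags[0]  # 11/53 ~ 0.2075 > 0.20
        assert not callset.flags[1]  # 10/53 ~ 0.1887
        cols5 = [np.zeros(toy_bins.n_bins) for _ in range(5)]
        cols5[0][2] = 1  # CF exactly 0.20
        callset5 = call_nads(contact_frequency(toy_matrix(toy_bins, cols5)), 0.20)
        assert not callset5.flags[2]

    def test_segment_merging(self, toy_bins):
        col = np.zeros(toy_bins.n_bins)
        col[[0, 1, 3]] = 1  # flags 1,1,0,1 -> two segments on chromosome 1
        callset = call_nads(contact_frequency(toy_matrix(toy_bins, [col])), 0.5)
        segs = callset.segments()
        assert len(segs) == 2
        assert segs.iloc[0]["n_bins"] == 2
        assert segs.iloc[0]["bp"] == 200_000

    def test_mean_segment_bp_matches_run_length_oracle(self, default_cohort):
        _, _, matrix = default_cohort
        callset = call_nads(contact_frequency(matrix), 0.20)
        segs = callset.segments()
        runs = []
        for chrom in matrix.bins.chrom_sizes:
            sl = matrix.bins.chrom_slice(chrom)
            flags = callset.flags[sl].astype(int)
            starts = np.nonzero(np.diff(np.concatenate(([0], flags))) == 1)[0]
            ends = np.nonzero(np.diff(np.concatenate((flags, [0]))) == -1)[0]
            widths = matrix.bins.widths[sl]
            runs.extend(int(widths[a : b + 1].sum()) for a, b in zip(starts, ends))
        assert len(segs) == len(runs)
        assert segs["bp"].mean() == pytest.approx(np.mean(runs))

    def test_cell_order_invariance(self, default_cohort):
        _, _, matrix = default_cohort
        rng = np.random.default_rng(0)
        perm = matrix.subset_cells(rng.permutation(matrix.n_cells))
        a = call_nads(contact_frequency(matrix), 0.20)
        b = call_nads(contact_frequency(perm), 0.20)
        np.testing.assert_array_equal(a.flags, b.flags)


class TestBinomialModel:
    def test_tail_and_cdf_boundary_identities(self):
        assert binomial_tail(0, 53, 0.3) == 1.0
        assert binomial_cdf(53, 53, 0.3) == 1.0

    def test_tail_matches_exact_rational_summation(self):
        got = binomial_tail(12, 53, 0.05)
        want = float(exact_tail(12, 53, Fraction(1, 20)))
        assert abs(got - want) / want < 1e-10

    @pytest.mark.parametrize("n", [1, 7, 20, 53, 100])
    def test_oracle_equivalence_over_p_grid(self, n):
        """binomial_tail agrees with arbitrary-precision summation."""
        for p_frac in [Fraction(1, 100), Fraction(1, 20), Fraction(1, 10),
                       Fraction(1, 3), Fraction(4, 5)]:
            for k in {0, 1, n // 2, n}:
                want = exact_tail(k, n, p_frac)
                got = binomial_tail(k, n, float(p_frac))
                if want > 0:
                    assert abs(got - float(want)) / float(want) < 1e-10

    def test_minimal_passing_count_for_53_cells(self):
        assert min_passing_count(53, 0.20) == 11
        # brute force: 11 is the smallest k with k/53 > 0.20
        assert all(k / 53 <= 0.20 for k in range(11))
        assert 11 / 53 > 0.20

    def test_worked_false_positive_example(self):
        """27,904 bins x per-bin rate 1.44e-6 -> ~0.04 expected false calls."""
        p_star = implied_contamination(1.44e-6, n=53, threshold=0.20)
        model = false_positive_model(53, p_star, 0.20, n_bins=27_904)
        assert model.k_min == 11
        assert model.per_bin_rate == pytest.approx(1.44e-6, rel=1e-6)
        assert model.expected_false_positives == pytest.approx(0.0402, abs=0.001)

    def test_zero_noise_gives_zero_false_positives(self):
        model = false_positive_model(53, 0.0, 0.20, n_bins=27_904)
        assert model.per_bin_rate == 0.0
        assert model.expected_false_positives == 0.0

    def test_model_monotonicities(self):
        base = false_positive_model(53, 0.05, 0.20, 10_000)
        assert false_positive_model(53, 0.08, 0.20, 10_000).per_bin_rate > base.per_bin_rate
        assert false_positive_model(53, 0.05, 0.30, 10_000).per_bin_rate < base.per_bin_rate
        assert false_positive_model(53, 0.05, 0.20, 20_000).expected_false_positives == pytest.approx(
            2 * base.expected_false_positives
        )


class TestImpliedContamination:
    def test_round_trip_inverse_consistency(self):
        rate = binomial_tail(11, 53, 0.04)
        assert implied_contamination(rate, 53, 0.20) == pytest.approx(0.04, abs=1e-6)

    def test_paper_rate_inversion_matches_grid_search(self):
        p_star = implied_contamination(1.44e-6, 53, 0.20)
        assert 0 < p_star < 1
        # dense-grid brute-force oracle
        grid = np.linspace(1e-4, 0.2, 20_000)
        rates = np.array([binomial_tail(11, 53, p) for p in grid])
        p_grid = grid[np.argmin(np.abs(rates - 1.44e-6))]
        assert abs(p_star - p_grid) < 2e-5

    def test_monotone_in_target_rate(self):
        lo = implied_contamination(1e-8, 53, 0.20)
        hi = implied_contamination(1e-4, 53, 0.20)
        assert hi > lo

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValidationError):
            implied_contamination(0.0, 53, 0.20)


class TestCoverage:
    def test_full_and_empty_columns(self, toy_bins):
        m = toy_matrix(toy_bins, [np.ones(toy_bins.n_bins), np.zeros(toy_bins.n_bins)])
        cov = per_cell_coverage(m)
        assert cov["raw"].tolist() == [1.0, 0.0]

    def test_default_cohort_recovers_15_percent_capture(self, default_cohort):
        _, _, matrix = default_cohort
        cov = per_cell_coverage(matrix)
        assert cov["raw"].mean() == pytest.approx(0.15, abs=0.02)

    def test_nad_restricted_coverage_never_exceeds_raw(self, default_cohort):
        _, _, matrix = default_cohort
        callset = call_nads(contact_frequency(matrix), 0.20)
        cov = per_cell_coverage(matrix, callset)
        assert (cov["nad_restricted"] <= cov["raw"] + 1e-12).all()


class TestStratifiedSummaries:
    def test_quintile1_only_cohort(self, toy_bins, toy_annotation):
        col = (toy_annotation.bin_quintile == 1).astype(float)
        m = toy_matrix(toy_bins, [col] * 5)
        callset = call_nads(contact_frequency(m), 0.20)
        table = quintile_coverage_vs_cf(m, callset, toy_annotation)
        populated = table.dropna(subset=["quintile1_share"])
        assert (populated["quintile1_share"] == 1.0).all()

    def test_rdna_boost_concentrates_high_cf_on_rdna_class(self):
        """Planted rDNA-chromosome contact boost makes the rDNA-class CF
        distribution stochastically dominate the non-rDNA class."""
        from nadscope.cohort import SimulationConfig, simulate_capture, simulate_truth
        from nadscope.genome import annotate

        config = SimulationConfig(n_populations=1, rdna_contact_boost=2.0, seed=3)
        truth = simulate_truth(config)
        matrix, _, _ = simulate_capture(truth, config)
        ann = annotate(matrix.bins)
        cf = contact_frequency(matrix)
        dist = class_cf_distribution(cf, ann)
        # dominance among NAD bins, where the boost acts
        rdna_nad = truth.nad & (ann.bin_class == "rDNA")
        non_nad = truth.nad & (ann.bin_class == "non_rDNA")
        for quantile in (0.25, 0.5, 0.75):
            assert np.quantile(cf.cf[rdna_nad], quantile) >= np.quantile(cf.cf[non_nad], quantile)
        assert cf.cf[rdna_nad].mean() > cf.cf[non_nad].mean()
        assert set(dist["class"]) == {"rDNA", "non_rDNA", "X", "Y"}

    def test_all_zero_matrix_degenerates_to_step_at_zero(self, toy_bins, toy_annotation):
        m = toy_matrix(toy_bins, [np.zeros(toy_bins.n_bins)])
        dist = class_cf_distribution(contact_frequency(m), toy_annotation)
        assert (dist["cf"] == 0).all()


class TestRPKM:
    def test_formula_and_degenerate_cases(self):
        assert rpkm(10, 1_000_000, 1000) == pytest.approx(10.0)
        assert rpkm(0, 1_000_000, 1000) == 0.0
        assert rpkm(10, 2_000_000, 1000) == pytest.approx(5.0)  # doubling N halves

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            rpkm(10, 0, 1000)
        with pytest.raises(ValidationError):
            rpkm(10, 1e6, 0)


class TestSignalComparison:
    def test_identical_sets_show_no_difference(self, toy_bins):
        rng = np.random.default_rng(2)
        signal = rng.normal(size=toy_bins.n_bins)
        mask = np.zeros(toy_bins.n_bins, bool)
        mask[:20] = True
        summary, tests = signal_at_nad_classes({"a": mask, "b": mask.copy()}, signal)
        assert tests.iloc[0]["mean_diff"] == pytest.approx(0.0)
        assert tests.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_planted_shift_detected_with_high_power(self):
        """+1 sd shift on 500 bins/set rejects at alpha=0.01."""
        rng = np.random.default_rng(4)
        rejections = 0
        for rep in range(20):
            signal = np.concatenate([rng.normal(1.0, 1.0, 500), rng.normal(0.0, 1.0, 500)])
            mask_a = np.arange(1000) < 500
            _, tests = signal_at_nad_classes({"a": mask_a, "b": ~mask_a}, signal)
            rejections += tests.iloc[0]["p_value"] < 0.01
        assert rejections == 20

    def test_missing_signal_is_skipped_not_zero(self, toy_bins):
        signal = np.full(toy_bins.n_bins, np.nan)
        signal[:10] = 1.0
        mask = np.zeros(toy_bins.n_bins, bool)
        mask[:20] = True  # half the set is missing
        summary, _ = signal_at_nad_classes({"a": mask, "b": mask}, signal)
        assert summary.iloc[0]["n"] == 10
        assert summary.iloc[0]["mean"] == pytest.approx(1.0)
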