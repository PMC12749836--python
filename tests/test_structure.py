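import numpy as np
import pytest

from conftest import toy_matrix
from nadscope.cf import contact_frequency
from nadscope.cohort import SimulationConfig, simulate_capture, simulate_truth
from nadscope.genome import ValidationError, annotate, build_bins
from nadscope.structure import (
    ACFCurve,
    acf,
    fit_exponential,
    randomized_cohort,
    subsample_saturation,
    yules_q,
)


class TestSubsampleSaturation:
    def test_full_size_subsample_has_unit_jaccard(self, default_cohort):
        _, _, matrix = default_cohort
        table = subsample_saturation(matrix, sizes=[matrix.n_cells - 1, matrix.n_cells],
                                     reps=3, seed=0)
        full = table[table["size"] == matrix.n_cells]
        assert (full["jaccard"] == 1.0).all()

    def test_jaccard_non_decreasing_in_subsample_size(self, default_cohort):
        _, _, matrix = default_cohort
        table = subsample_saturation(matrix, sizes=[10, 20, 30, 40], reps=20, seed=0)
        means = table.groupby("size")["jaccard"].mean()
        assert (np.diff(means.to_numpy()) >= 0).all()

    def test_duplicate_cell_cohort_saturates_immediately(self, toy_bins):
        col = np.zeros(toy_bins.n_bins)
        col[:10] = 1
        matrix = toy_matrix(toy_bins, [col] * 12)
        table = subsample_saturation(matrix, sizes=[2, 5], reps=5, seed=0)
        assert (table["jaccard"] == 1.0).all()

    def test_oversized_subsample_rejected(self, toy_bins):
        matrix = toy_matrix(toy_bins, [np.zeros(toy_bins.n_bins)] * 3)
        with pytest.raises(ValidationError):
            subsample_saturation(matrix, sizes=[4], reps=1)


class TestRandomizedCohort:
    def test_column_sums_preserved_exactly(self, default_cohort):
        _, _, matrix = default_cohort
        rand = randomized_cohort(matrix, seed=1)
        np.testing.assert_array_equal(rand.cell_bin_counts(), matrix.cell_bin_counts())

    def test_different_seeds_differ_but_keep_sums(self, default_cohort):
        _, _, matrix = default_cohort
        r1 = randomized_cohort(matrix, seed=1)
        r2 = randomized_cohort(matrix, seed=2)
        assert (r1.states != r2.states).any()
        np.testing.assert_array_equal(r1.cell_bin_counts(), r2.cell_bin_counts())

    def test_randomization_abolishes_rdna_cf_excess(self):
        """The planted rDNA-class CF excess of a structured cohort falls below
        3 permutation-null standard deviations after coverage-matched
        randomization."""
        cfg = SimulationConfig(n_populations=1, rdna_contact_boost=2.0, seed=4)
        truth = simulate_truth(cfg)
        matrix, _, _ = simulate_capture(truth, cfg)
        ann = annotate(matrix.bins, rdna_chroms=cfg.rdna_chroms)
        rdna = ann.bin_class == "rDNA"
        non = ann.bin_class == "non_rDNA"

        def class_delta(m):
            cf = contact_frequency(m).cf
            return cf[rdna].mean() - cf[non].mean()

        structured = class_delta(matrix)
        # permutation null: distribution of the delta under random bin labels
        rng = np.random.default_rng(0)
        cf = contact_frequency(matrix).cf
        null = []
        for _ in range(200):
            perm = rng.permutation(cf)
            null.append(perm[rdna].mean() - perm[non].mean())
        null_sd = np.std(null)
        assert structured > 3 * null_sd  # the planted excess is real
        randomized = class_delta(randomized_cohort(matrix, seed=5))
        assert abs(randomized) < 3 * null_sd  # and randomization destroys it


class TestYulesQ:
    def test_identical_cells_have_q_one(self, toy_bins):
        col = np.zeros(toy_bins.n_bins)
        col[:5] = 1
        q = yules_q(toy_matrix(toy_bins, [col, col.copy()]))
        assert q.q[0, 1] == pytest.approx(1.0)

    def test_complementary_cells_have_q_minus_one(self, toy_bins):
        a = np.zeros(toy_bins.n_bins)
        a[: toy_bins.n_bins // 2] = 1
        b = 1 - a
        q = yules_q(toy_matrix(toy_bins, [a, b]))
        assert q.q[0, 1] == pytest.approx(-1.0)

    def test_worked_2x2_example(self, toy_bins):
        # a=3 (both), b=1, c=1, d=n-5 -> use 8-bin genome for d=3
        bins8 = build_bins({"chrA": 800_000}, 100_000)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.uint8)
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=np.uint8)
        q = yules_q(toy_matrix(bins8, [x, y]))
        assert q.q[0, 1] == pytest.approx((3 * 3 - 1 * 1) / (3 * 3 + 1 * 1))

    def test_undefined_pairs_are_missing_not_zero(self, toy_bins):
        ones = np.ones(toy_bins.n_bins)
        zeros = np.zeros(toy_bins.n_bins)
        q = yules_q(toy_matrix(toy_bins, [ones, zeros]))
        assert np.isnan(q.q[0, 1])  # a=d=0 with b*c=0 -> undefined
        assert q.pair_values().size == 0

    def test_symmetry_and_bin_relabel_invariance(self, default_cohort):
        _, _, matrix = default_cohort
        q = yules_q(matrix).q
        np.testing.assert_allclose(q, q.T, atol=1e-12)
        rng = np.random.default_rng(8)
        perm = rng.permutation(matrix.bins.n_bins)
        from nadscope.contacts import ContactMatrix

        shuffled = ContactMatrix(bins=matrix.bins, cells=matrix.cells,
                                 states=matrix.states[perm])
        np.testing.assert_allclose(yules_q(shuffled).q, q, atol=1e-12)

    def test_heterogeneous_cohort_has_lower_median_q_than_homogeneous(self):
        """Cell-to-cell variability lowers Yule's Q: a two-population cohort
        shows lower median pairwise Q than a single-population cohort with
        the same capture settings."""
        hetero_cfg = SimulationConfig(n_populations=2, seed=10)
        homo_cfg = SimulationConfig(n_populations=1, seed=10)
        truth_het = simulate_truth(hetero_cfg)
        truth_hom = simulate_truth(homo_cfg)
        m_het, _, _ = simulate_capture(truth_het, hetero_cfg)
        m_hom, _, _ = simulate_capture(truth_hom, homo_cfg)
        med_het = np.median(yules_q(m_het).pair_values())
        med_hom = np.median(yules_q(m_hom).pair_values())
        assert med_het < med_hom


class TestACF:
    def test_alternating_profile_analytic_values(self):
        bins = build_bins({"chrA": 2_000_000}, 100_000)
        profile = np.tile([0.0, 1.0], 10)
        curve = acf(profile, bins, max_lag=4)
        assert curve.values[0] == pytest.approx(-1.0)
        assert curve.values[1] == pytest.approx(1.0)

    def test_iid_profile_has_no_autocorrelation(self):
        bins = build_bins({"chrA": 100_000 * 10_000}, 100_000)
        rng = np.random.default_rng(12)
        profile = (rng.random(10_000) < 0.3).astype(float)
        curve = acf(profile, bins, max_lag=20)
        assert np.nanmax(np.abs(curve.values)) < 0.05

    def test_matches_brute_force_pearson_oracle(self, default_cohort):
        _, _, matrix = default_cohort
        j = 0
        curve = acf(matrix.states[:, j].astype(float), matrix.bins, max_lag=10)
        for h in range(1, 11):
            nums, weights = [], []
            for chrom in matrix.bins.chrom_sizes:
                x = matrix.states[matrix.bins.chrom_slice(chrom), j].astype(float)
                if x.size <= h + 1 or np.all(x == x[0]):
                    continue
                lead, lagd = x[:-h], x[h:]
                if lead.std() == 0 or lagd.std() == 0:
                    continue
                r = np.corrcoef(lead, lagd)[0, 1]
                nums.append(r)
                weights.append(x.size - h)
            expected = np.average(nums, weights=weights)
            assert abs(curve.values[h - 1] - expected) < 1e-12

    def test_constant_profile_flagged_missing(self, toy_bins):
        curve = acf(np.ones(toy_bins.n_bins), toy_bins, max_lag=5)
        assert np.isnan(curve.values).all()

    def test_acf_never_crosses_chromosome_boundaries(self):
        # two chromosomes, each internally constant but different values:
        # any cross-boundary correlation would be spurious
        bins = build_bins({"a": 500_000, "b": 500_000}, 100_000)
        profile = np.concatenate([np.zeros(5), np.ones(5)])
        curve = acf(profile, bins, max_lag=3)
        assert np.isnan(curve.values).all()  # both chromosomes constant -> skipped


class TestFitExponential:
    @pytest.mark.parametrize("a,b", [(0.74, 0.23), (0.64, 0.34)])
    def test_noiseless_model_recovery(self, a, b):
        """Exact recovery of decay parameters from noiseless curves."""
        lags = np.arange(1, 51)
        curve = ACFCurve(lags=lags, values=a * np.exp(-b * lags))
        fit = fit_exponential(curve)
        assert fit.a == pytest.approx(a, abs=1e-6)
        assert fit.b == pytest.approx(b, abs=1e-6)

    def test_constant_positive_curve_fits_zero_decay(self):
        lags = np.arange(1, 21)
        curve = ACFCurve(lags=lags, values=np.full(20, 0.4))
        fit = fit_exponential(curve)
        assert fit.b == pytest.approx(0.0, abs=1e-8)
        assert fit.a == pytest.approx(0.4, abs=1e-6)
        # grid-search oracle: no (a, b) on a coarse grid beats the fit
        best = min(
            ((aa, bb) for aa in np.linspace(0.1, 0.8, 30) for bb in np.linspace(0, 1, 30)),
            key=lambda ab: np.sum((curve.values - ab[0] * np.exp(-ab[1] * lags)) ** 2),
        )
        fit_sse = np.sum((curve.values - fit.predict(lags)) ** 2)
        grid_sse = np.sum((curve.values - best[0] * np.exp(-best[1] * lags)) ** 2)
        assert fit_sse <= grid_sse + 1e-12

    def test_too_few_points_rejected(self):
        curve = ACFCurve(lags=np.array([1, 2]), values=np.array([0.5, 0.4]))
        with pytest.raises(ValidationError):
            fit_exponential(curve)

    def test_randomization_destroys_initial_autocorrelation(self, default_cohort):
        """Fitted initial autocorrelation drops on coverage-matched
        randomized profiles relative to structured profiles."""
        _, _, matrix = default_cohort
        rand = randomized_cohort(matrix, seed=3)

        def mean_fitted_a(m, n=10):
            fits = []
            for curve in acf(m.subset_cells(range(n)), max_lag=30):
                x, _ = curve.finite()
                if x.size >= 3:
                    fits.append(fit_exponential(curve).a)
            return np.mean(fits)

        assert mean_fitted_a(matrix) > mean_fitted_a(rand)
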