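"""Transform, variance model, nested fits, and model assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import optimize, stats

from poolbsa import (
    asin_sqrt,
    assign_best_model,
    bh_fdr,
    compute_shifts,
    fit_free,
    fit_group,
    fit_parallel,
    loglik_null,
    lrt_pvalues,
    run_bsa,
    sampling_variance,
)
from poolbsa.bsa import MODEL_LABELS

from conftest import make_counts

HIGH = np.array([True, True, False, False])


def fit_all(dz, var):
    ll0 = loglik_null(dz, var)
    _, ll1 = fit_parallel(dz, var)
    _, _, ll2 = fit_group(dz, var, HIGH)
    _, ll4 = fit_free(dz, var)
    return ll0, ll1, ll2, ll4


class TestTransform:
    @pytest.mark.parametrize(
        "p, z",
        [(0.0, 0.0), (0.25, np.pi / 6), (1.0, np.pi / 2), (0.5, np.pi / 4)],
    )
    def test_known_values(self, p, z):
        assert asin_sqrt(p) == pytest.approx(z, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            asin_sqrt(1.5)
        with pytest.raises(ValueError):
            asin_sqrt(-0.1)


class TestSamplingVariance:
    def test_paper_scale_pools(self):
        # 150 females at depth 100: 1/1200 + 1/400
        assert sampling_variance(150, 100) == pytest.approx(1 / 1200 + 1 / 400)

    def test_minimal_pool(self):
        assert sampling_variance(1, 1) == pytest.approx(0.375)

    def test_depth_limit_is_pool_term(self):
        assert sampling_variance(150, 1e12) == pytest.approx(1 / 1200, rel=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sampling_variance(0, 100)
        with pytest.raises(ValueError):
            sampling_variance(150, 0)


class TestComputeShifts:
    def test_identical_pools_zero_shift(self, design):
        counts = make_counts([{}])
        shifts = compute_shifts(counts, design)
        assert np.allclose(shifts.dz, 0.0)

    def test_closed_form_shift_and_variance(self, design):
        counts = make_counts(
            [{"BBM_control": (25, 100), "BBM_selected": (75, 100)}]
        )
        shifts = compute_shifts(counts, design)
        j = shifts.populations.index("BBM")
        assert shifts.dz[0, j] == pytest.approx(np.pi / 6, abs=1e-12)
        assert shifts.var[0, j] == pytest.approx(2 * (1 / 1200 + 1 / 400))

    def test_swapping_pools_negates_dz(self, design):
        counts = make_counts(
            [{"BBM_control": (25, 100), "BBM_selected": (75, 100)}]
        )
        swapped = make_counts(
            [{"BBM_control": (75, 100), "BBM_selected": (25, 100)}]
        )
        a = compute_shifts(counts, design)
        b = compute_shifts(swapped, design)
        assert np.allclose(a.dz, -b.dz)
        assert np.allclose(a.var, b.var)

    def test_zero_depth_rejected(self, design):
        counts = make_counts([{"GPO_control": (0, 0)}])
        with pytest.raises(ValueError, match="zero depth"):
            compute_shifts(counts, design)


class TestLikelihoods:
    def test_null_loglik_at_zero_shift(self):
        dz, var = np.zeros(4), np.full(4, 0.005)
        expected = -0.5 * np.sum(np.log(2 * np.pi * var))
        assert loglik_null(dz, var) == pytest.approx(expected)
        assert loglik_null(dz, var) == pytest.approx(6.92088, abs=1e-5)

    def test_null_loglik_one_standardized_unit(self):
        v = 0.004
        ll = loglik_null(np.array([np.sqrt(v)]), np.array([v]))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * v) - 0.5)

    def test_null_loglik_decreases_with_shift(self):
        var = np.full(4, 0.005)
        lls = [loglik_null(np.full(4, d), var) for d in (0.0, 0.05, 0.1)]
        assert lls[0] > lls[1] > lls[2]

    def test_parallel_equal_variances_is_mean(self):
        dz = np.array([0.1, 0.3, -0.2, 0.0])
        delta, _ = fit_parallel(dz, np.full(4, 0.005))
        assert delta == pytest.approx(dz.mean())

    def test_parallel_weighted_mean(self):
        dz = np.array([0.1, 0.2])
        var = np.array([0.01, 0.02])
        delta, _ = fit_parallel(dz, var)
        assert delta == pytest.approx((0.1 / 0.01 + 0.2 / 0.02) / (1 / 0.01 + 1 / 0.02))

    def test_group_single_population_groups(self):
        dz = np.array([0.3, -0.1])
        var = np.array([0.005, 0.005])
        d_high, d_low, _ = fit_group(dz, var, [True, False])
        assert d_high == pytest.approx(0.3)
        assert d_low == pytest.approx(-0.1)

    def test_group_requires_both_groups(self):
        with pytest.raises(ValueError):
            fit_group(np.zeros(4), np.full(4, 0.005), [True] * 4)

    def test_free_returns_observed_shifts(self):
        dz = np.array([0.2, 0.2, 0.0, 0.0])
        var = np.full(4, 0.005)
        delta, ll4 = fit_free(dz, var)
        assert np.allclose(delta, dz)
        assert ll4 == pytest.approx(-0.5 * np.sum(np.log(2 * np.pi * var)))


class TestMicroExamples:
    """Hand-derivable four-population cases exercising all three LRTs."""

    def test_parallel_shift_case(self):
        dz, var = np.full(4, 0.1), np.full(4, 0.005)
        ll0, ll1, ll2, ll4 = fit_all(dz, var)
        (l1, p1), (l2, p2), (l4, p4) = lrt_pvalues(ll0, ll1, ll2, ll4)
        # LRT1 = delta^2 sum(1/V) = 0.01 * 800 = 8; identical dz makes
        # the group and free fits no better than the parallel fit.
        assert l1 == pytest.approx(8.0, abs=1e-9)
        assert l2 == pytest.approx(8.0, abs=1e-9)
        assert l4 == pytest.approx(8.0, abs=1e-9)
        assert p1 == pytest.approx(0.004678, abs=1e-6)
        assert p2 == pytest.approx(np.exp(-4.0), rel=1e-9)
        assert p4 == pytest.approx(stats.chi2.sf(8.0, 4), rel=1e-9)
        assert assign_best_model(p1, p2, p4, ll1, ll2, ll4) == "LRT1"

    def test_group_shift_case(self):
        dz, var = np.array([0.2, 0.2, 0.0, 0.0]), np.full(4, 0.005)
        ll0, ll1, ll2, ll4 = fit_all(dz, var)
        (l1, p1), (l2, p2), (l4, p4) = lrt_pvalues(ll0, ll1, ll2, ll4)
        assert l1 == pytest.approx(8.0, abs=1e-9)
        assert l2 == pytest.approx(16.0, abs=1e-9)
        assert l4 == pytest.approx(16.0, abs=1e-9)
        assert p2 == pytest.approx(np.exp(-8.0), rel=1e-9)
        assert assign_best_model(p1, p2, p4, ll1, ll2, ll4) == "LRT2"

    def test_all_zero_shifts(self):
        dz, var = np.zeros(4), np.full(4, 0.005)
        ll0, ll1, ll2, ll4 = fit_all(dz, var)
        (l1, p1), (l2, p2), (l4, p4) = lrt_pvalues(ll0, ll1, ll2, ll4)
        assert l1 == l2 == l4 == 0.0
        assert p1 == p2 == p4 == 1.0


class TestLrtPvalues:
    def test_negative_lrt_beyond_tolerance_raises(self):
        with pytest.raises(ValueError, match="negative"):
            lrt_pvalues(np.array([1.0]), np.array([0.9]),
                        np.array([1.0]), np.array([1.0]))

    def test_tiny_negative_lrt_clipped(self):
        (l1, p1), _, _ = lrt_pvalues(1.0, 1.0 - 1e-12, 1.0, 1.0)
        assert l1 == 0.0 and p1 == 1.0


class TestBhFdr:
    def test_step_up_by_hand(self):
        _, flags = bh_fdr([0.001, 0.02, 0.8], q=0.1)
        assert flags.tolist() == [True, True, False]

    def test_all_ones_nothing_flagged(self):
        _, flags = bh_fdr([1.0, 1.0, 1.0], q=0.1)
        assert not flags.any()

    def test_single_pvalue(self):
        _, flags = bh_fdr([0.05], q=0.1)
        assert flags.tolist() == [True]

    def test_empty_input(self):
        adjusted, flags = bh_fdr([], q=0.1)
        assert len(adjusted) == 0 and len(flags) == 0

    def test_matches_manual_step_up(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1.0, size=200)
        adjusted, flags = bh_fdr(p, q=0.10)
        # independent step-up oracle
        m = len(p)
        order = np.argsort(p)
        thresh = 0.10 * (np.arange(1, m + 1)) / m
        passing = np.flatnonzero(p[order] <= thresh)
        expect = np.zeros(m, dtype=bool)
        if passing.size:
            expect[order[: passing.max() + 1]] = True
        assert flags.tolist() == expect.tolist()


class TestAssignBestModel:
    def test_underflow_tie_broken_by_loglik(self):
        assert assign_best_model(0.0, 0.0, 0.0, 10.0, 12.0, 15.0) == "LRT4"

    def test_exact_tie_and_equal_loglik_prefers_parsimony(self):
        assert assign_best_model(0.01, 0.01, 0.01, 5.0, 5.0, 5.0) == "LRT1"

    def test_small_pvalues_not_spuriously_tied(self):
        # p1 and p4 are both tiny but orders of magnitude apart: the
        # smaller raw p must win even though |p1 - p4| < 1e-12.
        assert (
            assign_best_model(1e-17, 1e-14, 1e-15, 10.0, 12.0, 15.0)
            == "LRT1"
        )

    @pytest.mark.parametrize("winner", [0, 1, 2])
    def test_minimum_pvalue_wins(self, winner):
        ps = np.array([0.02, 0.02, 0.02])
        ps[winner] = 0.001
        assert assign_best_model(*ps, 1.0, 2.0, 3.0) == MODEL_LABELS[winner]


class TestOracleEquivalence:
    """Closed-form MLEs against independent numeric maximization."""

    def test_parallel_and_group_match_numeric_optimum(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            dz = rng.normal(0, 0.2, size=4)
            var = rng.uniform(0.001, 0.02, size=4)

            delta1, ll1 = fit_parallel(dz, var)
            res1 = optimize.minimize_scalar(
                lambda d: -stats.norm.logpdf(dz, d, np.sqrt(var)).sum(),
                bounds=(-2, 2), method="bounded",
                options={"xatol": 1e-12},
            )
            assert delta1 == pytest.approx(res1.x, abs=1e-6)
            assert ll1 == pytest.approx(-res1.fun, abs=1e-6)

            d_high, d_low, ll2 = fit_group(dz, var, HIGH)
            means = np.where(HIGH, 0, 1)

            def nll(theta):
                mu = np.asarray(theta)[means]
                return -stats.norm.logpdf(dz, mu, np.sqrt(var)).sum()

            res2 = optimize.minimize(
                nll, x0=[0.0, 0.0], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12},
            )
            assert d_high == pytest.approx(res2.x[0], abs=1e-6)
            assert d_low == pytest.approx(res2.x[1], abs=1e-6)
            assert ll2 == pytest.approx(-res2.fun, abs=1e-6)


@st.composite
def shift_arrays(draw):
    dz = draw(hnp.arrays(np.float64, 4, elements=st.floats(-1.5, 1.5)))
    var = draw(hnp.arrays(np.float64, 4, elements=st.floats(1e-4, 0.05)))
    return dz, var


class TestModelProperties:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(shift_arrays())
    def test_nesting_of_likelihoods_and_statistics(self, arrays):
        dz, var = arrays
        ll0, ll1, ll2, ll4 = fit_all(dz, var)
        eps = 1e-9
        assert ll0 <= ll1 + eps <= ll2 + 2 * eps <= ll4 + 3 * eps
        (l1, _), (l2, _), (l4, _) = lrt_pvalues(ll0, ll1, ll2, ll4)
        assert 0 <= l1 <= l2 + eps <= l4 + 2 * eps

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(shift_arrays(), st.floats(0.25, 4.0))
    def test_scale_equivariance(self, arrays, c):
        dz, var = arrays
        stats_a = lrt_pvalues(*fit_all(dz, var))
        stats_b = lrt_pvalues(*fit_all(dz * np.sqrt(c), var * c))
        for (la, _), (lb, _) in zip(stats_a, stats_b):
            assert la == pytest.approx(lb, abs=1e-6, rel=1e-6)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(shift_arrays())
    def test_antisymmetry_under_allele_relabeling(self, arrays):
        dz, var = arrays
        stats_a = lrt_pvalues(*fit_all(dz, var))
        stats_b = lrt_pvalues(*fit_all(-dz, var))
        for (la, pa), (lb, pb) in zip(stats_a, stats_b):
            assert la == pytest.approx(lb, abs=1e-9)
            assert pa == pytest.approx(pb, abs=1e-12)


class TestRunBsa:
    def test_null_simulation_flags_almost_nothing(self, null_run):
        result, _ = null_run
        # BH under a global null controls family-wise-like behaviour
        assert result.summary["n_significant"] <= 5

    def test_table_has_one_row_per_snp_and_models_only_when_flagged(
        self, mixture_run
    ):
        result, truth = mixture_run
        assert len(result.table) == len(truth)
        flagged = result.table["significant"]
        assert (result.table.loc[~flagged, "best_model"] == "none").all()
        assert (result.table.loc[flagged, "best_model"]
                .isin(MODEL_LABELS).all())

    def test_parallel_truth_makes_parallel_model_modal(self, mixture_run):
        result, _ = mixture_run
        flagged = result.table[result.table["significant"]]
        assert flagged["best_model"].mode()[0] == "LRT1"
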