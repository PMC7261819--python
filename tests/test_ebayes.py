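"""Empirical-Bayes machinery: moments, d0 estimation, moderation, BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from deqms.datamodel import DesignSpec, RunConfig, ValidationError
from deqms.ebayes import (
    bh_adjust,
    compute_eg,
    estimate_d0,
    estimate_d0_newton,
    fit_trend,
    moderated_f,
    moderated_t,
    posterior_variance,
    prior_variance,
    spectra_count_ebayes,
    trigamma_inverse,
)
from deqms.linear_models import fit_group_means
from deqms.simulate import default_null_spec, simulate_null

from conftest import make_matrix


def design_of(groups):
    return DesignSpec(
        sample_to_group={f"s{j + 1}": g for j, g in enumerate(groups)}
    )


class TestComputeEg:
    def test_hand_computed(self):
        # d_g = 4, s_p^2 = 1: e_g = -digamma(2) + log 2 ~ 0.2704
        e = compute_eg(np.array([1.0]), 4)
        assert e[0] == pytest.approx(-special.digamma(2.0) + np.log(2.0))
        assert e[0] == pytest.approx(0.27036, abs=1e-5)

    def test_inversion_gives_zero(self):
        dg = 6
        v = np.exp(special.digamma(dg / 2) - np.log(dg / 2))
        assert compute_eg(np.array([v]), dg)[0] == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.1, 2.0, 50)
        shift = compute_eg(v * 3.0, 4) - compute_eg(v, 4)
        np.testing.assert_allclose(shift, np.log(3.0), rtol=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            compute_eg(np.array([0.0, 1.0]), 4)


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.1, 0.5, 1.0, 5.0, 50.0])
    def test_round_trip(self, x):
        assert trigamma_inverse(special.polygamma(1, x)) == pytest.approx(
            x, abs=1e-6
        )

    def test_classical_value(self):
        # trigamma(1) = pi^2/6
        assert trigamma_inverse(np.pi**2 / 6) == pytest.approx(1.0, abs=1e-6)

    def test_limits_monotone(self):
        assert trigamma_inverse(1e6) < trigamma_inverse(1.0) < trigamma_inverse(1e-6)
        assert trigamma_inverse(1e6) < 1e-2
        assert trigamma_inverse(1e-6) > 1e2

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            trigamma_inverse(0.0)


class TestEstimateD0:
    def test_result_on_grid(self):
        rng = np.random.default_rng(1)
        sp2 = 0.1 * 3 / rng.chisquare(3, 2000) * rng.chisquare(4, 2000) / 4
        eg = compute_eg(sp2, 4)
        d0 = estimate_d0(eg, np.full_like(eg, eg.mean()), 4)
        assert d0 == pytest.approx(round(d0 * 10) / 10)

    def test_underdispersed_returns_inf(self):
        # spread below the sampling floor trigamma(d_g/2): no finite d0
        eg = np.zeros(100)
        assert np.isinf(estimate_d0(eg, eg, 4))

    def test_parameter_recovery(self):
        # pooled variances from a scaled inverse-chi-square prior (d0=4)
        rng = np.random.default_rng(99)
        n, dg, d0_true = 5000, 4, 4.0
        prior = 0.05 * d0_true / rng.chisquare(d0_true, n)
        sp2 = prior * rng.chisquare(dg, n) / dg
        eg = compute_eg(sp2, dg)
        d0 = estimate_d0(eg, np.full_like(eg, eg.mean()), dg)
        assert 3.0 <= d0 <= 5.0
        d0n = estimate_d0_newton(eg, np.full_like(eg, eg.mean()), dg)
        assert abs(d0n - d0) < 0.2

    def test_empty_error(self):
        with pytest.raises(ValidationError):
            estimate_d0(np.array([]), np.array([]), 4)


class TestPriorPosterior:
    def test_prior_hand_computed(self):
        # d_g=4, d0=2, fitted logVAR = 0
        s0 = prior_variance(np.zeros(1), 2.0, 4)
        expected = np.exp(
            -special.digamma(2.0) + np.log(2.0) + special.digamma(1.0)
        )
        assert s0[0] == pytest.approx(expected)
        assert s0[0] == pytest.approx(0.73576, abs=1e-5)

    def test_flat_trend_constant_prior(self):
        s0 = prior_variance(np.full(5, -1.3), 3.0, 4)
        assert np.ptp(s0) == 0

    def test_scale_equivariance(self):
        f = np.array([-1.0, 0.0, 0.5])
        ratio = prior_variance(f + np.log(2), 3.0, 4) / prior_variance(f, 3.0, 4)
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-12)

    def test_infinite_d0_limit(self):
        s0 = prior_variance(np.array([0.3]), np.inf, 4)
        pred_eg = 0.3 - special.digamma(2.0) + np.log(2.0)
        assert s0[0] == pytest.approx(np.exp(pred_eg))

    def test_posterior_hand_computed(self):
        pv = posterior_variance(np.array([1.0]), np.array([4.0]), 4, 2.0)
        assert pv[0] == pytest.approx(2.0)

    def test_posterior_limits(self):
        v, s0 = np.array([1.0, 2.0]), np.array([3.0, 0.5])
        np.testing.assert_allclose(posterior_variance(v, s0, 4, 0.0), v)
        np.testing.assert_allclose(posterior_variance(v, s0, 4, np.inf), s0)

    def test_posterior_is_convex_combination(self):
        rng = np.random.default_rng(2)
        v, s0 = rng.uniform(0.1, 2, 100), rng.uniform(0.1, 2, 100)
        pv = posterior_variance(v, s0, 4, 3.7)
        assert np.all(pv >= np.minimum(v, s0) - 1e-12)
        assert np.all(pv <= np.maximum(v, s0) + 1e-12)


class TestModeratedStatistics:
    def test_moderated_t_hand_computed(self):
        m = make_matrix([[1, 1, 1, 2, 2, 2]])
        base = fit_group_means(m, design_of("AAABBB"))
        t, p = moderated_t(base, np.array([0.75]), 2.0, ("A", "B"))
        assert t[0] == pytest.approx(-1.0 / np.sqrt(0.5))
        assert p[0] == pytest.approx(2 * stats.t.sf(np.sqrt(2), 6))

    def test_equal_means_zero(self):
        m = make_matrix([[1, 2, 3, 1, 2, 3]])
        base = fit_group_means(m, design_of("AAABBB"))
        t, p = moderated_t(base, np.array([0.5]), 1.0, ("A", "B"))
        assert t[0] == 0 and p[0] == pytest.approx(1.0)

    def test_d0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(50, 6))
        base = fit_group_means(make_matrix(vals), design_of("AAABBB"))
        t, p = moderated_t(base, base.pooled_var, 0.0, ("A", "B"))
        ref = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-10)

    def test_moderated_f_reduces_to_anova(self):
        from deqms.linear_models import anova_f

        rng = np.random.default_rng(4)
        vals = rng.normal(size=(50, 9))
        base = fit_group_means(make_matrix(vals), design_of("AAABBBCCC"))
        F, p = moderated_f(base, base.pooled_var, 0.0)
        F_ref, p_ref = anova_f(base)
        np.testing.assert_allclose(F, F_ref, rtol=1e-10)
        np.testing.assert_allclose(p, p_ref, rtol=1e-10)

    def test_moderated_f_is_t_squared_for_two_groups(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(50, 6))
        base = fit_group_means(make_matrix(vals), design_of("AAABBB"))
        post = np.full(50, 0.4)
        F, _ = moderated_f(base, post, 3.0)
        t, _ = moderated_t(base, post, 3.0, ("A", "B"))
        np.testing.assert_allclose(F, t**2, rtol=1e-10)

    def test_shrinkage_direction(self):
        # moderated |t| exceeds pooled |t| exactly when post_var < s_p^2
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(200, 6))
        base = fit_group_means(make_matrix(vals), design_of("AAABBB"))
        s0 = np.full(200, np.median(base.pooled_var))
        post = posterior_variance(base.pooled_var, s0, base.resid_df, 2.0)
        tmod, _ = moderated_t(base, post, 2.0, ("A", "B"))
        tpooled, _ = moderated_t(base, base.pooled_var, 0.0, ("A", "B"))
        shrunk = post < base.pooled_var
        nz = tpooled != 0
        assert np.all(np.abs(tmod)[shrunk & nz] >= np.abs(tpooled)[shrunk & nz])
        assert np.all(np.abs(tmod)[~shrunk & nz] <= np.abs(tpooled)[~shrunk & nz])


def brute_force_bh(p):
    """Step-up definition evaluated literally."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.full(7, 0.4)), 0.4)

    def test_against_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 13))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.5, 1.2]))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_step_up_property(self, p):
        p = np.array(p)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, brute_force_bh(p), rtol=1e-12)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)


class TestFitTrend:
    def test_constant_input_constant_fit(self):
        x = np.linspace(0, 5, 40)
        fitted, _ = fit_trend(x, np.full(40, 2.5))
        np.testing.assert_allclose(fitted, 2.5, atol=1e-10)

    def test_reproduces_linear_data(self):
        x = np.linspace(0, 5, 60)
        y = 1.4 - 0.7 * x
        for degree in (1, 2):
            fitted, _ = fit_trend(x, y, span=0.6, degree=degree)
            np.testing.assert_allclose(fitted, y, atol=1e-8)

    def test_constant_covariate_returns_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        fitted, sm = fit_trend(np.zeros(4), y)
        assert sm is None
        np.testing.assert_allclose(fitted, 3.0)

    def test_monotone_decreasing_trend_recovered(self):
        matrix, _ = simulate_null(default_null_spec(seed=13, proteins_per_group=60))
        design = design_of("AAABBBCCC")
        base = fit_group_means(matrix, design)
        x = np.log2(matrix.count.to_numpy(float))
        fitted, _ = fit_trend(x, np.log(base.pooled_var))
        by_count = {}
        for c in np.unique(matrix.count):
            by_count[c] = fitted[matrix.count.to_numpy() == c].mean()
        levels = [by_count[c] for c in sorted(by_count)]
        assert np.all(np.diff(levels) <= 0.05)


class TestFullPipeline:
    def test_constant_count_matches_constant_mode(self):
        # all counts equal: the count trend degenerates to the flat prior
        rng = np.random.default_rng(21)
        m = make_matrix(rng.normal(size=(200, 6)), counts=np.full(200, 5))
        design = design_of("AAABBB")
        design.contrasts = [("A", "B")]
        t_count = spectra_count_ebayes(
            m, design, RunConfig(covariate_mode="count")
        ).results[("A", "B")]["t_mod"]
        t_const = spectra_count_ebayes(
            m, design, RunConfig(covariate_mode="constant")
        ).results[("A", "B")]["t_mod"]
        np.testing.assert_allclose(t_count, t_const, atol=1e-9)

    def test_prior_variance_decreases_with_count(self):
        matrix, _ = simulate_null(default_null_spec(seed=30, proteins_per_group=60))
        design = design_of("AAABBBCCC")
        fit = spectra_count_ebayes(matrix, design, RunConfig())
        counts = matrix.count.to_numpy()
        med_prior = [
            np.median(fit.s0_sq[counts == c]) for c in sorted(np.unique(counts))
        ]
        assert np.all(np.diff(np.log(med_prior)) <= 0.05)

    def test_posterior_between_pooled_and_prior(self, small_matrix, two_group_design):
        fit = spectra_count_ebayes(small_matrix, two_group_design, RunConfig())
        lo = np.minimum(fit.base.pooled_var, fit.s0_sq)
        hi = np.maximum(fit.base.pooled_var, fit.s0_sq)
        assert np.all(fit.post_var >= lo - 1e-12)
        assert np.all(fit.post_var <= hi + 1e-12)

    def test_flat_prior_matches_independent_implementation(self):
        # naive reimplementation of the flat-prior pipeline, protein by protein
        rng = np.random.default_rng(17)
        # heteroskedastic proteins (inverse-chi-square variances) so that a
        # finite d0 exists
        true_var = 0.1 * 3 / rng.chisquare(3, 400)
        vals = rng.normal(size=(400, 6)) * np.sqrt(true_var)[:, None]
        m = make_matrix(vals, counts=rng.integers(1, 20, 400))
        design = design_of("AAABBB")
        fit = spectra_count_ebayes(
            m, design, RunConfig(covariate_mode="constant"), contrasts=[("A", "B")]
        )

        # oracle: everything computed with plain loops / library calls
        sp2 = np.array(
            [
                (np.var(v[:3], ddof=1) + np.var(v[3:], ddof=1)) / 2
                for v in vals
            ]
        )
        dg = 4
        eg = np.log(sp2) - special.digamma(dg / 2) + np.log(dg / 2)
        pred = np.full_like(eg, eg.mean())
        excess = np.mean((eg - pred) ** 2) - special.polygamma(1, dg / 2)
        assert excess > 0
        d0, best = None, np.inf
        for k in range(1, 5001):
            diff = abs(excess - special.polygamma(1, (k * 0.1) / 2))
            if diff > best:
                d0 = (k - 1) * 0.1
                break
            best = diff
        assert d0 is not None
        s0 = np.exp(
            eg.mean()
            + special.digamma(d0 / 2)
            - np.log(d0 / 2)
        )
        post = (dg * sp2 + d0 * s0) / (dg + d0)
        means = vals[:, :3].mean(axis=1) - vals[:, 3:].mean(axis=1)
        t_ref = means / np.sqrt(post * (2 / 3))
        p_ref = 2 * stats.t.sf(np.abs(t_ref), dg + d0)

        assert fit.d0 == pytest.approx(d0, rel=1e-6)
        np.testing.assert_allclose(fit.s0_sq, s0, rtol=1e-6)
        tbl = fit.results[("A", "B")]
        np.testing.assert_allclose(tbl["t_mod"], t_ref, rtol=1e-6)
        np.testing.assert_allclose(tbl["p_mod"], p_ref, rtol=1e-6)

    def test_zero_variance_proteins_kept_with_prior(self):
        rng = np.random.default_rng(19)
        vals = rng.normal(size=(50, 6))
        vals[7] = 1.0  # constant protein: zero pooled variance
        m = make_matrix(vals, counts=rng.integers(1, 10, 50))
        fit = spectra_count_ebayes(m, design_of("AAABBB"), RunConfig())
        assert fit.post_var[7] == pytest.approx(fit.s0_sq[7])
        assert fit.post_var[7] > 0
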