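"""Closed-form theory against independent Monte-Carlo and brute-force oracles.

Monte-Carlo comparisons use 3 binomial standard errors as the tolerance
throughout; the simulation oracles are written directly in numpy/scipy and
never call the closed forms they check.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from screenmin import (
    GaussianShift,
    MixtureModel,
    approx_fwer,
    approx_oracle_threshold,
    approx_power,
    cond_cdf_doublenull,
    cond_cdf_mixed,
    conditional_power,
    expected_selection_size,
    fwer_bound,
    gaussian_p_cdf,
    oracle_threshold,
    power_exact,
    selection_prob,
    selection_size_pmf,
)

EX2 = MixtureModel(0, 10, 0, GaussianShift(2.0))  # 10 one-false pairs, shift 2
EX3 = MixtureModel(70, 25, 5, GaussianShift(2.0))  # mixed family of 100


def draw_pair_pvalues(rng, n, snr1, snr2):
    """n independent (p1, p2) pairs from one-sided Gaussian tests."""
    z = rng.standard_normal((n, 2)) + [snr1, snr2]
    return stats.norm.sf(z)


class TestGaussianPCdf:
    def test_uniform_when_no_shift(self):
        u = np.linspace(0, 1, 11)
        np.testing.assert_allclose(gaussian_p_cdf(u, 0.0), u, atol=1e-12)

    def test_boundaries(self):
        assert gaussian_p_cdf(1.0, 3.0) == pytest.approx(1.0)
        assert gaussian_p_cdf(0.0, 3.0) == pytest.approx(0.0)

    def test_shift_two_at_default_threshold(self):
        # F(0.005) ≈ 0.282 so that the one-false selection probability is ≈ 0.29
        assert gaussian_p_cdf(0.005, 2.0) == pytest.approx(0.282, abs=5e-4)
        assert selection_prob("01", 0.005, 2.0) == pytest.approx(0.29, abs=5e-3)

    def test_stochastically_larger_than_uniform(self):
        u = np.linspace(0.01, 0.99, 20)
        assert np.all(gaussian_p_cdf(u, 1.5) > u)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gaussian_p_cdf(1.2, 1.0)
        with pytest.raises(ValueError):
            gaussian_p_cdf(0.5, -1.0)


class TestConditionalCdfs:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(c=st.floats(1e-4, 0.999), snr=st.floats(0.0, 6.0))
    def test_valid_cdf_and_continuity_at_junction(self, c, snr):
        F = GaussianShift(snr)
        u = np.unique(np.concatenate([np.linspace(0, 1, 101), [c]]))
        for cdf in (lambda v: cond_cdf_mixed(v, c, F),
                    lambda v: cond_cdf_doublenull(v, c)):
            vals = cdf(u)
            assert vals[0] == pytest.approx(0.0, abs=1e-12)
            assert vals[-1] == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(vals) >= -1e-12)
            lo, hi = cdf(c * (1 - 1e-9)), cdf(min(c * (1 + 1e-9), 1.0))
            assert hi - lo < 1e-6

    def test_doublenull_closed_form_point(self):
        assert cond_cdf_doublenull(0.01, 0.05) == pytest.approx(
            0.0001 / (0.05 * 1.95), rel=1e-12
        )

    def test_mixed_against_simulation(self, rng):
        c, snr = 0.005, 2.0
        p = draw_pair_pvalues(rng, 10**6, 0.0, snr)
        keep = p.min(axis=1) <= c
        pmax = p[keep].max(axis=1)
        n = keep.sum()
        for s in range(1, 11):
            u = 0.05 / s
            emp = (pmax <= u).mean()
            se = np.sqrt(emp * (1 - emp) / n) + 1e-6
            assert cond_cdf_mixed(u, c, GaussianShift(snr)) == pytest.approx(
                emp, abs=3 * se
            )

    def test_doublenull_against_simulation(self, rng):
        c = 0.05
        p = rng.random((10**6, 2))
        keep = p.min(axis=1) <= c
        pmax = p[keep].max(axis=1)
        n = keep.sum()
        for u in (0.01, 0.05, 0.2, 0.8):
            emp = (pmax <= u).mean()
            se = np.sqrt(emp * (1 - emp) / n) + 1e-6
            assert cond_cdf_doublenull(u, c) == pytest.approx(emp, abs=3 * se)

    def test_post_selection_level_bounded_by_single_threshold(self):
        """P0(c, c) ≤ c on a dense grid — single-threshold validity."""
        for snr in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0):
            F = GaussianShift(snr)
            for c in np.geomspace(1e-5, 0.99, 200):
                assert cond_cdf_mixed(c, c, F) <= c + 1e-12

    def test_small_threshold_inflates_conditional_level(self):
        """At c = 5e-4 the 5% conditional quantile overshoots for moderate
        signal and recovers as the signal grows."""
        c = 5e-4
        vals = [cond_cdf_mixed(0.05, c, GaussianShift(s))
                for s in np.linspace(0.0, 5.0, 26)]
        assert max(vals) > 0.05
        assert cond_cdf_mixed(0.05, c, GaussianShift(30.0)) == pytest.approx(
            0.05, abs=1e-6
        )

    def test_degenerate_threshold_errors(self):
        with pytest.raises(ValueError):
            cond_cdf_mixed(0.5, 0.0, GaussianShift(1.0))


class TestSelectionSize:
    def test_type_identities(self):
        c = 0.02
        assert selection_prob("00", c) == pytest.approx(1 - (1 - c) ** 2)
        assert selection_prob("11", c, 0.0) == pytest.approx(2 * c - c * c)
        F = GaussianShift(1.7)
        for t in ("00", "01", "11"):
            probs = {"00": (c, c), "01": (c, float(F(c))), "11": (float(F(c)),) * 2}[t]
            both_miss = (1 - probs[0]) * (1 - probs[1])
            assert selection_prob(t, c, F) == pytest.approx(1 - both_miss)

    def test_binomial_special_case(self):
        pmf = selection_size_pmf(MixtureModel(0, 10, 0, GaussianShift(2.0)), 0.005)
        psel = selection_prob("01", 0.005, 2.0)
        np.testing.assert_allclose(
            pmf.probs, stats.binom.pmf(np.arange(11), 10, psel), atol=1e-14
        )

    def test_point_mass_as_threshold_approaches_one(self):
        pmf = selection_size_pmf(EX3, 1 - 1e-12)
        assert pmf.probs[-1] == pytest.approx(1.0, abs=1e-6)

    def test_mean_matches_expected_size(self):
        for c in (0.001, 0.01, 0.1, 0.5):
            pmf = selection_size_pmf(EX3, c)
            assert pmf.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert pmf.mean == pytest.approx(
                expected_selection_size(EX3, c), abs=1e-9
            )

    def test_pmf_against_simulation(self, rng):
        model = MixtureModel(5, 5, 5, GaussianShift(3.0))
        c, n = 0.01, 10**5
        snrs = np.repeat([[0, 0], [0, 3.0], [3.0, 3.0]], 5, axis=0)
        z = rng.standard_normal((n, 15, 2)) + snrs
        sizes = ((stats.norm.sf(z).min(axis=2)) <= c).sum(axis=1)
        emp = np.bincount(sizes, minlength=16) / n
        pmf = selection_size_pmf(model, c)
        se = np.sqrt(pmf.probs * (1 - pmf.probs) / n) + 1e-5
        np.testing.assert_array_less(np.abs(emp - pmf.probs), 3 * se)

    def test_closed_form_all_null(self):
        m, c = 12, 0.03
        model = MixtureModel(m, 0, 0, GaussianShift(0.0))
        assert expected_selection_size(model, c) == pytest.approx(
            m * (2 * c - c * c)
        )


class TestFwerBound:
    def test_worst_case_example_value(self):
        """m = 10 one-false pairs at shift 2: exact FWER 0.055 > α."""
        assert fwer_bound(EX2, 0.005, 0.05) == pytest.approx(0.0545, abs=5e-4)
        assert round(fwer_bound(EX2, 0.005, 0.05), 3) == 0.055

    def test_equals_simulation_when_all_pairs_one_false(self, rng):
        m, snr, alpha = 30, 2.0, 0.05
        c = alpha / m
        reps = 20000
        z = rng.standard_normal((reps, m, 2))
        z[:, :, 1] += snr
        p = stats.norm.sf(z)
        pmin, pmax = p.min(axis=2), p.max(axis=2)
        sel = pmin <= c
        ns = sel.sum(axis=1)
        rej = sel & (pmax <= (alpha / np.maximum(ns, 1))[:, None])
        emp = rej.any(axis=1).mean()
        se = np.sqrt(emp * (1 - emp) / reps)
        model = MixtureModel(0, m, 0, GaussianShift(snr))
        assert fwer_bound(model, c, alpha) == pytest.approx(emp, abs=3 * se)

    def test_upper_bounds_simulation_with_double_nulls(self, rng):
        m0, m1, snr, alpha = 20, 10, 2.5, 0.05
        m = m0 + m1
        c = alpha / m
        reps = 20000
        z = rng.standard_normal((reps, m, 2))
        z[:, m0:, 1] += snr
        p = stats.norm.sf(z)
        pmin, pmax = p.min(axis=2), p.max(axis=2)
        sel = pmin <= c
        ns = sel.sum(axis=1)
        rej = sel & (pmax <= (alpha / np.maximum(ns, 1))[:, None])
        emp = rej.any(axis=1).mean()
        se = np.sqrt(emp * (1 - emp) / reps)
        model = MixtureModel(m0, m1, 0, GaussianShift(snr))
        assert fwer_bound(model, c, alpha) >= emp - 3 * se


class TestPower:
    def test_conditional_power_uniform_reduction(self):
        c, alpha, s = 0.002, 0.05, 10
        assert conditional_power(s, c, alpha, 0.0) == pytest.approx(
            2 * c * (alpha / s) - c * c
        )

    def test_zero_when_nothing_selected(self):
        assert conditional_power(0, 0.01, 0.05, 2.0) == 0.0

    def test_against_simulation(self, rng):
        c, alpha, s, snr = 0.001, 0.05, 10, 3.0
        p = draw_pair_pvalues(rng, 10**6, snr, snr)
        emp = ((p.max(axis=1) <= alpha / s) & (p.min(axis=1) <= c)).mean()
        se = np.sqrt(emp * (1 - emp) / 10**6)
        assert conditional_power(s, c, alpha, snr) == pytest.approx(
            emp, abs=3 * se
        )

    def test_large_threshold_branch(self, rng):
        c, alpha, s, snr = 0.02, 0.05, 10, 3.0  # c*s > alpha
        p = draw_pair_pvalues(rng, 10**6, snr, snr)
        emp = ((p.max(axis=1) <= alpha / s) & (p.min(axis=1) <= c)).mean()
        se = np.sqrt(emp * (1 - emp) / 10**6)
        assert conditional_power(s, c, alpha, snr) == pytest.approx(
            emp, abs=3 * se
        )

    def test_single_pair_power(self):
        model = MixtureModel(0, 0, 1, GaussianShift(2.0))
        assert power_exact(model, 0.01, 0.05) == pytest.approx(
            conditional_power(1, 0.01, 0.05, 2.0)
        )

    def test_limit_is_bonferroni_power(self):
        c = 1 - 1e-12
        expected = gaussian_p_cdf(0.05 / EX3.m, 2.0) ** 2
        assert power_exact(EX3, c, 0.05) == pytest.approx(expected, rel=1e-6)

    def test_focal_conventions_agree_for_large_family(self):
        model = MixtureModel(140, 50, 10, GaussianShift(3.0))
        a = power_exact(model, 0.001, 0.05, focal="marginal")
        b = power_exact(model, 0.001, 0.05, focal="shifted")
        assert a == pytest.approx(b, rel=0.02)

    def test_power_curve_unimodal_and_beats_bonferroni(self):
        cs = np.geomspace(1e-4, 0.05, 40)
        pw = np.array([power_exact(EX3, c, 0.05) for c in cs])
        peak = int(pw.argmax())
        assert 0 < peak < len(cs) - 1
        assert np.all(np.diff(pw[peak:]) <= 1e-12), "decreasing past the peak"
        bonf = gaussian_p_cdf(0.05 / EX3.m, 2.0) ** 2
        assert pw[peak] > bonf

    def test_exact_vs_simulated_power(self, rng):
        model = MixtureModel(70, 25, 5, GaussianShift(2.0))
        alpha, reps = 0.05, 20000
        for c in (0.001, 0.005, 0.02):
            # row layout: 70 both-null, 25 one-false, 5 both-false
            z = rng.standard_normal((reps, 100, 2))
            z[:, 70:95, 1] += 2.0
            z[:, 95:, :] += 2.0
            p = stats.norm.sf(z)
            pmin, pmax = p.min(axis=2), p.max(axis=2)
            sel = pmin <= c
            ns = sel.sum(axis=1)
            rej = sel & (pmax <= (alpha / np.maximum(ns, 1))[:, None])
            emp = rej[:, 95:].mean()
            se = np.sqrt(emp * (1 - emp) / (reps * 5))
            assert power_exact(model, c, alpha) == pytest.approx(
                emp, abs=3 * se
            )


class TestApproximations:
    def test_approx_close_to_exact_fwer(self):
        exact = fwer_bound(EX2, 0.005, 0.05)
        approx = approx_fwer(EX2, 0.005, 0.05)
        assert approx == pytest.approx(exact, abs=0.01)
        assert approx != exact  # documented approximation error

    def test_alpha_recovered_at_strong_signal(self):
        model = MixtureModel(0, 200, 0, GaussianShift(8.0))
        assert approx_fwer(model, 0.05 / 200, 0.05) == pytest.approx(
            0.05, abs=2e-3
        )

    def test_approx_power_uses_expected_size(self):
        c, alpha = 0.003, 0.05
        E = expected_selection_size(EX3, c)
        assert approx_power(EX3, c, alpha) == pytest.approx(
            conditional_power(E, c, alpha, EX3.nonnull)
        )


class TestOracleThresholds:
    def test_worst_case_default_threshold_infeasible(self):
        """For the 10-pair worst case the default α/m violates the constraint
        and the oracle threshold sits strictly above it."""
        assert approx_fwer(EX2, 0.005, 0.05) > 0.05
        c_star = oracle_threshold(EX2, 0.05)
        assert c_star > 0.005
        assert approx_fwer(EX2, c_star, 0.05) == pytest.approx(0.05, abs=1e-6)

    def test_mixed_family_constraint_active_and_power_maximal(self):
        res = oracle_threshold(EX3, 0.05, full_output=True)
        assert res.constraint_binding
        assert res.constraint_value == pytest.approx(0.05, abs=1e-6)
        assert res.power_maximal_on_grid
        # the unconstrained power maximizer is smaller and infeasible
        cs = np.geomspace(0.05 / 1000, 0.05, 300)
        pw = [approx_power(EX3, c, 0.05) for c in cs]
        c_unconstrained = cs[int(np.argmax(pw))]
        assert c_unconstrained < res.threshold
        assert approx_fwer(EX3, c_unconstrained, 0.05) > 0.05

    def test_all_false_strong_signal_nonbinding(self):
        model = MixtureModel(0, 0, 100, GaussianShift(8.0))
        res = oracle_threshold(model, 0.05, full_output=True)
        assert not res.constraint_binding
        assert res.threshold <= 0.05 / 100

    def test_agrees_with_simpler_root(self):
        a = oracle_threshold(EX2, 0.05)
        b = approx_oracle_threshold(EX2, 0.05)
        assert b == pytest.approx(a, rel=0.15)  # the documented approximation gap

    def test_root_matches_cubic_all_null(self):
        # all-null family: c·m(2c − c²) = α is a cubic with one root in (0, α]
        m, alpha = 400, 0.05
        model = MixtureModel(m, 0, 0, GaussianShift(0.0))
        root = approx_oracle_threshold(model, alpha)
        coeffs = [-m, 2 * m, 0, -alpha]  # -mc³ + 2mc² - α = 0
        real = [r.real for r in np.roots(coeffs)
                if abs(r.imag) < 1e-12 and 0 < r.real <= alpha]
        assert root == pytest.approx(real[0], abs=1e-10)
        g = lambda c: c * expected_selection_size(model, c) - alpha
        assert abs(g(root)) < 1e-10

    def test_root_capped_at_alpha_for_single_pair(self):
        model = MixtureModel(1, 0, 0, GaussianShift(0.0))
        with pytest.warns(RuntimeWarning, match="cap"):
            root, capped = approx_oracle_threshold(model, 0.05, full_output=True)
        assert capped and root == 0.05

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        m0=st.integers(0, 50), m1=st.integers(0, 50), m2=st.integers(0, 20),
        snr=st.floats(0.0, 5.0),
    )
    def test_pfer_estimate_curve_strictly_increasing(self, m0, m1, m2, snr):
        """c·E|S(c)| is strictly increasing, so the root is unique."""
        if m0 + m1 + m2 == 0:
            return
        model = MixtureModel(m0, m1, m2, GaussianShift(snr))
        cs = np.geomspace(1e-5, 0.999, 60)
        g = cs * np.array([expected_selection_size(model, c) for c in cs])
        assert np.all(np.diff(g) > 0)
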