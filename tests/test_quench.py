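"""Quenching models: Stern–Volmer, NAF, distribution analysis, parallax."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepmem.errors import FitDegenerateError, InvalidInputError, LogDomainError
from pepmem import quench
from pepmem.quench import (
    BRPC_DEPTHS, DepthQuenchProfile, QuenchSeries, compute_naf, da_model,
    fit_distribution_analysis, fit_parallax, fit_stern_volmer, pm_model,
    profile_area, simulate_depth_quenching, simulate_stern_volmer,
)

TABLE_DA = {"hm": 12.4, "sigma": 8.9, "s_area": 1.7}
TABLE_PM = {"hm": 12.5, "rc": 13.8, "c_conc": 0.0043}


def grid_search_da(profile, hm_range, sigma_range, s_range, n=41):
    """Independent brute-force oracle: minimize rss over a parameter grid."""
    best, best_rss = None, np.inf
    for hm in np.linspace(*hm_range, n):
        for sigma in np.linspace(*sigma_range, n):
            for s in np.linspace(*s_range, n):
                rss = float(np.sum(
                    (da_model(profile.h_quencher, hm, sigma, s) - profile.ln_ratio) ** 2))
                if rss < best_rss:
                    best, best_rss = (hm, sigma, s), rss
    return best, best_rss


def grid_search_pm(profile, hm_range, rc_range, c_range, n=41):
    best, best_rss = None, np.inf
    for hm in np.linspace(*hm_range, n):
        for rc in np.linspace(*rc_range, n):
            for c in np.linspace(*c_range, n):
                rss = float(np.sum(
                    (pm_model(profile.h_quencher, hm, rc, c, truncate=False)
                     - profile.ln_ratio) ** 2))
                if rss < best_rss:
                    best, best_rss = (hm, rc, c), rss
    return best, best_rss


# --------------------------------------------------------------------------
# Stern–Volmer
# --------------------------------------------------------------------------

class TestSternVolmer:
    def test_flat_series_gives_zero_constant(self):
        series = QuenchSeries([0.0, 0.05, 0.1, 0.2], [1.0, 1.0, 1.0, 1.0])
        fit = fit_stern_volmer(series)
        assert fit.ksv == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_exact_linear_data_recovered_to_machine_precision(self):
        q = np.array([0.0, 0.05, 0.1, 0.2])
        series = QuenchSeries(q, 1.0 + 5.0 * q)
        fit = fit_stern_volmer(series)
        assert fit.ksv == pytest.approx(5.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_three_standard_errors(self):
        q = np.linspace(0.0, 0.35, 8)
        series = simulate_stern_volmer(16.6, q, noise_sd=0.05, seed=11)
        fit = fit_stern_volmer(series)
        # closed-form OLS oracle on the same simulated points
        design = np.column_stack([np.ones(len(q)), q])
        coef, *_ = np.linalg.lstsq(design, series.f_ratio, rcond=None)
        assert fit.ksv == pytest.approx(coef[1], abs=1e-10)
        assert abs(fit.ksv - 16.6) < 3.0 * fit.ksv_se

    def test_fixed_intercept_variant(self):
        q = np.array([0.0, 0.1, 0.2])
        series = QuenchSeries(q, 1.0 + 4.0 * q)
        fit = fit_stern_volmer(series, fix_intercept=True)
        assert fit.intercept == 1.0
        assert fit.ksv == pytest.approx(4.0, abs=1e-10)

    @pytest.mark.parametrize("q,f", [
        ([0.1], [1.5]),
        ([0.1, 0.1], [1.0, 1.2]),
    ])
    def test_invalid_series_rejected(self, q, f):
        with pytest.raises(InvalidInputError):
            QuenchSeries(q, f)

    def test_nonunit_zero_point_rejected(self):
        with pytest.raises(InvalidInputError):
            QuenchSeries([0.0, 0.1], [1.5, 2.0])


# --------------------------------------------------------------------------
# NAF
# --------------------------------------------------------------------------

class TestNAF:
    @pytest.mark.parametrize("mem,buf,expected", [
        (7.5, 14.2, 0.53),   # penetratin in DOPC
        (3.0, 16.6, 0.18),   # RW16 in DOPC
    ])
    def test_published_constant_pairs(self, mem, buf, expected):
        assert compute_naf(mem, buf).rounded(2) == pytest.approx(expected)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_self_normalization_is_one(self, x):
        assert compute_naf(x, x).naf == pytest.approx(1.0)

    @given(st.floats(min_value=0.1, max_value=30.0),
           st.floats(min_value=0.1, max_value=30.0),
           st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, mem, buf, scale):
        a = compute_naf(mem, buf).naf
        b = compute_naf(mem * scale, buf * scale).naf
        assert a == pytest.approx(b, rel=1e-12)

    def test_uncertainty_propagation_of_the_ratio(self):
        res = compute_naf(3.0, 16.6, sd_mem=0.2, sd_buffer=0.7)
        expected = (3.0 / 16.6) * math.sqrt((0.2 / 3.0) ** 2 + (0.7 / 16.6) ** 2)
        assert res.naf_sd == pytest.approx(expected)

    def test_nonpositive_buffer_constant_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_naf(3.0, 0.0)


# --------------------------------------------------------------------------
# distribution analysis
# --------------------------------------------------------------------------

class TestDistributionAnalysis:
    def test_roundtrip_of_published_parameters(self):
        prof = simulate_depth_quenching("DA", TABLE_DA, BRPC_DEPTHS)
        fit = fit_distribution_analysis(prof)
        assert fit.hm == pytest.approx(12.4, abs=1e-6)
        assert fit.sigma == pytest.approx(8.9, abs=1e-6)
        assert fit.s_area == pytest.approx(1.7, abs=1e-6)
        assert fit.rss < 1e-10

    def test_closed_form_agrees_with_grid_search_oracle(self):
        prof = simulate_depth_quenching("DA", TABLE_DA, BRPC_DEPTHS)
        fit = fit_distribution_analysis(prof)
        (hm, sigma, s), _ = grid_search_da(
            prof, (10.0, 14.0), (7.0, 11.0), (1.0, 3.0))
        assert fit.hm == pytest.approx(hm, abs=(14.0 - 10.0) / 40)
        assert fit.sigma == pytest.approx(sigma, abs=(11.0 - 7.0) / 40)
        assert fit.s_area == pytest.approx(s, abs=(3.0 - 1.0) / 40)

    def test_flat_profile_is_degenerate(self):
        prof = DepthQuenchProfile(BRPC_DEPTHS, [0.4, 0.4, 0.4])
        with pytest.raises(FitDegenerateError):
            fit_distribution_analysis(prof)

    def test_symmetric_profile_puts_mean_at_midpoint(self):
        prof = DepthQuenchProfile([6.0, 10.0, 14.0], [0.3, 0.8, 0.3])
        fit = fit_distribution_analysis(prof)
        assert fit.hm == pytest.approx(10.0, abs=1e-9)

    def test_nonpositive_ln_ratio_is_log_domain_error(self):
        with pytest.raises(LogDomainError):
            fit_distribution_analysis(
                DepthQuenchProfile(BRPC_DEPTHS, [0.5, -0.1, 0.2]))

    def test_multipoint_nls_recovers_generator(self):
        depths = [4.0, 6.5, 8.3, 11.0, 14.0, 18.0]
        prof = simulate_depth_quenching("DA", TABLE_DA, depths)
        fit = fit_distribution_analysis(prof)
        assert fit.method == "nls"
        assert fit.hm == pytest.approx(12.4, abs=1e-5)
        assert fit.sigma == pytest.approx(8.9, abs=1e-5)
        assert fit.s_area == pytest.approx(1.7, abs=1e-5)

    @given(st.floats(min_value=-4.0, max_value=4.0))
    @settings(max_examples=25, deadline=None)
    def test_translation_equivariance_of_the_depth_scale(self, delta):
        depths = np.array(BRPC_DEPTHS)
        prof = simulate_depth_quenching("DA", TABLE_DA, depths)
        shifted = DepthQuenchProfile(depths + delta + 0.1, prof.ln_ratio)
        base = fit_distribution_analysis(prof)
        moved = fit_distribution_analysis(shifted)
        assert moved.hm - base.hm == pytest.approx(delta + 0.1, abs=1e-6)
        assert moved.sigma == pytest.approx(base.sigma, abs=1e-6)
        assert moved.s_area == pytest.approx(base.s_area, abs=1e-6)


# --------------------------------------------------------------------------
# parallax method
# --------------------------------------------------------------------------

class TestParallax:
    def test_roundtrip_of_published_parameters(self):
        prof = simulate_depth_quenching("PM", TABLE_PM, BRPC_DEPTHS)
        fit = fit_parallax(prof)
        assert fit.hm == pytest.approx(12.5, abs=1e-6)
        assert fit.rc == pytest.approx(13.8, abs=1e-6)
        assert fit.c_conc == pytest.approx(0.0043, abs=1e-9)
        assert fit.rss < 1e-10

    def test_closed_form_agrees_with_grid_search_oracle(self):
        prof = simulate_depth_quenching("PM", TABLE_PM, BRPC_DEPTHS)
        fit = fit_parallax(prof)
        (hm, rc, c), _ = grid_search_pm(
            prof, (11.0, 14.0), (12.0, 16.0), (0.003, 0.007))
        assert fit.hm == pytest.approx(hm, abs=(14.0 - 11.0) / 40)
        assert fit.rc == pytest.approx(rc, abs=(16.0 - 12.0) / 40)

    def test_symmetric_flanks_put_mean_at_center_depth(self):
        prof = DepthQuenchProfile([6.0, 10.0, 14.0], [0.2, 0.9, 0.2])
        fit = fit_parallax(prof)
        assert fit.hm == pytest.approx(10.0, abs=1e-9)

    def test_truncation_outside_quenching_radius(self):
        fit = fit_parallax(simulate_depth_quenching("PM", TABLE_PM, BRPC_DEPTHS))
        far = pm_model(fit.hm + 2.0 * fit.rc, fit.hm, fit.rc, fit.c_conc)
        assert far == 0.0

    def test_negative_vertex_is_degenerate(self):
        prof = DepthQuenchProfile([2.0, 6.0, 10.0], [-0.5, -0.1, -0.6])
        with pytest.raises(FitDegenerateError):
            fit_parallax(prof)

    def test_fixed_c_mode_recovers_depth_and_radius(self):
        prof = simulate_depth_quenching("PM", TABLE_PM, BRPC_DEPTHS)
        fit = fit_parallax(prof, c_fixed=0.0043)
        assert fit.c_fixed
        assert fit.hm == pytest.approx(12.5, abs=1e-5)
        assert fit.rc == pytest.approx(13.8, abs=1e-5)

    def test_in_plane_concentration_helper(self):
        c = quench.in_plane_concentration(0.3, area_per_lipid=70.0)
        assert c == pytest.approx(0.3 / 70.0)


# --------------------------------------------------------------------------
# simulation and area
# --------------------------------------------------------------------------

class TestSimulation:
    def test_noiseless_da_matches_direct_model_evaluation(self):
        prof = simulate_depth_quenching("DA", TABLE_DA, BRPC_DEPTHS)
        np.testing.assert_allclose(
            prof.ln_ratio, da_model(np.array(BRPC_DEPTHS), **TABLE_DA))

    def test_pm_outside_truncation_radius_is_zero(self):
        prof = simulate_depth_quenching("PM", {"hm": 5.0, "rc": 2.0, "c_conc": 0.01},
                                        [1.0, 5.0, 9.0])
        assert prof.ln_ratio[0] == 0.0 and prof.ln_ratio[2] == 0.0

    def test_same_seed_reproduces_profile(self):
        a = simulate_depth_quenching("DA", TABLE_DA, BRPC_DEPTHS, 0.05, seed=4)
        b = simulate_depth_quenching("DA", TABLE_DA, BRPC_DEPTHS, 0.05, seed=4)
        np.testing.assert_array_equal(a.ln_ratio, b.ln_ratio)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_depth_quenching("DA", TABLE_DA, BRPC_DEPTHS, noise_sd=-0.1)

    def test_area_equals_s_parameter(self):
        fit = fit_distribution_analysis(
            simulate_depth_quenching("DA", TABLE_DA, BRPC_DEPTHS))
        assert profile_area(fit) == pytest.approx(fit.s_area, abs=1e-6)

    @given(st.floats(min_value=-10.0, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_area_invariant_under_depth_translation(self, hm):
        from pepmem.quench import DAFit
        fit = DAFit(hm=hm, sigma=3.0, s_area=1.0, rss=0.0)
        assert profile_area(fit) == pytest.approx(1.0, abs=1e-6)


# --------------------------------------------------------------------------
# shared 3-point properties
# --------------------------------------------------------------------------

@st.composite
def admissible_profiles(draw):
    """Random 3-point profiles with an interior maximum in log space."""
    hm = draw(st.floats(min_value=8.0, max_value=16.0))
    sigma = draw(st.floats(min_value=4.0, max_value=12.0))
    s = draw(st.floats(min_value=0.5, max_value=3.0))
    return simulate_depth_quenching("DA", (hm, sigma, s), BRPC_DEPTHS), (hm, sigma, s)


@given(admissible_profiles())
@settings(max_examples=40, deadline=None)
def test_three_point_closed_forms_interpolate_exactly(case):
    profile, truth = case
    da = fit_distribution_analysis(profile)
    assert da.rss <= 1e-10
    assert da.hm == pytest.approx(truth[0], abs=1e-6)
    # round-trip: simulating from the fit reproduces the profile exactly
    back = simulate_depth_quenching("DA", (da.hm, da.sigma, da.s_area), BRPC_DEPTHS)
    np.testing.assert_allclose(back.ln_ratio, profile.ln_ratio, atol=1e-8)
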