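"""Activation-field construction: parameter rules, placement, normalization,
periodicity, skew direction and conduction-speed recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lymphchain.activation import (
    ANTEGRADE,
    RETROGRADE,
    ActivationParams,
    InvalidParameterError,
    PacemakerSite,
    bivariate_gaussian,
    build_activation_field,
    derive_activation_params,
    place_pacemakers,
)

WT = dict(sites_per_length=10.0, conduction_speed=0.98, frequency=8.3, period_T=7.23)
KO = dict(sites_per_length=11.0, conduction_speed=0.063, frequency=15.8, period_T=3.80)


class TestDeriveParams:
    def test_wt_sigmas_follow_decay_rules(self):
        p = derive_activation_params(**WT)
        assert p.sigma_z == pytest.approx(0.0125)
        assert p.sigma_t == pytest.approx(1.8075)

    def test_ko_sigmas_follow_decay_rules(self):
        p = derive_activation_params(**KO)
        assert p.sigma_z == pytest.approx(1.0 / 88.0)
        assert p.sigma_t == pytest.approx(0.95)

    def test_rho_recovers_stated_speed_limits(self):
        # slope of the Gaussian ridge is rho*sigma_t/sigma_z = 1/c
        wt = derive_activation_params(**WT)
        assert wt.rho == pytest.approx(wt.sigma_z / (0.98 * wt.sigma_t))
        assert wt.rho == pytest.approx(0.00706, rel=1e-2)
        ko = derive_activation_params(**KO)
        assert ko.rho == pytest.approx(0.19, rel=1e-2)
        # infinitely fast conduction -> unskewed signal
        fast = derive_activation_params(10.0, 1e12, 8.3, 7.23)
        assert fast.rho == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bad", ["sites_per_length", "conduction_speed",
                                     "frequency", "period_T"])
    def test_nonpositive_inputs_rejected(self, bad):
        kwargs = dict(WT)
        kwargs[bad] = 0.0
        with pytest.raises(InvalidParameterError):
            derive_activation_params(**kwargs)

    def test_rho_clipped_at_rho_max(self):
        slow = derive_activation_params(10.0, 1e-6, 8.3, 7.23)
        assert slow.rho == slow.rho_max < 1.0


class TestPlacePacemakers:
    def test_wt_sites_centred_at_pacemaking_distance(self):
        sites = place_pacemakers(0.3, 10.0, "antegrade")
        assert [s.position_z for s in sites] == pytest.approx([0.05, 0.15, 0.25])
        assert all(s.direction == ANTEGRADE for s in sites)

    def test_alternating_pattern_directions(self):
        sites = place_pacemakers(0.3, 11.0, "alternating")
        assert len(sites) == 3
        spacing = sites[1].position_z - sites[0].position_z
        assert spacing == pytest.approx(1.0 / 11.0)
        assert [s.direction for s in sites] == [ANTEGRADE, RETROGRADE, ANTEGRADE]

    def test_zero_density_rejected(self):
        with pytest.raises(InvalidParameterError):
            place_pacemakers(0.3, 0.0)

    def test_sparse_chain_gets_single_midpoint_site(self):
        with pytest.warns(UserWarning):
            sites = place_pacemakers(0.3, 2.0)  # spacing 0.5 cm > chain
        assert len(sites) == 1
        assert sites[0].position_z == pytest.approx(0.15)

    def test_conduction_delays_stagger_firing(self):
        sites = place_pacemakers(0.3, 11.0, "antegrade", period_T=3.8,
                                 conduction_speed=0.063)
        delays = [(s.mu_t - sites[0].mu_t) % 3.8 for s in sites]
        spacing = 1.0 / 11.0
        assert delays == pytest.approx([0.0, spacing / 0.063, 2 * spacing / 0.063])
        # fast conduction: near-simultaneous firing
        wt = place_pacemakers(0.3, 10.0, "antegrade", period_T=7.23,
                              conduction_speed=0.98)
        spread = max(s.mu_t for s in wt) - min(s.mu_t for s in wt)
        assert spread < 0.25  # s, << period

    def test_retrograde_delays_run_backwards(self):
        sites = place_pacemakers(0.3, 11.0, "retrograde", period_T=3.8,
                                 conduction_speed=0.063)
        # delay relative to the most downstream site grows moving upstream
        rel = [(s.mu_t - sites[-1].mu_t) % 3.8 for s in sites]
        assert rel[-1] == pytest.approx(0.0)
        assert rel[0] > rel[1] > rel[2]


class TestBivariateGaussian:
    def test_peak_value_is_gaussian_amplitude(self):
        p = derive_activation_params(**WT)
        site = PacemakerSite(0.15, 3.0)
        peak = bivariate_gaussian(0.15, 3.0, site, p)
        # rho ~ 0.007: amplitude within 0.01% of 1/(2 pi sz st)
        assert peak == pytest.approx(7.043, rel=1e-3)

    def test_symmetry_without_correlation(self):
        p = ActivationParams(**WT, sigma_z=0.0125, sigma_t=1.8075, rho=0.0)
        site = PacemakerSite(0.15, 3.0)
        for delta in (0.001, 0.01, 0.03):
            left = bivariate_gaussian(0.15 - delta, 3.0, site, p)
            right = bivariate_gaussian(0.15 + delta, 3.0, site, p)
            assert left == pytest.approx(right, rel=1e-12)

    def test_antegrade_skew_delays_downstream_activation(self):
        p = derive_activation_params(**KO)
        t = np.linspace(0.0, 3.8, 2001)
        site = PacemakerSite(0.15, 1.9, ANTEGRADE)
        t_up = t[np.argmax(bivariate_gaussian(0.15 - 0.005, t, site, p))]
        t_down = t[np.argmax(bivariate_gaussian(0.15 + 0.005, t, site, p))]
        assert t_down > t_up
        retro = PacemakerSite(0.15, 1.9, RETROGRADE)
        t_up_r = t[np.argmax(bivariate_gaussian(0.15 - 0.005, t, retro, p))]
        t_down_r = t[np.argmax(bivariate_gaussian(0.15 + 0.005, t, retro, p))]
        assert t_down_r < t_up_r

    def test_ridge_slope_recovers_conduction_speed(self):
        # brute-force argmax_t(z) near a site; slope must be 1/c
        p = derive_activation_params(**KO)
        site = PacemakerSite(0.15, 1.9, ANTEGRADE)
        t = np.linspace(1.0, 2.8, 20001)
        zs = np.array([0.145, 0.1475, 0.15, 0.1525, 0.155])
        ridge = [t[np.argmax(bivariate_gaussian(z, t, site, p))] for z in zs]
        slope = np.polyfit(zs, ridge, 1)[0]
        assert slope == pytest.approx(1.0 / 0.063, rel=0.02)


class TestBuildField:
    def grids(self, period, n_t=400):
        z = np.linspace(0.0, 0.3, 121)
        t = np.arange(n_t) * (period / n_t)
        return z, t

    def test_single_site_normalizes_to_one_at_centre(self):
        p = derive_activation_params(**WT)
        z, t = self.grids(p.period_T)
        site = PacemakerSite(0.15, p.period_T / 2)
        f = build_activation_field([site], p, z, t)
        assert f.values.max() == 1.0
        j = np.argmin(np.abs(z - 0.15))
        i = np.argmin(np.abs(t - p.period_T / 2))
        assert f.values[j, i] == pytest.approx(1.0, abs=1e-6)

    def test_coincident_sites_match_single_site(self):
        p = derive_activation_params(**WT)
        z, t = self.grids(p.period_T)
        site = PacemakerSite(0.15, p.period_T / 2)
        one = build_activation_field([site], p, z, t)
        two = build_activation_field([site, site], p, z, t)
        np.testing.assert_allclose(two.values, one.values, rtol=1e-12)

    def test_separated_sites_each_reach_unit_activation(self):
        p = derive_activation_params(**WT)
        z, t = self.grids(p.period_T)
        sites = place_pacemakers(0.3, 10.0, period_T=p.period_T)
        f = build_activation_field(sites, p, z, t)
        for s in sites:
            j = np.argmin(np.abs(z - s.position_z))
            assert f.values[j].max() == pytest.approx(1.0, abs=1e-3)

    def test_field_bounds_and_exact_max(self):
        p = derive_activation_params(**KO)
        z, t = self.grids(p.period_T)
        sites = place_pacemakers(0.3, 11.0, "alternating", period_T=p.period_T,
                                 conduction_speed=0.063)
        f = build_activation_field(sites, p, z, t)
        assert f.values.min() >= 0.0
        assert f.values.max() == 1.0

    def test_periodicity_of_lookup(self):
        p = derive_activation_params(**WT)
        z, t = self.grids(p.period_T)
        sites = place_pacemakers(0.3, 10.0, period_T=p.period_T)
        f = build_activation_field(sites, p, z, t)
        for tau in (0.4, 1.77, 5.0):
            np.testing.assert_array_equal(f.at_time(tau), f.at_time(tau + p.period_T))

    def test_wt_synchrony_vs_ko_ridge_delay(self):
        # time of peak activation across the chain spreads far more in KO
        def spread(metrics, pattern, speed):
            p = derive_activation_params(**metrics)
            z = np.linspace(0.0, 0.3, 121)
            t = np.arange(800) * (p.period_T / 800)
            sites = place_pacemakers(0.3, metrics["sites_per_length"], pattern,
                                     period_T=p.period_T, conduction_speed=speed)
            f = build_activation_field(sites, p, z, t)
            tpk = t[np.argmax(f.values, axis=1)]
            return np.ptp(tpk)

        delay_wt = spread(WT, "antegrade", 0.98)
        delay_ko = spread(KO, "antegrade", 0.063)
        assert delay_wt < delay_ko

    def test_empty_sites_rejected(self):
        p = derive_activation_params(**WT)
        z, t = self.grids(p.period_T)
        with pytest.raises(InvalidParameterError):
            build_activation_field([], p, z, t)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    spl=st.floats(4.0, 20.0),
    speed=st.floats(0.05, 2.0),
    period=st.floats(2.0, 10.0),
)
def test_field_invariants_hold_for_random_metrics(spl, speed, period):
    """Normalization and bounds hold across the physiological metric range."""
    p = derive_activation_params(spl, speed, 60.0 / period, period)
    z = np.linspace(0.0, 0.3, 61)
    t = np.arange(200) * (period / 200)
    sites = place_pacemakers(0.3, spl, "antegrade", period_T=period,
                             conduction_speed=speed)
    f = build_activation_field(sites, p, z, t)
    assert f.values.max() == 1.0
    assert f.values.min() >= 0.0
    assert np.isfinite(f.gamma) and f.gamma > 0
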