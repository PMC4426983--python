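"""Pool dynamics: fusion-rate onset, integration, steady states, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrpfit import (
    ModelParams,
    SiteModelParams,
    integrate_pools,
    integrate_site_model,
    k2_time_course,
    rrp_no_replenishment,
    rrp_recovery,
    split_replenishment,
    steady_state_rrp,
    steady_state_rrp_sites,
)
from rrpfit.model import initial_state


class TestFusionRateOnset:
    def test_baseline_before_onset_and_saturation(self, default_params):
        p = default_params.replace(k2_baseline=0.01)
        t = np.linspace(0.0, 30.0, 3001)
        k2 = k2_time_course(p, t)
        assert np.all(k2[t < p.t0] == 0.01)
        on = t >= p.t0
        assert np.all(np.diff(k2[on]) >= 0)
        assert k2.max() <= p.k2_max
        assert k2[-1] == pytest.approx(p.k2_max, rel=1e-10)

    def test_value_at_delay_is_k2max_over_e(self, default_params):
        p = default_params
        val = k2_time_course(p, np.array([p.t0 + p.t_del]))[0]
        assert val == pytest.approx(p.k2_max / np.e, rel=1e-12)

    def test_canonical_set_at_0p8s_past_onset(self, default_params):
        # k2 = 3.5 * exp(-exp(-1)) for t - t0 = t_del + tau
        val = k2_time_course(default_params, np.array([default_params.t0 + 0.8]))[0]
        assert val == pytest.approx(3.5 * np.exp(-np.exp(-1.0)), rel=1e-12)
        assert val == pytest.approx(2.4228, abs=2e-4)

    def test_non_monotone_grid_rejected(self, default_params):
        with pytest.raises(ValueError):
            k2_time_course(default_params, np.array([0.0, 1.0, 0.5]))

    def test_offset_returns_to_baseline(self, default_params):
        t = np.linspace(0.0, 10.0, 1001)
        k2 = k2_time_course(default_params, t, t_off=5.0)
        assert np.all(k2[t > 5.0] == default_params.k2_baseline)


class TestSteadyStates:
    def test_printed_fitted_means_give_printed_rrp(self):
        # k1*D = 0.132 nC/s and k_minus1 = 0.11 1/s imply a 1.2 nC RRP
        p = ModelParams(k1=0.132 / 1000.0, D0=1000.0, k_minus1=0.11)
        assert steady_state_rrp(p, k2=0.0) == pytest.approx(1.2, rel=1e-3)

    def test_zero_priming_and_large_k2_limits(self):
        p = ModelParams(k1=0.0, k_minus1=0.2)
        assert steady_state_rrp(p) == 0.0
        p2 = ModelParams()
        assert steady_state_rrp(p2, k2=1e9) < 1e-6 * steady_state_rrp(p2)

    def test_degenerate_denominator_raises(self):
        p = ModelParams(k_minus1=0.0)
        with pytest.raises(ValueError):
            steady_state_rrp(p, k2=0.0)

    def test_site_model_limits_and_equivalence(self):
        p = SiteModelParams(k1=0.002, D0=1000.0, k_minus1=0.16, S=500.0)
        # k2=0, k1D >> k_minus1: all sites filled
        p_full = SiteModelParams(k1=0.05, D0=1000.0, k_minus1=1e-4, S=500.0)
        assert steady_state_rrp_sites(p_full, k2=0.0) == pytest.approx(500.0, rel=1e-2)
        # parameter transformation reproduces the unrestricted steady state
        eq = p.equivalent_unrestricted()
        assert steady_state_rrp_sites(p, k2=1.3) == pytest.approx(
            steady_state_rrp(eq, k2=1.3), rel=1e-12
        )

    def test_site_model_large_S_limit(self):
        c = 7.0  # hold k1*D0*S at c while S grows
        p = SiteModelParams(k1=c / (1000.0 * 1e6), D0=1000.0, k_minus1=0.16, S=1e6)
        # with S -> inf at fixed k1*D0*S = c, R_inf -> c / (k1*D0 + k_minus1 + k2)
        assert steady_state_rrp_sites(p, k2=0.5) == pytest.approx(
            c / (0.16 + 0.5), rel=1e-4
        )


class TestIntegration:
    def test_no_stimulus_preserves_equilibrium(self, default_params):
        p = default_params.replace(k2_max=0.0)
        traj = integrate_pools(p, 5.0)
        assert np.allclose(traj.R, traj.R[0], rtol=1e-9)

    def test_requires_explicit_r0_when_unpriming_zero(self):
        p = ModelParams(k_minus1=0.0)
        with pytest.raises(ValueError):
            integrate_pools(p, 1.0)
        traj = integrate_pools(p, 1.0, r0=5.0)
        assert traj.R[0] == 5.0

    def test_closed_form_oracle_without_replenishment(self):
        # k1 = k_minus1 = 0 with the delay-free rate matches the closed form
        t = np.linspace(0.0, 5.0, 501)
        for k2m in (0.5, 3.0):
            p = ModelParams(k1=0.0, k_minus1=0.0, k2_max=k2m, tau=0.2, t0=0.0)

            def rate(tt):
                return k2m * (1.0 - np.exp(-np.asarray(tt) / 0.2))

            traj = integrate_pools(p, 5.0, t_eval=t, r0=100.0, k2_fn=rate)
            R_exact, _ = rrp_no_replenishment(100.0, k2m, 0.2, t)
            assert np.max(np.abs(traj.R - R_exact) / R_exact.max()) < 1e-6

    def test_monotone_depletion_without_priming(self):
        p = ModelParams(k1=0.0, k2_max=2.0, t0=0.0, t_del=0.0, tau=0.05)
        traj = integrate_pools(p, 4.0, r0=50.0)
        assert np.all(np.diff(traj.R) < 0)

    def test_mass_conservation_along_trajectory(self, default_params):
        traj = integrate_pools(default_params, 30.0, mode="depletable_D")
        drift = np.abs(traj.total - traj.total[0]) / traj.total[0]
        assert drift.max() < 1e-9

    def test_site_dynamics_match_transformed_plain_model(self):
        site = SiteModelParams(k1=0.0008, D0=1000.0, k_minus1=0.12,
                               k2_max=2.0, t0=0.5, t_del=0.4, tau=0.15, S=700.0)
        t = np.arange(0.0, 6.0, 1e-3)
        a = integrate_site_model(site, 6.0, t_eval=t)
        b = integrate_pools(site.equivalent_unrestricted(), 6.0,
                            mode="constant_k1D", t_eval=t)
        assert np.max(np.abs(a.R - b.R)) < 1e-8 * np.max(b.R)


class TestReplenishmentSplit:
    def test_components_sum_to_joint_solution(self, default_params):
        t = np.arange(0.0, 6.0, 1e-3)
        split = split_replenishment(default_params, 6.0, t_eval=t,
                                    rtol=1e-10, atol=1e-12)
        joint = integrate_pools(default_params, 6.0, mode="constant_k1D",
                                t_eval=t, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(split.R - joint.R) / joint.R.max()) < 1e-8

    def test_no_priming_means_no_new_pool(self):
        p = ModelParams(k1=0.0, k_minus1=0.1, k2_max=2.0, t0=0.2, t_del=0.3,
                        tau=0.1)
        split = split_replenishment(p, 4.0, r0=10.0)
        assert np.all(split.R_new == 0.0)
        assert np.all(split.I_new == 0.0)

    def test_new_pool_bounded_by_asymptotic_steady_state(self, default_params):
        split = split_replenishment(default_params, 7.5)
        bound = default_params.k1D / (default_params.k_minus1 + default_params.k2_max)
        assert 0.0 < split.R_new[-1] <= bound * 1.001

    def test_current_sign_convention(self, default_params):
        split = split_replenishment(default_params, 6.0)
        assert split.I.min() < 0 and split.I.max() <= 0


class TestRecovery:
    def test_endpoints(self, default_params):
        R_inf = steady_state_rrp(default_params)
        r = rrp_recovery(default_params, R_end=10.0, t=np.array([0.0, 1e4]))
        assert r[0] == pytest.approx(10.0)
        assert r[1] == pytest.approx(R_inf, rel=1e-9)

    def test_printed_unpriming_rate_gives_9p1_s_time_constant(self):
        p = ModelParams(k_minus1=0.11)
        assert 1.0 / p.k_minus1 == pytest.approx(9.1, abs=0.01)
        # e-fold recovery toward equilibrium after exactly 1/k_minus1
        R_inf = steady_state_rrp(p)
        r = rrp_recovery(p, R_end=0.0, t=np.array([1.0 / p.k_minus1]))
        assert (R_inf - r[0]) / R_inf == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_ode_matches_closed_form_post_stimulus(self, default_params):
        # after the stimulus, k2 = 0 integration follows the recovery law
        p = default_params.replace(k2_max=0.0)
        R_end = 30.0
        t = np.arange(0.0, 20.0, 1e-2)
        traj = integrate_pools(p, 20.0, mode="constant_k1D", t_eval=t, r0=R_end)
        exact = rrp_recovery(p, R_end, t)
        assert np.max(np.abs(traj.R - exact) / exact.max()) < 1e-8

    def test_requires_positive_unpriming(self):
        with pytest.raises(ValueError):
            rrp_recovery(ModelParams(k_minus1=0.0), 1.0, np.array([0.0]))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    k1=st.floats(1e-4, 1.0),
    k_minus1=st.floats(1e-3, 1.0),
    k2_max=st.floats(0.0, 20.0),
    t_del=st.floats(0.0, 1.5),
    tau=st.floats(0.02, 1.0),
)
def test_mass_conservation_property(k1, k_minus1, k2_max, t_del, tau):
    """D + R + F stays constant for arbitrary parameter draws."""
    p = ModelParams(k1=k1, k_minus1=k_minus1, k2_max=k2_max, t0=0.3,
                    t_del=t_del, tau=tau, D0=100.0)
    traj = integrate_pools(p, 10.0, mode="depletable_D",
                           t_eval=np.linspace(0.0, 10.0, 201))
    drift = np.abs(traj.total - traj.total[0]) / traj.total[0]
    assert drift.max() < 1e-9


@settings(deadline=None, max_examples=40, derandomize=True)
@given(k2=st.floats(0.0, 1e3), k2b=st.floats(0.0, 1e3))
def test_steady_state_monotone_in_k2(k2, k2b):
    p = ModelParams()
    lo, hi = sorted((k2, k2b))
    assert steady_state_rrp(p, hi) <= steady_state_rrp(p, lo)
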