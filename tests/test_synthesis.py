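"""Trace synthesis: kernel normalization, convolution, noise, sweeps."""

import numpy as np
import pytest

from rrpfit import (
    MEPSCKernel,
    ModelParams,
    Trace,
    integrate_pools,
    release_rate_to_current,
    simulate_current,
    sweep_k2max,
    synthesize_trace,
)


class TestKernel:
    def test_unit_charge_normalization(self):
        k = MEPSCKernel()
        w = k.waveform()
        assert w.sum() * k.sample_dt == pytest.approx(1.0, rel=1e-6)
        assert w.min() >= 0.0

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            MEPSCKernel(rise_tau=3e-3, decay_tau=0.5e-3)


class TestConvolution:
    def test_identity_like_for_fast_kernel(self):
        # boxcar rate of 1 nC/s: peak current within 0.2% of 1 nA
        k = MEPSCKernel(rise_tau=0.5e-3, decay_tau=3e-3, sample_dt=1e-4)
        rate = np.zeros(20000)
        rate[5000:15000] = 1.0
        I = release_rate_to_current(rate, k)
        assert abs(I.min() + 1.0) < 2e-3
        assert I.max() <= 0.0

    def test_charge_conservation(self):
        k = MEPSCKernel(sample_dt=1e-4)
        rng = np.random.default_rng(3)
        rate = np.abs(rng.normal(0, 1, 30000))
        rate[-2000:] = 0.0  # let the kernel tail decay inside the record
        I = release_rate_to_current(rate, k)
        assert -I.sum() == pytest.approx(rate.sum(), rel=5e-3)


class TestSynthesize:
    def test_flat_zero_without_stimulus_or_noise(self, kernel):
        p = ModelParams(k2_max=0.0)
        tr = synthesize_trace(p, kernel, noise_sd=0.0, duration=3.0, dt=2e-4)
        assert np.all(tr.I == 0.0)

    def test_seed_determinism(self, default_params, kernel):
        a = synthesize_trace(default_params, kernel, noise_sd=10.0, seed=42,
                             duration=2.0, dt=2e-4)
        b = synthesize_trace(default_params, kernel, noise_sd=10.0, seed=42,
                             duration=2.0, dt=2e-4)
        assert np.array_equal(a.I, b.I)
        c = synthesize_trace(default_params, kernel, noise_sd=10.0, seed=43,
                             duration=2.0, dt=2e-4)
        assert not np.array_equal(a.I, c.I)

    def test_canonical_fixture_noise_statistics(self, default_params):
        k10 = MEPSCKernel()  # 10 kHz default sampling
        tr = synthesize_trace(default_params, k10, noise_sd=10.0, seed=0,
                              duration=8.0)
        clean = synthesize_trace(default_params, k10, noise_sd=0.0,
                                 duration=8.0)
        resid = tr.I - clean.I
        assert tr.t.size == 80001
        assert resid.mean() == pytest.approx(0.0, abs=0.2)
        assert resid.std() == pytest.approx(10.0, rel=0.02)

    def test_charge_bookkeeping_noiseless(self, default_params, kernel):
        tr = synthesize_trace(default_params, kernel, noise_sd=0.0,
                              duration=8.0, dt=2e-4, mode="depletable_D")
        traj = integrate_pools(default_params, 8.0, t_eval=tr.t)
        released = traj.F[-1]
        measured = -np.trapezoid(tr.I, tr.t) / 1000.0  # pA s -> nC
        assert measured == pytest.approx(released, rel=5e-3)


class TestSweep:
    def test_equal_values_give_identical_traces(self, default_params, kernel):
        trs = sweep_k2max(default_params, [3.5, 3.5], kernel, duration=3.0,
                          dt=2e-4)
        assert np.array_equal(trs[0].I, trs[1].I)

    def test_peak_grows_and_speeds_up_with_k2max(self, default_params, kernel):
        # the published simulation family
        trs = sweep_k2max(default_params, [0.5, 3.0, 5.0, 10.0], kernel,
                          duration=6.0, dt=2e-4)
        peaks = np.array([-tr.I.min() for tr in trs])
        ttp = np.array([tr.t[int(np.argmin(tr.I))] for tr in trs])
        assert np.all(np.diff(peaks) > 0)
        assert np.all(np.diff(ttp) < 0)

    def test_doubling_k2max_roughly_halves_time_to_peak(self, default_params, kernel):
        # regression snapshot of the qualitative contract, not an exact law
        trs = sweep_k2max(default_params, [3.5, 7.0], kernel, duration=6.0,
                          dt=2e-4, noise_sd=0.0)
        # measured from the delayed fusion-rate onset, not stimulus onset
        start = default_params.t0 + default_params.t_del
        ttp = [tr.t[int(np.argmin(tr.I))] - start for tr in trs]
        assert 0.3 < ttp[1] / ttp[0] < 0.7


class TestParameterSensitivity:
    """Shape contracts of the single-parameter adaptation family."""

    @staticmethod
    def _aligned_shape(tr):
        sig = -tr.I
        i = int(np.argmax(sig))
        w = int(0.5 / tr.dt)
        seg = sig[max(i - w, 0): i + w]
        return seg / seg.max()

    def test_k1_or_D_scale_steady_phase_not_peak_shape(self, default_params, kernel):
        base = synthesize_trace(default_params, kernel, noise_sd=0.0,
                                duration=8.0, dt=2e-4, mode="constant_k1D")
        for change in ({"k1": 0.18}, {"D0": 2000.0}):
            up = synthesize_trace(default_params.replace(**change), kernel,
                                  noise_sd=0.0, duration=8.0, dt=2e-4,
                                  mode="constant_k1D")
            # steady phase doubles
            ss_b = -base.I[-2000:].mean()
            ss_u = -up.I[-2000:].mean()
            assert ss_u / ss_b == pytest.approx(2.0, rel=0.02)
            # scaled-and-aligned peak shape unchanged
            d = np.abs(self._aligned_shape(base) - self._aligned_shape(up))
            assert d.max() < 0.02

    def test_t_del_time_shifts_without_shape_change(self, default_params, kernel):
        base = synthesize_trace(default_params, kernel, noise_sd=0.0,
                                duration=8.0, dt=2e-4, mode="constant_k1D")
        shifted = synthesize_trace(default_params.replace(t_del=1.2), kernel,
                                   noise_sd=0.0, duration=8.0, dt=2e-4,
                                   mode="constant_k1D")
        shift = int(round(0.6 / base.dt))
        d = np.abs(base.I[:-shift] - shifted.I[shift:])
        assert d.max() < 1e-3 * np.abs(base.I).max()


class TestTraceType:
    def test_rejects_non_uniform_sampling(self):
        t = np.array([0.0, 1e-4, 3e-4])
        with pytest.raises(ValueError):
            Trace(t=t, I=np.zeros(3), stim_on=0.0, stim_off=1.0)

    def test_rejects_inverted_stimulus_window(self):
        t = np.arange(0.0, 1.0, 1e-3)
        with pytest.raises(ValueError):
            Trace(t=t, I=np.zeros(t.size), stim_on=0.8, stim_off=0.2)
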