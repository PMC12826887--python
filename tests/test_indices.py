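import math

import numpy as np
import pytest

from ppgsurv.fiducials import FiducialSet, detect_fiducials
from ppgsurv.indices import (
    INDEX_NAMES,
    compute_areas,
    compute_ipad,
    compute_sdppg_indices,
    compute_stiffness_k,
    compute_timing,
    extract_all,
    extract_batch,
)
from ppgsurv.synthetic_data import (
    BeatParams,
    canonical_beat_params,
    generate_beat,
)
from ppgsurv.waveform_core import PulseWave

from conftest import random_beat_params


def make_fp(**kwargs) -> FiducialSet:
    base = dict(
        t_foot=0.0, t_sys=0.15, amp_sys=1.0, t_notch=0.4, amp_notch=0.2,
        t_dia=0.5, amp_dia=0.3, t_end=0.8, t_ms=0.08, amp_ms=10.0,
        wave_times={}, wave_amps={},
    )
    base.update(kwargs)
    return FiducialSet(**base)


class TestAreas:
    def test_rectangle(self):
        fs = 1000.0
        n = 1001
        x = np.zeros(n)
        x[: 301] = 1.0
        pulse = PulseWave(x, 1 / fs)
        fp = make_fp(t_notch=0.3, t_end=1.0)
        A1, A2 = compute_areas(pulse, fp)
        assert A1 == pytest.approx(0.3, abs=1e-3)
        assert A2 == pytest.approx(0.0, abs=1e-3)

    def test_triangle(self):
        fs = 1000.0
        t = np.arange(1001) / fs
        x = np.where(t <= 0.5, t, 1.0 - t) * 2
        pulse = PulseWave(x, 1 / fs)
        fp = make_fp(t_notch=0.5, t_end=1.0)
        A1, A2 = compute_areas(pulse, fp)
        assert A1 == pytest.approx(0.25, abs=1e-6)
        assert A2 == pytest.approx(0.25, abs=1e-6)

    def test_quadrature_oracle(self, canonical_beat_500, canonical_params):
        from scipy.integrate import quad

        from ppgsurv.synthetic_data import beat_function

        pulse, truth = canonical_beat_500
        fp = detect_fiducials(pulse)
        A1, A2 = compute_areas(pulse, fp)

        def f(x):
            return (beat_function(canonical_params, x, 0) - truth.norm_offset) / truth.norm_scale

        A1o = quad(f, 0.0, fp.t_notch, limit=200)[0]
        A2o = quad(f, fp.t_notch, pulse.period_T, limit=200)[0]
        assert A1 == pytest.approx(A1o, abs=1e-4)
        assert A2 == pytest.approx(A2o, abs=1e-4)

    def test_missing_notch_undefined(self, canonical_beat):
        pulse, _ = canonical_beat
        fp = make_fp(t_notch=math.nan)
        A1, A2 = compute_areas(pulse, fp)
        assert math.isnan(A1) and math.isnan(A2)

    def test_conservation(self, canonical_beat):
        pulse, _ = canonical_beat
        fp = detect_fiducials(pulse)
        A1, A2 = compute_areas(pulse, fp)
        total = np.trapezoid(pulse.samples, pulse.t)
        assert A1 + A2 == pytest.approx(total, abs=1e-12)


class TestTiming:
    def test_subtraction(self):
        fp = make_fp(t_sys=0.15, t_dia=0.45)
        out = compute_timing(fp)
        assert out["DT"] == pytest.approx(0.30)
        assert out["CT"] == pytest.approx(0.15)

    def test_dilation(self):
        fp = make_fp(
            wave_times={"b": 0.1, "c": 0.2, "d": 0.3},
            wave_amps={"b": -1.0, "c": 0.5, "d": -0.2},
        )
        out = compute_timing(fp)
        fp2 = make_fp(
            t_sys=0.15 * 1.2, t_notch=0.4 * 1.2, t_dia=0.5 * 1.2,
            t_end=0.8 * 1.2,
            wave_times={"b": 0.12, "c": 0.24, "d": 0.36},
            wave_amps={"b": -1.0, "c": 0.5, "d": -0.2},
        )
        out2 = compute_timing(fp2)
        for key in ("T", "DT", "CT", "t_systole", "t_bc", "t_bd"):
            assert out2[key] == pytest.approx(1.2 * out[key])

    @pytest.mark.parametrize("bpm", [50, 60, 75, 90])
    def test_period_across_heart_rates(self, bpm):
        period = 60.0 / bpm
        pulse, _ = generate_beat(canonical_beat_params(period=period), 250.0)
        iv = extract_all(pulse)
        assert abs(iv.T - period) <= 1 / 250.0


class TestSdppg:
    def test_agi_mod_formula(self):
        fp = make_fp(
            wave_times={"a": 0.03, "b": 0.1, "c": 0.2, "d": 0.3, "e": 0.38},
            wave_amps={"a": 2.0, "b": -1.0, "c": 0.5, "d": -0.4, "e": 0.1},
        )
        out = compute_sdppg_indices(fp)
        assert out["AGI_mod"] == pytest.approx((-1.0 - 0.5 - (-0.4)) / 2.0)
        assert out["AGI_mod"] == pytest.approx(-0.55)

    def test_zero_slope(self):
        fp = make_fp(
            wave_times={"a": 0.03, "b": 0.1, "c": 0.2, "d": 0.3, "e": 0.38},
            wave_amps={"a": 2.0, "b": 0.7, "c": 0.7, "d": -0.4, "e": 0.1},
        )
        assert compute_sdppg_indices(fp)["slope_bc"] == pytest.approx(0.0)

    def test_slope_formula(self):
        fp = make_fp(
            wave_times={"a": 0.03, "b": 0.1, "c": 0.2, "d": 0.35, "e": 0.4},
            wave_amps={"a": 2.0, "b": -1.0, "c": 0.5, "d": -0.4, "e": 0.1},
        )
        out = compute_sdppg_indices(fp)
        assert out["slope_bc"] == pytest.approx((0.5 + 1.0) / (0.1 * 2.0))
        assert out["slope_bd"] == pytest.approx((-0.4 + 1.0) / (0.25 * 2.0))

    def test_zero_a_undefined(self):
        fp = make_fp(wave_times={"a": 0.03, "b": 0.1}, wave_amps={"a": 0.0, "b": -1.0})
        out = compute_sdppg_indices(fp)
        assert math.isnan(out["AGI_mod"])

    def test_amplitude_scale_invariance_full_pipeline(self, canonical_params):
        pulse, _ = generate_beat(canonical_params, 250.0)
        iv1 = extract_all(pulse)
        scaled = PulseWave((3.5 * pulse.samples - 3.5 * pulse.samples.min())
                           / (3.5 * np.ptp(pulse.samples)), pulse.dt)
        from ppgsurv.waveform_core import normalize_pulse
        iv2 = extract_all(normalize_pulse(3.5 * pulse.samples + 7.0, pulse.dt))
        for name in INDEX_NAMES:
            v1, v2 = getattr(iv1, name), getattr(iv2, name)
            assert v1 == pytest.approx(v2, rel=1e-9), name


class TestIpad:
    def test_formula(self):
        assert compute_ipad(1.0, 0.4, 1.0, -0.2) == pytest.approx(0.2)

    def test_zero_case(self):
        assert compute_ipad(0.5, 0.0, 2.0, 0.0) == pytest.approx(0.0)

    def test_a1_zero_undefined(self):
        assert math.isnan(compute_ipad(0.0, 0.4, 1.0, -0.2))

    def test_oracle_composition(self, canonical_beat_500):
        pulse, truth = canonical_beat_500
        iv = extract_all(pulse)
        expected = truth.A2 / truth.A1 + truth.wave_amps["d"] / truth.wave_amps["a"]
        assert iv.IPAD == pytest.approx(expected, abs=0.05)


class TestStiffnessK:
    @staticmethod
    def _exp_tail_pulse(rate, fs=250.0, tail_s=3.2):
        t = np.arange(int(tail_s * fs)) / fs
        rise = np.sin(np.pi * np.clip(t, 0, 0.2) / 0.4)
        tail = np.exp(-rate * (t - 0.2))
        x = np.where(t <= 0.2, rise, tail)
        pulse = PulseWave(x, 1 / fs)
        return pulse, make_fp(t_dia=0.2, t_end=t[-1])

    def test_exact_exponential_recovery(self):
        pulse, fp = self._exp_tail_pulse(3.0)
        assert compute_stiffness_k(pulse, fp) == pytest.approx(3.0, abs=0.01)

    def test_flat_tail_zero(self):
        fs = 250.0
        x = np.concatenate([np.linspace(0, 1, 50), np.full(200, 1.0)])
        pulse = PulseWave(x, 1 / fs)
        fp = make_fp(t_dia=50 / fs, t_end=(len(x) - 1) / fs)
        assert compute_stiffness_k(pulse, fp) == 0.0

    def test_decay_sweep_rank_order(self):
        ks = []
        for rate in (2.0, 4.0, 6.0):
            pulse, fp = self._exp_tail_pulse(rate)
            ks.append(compute_stiffness_k(pulse, fp))
        assert ks[0] < ks[1] < ks[2]

    def test_too_few_samples_undefined(self, canonical_beat):
        pulse, _ = canonical_beat
        fp = make_fp(t_dia=pulse.period_T - 2 * pulse.dt, t_end=pulse.period_T)
        assert math.isnan(compute_stiffness_k(pulse, fp))


class TestExtractAll:
    def test_canonical_all_defined(self, canonical_beat):
        pulse, _ = canonical_beat
        iv = extract_all(pulse)
        for name in INDEX_NAMES:
            assert np.isfinite(getattr(iv, name)), name
        assert iv.T > 0
        assert 0 < iv.CT < iv.t_systole <= iv.T
        assert iv.t_bc > 0 and iv.t_bd > iv.t_bc
        assert iv.DT > 0
        assert iv.A1 >= 0 and iv.A2 >= 0

    def test_excluded_features_never_emitted(self):
        assert "heart_rate" not in INDEX_NAMES
        assert "SI" not in INDEX_NAMES
        assert "stiffness_index" not in INDEX_NAMES
        assert len(INDEX_NAMES) == 20

    def test_notchless_flagged(self):
        p = BeatParams(
            amplitudes=(1.0, 0.42, 0.20, 1e-4),
            centers=(0.13, 0.24, 0.315, 0.52),
            widths=(0.046, 0.07, 0.05, 0.001),
            decay=1.0, period=0.68,
        )
        pulse, _ = generate_beat(p, 250.0)
        iv = extract_all(pulse)
        assert iv.flags.get("notch") == "fallback_e_wave"

    def test_batch_contract(self, rng):
        pulses = []
        for i in range(17):
            params = random_beat_params(rng)
            pulses.append((f"p{i}", generate_beat(params, 250.0)[0]))
        # 3 degenerate entries
        for i in range(3):
            flat = PulseWave(np.linspace(0, 1, 30), 1 / 250.0)
            pulses.append((f"bad{i}", flat))
        df = extract_batch(pulses)
        assert len(df) == 20
        assert df["flags"].str.len().gt(0).sum() >= 3


class TestDilationCovariance:
    def test_self_similar_dilation(self, rng):
        gamma = 1.3
        params = random_beat_params(rng)
        pulse, _ = generate_beat(params, 250.0)
        iv = extract_all(pulse)
        dilated = PulseWave(pulse.samples.copy(), pulse.dt * gamma)
        iv2 = extract_all(dilated, smoothing_window_s=0.05 * gamma)
        scale = {
            "T": gamma, "DT": gamma, "CT": gamma, "t_systole": gamma,
            "t_bc": gamma, "t_bd": gamma, "A1": gamma, "A2": gamma,
            "dia_amp": 1.0, "ms": 1 / gamma, "a": gamma**-2, "b": gamma**-2,
            "c": gamma**-2, "d": gamma**-2, "e": gamma**-2,
            "AGI_mod": 1.0, "IPAD": 1.0,
            "slope_bc": 1 / gamma, "slope_bd": 1 / gamma, "k": 1 / gamma,
        }
        for name, fac in scale.items():
            tol = 1e-9 if name != "k" else 1e-3
            assert getattr(iv2, name) == pytest.approx(
                fac * getattr(iv, name), rel=tol
            ), name
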