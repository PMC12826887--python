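"""Fiducial-point detection on a normalized beat and its derivatives.

Landmarks detected on the waveform itself: foot (t = 0 by construction),
systolic peak, dicrotic notch, diastolic peak and pulse end.  On the first
derivative: the maximum-upslope point (``ms``).  On the second derivative:
the alternating a-e waves of systole / early diastole.

Detection is windowed so that diastolic structure can never be mistaken
for a/b waves; landmarks that do not exist on a given contour (e.g. the
notch on an older-physiology beat) are resolved by documented fallbacks
and flagged, or marked missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ppgsurv.waveform_core import DerivativePair, PulseWave, derivatives

__all__ = [
    "FiducialSet",
    "detect_systolic_peak",
    "detect_ms",
    "detect_abcde",
    "detect_dicrotic_notch",
    "detect_diastolic_peak",
    "detect_fiducials",
]

WAVE_LABELS = ("a", "b", "c", "d", "e")


@dataclass
class FiducialSet:
    """Times (s), amplitudes and quality flags of all detected landmarks.

    Missing landmarks are NaN; ``flags`` records fallback and missing
    markers (e.g. ``notch: "fallback_e_wave"``, ``c: "missing"``).
    """

    t_foot: float
    t_sys: float
    amp_sys: float
    t_notch: float
    amp_notch: float
    t_dia: float
    amp_dia: float
    t_end: float
    t_ms: float
    amp_ms: float
    wave_times: dict[str, float]
    wave_amps: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)

    def wave(self, label: str) -> tuple[float, float]:
        return self.wave_times.get(label, math.nan), self.wave_amps.get(label, math.nan)

    def has(self, label: str) -> bool:
        return label in self.wave_times and np.isfinite(self.wave_times[label])

    def to_dict(self) -> dict:
        d = asdict(self)
        waves_t = d.pop("wave_times")
        waves_a = d.pop("wave_amps")
        for lab in WAVE_LABELS:
            d[f"t_{lab}"] = waves_t.get(lab, math.nan)
            d[f"amp_{lab}"] = waves_a.get(lab, math.nan)
        d["flags"] = ";".join(f"{k}={v}" for k, v in self.flags.items())
        return d


def _local_maxima(x: np.ndarray, prominence: float = 0.0) -> np.ndarray:
    """Indices of local maxima with at least the given prominence.

    Plateaus yield their first sample (earliest-tie rule); with zero
    prominence every strict local maximum is returned.
    """
    from scipy.signal import find_peaks

    if len(x) < 3:
        return np.array([], dtype=int)
    peaks, props = find_peaks(
        x, prominence=prominence if prominence > 0 else None, plateau_size=1
    )
    if len(peaks) == 0:
        return peaks
    return props["left_edges"].astype(int)


def _local_minima(x: np.ndarray, prominence: float = 0.0) -> np.ndarray:
    return _local_maxima(-np.asarray(x), prominence)


def detect_systolic_peak(pulse: PulseWave) -> tuple[float, float]:
    """Time and amplitude of the global maximum (earliest sample on ties)."""
    i = int(np.argmax(pulse.samples))
    return i * pulse.dt, float(pulse.samples[i])


def detect_ms(deriv: DerivativePair, t_sys: float) -> tuple[float, float]:
    """Maximum of the first derivative on the rising edge [0, t_sys]."""
    n = int(round(t_sys / deriv.dt)) + 1
    if n < 1:
        raise ValueError("empty search window for ms")
    seg = deriv.d1[:n]
    i = int(np.argmax(seg))
    return i * deriv.dt, float(seg[i])


def detect_abcde(
    deriv: DerivativePair,
    t_sys: float,
    t_notch_estimate: float,
    prominence_frac: float = 0.04,
) -> tuple[dict[str, float], dict[str, float], dict[str, str]]:
    """Locate the alternating a-e waves of the second derivative.

    a is the first maximum of d2 after the foot; b the first minimum after
    a; c, d, e continue the alternation.  Extrema must have prominence of
    at least ``prominence_frac`` of the d2 range, so residual noise
    wiggles on ensemble-averaged beats are not mistaken for waves.  The e
    wave must fall within ``[t_sys, 1.2 * t_notch_estimate]``; waves whose
    extremum does not exist (monotone d2 segment) are flagged missing.
    """
    d2 = deriv.d2
    dt = deriv.dt
    limit = int(round(min(1.2 * t_notch_estimate, (len(d2) - 1) * dt) / dt))
    seg = d2[: limit + 1]
    prom = prominence_frac * float(np.ptp(seg))
    maxima = _local_maxima(seg, prom)
    minima = _local_minima(seg, prom)
    # a boundary-maximum start (monotone-falling d2, e.g. a half-sine arch)
    # still defines an a wave at the foot
    boundary_a = -1
    if len(minima) > 0 and (len(maxima) == 0 or minima[0] < maxima[0]):
        boundary_a = int(np.argmax(seg[: minima[0] + 1]))
        maxima = np.concatenate(([boundary_a], maxima)).astype(int)
    times: dict[str, float] = {}
    amps: dict[str, float] = {}
    flags: dict[str, str] = {}
    prev = 0
    for k, lab in enumerate(WAVE_LABELS):
        pool = maxima if k % 2 == 0 else minima
        after = pool[pool > prev] if k > 0 else pool[pool >= prev]
        if lab == "e":
            after = after[after * dt >= t_sys]
        # canonical morphology: the a wave is positive, b negative; this
        # keeps noise wiggles on the a plateau from being labeled b
        if lab == "a":
            after = after[(d2[after] > 0) | (after == boundary_a)]
        elif lab == "b":
            after = after[d2[after] < 0]
        if len(after) == 0:
            for missing in WAVE_LABELS[k:]:
                flags[missing] = "missing"
            break
        i = int(after[0])
        times[lab] = i * dt
        amps[lab] = float(d2[i])
        prev = i
    return times, amps, flags


def detect_dicrotic_notch(
    pulse: PulseWave,
    deriv: DerivativePair,
    t_sys: float,
    wave_times: dict[str, float] | None = None,
    prominence: float = 0.02,
) -> tuple[float, float, str | None]:
    """Dicrotic notch: earliest waveform local minimum after the systolic peak.

    Candidate minima need ``prominence`` (in normalized amplitude units)
    so residual noise dips near the rounded systolic peak are ignored.
    When the contour has no post-systolic local minimum the time of the
    e wave of the second derivative is used instead and the result is
    flagged ``"fallback_e_wave"``.

    Raises
    ------
    ValueError
        If neither a minimum nor an e wave is available.
    """
    i_sys = int(round(t_sys / pulse.dt))
    seg = pulse.samples[i_sys:]
    minima = _local_minima(seg, prominence)
    if len(minima) > 0:
        i = i_sys + int(minima[0])
        return i * pulse.dt, float(pulse.samples[i]), None
    if wave_times and "e" in wave_times and np.isfinite(wave_times["e"]):
        t_e = wave_times["e"]
        i = int(round(t_e / pulse.dt))
        return t_e, float(pulse.samples[i]), "fallback_e_wave"
    raise ValueError("notch undetectable: no local minimum and no e wave")


def detect_diastolic_peak(
    pulse: PulseWave,
    t_notch: float,
    deriv: DerivativePair | None = None,
    prominence: float = 0.01,
) -> tuple[float, float, str | None]:
    """Diastolic peak: waveform local maximum after the notch.

    On monotone-decay diastoles the inflection point (zero crossing of the
    second derivative) in the window is returned, flagged
    ``"fallback_inflection"``.
    """
    i_notch = int(round(t_notch / pulse.dt))
    seg = pulse.samples[i_notch:]
    if len(seg) < 3:
        raise ValueError("empty diastolic search window")
    maxima = _local_maxima(seg, prominence)
    if len(maxima) > 0:
        i = i_notch + int(maxima[0])
        return i * pulse.dt, float(pulse.samples[i]), None
    if deriv is not None:
        d2 = deriv.d2[i_notch:]
        sign = np.sign(d2)
        crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        if len(crossings) > 0:
            i = i_notch + int(crossings[0])
            return i * pulse.dt, float(pulse.samples[i]), "fallback_inflection"
    raise ValueError("no diastolic peak or inflection in window")


def detect_fiducials(
    pulse: PulseWave,
    deriv: DerivativePair | None = None,
    smoothing_window_s: float = 0.05,
    poly_order: int = 3,
) -> FiducialSet:
    """Run the full landmark chain on one normalized beat."""
    if deriv is None:
        deriv = derivatives(pulse, smoothing_window_s, poly_order)
    t_sys, amp_sys = detect_systolic_peak(pulse)
    t_ms, amp_ms = detect_ms(deriv, t_sys)
    flags: dict[str, str] = {}

    # first pass at the notch from the waveform alone; the a-e search window
    # needs an estimate even when the true notch will come from the e wave
    i_sys = int(round(t_sys / pulse.dt))
    minima = _local_minima(pulse.samples[i_sys:], 0.02)
    notch_est = (
        (i_sys + int(minima[0])) * pulse.dt
        if len(minima) > 0
        else t_sys + 0.6 * (pulse.period_T - t_sys)
    )
    wave_times, wave_amps, wave_flags = detect_abcde(deriv, t_sys, notch_est)
    flags.update(wave_flags)

    try:
        t_notch, amp_notch, notch_flag = detect_dicrotic_notch(
            pulse, deriv, t_sys, wave_times
        )
        if notch_flag:
            flags["notch"] = notch_flag
    except ValueError:
        t_notch = amp_notch = math.nan
        flags["notch"] = "missing"

    if np.isfinite(t_notch):
        try:
            t_dia, amp_dia, dia_flag = detect_diastolic_peak(pulse, t_notch, deriv)
            if dia_flag:
                flags["dia"] = dia_flag
        except ValueError:
            t_dia = amp_dia = math.nan
            flags["dia"] = "missing"
    else:
        t_dia = amp_dia = math.nan
        flags["dia"] = "missing"

    return FiducialSet(
        t_foot=0.0,
        t_sys=t_sys,
        amp_sys=amp_sys,
        t_notch=t_notch,
        amp_notch=amp_notch,
        t_dia=t_dia,
        amp_dia=amp_dia,
        t_end=pulse.period_T,
        t_ms=t_ms,
        amp_ms=amp_ms,
        wave_times=wave_times,
        wave_amps=wave_amps,
        flags=flags,
    )
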