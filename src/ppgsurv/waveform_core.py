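"""Core waveform handling: loading, segmentation, averaging, derivatives.

The processing chain turns a raw finger-sensor trace into a single
analysis-ready beat:

``RawSignal -> segment_beats -> ensemble_average -> PulseWave -> derivatives``

All times are in seconds and amplitudes of a :class:`PulseWave` are min-max
normalized to ``[0, 1]``; downstream indices are therefore invariant to the
arbitrary amplitude units of the sensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "RawSignal",
    "PulseWave",
    "DerivativePair",
    "InsufficientBeatsError",
    "segment_beats",
    "ensemble_average",
    "normalize_pulse",
    "derivatives",
    "read_waveform_csv",
]

#: minimum plausible beat duration (s); shorter slices are discarded
MIN_BEAT_S = 0.3
#: maximum plausible beat duration (s); longer slices are discarded
MAX_BEAT_S = 2.0
#: window before an upslope maximum searched for the pulse foot (s)
FOOT_SEARCH_S = 0.25


class InsufficientBeatsError(ValueError):
    """Raised when fewer than the required number of beats are detected."""


@dataclass(frozen=True)
class RawSignal:
    """A raw PPG trace in arbitrary light-intensity units."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def duration_s(self) -> float:
        return (len(self.samples) - 1) / self.sampling_rate


@dataclass(frozen=True)
class PulseWave:
    """One normalized, ensemble-averaged beat.

    ``samples`` are min-max scaled to [0, 1]; the time axis starts at the
    pulse foot (t = 0) and spans ``period_T = (n - 1) * dt`` seconds.
    """

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(samples) < 3:
            raise ValueError("a beat needs at least 3 samples")

    @property
    def period_T(self) -> float:
        return (len(self.samples) - 1) * self.dt

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class DerivativePair:
    """First and second derivatives of a beat (units 1/s and 1/s^2)."""

    d1: np.ndarray
    d2: np.ndarray
    dt: float

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.d1)) * self.dt


def normalize_pulse(beat: np.ndarray, dt: float) -> PulseWave:
    """Min-max scale a beat to [0, 1] and attach its time axis.

    Raises
    ------
    ValueError
        If the beat is constant (zero amplitude range).
    """
    beat = np.asarray(beat, dtype=float)
    lo, hi = beat.min(), beat.max()
    if hi - lo == 0:
        raise ValueError("cannot normalize a constant beat (zero range)")
    return PulseWave((beat - lo) / (hi - lo), dt)


def _smoothed(samples: np.ndarray, fs: float, window_s: float = 0.05) -> np.ndarray:
    win = max(5, int(round(window_s * fs)) | 1)
    if win >= len(samples):
        return samples
    return savgol_filter(samples, win, 3)


def _upslope_peaks(samples: np.ndarray, fs: float) -> np.ndarray:
    """Indices of maxima of the first derivative, one per heartbeat upstroke.

    Works on a smoothed copy so sample-level noise cannot fragment beats;
    peaks must be prominent relative to the slope scale and separated by
    at least the minimum beat duration.
    """
    from scipy.signal import find_peaks

    d1 = np.gradient(_smoothed(samples, fs, window_s=0.08)) * fs
    prom = 0.25 * (d1.max() - d1.min())
    if prom <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        d1,
        prominence=prom,
        height=0.5 * d1.max(),
        distance=max(1, int(MIN_BEAT_S * fs)),
    )
    return peaks


def segment_beats(signal: RawSignal) -> list[np.ndarray]:
    """Slice a raw trace into foot-to-foot beats.

    The foot of each beat is the minimum of the waveform in a
    ``FOOT_SEARCH_S`` window preceding each maximum-upslope point.  Slices
    shorter than ``MIN_BEAT_S`` or longer than ``MAX_BEAT_S`` are discarded.

    Raises
    ------
    InsufficientBeatsError
        If fewer than 3 beats are found.
    """
    fs = signal.sampling_rate
    if signal.duration_s < 2.0:
        raise InsufficientBeatsError("signal shorter than 2 s")
    feet = detect_foot_indices(signal)
    beats = []
    for i0, i1 in zip(feet[:-1], feet[1:]):
        dur = (i1 - i0) / fs
        if MIN_BEAT_S <= dur <= MAX_BEAT_S:
            beats.append(signal.samples[i0:i1 + 1].copy())
    if len(beats) < 3:
        raise InsufficientBeatsError(
            f"only {len(beats)} beats detected; at least 3 required"
        )
    return beats


def detect_foot_indices(signal: RawSignal) -> np.ndarray:
    """Sample indices of detected pulse feet.

    The foot is the minimum of the smoothed waveform within a
    ``FOOT_SEARCH_S`` window before each maximum-upslope point (earliest
    sample on ties).
    """
    fs = signal.sampling_rate
    smooth = _smoothed(signal.samples, fs)
    peaks = _upslope_peaks(signal.samples, fs)
    window = max(1, int(FOOT_SEARCH_S * fs))
    raw_feet = []
    offsets = []
    for p in peaks:
        lo = max(0, p - window)
        if p <= lo:
            continue
        foot = lo + int(np.argmin(smooth[lo:p + 1]))
        raw_feet.append((p, foot))
        offsets.append(p - foot)
    if not raw_feet:
        return np.array([], dtype=int)
    # beats in one train share their morphology, so the upslope-to-foot
    # offset is common: the per-beat argmin (noisy in the flat diastolic
    # valley) is replaced by the median offset from each upslope peak,
    # refined on a lightly smoothed copy around the consensus position
    med = int(round(float(np.median(offsets))))
    light = _smoothed(signal.samples, fs, window_s=0.02)
    refined = []
    halo = max(2, int(0.02 * fs))
    for p, _ in raw_feet:
        guess = p - med
        lo = max(0, guess - halo)
        hi = min(len(light) - 1, guess + halo)
        if hi <= lo:
            continue
        refined.append(p - (lo + int(np.argmin(light[lo:hi + 1]))))
    med2 = int(round(float(np.median(refined)))) if refined else med
    # final per-beat touch-up: the valley argmin in a tight neighborhood of
    # the consensus position absorbs upslope-peak jitter without letting a
    # flat diastole drag the estimate away
    feet = []
    tight = max(2, int(0.012 * fs))
    for p, _ in raw_feet:
        guess = max(0, p - med2)
        lo = max(0, guess - tight)
        hi = min(len(light) - 1, guess + tight)
        foot = lo + int(np.argmin(light[lo:hi + 1])) if hi > lo else guess
        if not feet or foot > feet[-1]:
            feet.append(foot)
    return np.asarray(feet, dtype=int)


def ensemble_average(
    beats: list[np.ndarray],
    dt: float,
    window_s: float = 15.0,
) -> PulseWave:
    """Average length-aligned consecutive beats into one normalized beat.

    Beats are linearly resampled onto the median beat length, averaged
    pointwise over at most ``window_s`` seconds of data, and the result is
    min-max normalized.  The output period equals the median beat duration.
    """
    if len(beats) == 0:
        raise ValueError("no beats to average")
    # keep beats fitting in the averaging window (in acquisition order)
    kept: list[np.ndarray] = []
    total = 0.0
    for b in beats:
        total += (len(b) - 1) * dt
        kept.append(np.asarray(b, dtype=float))
        if total >= window_s:
            break
    lengths = np.array([len(b) for b in kept])
    n_target = int(np.median(lengths))
    grid = np.linspace(0.0, 1.0, n_target)
    resampled = np.stack(
        [np.interp(grid, np.linspace(0.0, 1.0, len(b)), b) for b in kept]
    )
    return normalize_pulse(resampled.mean(axis=0), dt)


def derivatives(
    pulse: PulseWave,
    smoothing_window_s: float = 0.05,
    poly_order: int = 3,
) -> DerivativePair:
    """Smoothed polynomial-filter first and second derivatives of a beat.

    The beat is smoothed with a Savitzky-Golay polynomial filter (default
    50 ms window, order 3 — the second-derivative fiducials are noise
    sensitive), then differentiated by central differences; d2 is the
    derivative of d1 under the same scheme.
    """
    n = len(pulse.samples)
    win = int(round(smoothing_window_s / pulse.dt))
    if win % 2 == 0:
        win += 1
    win = max(win, poly_order + 1 + ((poly_order + 1) % 2 == 0))
    if win % 2 == 0:
        win += 1
    if win >= n:
        raise ValueError(
            f"smoothing window ({win} samples) must be smaller than the beat ({n})"
        )
    smooth = savgol_filter(pulse.samples, win, poly_order)
    d1 = np.gradient(smooth, pulse.dt)
    d2 = np.gradient(d1, pulse.dt)
    return DerivativePair(d1=d1, d2=d2, dt=pulse.dt)


def read_waveform_csv(path) -> dict[str, RawSignal]:
    """Read delimited-text waveforms into :class:`RawSignal` objects.

    Expected columns: ``amplitude`` (required), ``t_seconds`` (optional,
    used to infer the sampling rate), ``participant_id`` (optional; long
    format with several participants per file).  Returns a mapping from
    participant id (``"0"`` when absent) to signal.
    """
    df = pd.read_csv(path)
    if "amplitude" not in df.columns:
        raise ValueError("waveform file must have an 'amplitude' column")
    out: dict[str, RawSignal] = {}
    groups = (
        df.groupby("participant_id", sort=False)
        if "participant_id" in df.columns
        else [("0", df)]
    )
    for pid, g in groups:
        if "t_seconds" in g.columns:
            dts = np.diff(np.asarray(g["t_seconds"], dtype=float))
            if len(dts) == 0 or not np.allclose(dts, dts[0], rtol=1e-6):
                raise ValueError(f"non-uniform t_seconds for participant {pid}")
            fs = 1.0 / dts[0]
        else:
            raise ValueError(
                "waveform file needs a 't_seconds' column to infer the sampling rate"
            )
        out[str(pid)] = RawSignal(np.asarray(g["amplitude"], dtype=float), fs)
    return out
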