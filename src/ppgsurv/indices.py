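"""Computation of the 20 morphological indices from a beat and its landmarks.

Timing indices (s): T, DT, CT, t_systole, t_bc, t_bd.  Amplitudes:
dia_amp (unitless), ms (1/s), a-e (1/s^2).  Areas (s, of the unit-normalized
waveform): A1, A2.  Composites: AGI_mod, slope_bc, slope_bd (1/s), IPAD,
and the diastolic stiffness decay constant k (1/s).

Indices whose inputs are unavailable (missing waves, undetectable notch)
come out as NaN and are flagged; a batch run never aborts on a degenerate
beat.  Heart rate and the height-calibrated stiffness index are
deliberately not part of the emitted set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.optimize import curve_fit

from ppgsurv.fiducials import FiducialSet, detect_fiducials
from ppgsurv.waveform_core import PulseWave, derivatives

__all__ = [
    "IndexVector",
    "INDEX_NAMES",
    "compute_areas",
    "compute_timing",
    "compute_sdppg_indices",
    "compute_ipad",
    "compute_stiffness_k",
    "extract_all",
    "extract_batch",
]

INDEX_NAMES = [
    "T", "DT", "CT", "t_systole", "t_bc", "t_bd", "dia_amp", "A1", "A2",
    "ms", "a", "b", "c", "d", "e", "AGI_mod", "slope_bc", "slope_bd",
    "IPAD", "k",
]


@dataclass
class IndexVector:
    """The 20 emitted indices for one participant (NaN = undefined)."""

    T: float = math.nan
    DT: float = math.nan
    CT: float = math.nan
    t_systole: float = math.nan
    t_bc: float = math.nan
    t_bd: float = math.nan
    dia_amp: float = math.nan
    A1: float = math.nan
    A2: float = math.nan
    ms: float = math.nan
    a: float = math.nan
    b: float = math.nan
    c: float = math.nan
    d: float = math.nan
    e: float = math.nan
    AGI_mod: float = math.nan
    slope_bc: float = math.nan
    slope_bd: float = math.nan
    IPAD: float = math.nan
    k: float = math.nan
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "flags"}
        out["flags"] = ";".join(f"{k}={v}" for k, v in self.flags.items())
        return out


def _idx(t: float, dt: float) -> int:
    return int(round(t / dt))


def compute_areas(pulse: PulseWave, fp: FiducialSet) -> tuple[float, float]:
    """Trapezoidal systolic (foot-to-notch) and diastolic (notch-to-end) areas.

    Returns (NaN, NaN) when the notch is missing with no fallback.
    """
    if not np.isfinite(fp.t_notch):
        return math.nan, math.nan
    i_notch = _idx(fp.t_notch, pulse.dt)
    t = pulse.t
    x = pulse.samples
    A1 = float(np.trapezoid(x[: i_notch + 1], t[: i_notch + 1]))
    A2 = float(np.trapezoid(x[i_notch:], t[i_notch:]))
    return A1, A2


def compute_timing(fp: FiducialSet) -> dict[str, float]:
    """Timing indices: T, CT, t_systole, DT, t_bc, t_bd (seconds)."""
    t_b, _ = fp.wave("b")
    t_c, _ = fp.wave("c")
    t_d, _ = fp.wave("d")
    return {
        "T": fp.t_end,
        "CT": fp.t_sys,
        "t_systole": fp.t_notch,
        "DT": fp.t_dia - fp.t_sys,
        "t_bc": t_c - t_b,
        "t_bd": t_d - t_b,
    }


def compute_sdppg_indices(fp: FiducialSet) -> dict[str, float]:
    """Second-derivative wave amplitudes and their composites.

    ``slope_bc = (c - b) / ((t_c - t_b) * a)``, analogously ``slope_bd``;
    ``AGI_mod = (b - c - d) / a``.  All NaN when the a wave is missing or
    has zero amplitude.
    """
    t_a, a = fp.wave("a")
    t_b, b = fp.wave("b")
    t_c, c = fp.wave("c")
    t_d, d = fp.wave("d")
    _, e = fp.wave("e")
    out = {"a": a, "b": b, "c": c, "d": d, "e": e}
    if not np.isfinite(a) or a == 0:
        out.update(AGI_mod=math.nan, slope_bc=math.nan, slope_bd=math.nan,
                   d_over_a=math.nan)
        return out
    out["AGI_mod"] = (b - c - d) / a
    out["slope_bc"] = (c - b) / ((t_c - t_b) * a) if np.isfinite(t_c) else math.nan
    out["slope_bd"] = (d - b) / ((t_d - t_b) * a) if np.isfinite(t_d) else math.nan
    out["d_over_a"] = d / a
    return out


def compute_ipad(A1: float, A2: float, amp_a: float, amp_d: float) -> float:
    """IPAD = A2/A1 + d/a; NaN when A1 is zero/undefined or a is zero."""
    if not np.isfinite(A1) or A1 == 0 or not np.isfinite(amp_a) or amp_a == 0:
        return math.nan
    if not (np.isfinite(A2) and np.isfinite(amp_d)):
        return math.nan
    return A2 / A1 + amp_d / amp_a


def compute_stiffness_k(
    pulse: PulseWave,
    fp: FiducialSet,
    min_samples: int = 5,
) -> float:
    """Diastolic decay constant: rate of ``A * exp(-k (t - t_dia)) + offset``.

    Least-squares fit over the diastolic tail [t_dia, t_end] with the
    offset pinned at the final sample.  A flat tail gives k = 0; fewer
    than ``min_samples`` samples gives NaN.  This default definition is a
    strategy and can be substituted by callers needing another convention.
    """
    if not np.isfinite(fp.t_dia):
        return math.nan
    i0 = _idx(fp.t_dia, pulse.dt)
    y = pulse.samples[i0:]
    if len(y) < min_samples:
        return math.nan
    t = np.arange(len(y)) * pulse.dt
    offset = y[-1]
    z = y - offset
    zmax = z.max()
    if zmax <= 1e-12 or np.ptp(y) <= 1e-12:
        return 0.0
    # log-linear initial estimate on the clearly-positive part of the tail
    mask = z > 0.05 * zmax
    if mask.sum() >= 2:
        k0 = max(0.0, -float(np.polyfit(t[mask], np.log(z[mask]), 1)[0]))
    else:
        k0 = 1.0
    try:
        popt, _ = curve_fit(
            lambda tt, A, k: A * np.exp(-k * tt) + offset,
            t, y, p0=[zmax, max(k0, 1e-3)], maxfev=5000,
        )
        return float(max(popt[1], 0.0))
    except RuntimeError:
        return float(k0)


def extract_all(
    pulse: PulseWave,
    smoothing_window_s: float = 0.05,
    poly_order: int = 3,
) -> IndexVector:
    """Full chain: derivatives -> fiducials -> all 20 indices for one beat.

    Upstream failures degrade individual indices to NaN with flags; the
    call itself never raises on a degenerate but validly-typed beat.
    """
    deriv = derivatives(pulse, smoothing_window_s, poly_order)
    fp = detect_fiducials(pulse, deriv)
    iv = IndexVector()
    iv.flags = dict(fp.flags)

    timing = compute_timing(fp)
    for name in ("T", "CT", "t_systole", "DT", "t_bc", "t_bd"):
        setattr(iv, name, timing[name])
    iv.dia_amp = fp.amp_dia
    iv.ms = fp.amp_ms
    iv.A1, iv.A2 = compute_areas(pulse, fp)
    sd = compute_sdppg_indices(fp)
    for name in ("a", "b", "c", "d", "e", "AGI_mod", "slope_bc", "slope_bd"):
        setattr(iv, name, sd[name])
    iv.IPAD = compute_ipad(iv.A1, iv.A2, sd["a"], sd["d"])
    iv.k = compute_stiffness_k(pulse, fp)
    return iv


def extract_batch(pulses, **kwargs):
    """Extract indices for a sequence of (id, PulseWave) pairs.

    Returns a pandas DataFrame with one row per input beat, the 20 index
    columns and a ``flags`` column; rows for degenerate beats carry NaNs
    and flags instead of aborting the batch.
    """
    import pandas as pd

    rows = []
    for pid, pulse in pulses:
        try:
            iv = extract_all(pulse, **kwargs)
            row = iv.to_dict()
        except Exception as exc:  # degenerate input: keep the row, flag it
            row = {name: math.nan for name in INDEX_NAMES}
            row["flags"] = f"error={type(exc).__name__}"
        row["participant_id"] = pid
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["participant_id", *INDEX_NAMES, "flags"]]
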