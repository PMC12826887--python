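"""Synthetic PPG beats, beat trains and survival cohorts with known truth.

The beat model is a sum of four Gaussian lobes (systolic, reflected,
mid-late-systolic, diastolic) under a smooth exponential decay envelope:

``f(t) = [sum_i A_i exp(-(t - mu_i)^2 / (2 s_i^2))] * exp(-decay * t)``

All derivatives of ``f`` are closed-form, so every fiducial point and area
has an analytic/quadrature ground truth computed on the *continuous*
function — independent of any sampling grid the pipeline later uses.

Survival cohorts follow a Weibull proportional-hazards model with
standardized covariate and index effects, sampled by inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from ppgsurv.waveform_core import PulseWave, RawSignal

__all__ = [
    "BeatParams",
    "BeatTruth",
    "CohortSpec",
    "canonical_beat_params",
    "beat_function",
    "generate_beat",
    "generate_beat_train",
    "simulate_cohort",
    "PPG_INDEX_NAMES",
    "COVARIATE_NAMES",
]

#: the 20 emitted morphology indices, in canonical order
PPG_INDEX_NAMES = [
    "T", "DT", "CT", "t_systole", "t_bc", "t_bd", "dia_amp", "A1", "A2",
    "ms", "a", "b", "c", "d", "e", "AGI_mod", "slope_bc", "slope_bd",
    "IPAD", "k",
]

COVARIATE_NAMES = [
    "age", "sex", "ethnicity", "bmi", "smoking", "diabetes", "tchdl",
    "sbp", "bp_med",
]


@dataclass(frozen=True)
class BeatParams:
    """Four-lobe Gaussian beat model parameters.

    ``amplitudes``, ``centers`` (s) and ``widths`` (s) describe the
    systolic, reflected, mid-late-systolic and diastolic lobes in order;
    ``decay`` (1/s) is the global decay-envelope rate and ``period`` (s)
    the beat duration.
    """

    amplitudes: tuple[float, float, float, float]
    centers: tuple[float, float, float, float]
    widths: tuple[float, float, float, float]
    decay: float = 1.5
    period: float = 0.8

    def __post_init__(self) -> None:
        if len(self.amplitudes) != 4 or len(self.centers) != 4 or len(self.widths) != 4:
            raise ValueError("exactly 4 Gaussian components are required")
        if not all(np.diff(self.centers) > 0):
            raise ValueError("component centers must be strictly increasing")
        if not all(w > 0 for w in self.widths):
            raise ValueError("component widths must be positive")
        if self.period <= 0:
            raise ValueError("period must be positive")


def canonical_beat_params(
    morph_c: float = 1.0,
    decay: float = 1.0,
    period: float = 0.68,
) -> BeatParams:
    """Default beat exhibiting all fiducials of a healthy young contour.

    ``morph_c`` scales the mid-late-systolic lobe: raising it increases
    the curvature of the mid-late systolic portion of the pulse (and the
    c-wave amplitude of the second derivative); lowering it does the
    opposite.
    """
    return BeatParams(
        amplitudes=(1.0, 0.42, 0.20 * morph_c, 0.40),
        centers=(0.13, 0.24, 0.315, 0.52),
        widths=(0.046, 0.07, 0.05, 0.105),
        decay=decay,
        period=period,
    )


def beat_function(params: BeatParams, t, order: int = 0):
    """Evaluate the continuous beat model or one of its derivatives.

    ``order`` in {0, 1, 2, 3}: the function itself, or its first, second
    or third time derivative (closed form).
    """
    t = np.asarray(t, dtype=float)
    S0 = np.zeros_like(t)
    S1 = np.zeros_like(t)
    S2 = np.zeros_like(t)
    S3 = np.zeros_like(t)
    for A, mu, sig in zip(params.amplitudes, params.centers, params.widths):
        u = (t - mu) / sig**2
        g = A * np.exp(-((t - mu) ** 2) / (2 * sig**2))
        S0 += g
        S1 += -u * g
        S2 += (u * u - 1.0 / sig**2) * g
        S3 += (3.0 * u / sig**2 - u**3) * g
    lam = params.decay
    E = np.exp(-lam * t)
    if order == 0:
        return S0 * E
    if order == 1:
        return (S1 - lam * S0) * E
    if order == 2:
        return (S2 - 2 * lam * S1 + lam**2 * S0) * E
    if order == 3:
        return (S3 - 3 * lam * S2 + 3 * lam**2 * S1 - lam**3 * S0) * E
    raise ValueError("order must be 0..3")


def _roots_of(params: BeatParams, order: int, lo: float, hi: float,
              n_grid: int = 20001) -> list[float]:
    """Roots of the order-th derivative on (lo, hi) by bracketing + brentq."""
    tt = np.linspace(lo, hi, n_grid)
    vv = beat_function(params, tt, order)
    roots = []
    sign = np.sign(vv)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        r = brentq(lambda x: float(beat_function(params, x, order)),
                   tt[i], tt[i + 1], xtol=1e-12)
        roots.append(float(r))
    return roots


@dataclass
class BeatTruth:
    """Analytic ground truth for one generated beat (normalized units).

    Times in seconds from the beat foot; amplitudes on the normalized
    waveform and its continuous derivatives.  Fields are ``None`` when the
    corresponding landmark does not exist for the parameter set.
    """

    t_end: float
    t_sys: float
    amp_sys: float
    t_notch: float | None
    amp_notch: float | None
    t_dia: float | None
    amp_dia: float | None
    t_ms: float
    amp_ms: float
    wave_times: dict[str, float]        # keys among "a".."e"
    wave_amps: dict[str, float]
    A1: float | None
    A2: float | None
    norm_offset: float                  # continuous min of the raw beat
    norm_scale: float                   # continuous max - min


def _beat_truth(params: BeatParams, t_end: float) -> BeatTruth:
    eps = 1e-6
    crit = _roots_of(params, 1, eps, t_end - eps)
    cand = [0.0, t_end] + crit
    vals = beat_function(params, np.array(cand), 0)
    m, M = float(vals.min()), float(vals.max())
    scale = M - m
    t_sys = float(cand[int(np.argmax(vals))])

    def fn(t, order=0):
        v = beat_function(params, t, order)
        return (v - m) / scale if order == 0 else v / scale

    # local minima / maxima of f after the systolic peak; like the
    # detector, a minimum only counts as the dicrotic notch when it is
    # prominent (>= 1% amplitude relative to the flanking maxima), so tiny
    # systolic ripples are not mislabeled
    post = [r for r in crit if r > t_sys + eps]
    t_notch = t_dia = None
    for i, r in enumerate(post):
        curv = beat_function(params, r, 2)
        if t_notch is None and curv > 0:
            left_vals = [beat_function(params, q, 0) for q in [t_sys] + post[:i]]
            right = post[i + 1:] + [t_end]
            right_vals = [beat_function(params, q, 0) for q in right]
            v = beat_function(params, r, 0)
            prom = (min(max(left_vals), max(right_vals)) - v) / scale
            if prom >= 0.01:
                t_notch = r
        elif t_notch is not None and curv < 0:
            t_dia = r
            break
    # ms: maximum of f' on [0, t_sys]
    d1_crit = [r for r in _roots_of(params, 2, eps, t_sys) ]
    cand_ms = d1_crit + [eps, t_sys]
    ms_vals = beat_function(params, np.array(cand_ms), 1)
    t_ms = float(cand_ms[int(np.argmax(ms_vals))])

    # a..e: alternating extrema of f'' from the foot onward
    d2_crit = _roots_of(params, 3, eps, t_end - eps)
    waves_t: dict[str, float] = {}
    waves_a: dict[str, float] = {}
    labels = iter("abcde")
    expecting_max = True
    for r in d2_crit:
        slope = beat_function(params, r, 3)
        before = beat_function(params, r - 1e-5, 3)
        is_max = before > 0
        if is_max != expecting_max:
            continue
        try:
            lab = next(labels)
        except StopIteration:
            break
        waves_t[lab] = r
        waves_a[lab] = float(fn(r, 2))
        expecting_max = not expecting_max

    A1 = A2 = None
    if t_notch is not None:
        A1 = quad(lambda x: fn(x), 0.0, t_notch, limit=200, epsabs=1e-12)[0]
        A2 = quad(lambda x: fn(x), t_notch, t_end, limit=200, epsabs=1e-12)[0]

    return BeatTruth(
        t_end=t_end,
        t_sys=t_sys,
        amp_sys=float(fn(t_sys)),
        t_notch=t_notch,
        amp_notch=None if t_notch is None else float(fn(t_notch)),
        t_dia=t_dia,
        amp_dia=None if t_dia is None else float(fn(t_dia)),
        t_ms=t_ms,
        amp_ms=float(fn(t_ms, 1)),
        wave_times=waves_t,
        wave_amps=waves_a,
        A1=A1,
        A2=A2,
        norm_offset=m,
        norm_scale=scale,
    )


def generate_beat(
    params: BeatParams,
    sampling_rate: float = 250.0,
) -> tuple[PulseWave, BeatTruth]:
    """Sample one beat on a uniform grid and compute its analytic truth.

    The truth record is derived from the continuous model (root finding on
    closed-form derivatives; adaptive quadrature for areas), never from the
    returned sample grid.
    """
    dt = 1.0 / sampling_rate
    n = int(round(params.period * sampling_rate)) + 1
    t = np.arange(n) * dt
    raw = beat_function(params, t, 0)
    lo, hi = raw.min(), raw.max()
    pulse = PulseWave((raw - lo) / (hi - lo), dt)
    truth = _beat_truth(params, t_end=float(t[-1]))
    return pulse, truth


def generate_beat_train(
    params: BeatParams,
    n_beats: int,
    noise_sd: float = 0.0,
    period_jitter_sd: float = 0.0,
    seed: int | None = None,
    sampling_rate: float = 250.0,
) -> tuple[RawSignal, dict]:
    """Concatenate jittered copies of a beat with additive Gaussian noise.

    Returns the raw signal and a truth dict with the generated foot sample
    indices and per-beat periods.  Deterministic under ``seed``.
    """
    if n_beats < 3:
        raise ValueError("need at least 3 beats")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    pieces = []
    foot_indices = [0]
    periods = []
    for _ in range(n_beats):
        period = params.period * (1.0 + period_jitter_sd * rng.standard_normal())
        period = max(period, 0.35)
        n = int(round(period * sampling_rate))
        # time-scale the canonical beat onto the jittered period (exclusive
        # of the endpoint so beats tile without duplicated feet)
        tt = np.arange(n) * dt * (params.period / period)
        pieces.append(beat_function(params, tt, 0))
        periods.append(n * dt)
        foot_indices.append(foot_indices[-1] + n)
    samples = np.concatenate(pieces)
    if noise_sd > 0:
        samples = samples + noise_sd * rng.standard_normal(len(samples))
    truth = {
        "foot_indices": np.array(foot_indices[:-1], dtype=int),
        "periods_s": np.array(periods),
        "seed": seed,
    }
    return RawSignal(samples, sampling_rate), truth


# ---------------------------------------------------------------------------
# survival cohort simulation
# ---------------------------------------------------------------------------

#: default per-SD log-hazard coefficients; index defaults target the
#: effect sizes the recovery tests aim to re-estimate
DEFAULT_BETA = {
    "age": 0.60,
    "sex": 0.25,
    "sbp": 0.20,
    "smoking": 0.25,
    "diabetes": 0.20,
    "t_systole": float(np.log(1.43)),
    "A1": float(np.log(0.79)),
    "c": float(np.log(0.80)),
}

#: marginal covariate distributions (means/SDs or prevalences)
DEFAULT_COVARIATES = {
    "age": ("normal", 57.0, 8.0),
    "sex": ("bernoulli", 0.48),        # 1 = male
    "ethnicity": ("bernoulli", 0.06),  # 1 = non-white
    "bmi": ("normal", 27.3, 4.7),
    "smoking": ("bernoulli", 0.10),
    "diabetes": ("bernoulli", 0.05),
    "tchdl": ("normal", 4.0, 1.1),
    "sbp": ("normal", 138.0, 18.0),
    "bp_med": ("bernoulli", 0.20),
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic survival cohort."""

    n: int
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    age_index_corr: float = 0.3
    index_resid_corr: float = 0.0
    weibull_shape: float = 1.2
    weibull_scale: float = 25.0
    censor_years: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.weibull_shape <= 0:
            raise ValueError("Weibull shape must be positive")
        for k, v in self.beta.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient for {k}")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort with covariates, index values and survival outcomes.

    Index values are standardized latent scores correlated with age
    (``age_index_corr``) and optionally with each other
    (``index_resid_corr``).  Event times come from a Weibull
    proportional-hazards model ``S(t|x) = exp(-(t/scale)^shape * e^eta)``
    by inverse transform, censored administratively at ``censor_years``.
    The true coefficients are attached in ``df.attrs["true_beta"]``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    df = pd.DataFrame({"participant_id": np.arange(n)})
    z: dict[str, np.ndarray] = {}
    for name, dist in spec.covariates.items():
        if dist[0] == "normal":
            _, mean, sd = dist
            raw = mean + sd * rng.standard_normal(n)
            df[name] = raw
            z[name] = (raw - raw.mean()) / raw.std(ddof=0)
        elif dist[0] == "bernoulli":
            _, p = dist
            raw = (rng.random(n) < p).astype(float)
            df[name] = raw
            sd = raw.std(ddof=0)
            z[name] = (raw - raw.mean()) / sd if sd > 0 else raw * 0.0
        else:
            raise ValueError(f"unknown distribution {dist[0]!r}")

    # correlated index block: common age factor plus (optionally) a shared
    # residual factor among indices
    r = spec.age_index_corr
    rho = spec.index_resid_corr
    if not (0 <= rho < 1) or not (-1 < r < 1):
        raise ValueError("correlations out of range: need |r| < 1, rho in [0, 1)")
    resid_var = 1.0 - r**2
    shared = rng.standard_normal(n)
    for name in PPG_INDEX_NAMES:
        eps = (np.sqrt(rho) * shared
               + np.sqrt(1.0 - rho) * rng.standard_normal(n))
        df[name] = r * z["age"] + np.sqrt(resid_var) * eps
        z[name] = np.asarray(df[name])

    eta = np.zeros(n)
    for name, b in spec.beta.items():
        if name not in z:
            raise KeyError(f"coefficient for unknown feature {name!r}")
        zz = z[name]
        sd = zz.std(ddof=0)
        eta += b * (zz - zz.mean()) / sd if sd > 0 else 0.0

    u = rng.uniform(size=n)
    t_event = spec.weibull_scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / spec.weibull_shape)
    time = np.minimum(t_event, spec.censor_years)
    event = (t_event <= spec.censor_years).astype(int)
    df["time_years"] = time
    df["event"] = event
    df.attrs["true_beta"] = dict(spec.beta)
    df.attrs["seed"] = spec.seed
    return df
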