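"""Concordance-based incremental-prediction evaluation.

Harrell's C over usable pairs, percentile-bootstrap confidence intervals,
paired-bootstrap Z-tests for the change in C when variables are added,
the fixed nested model ladder, and age-stratified comparisons of
classical-risk-factor models with and without the waveform indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ppgsurv.survival import fit_adjusted_cox
from ppgsurv.synthetic_data import PPG_INDEX_NAMES

__all__ = [
    "ConcordanceResult",
    "LadderRow",
    "concordance",
    "bootstrap_ci",
    "delta_c_test",
    "model_ladder",
    "age_stratified_eval",
    "LADDER_STEPS",
]

#: fixed nested-model order: variable added at each step
LADDER_STEPS = [
    ("age", ["age"]),
    ("+ sex", ["sex"]),
    ("+ ethnicity", ["ethnicity"]),
    ("+ BMI", ["bmi"]),
    ("+ smoking", ["smoking"]),
    ("+ diabetes", ["diabetes"]),
    ("+ TC/HDL", ["tchdl"]),
    ("+ BP medication", ["bp_med"]),
    ("+ SBP", ["sbp"]),
    ("+ PPG indices", list(PPG_INDEX_NAMES)),
]

AGE_STRATA = [("age<50", -np.inf, 50.0), ("50<=age<65", 50.0, 65.0),
              ("age>=65", 65.0, np.inf)]


@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_pairs: int = 0
    n_boot: int = 0


@dataclass
class LadderRow:
    label: str
    added: list[str]
    c: float
    ci_low: float
    ci_high: float
    delta_c: float = np.nan
    delta_ci_low: float = np.nan
    delta_ci_high: float = np.nan
    p: float = np.nan


def _pair_counts(time, event, risk, chunk: int = 2048) -> tuple[float, int]:
    """(concordance weight, usable pairs) over ordered pairs (i earlier)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    r = np.asarray(risk, dtype=float)
    n = len(t)
    weight = 0.0
    pairs = 0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        ti = t[lo:hi, None]
        ei = e[lo:hi, None]
        ri = r[lo:hi, None]
        usable = (ti < t[None, :]) & ei
        usable |= (ti == t[None, :]) & ei & ~e[None, :]
        conc = usable & (ri > r[None, :])
        tied = usable & (ri == r[None, :])
        weight += conc.sum() + 0.5 * tied.sum()
        pairs += int(usable.sum())
    return weight, pairs


def concordance(time, event, risk) -> ConcordanceResult:
    """Harrell's C of risk scores against right-censored outcomes.

    A pair is usable when the member with the shorter time has the event
    (or, at tied times, exactly the earlier-event member does); it is
    concordant when that member has the higher risk score, and tied risk
    scores count one half.  Equals Somers' Dxy / 2 + 0.5.

    Raises
    ------
    ValueError
        If no usable pairs exist.
    """
    weight, pairs = _pair_counts(time, event, risk)
    if pairs == 0:
        raise ValueError("no usable pairs: cannot compute concordance")
    return ConcordanceResult(c=weight / pairs, n_pairs=pairs)


def bootstrap_ci(
    time,
    event,
    risk=None,
    B: int = 1000,
    seed: int | None = None,
    risk_fn=None,
    df: pd.DataFrame | None = None,
) -> ConcordanceResult:
    """Percentile-bootstrap CI for C by participant-level resampling.

    Pass precomputed ``risk`` scores, or a ``risk_fn(df_resampled)`` with
    the cohort ``df`` to refit/rescore each resample.  Resamples with no
    events are redrawn (and counted in ``meta``); B = 1 degenerates the
    CI to a point.
    """
    if B < 1:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    if risk is None and risk_fn is None:
        raise ValueError("either risk or risk_fn is required")
    base_risk = np.asarray(risk, dtype=float) if risk is not None else risk_fn(df)
    point = concordance(t, e, base_risk).c
    n = len(t)
    cs = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            if e[idx].sum() > 0:
                break
            redraws += 1
        rb = base_risk[idx] if risk_fn is None else risk_fn(df.iloc[idx])
        cs[b] = concordance(t[idx], e[idx], rb).c
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return ConcordanceResult(c=point, ci_low=float(lo), ci_high=float(hi),
                             n_pairs=concordance(t, e, base_risk).n_pairs,
                             n_boot=B)


def delta_c_test(
    time,
    event,
    risk_a,
    risk_b,
    B: int = 1000,
    seed: int | None = None,
) -> dict:
    """Paired bootstrap Z-test for the difference in C of two risk scores.

    ΔC = C(b) - C(a) on the same rows; the bootstrap resamples
    participants jointly, the Z statistic is ΔC over the bootstrap SE and
    the two-sided p comes from the normal reference.  Identical scores
    short-circuit to ΔC = 0, p = 1.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    ra = np.asarray(risk_a, dtype=float)
    rb = np.asarray(risk_b, dtype=float)
    if np.array_equal(ra, rb):
        return {"delta_c": 0.0, "ci_low": 0.0, "ci_high": 0.0, "p": 1.0, "z": 0.0}
    delta = concordance(t, e, rb).c - concordance(t, e, ra).c
    rng = np.random.default_rng(seed)
    n = len(t)
    deltas = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            if e[idx].sum() > 0:
                break
        deltas[b] = (concordance(t[idx], e[idx], rb[idx]).c
                     - concordance(t[idx], e[idx], ra[idx]).c)
    se = deltas.std(ddof=1)
    if se == 0:
        z, p = 0.0, 1.0
    else:
        z = delta / se
        p = 2.0 * stats.norm.sf(abs(z))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return {"delta_c": float(delta), "ci_low": float(lo), "ci_high": float(hi),
            "p": float(p), "z": float(z), "se": float(se)}


def _split(df: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(df))
    n_test = int(round(0.2 * len(df)))
    test = df.iloc[np.sort(perm[:n_test])].reset_index(drop=True)
    train = df.iloc[np.sort(perm[n_test:])].reset_index(drop=True)
    return train, test


def model_ladder(
    cohort: pd.DataFrame,
    steps=None,
    B: int = 1000,
    seed: int = 0,
    time_col: str = "time_years",
    event_col: str = "event",
    holdout: bool = True,
) -> list[LadderRow]:
    """Fit the nested model ladder and evaluate C at every rung.

    Models are fit on the 80% training part; C, its bootstrap CI and the
    paired ΔC test against the previous rung are computed on the held-out
    20% (or in-sample when ``holdout=False``).  Raises ``KeyError`` naming
    the first missing ladder variable.
    """
    steps = steps or LADDER_STEPS
    needed = [v for _, vs in steps for v in vs]
    for v in needed:
        if v not in cohort.columns:
            raise KeyError(f"ladder variable {v!r} missing from cohort")
    train, test = _split(cohort, seed)
    eval_df = test if holdout else train
    t = eval_df[time_col].to_numpy()
    e = eval_df[event_col].to_numpy()
    rows: list[LadderRow] = []
    variables: list[str] = []
    prev_risk = None
    for label, added in steps:
        variables = variables + [v for v in added if v not in variables]
        fit = fit_adjusted_cox(
            train, variables, adjustment_set=[],
            time_col=time_col, event_col=event_col,
        )
        risk = fit.linear_predictor(eval_df)
        res = bootstrap_ci(t, e, risk, B=B, seed=seed + 17)
        row = LadderRow(label=label, added=list(added), c=res.c,
                        ci_low=res.ci_low, ci_high=res.ci_high)
        if prev_risk is not None:
            d = delta_c_test(t, e, prev_risk, risk, B=B, seed=seed + 31)
            row.delta_c = d["delta_c"]
            row.delta_ci_low = d["ci_low"]
            row.delta_ci_high = d["ci_high"]
            row.p = d["p"]
        rows.append(row)
        prev_risk = risk
    return rows


def ladder_frame(rows: list[LadderRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.label for r in rows],
            "C": [r.c for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "delta_c_x100": [100 * r.delta_c for r in rows],
            "p": [r.p for r in rows],
        }
    )


def age_stratified_eval(
    cohort: pd.DataFrame,
    crf: list[str] | None = None,
    indices: list[str] | None = None,
    B: int = 500,
    seed: int = 0,
    time_col: str = "time_years",
    event_col: str = "event",
) -> pd.DataFrame:
    """Compare risk-factor-only vs risk-factor + index models per age stratum.

    Strata: age < 50, 50-64, >= 65; each row reports the two C statistics
    and the paired ΔC test on the stratum's held-out split.  Empty strata
    are flagged rather than fatal.
    """
    crf = crf or ["age", "sex", "ethnicity", "bmi", "smoking", "diabetes",
                  "tchdl", "bp_med", "sbp"]
    indices = indices or list(PPG_INDEX_NAMES)
    rows = []
    for label, lo, hi in AGE_STRATA:
        sub = cohort[(cohort["age"] >= lo) & (cohort["age"] < hi)]
        if len(sub) < 50 or sub[event_col].sum() < 5:
            rows.append({"stratum": label, "n": len(sub), "flag": "empty_or_sparse"})
            continue
        sub = sub.reset_index(drop=True)
        train, test = _split(sub, seed)
        t = test[time_col].to_numpy()
        e = test[event_col].to_numpy()
        crf_strat = [c for c in crf if c != "age" or sub["age"].nunique() > 1]
        fit_a = fit_adjusted_cox(train, crf_strat, adjustment_set=[],
                                 time_col=time_col, event_col=event_col)
        fit_b = fit_adjusted_cox(train, crf_strat + indices, adjustment_set=[],
                                 time_col=time_col, event_col=event_col)
        risk_a = fit_a.linear_predictor(test)
        risk_b = fit_b.linear_predictor(test)
        ca = bootstrap_ci(t, e, risk_a, B=B, seed=seed + 7)
        cb = bootstrap_ci(t, e, risk_b, B=B, seed=seed + 7)
        d = delta_c_test(t, e, risk_a, risk_b, B=B, seed=seed + 13)
        rows.append({
            "stratum": label, "n": len(sub), "flag": "",
            "c_crf": ca.c, "c_crf_ci_low": ca.ci_low, "c_crf_ci_high": ca.ci_high,
            "c_full": cb.c, "c_full_ci_low": cb.ci_low, "c_full_ci_high": cb.ci_high,
            "delta_c": d["delta_c"], "delta_ci_low": d["ci_low"],
            "delta_ci_high": d["ci_high"], "p": d["p"],
        })
    return pd.DataFrame(rows)
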