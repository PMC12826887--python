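"""Event classification, censoring rules and cohort-flow accounting.

Hospitalization and death records carry ICD-9/ICD-10 codes; the shipped
plain-text code lists map them onto outcome categories (CVD, CHD, MI,
heart failure, hypertension, stroke).  Outcomes are derived per
participant under first-event / administrative-censoring rules, and
exclusion stages are tracked in an auditable cohort-flow ledger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "EventRecord",
    "OutcomeRow",
    "CohortFlow",
    "load_icd_map",
    "expand_code_range",
    "classify_icd",
    "derive_outcome",
    "apply_exclusions",
    "PrevalentDiseaseError",
]

DAYS_PER_YEAR = 365.25
#: administrative horizon for incident-event follow-up (years)
EVENT_HORIZON_YEARS = 10.0

CATEGORIES = ("CVD", "CHD", "MI", "HF", "hypertension", "stroke")


class PrevalentDiseaseError(ValueError):
    """A qualifying event predates baseline: participant is prevalent."""


@dataclass(frozen=True)
class EventRecord:
    participant_id: str
    icd_version: int
    code: str
    date: date

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("empty ICD code")
        if self.icd_version not in (9, 10):
            raise ValueError(f"unknown ICD version {self.icd_version}")


@dataclass(frozen=True)
class OutcomeRow:
    participant_id: str
    category: str            # "cvd_event" | "cvd_death" | "all_cause_death"
    time_years: float
    event_indicator: int

    def __post_init__(self) -> None:
        if self.time_years < 0:
            raise ValueError("negative follow-up time")
        if self.event_indicator not in (0, 1):
            raise ValueError("event indicator must be 0/1")


@dataclass
class CohortFlow:
    """Ordered exclusion ledger: (stage label, removed, remaining)."""

    initial: int
    stages: list[tuple[str, int, int]]

    @property
    def final(self) -> int:
        return self.stages[-1][2] if self.stages else self.initial

    def to_json(self) -> str:
        return json.dumps(
            {
                "initial": self.initial,
                "stages": [
                    {"stage": s, "removed": r, "remaining": n}
                    for s, r, n in self.stages
                ],
            },
            indent=2,
        )


def expand_code_range(token: str) -> list[str]:
    """Expand a code-list token into match prefixes.

    ``"I21-25"`` and ``"I21-I23"`` expand to ``I21..I25`` / ``I21..I23``;
    ``"39-44"`` to ``39..44``; plain tokens pass through.
    """
    token = token.strip().replace("‐", "-").replace("–", "-")
    if "-" not in token:
        return [token]
    lo, hi = (p.strip() for p in token.split("-", 1))
    prefix = "".join(ch for ch in lo if ch.isalpha())
    lo_num = lo[len(prefix):]
    hi_num = hi[len(prefix):] if hi.startswith(prefix) and prefix else hi
    width = len(lo_num)
    return [f"{prefix}{i:0{width}d}" for i in range(int(lo_num), int(hi_num) + 1)]


def load_icd_map() -> dict[tuple[str, int], list[str]]:
    """Load the shipped code lists as {(category, icd_version): prefixes}."""
    text = (
        resources.files("ppgsurv").joinpath("data/icd_codes.tsv").read_text()
    )
    mapping: dict[tuple[str, int], list[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        category, version, codes = line.split("\t")
        prefixes = []
        for token in codes.split(","):
            prefixes.extend(expand_code_range(token))
        mapping[(category, int(version))] = prefixes
    return mapping


_ICD_MAP: dict[tuple[str, int], list[str]] | None = None


def _icd_map() -> dict[tuple[str, int], list[str]]:
    global _ICD_MAP
    if _ICD_MAP is None:
        _ICD_MAP = load_icd_map()
    return _ICD_MAP


def classify_icd(code: str, icd_version: int) -> set[str]:
    """Outcome categories matched by an ICD code (possibly several).

    Matching is by listed prefix after stripping dots; an MI code is by
    construction also CHD and CVD.  Returns the empty set for unlisted
    codes.
    """
    if icd_version not in (9, 10):
        raise ValueError(f"unknown ICD version {icd_version}")
    code = code.strip().replace(".", "").upper()
    cats = set()
    for (category, version), prefixes in _icd_map().items():
        if version != icd_version:
            continue
        if any(code.startswith(p) for p in prefixes):
            cats.add(category)
    return cats


def _years(later, earlier) -> float:
    return (pd.Timestamp(later) - pd.Timestamp(earlier)).days / DAYS_PER_YEAR


def derive_outcome(
    events: list[EventRecord],
    baseline_date,
    death_date=None,
    lost_date=None,
    death_codes: list[tuple[str, int]] | None = None,
    horizon_years: float = EVENT_HORIZON_YEARS,
    mortality_cutoff_date=None,
    participant_id: str = "",
) -> dict[str, OutcomeRow]:
    """Derive the three outcome rows for one participant.

    ``events`` are hospitalization records sorted by date; ``death_codes``
    are the (code, icd_version) causes of death.  Incident events are
    censored at ``min(death, lost, baseline + horizon_years)``; mortality
    follow-up runs to ``mortality_cutoff_date`` when given, otherwise to
    the same horizon.  Deaths from a CVD cause without prior qualifying
    hospitalization count for the death outcomes only.

    Raises
    ------
    PrevalentDiseaseError
        If any qualifying CVD event predates baseline.
    """
    baseline = pd.Timestamp(baseline_date)
    cvd_dates = []
    for ev in events:
        if "CVD" not in classify_icd(ev.code, ev.icd_version):
            continue
        if pd.Timestamp(ev.date) < baseline:
            raise PrevalentDiseaseError(
                f"CVD event {ev.code} predates baseline for {participant_id!r}"
            )
        cvd_dates.append(pd.Timestamp(ev.date))
    t_event = min((_years(d, baseline) for d in cvd_dates), default=np.inf)
    t_death = _years(death_date, baseline) if death_date is not None else np.inf
    t_lost = _years(lost_date, baseline) if lost_date is not None else np.inf

    # incident CVD events: 10-year administrative horizon
    t_cvd = min(t_event, t_death, t_lost, horizon_years)
    cvd_row = OutcomeRow(
        participant_id, "cvd_event", max(t_cvd, 0.0),
        int(np.isfinite(t_event) and t_event <= min(t_death, t_lost, horizon_years)),
    )

    # mortality: calendar cutoff when configured
    t_mort_end = (
        _years(mortality_cutoff_date, baseline)
        if mortality_cutoff_date is not None
        else horizon_years
    )
    died_in_window = np.isfinite(t_death) and t_death <= min(t_lost, t_mort_end)
    t_mort = min(t_death, t_lost, t_mort_end)
    death_is_cvd = False
    if death_codes and died_in_window:
        death_is_cvd = any(
            "CVD" in classify_icd(code, ver) for code, ver in death_codes
        )
    rows = {
        "cvd_event": cvd_row,
        "cvd_death": OutcomeRow(
            participant_id, "cvd_death", max(t_mort, 0.0), int(death_is_cvd)
        ),
        "all_cause_death": OutcomeRow(
            participant_id, "all_cause_death", max(t_mort, 0.0), int(died_in_window)
        ),
    }
    return rows


def apply_exclusions(source, stages=None, initial: int | None = None) -> CohortFlow:
    """Build a cohort-flow ledger from a table or from printed stage counts.

    Two call styles:

    * ``apply_exclusions(df, stages=[(label, bool_mask_column), ...])`` —
      participants matching a stage mask (and not already removed) are
      removed in order.
    * ``apply_exclusions([(label, removed_count), ...], initial=N)`` —
      reproduce a published flow from stage counts.
    """
    ledger: list[tuple[str, int, int]] = []
    if isinstance(source, pd.DataFrame):
        remaining_mask = np.ones(len(source), dtype=bool)
        start = len(source)
        for label, column in stages or []:
            mask = np.asarray(source[column], dtype=bool) & remaining_mask
            removed = int(mask.sum())
            remaining_mask &= ~mask
            ledger.append((label, removed, int(remaining_mask.sum())))
        return CohortFlow(initial=start, stages=ledger)
    if initial is None:
        raise ValueError("initial count required for count-based flows")
    remaining = initial
    for label, removed in source:
        remaining -= removed
        if remaining < 0:
            raise ValueError(f"negative remaining count after stage {label!r}")
        ledger.append((label, int(removed), int(remaining)))
    return CohortFlow(initial=initial, stages=ledger)
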