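"""Derivation of the four study outcomes from longitudinal visit/relapse data.

The four outcomes compared between the two drugs are

1. count of relapses over follow-up (analysed with an exposure offset),
2. time to first relapse,
3. time to first confirmed EDSS worsening,
4. time to first confirmed EDSS improvement.

Confirmed worsening is an EDSS increase from the fixed baseline score that
meets a baseline-dependent threshold (1.5 steps from EDSS 0, 1.0 steps from
EDSS 1.0-5.5, 0.5 steps above 5.5) and is sustained at all consecutive
visits over at least six months; the confirming visit may not fall within 30
days after a relapse onset.  Improvement mirrors this with its own threshold
schedule (1.5 from EDSS 1.5, 1.0 from 2.0-6.0, 0.5 above 6.0) and no relapse
clause.  Events are timed at the onset visit.  An EDSS of 0.5 or 1.0 at
baseline cannot worsen by a listed band; the 1.0-step threshold is applied
to baseline 0.5 (the nearest band), and improvement is structurally
undefined below baseline 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

OUTCOMES = ("relapse_count", "first_relapse", "worsening", "improvement")

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ConfirmationParams:
    confirmation_days: float = 180.0
    relapse_exclusion_days: float = 30.0


@dataclass(frozen=True)
class AnalysisWindow:
    """Per-patient analysis interval [start, end] with the censoring reason."""

    patient_id: object
    start: float
    end: float
    reason: str = "last record"

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"window end < start for patient {self.patient_id}")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class OutcomeRecord:
    patient_id: object
    outcome: str
    followup_days: float
    event: int  # indicator for time-to-event outcomes, count for relapse_count
    event_day: float | None = None  # onset day, relative to window start
    visit_density: float | None = None  # EDSS visits per follow-up year


def _check_grid(values: Iterable[float]) -> None:
    arr = np.asarray(list(values), dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 10) or np.any((arr * 2) % 1 != 0)):
        raise ValueError("EDSS scores must lie on the half-point grid 0-10")


def worsening_threshold(baseline_edss: float) -> float:
    _check_grid([baseline_edss])
    if baseline_edss == 0.0:
        return 1.5
    if baseline_edss <= 5.5:
        return 1.0
    return 0.5


def improvement_threshold(baseline_edss: float) -> float | None:
    """Required EDSS decrease; None below baseline 1.5 (undefined)."""
    _check_grid([baseline_edss])
    if baseline_edss < 1.5:
        return None
    if baseline_edss == 1.5:
        return 1.5
    if baseline_edss <= 6.0:
        return 1.0
    return 0.5


def count_relapses(relapse_days: Sequence[float], window: AnalysisWindow):
    """Count relapse onsets in (start, end]; returns (count, exposure_days).

    The half-open interval keeps an onset on the index day itself in the
    baseline history rather than in follow-up.
    """
    days = np.asarray(relapse_days, dtype=float)
    count = int(np.sum((days > window.start) & (days <= window.end)))
    return count, window.length


def time_to_first_relapse(relapse_days: Sequence[float], window: AnalysisWindow) -> OutcomeRecord:
    days = np.asarray(relapse_days, dtype=float)
    in_window = days[(days > window.start) & (days <= window.end)]
    if in_window.size:
        return OutcomeRecord(
            window.patient_id, "first_relapse", window.length, 1, float(in_window.min() - window.start)
        )
    return OutcomeRecord(window.patient_id, "first_relapse", window.length, 0, None)


def detect_confirmed_change(
    visit_days: Sequence[float],
    visit_edss: Sequence[float],
    relapse_days: Sequence[float],
    baseline_edss: float,
    direction: str,
    window: AnalysisWindow,
    params: ConfirmationParams = ConfirmationParams(),
) -> OutcomeRecord:
    """Scan post-baseline visits for a confirmed sustained EDSS change.

    A candidate onset is the first in-window visit whose change from
    ``baseline_edss`` meets the direction's threshold.  It is confirmed iff a
    visit at least ``confirmation_days`` later exists such that every visit
    from onset through that confirming visit (inclusive) meets the
    threshold; for worsening, the confirming visit must additionally not
    fall within ``relapse_exclusion_days`` after any relapse onset.  A
    candidate broken by a sub-threshold visit is discarded and scanning
    resumes after the breaking visit.  Confirmed events are timed at the
    onset visit.
    """
    if direction not in ("worsening", "improvement"):
        raise ValueError(f"unknown direction {direction!r}")
    _check_grid([baseline_edss])
    days = np.asarray(visit_days, dtype=float)
    edss = np.asarray(visit_edss, dtype=float)
    if days.size and np.any(np.diff(days) < 0):
        raise ValueError("visit days must be sorted")
    _check_grid(edss)
    outcome = direction
    keep = (days > window.start) & (days <= window.end)
    days, edss = days[keep], edss[keep]
    relapses = np.asarray(relapse_days, dtype=float)

    if direction == "worsening":
        threshold = worsening_threshold(baseline_edss)
        meets = edss - baseline_edss >= threshold
    else:
        threshold = improvement_threshold(baseline_edss)
        if threshold is None:  # structurally censored
            return OutcomeRecord(window.patient_id, outcome, window.length, 0, None)
        meets = baseline_edss - edss >= threshold

    i = 0
    n = days.size
    while i < n:
        if not meets[i]:
            i += 1
            continue
        onset = i
        j = onset + 1
        failed_at = None
        while j < n:
            if not meets[j]:
                failed_at = j
                break
            if days[j] - days[onset] >= params.confirmation_days:
                blocked = direction == "worsening" and np.any(
                    (days[j] - relapses > 0) & (days[j] - relapses <= params.relapse_exclusion_days)
                )
                if not blocked:
                    return OutcomeRecord(
                        window.patient_id,
                        outcome,
                        window.length,
                        1,
                        float(days[onset] - window.start),
                    )
            j += 1
        if failed_at is None:
            break  # no confirming visit remains in the window
        i = failed_at + 1
    return OutcomeRecord(window.patient_id, outcome, window.length, 0, None)


def visit_density(visit_days: Sequence[float], window: AnalysisWindow) -> float:
    """Annualized EDSS-visit density over the window (visits per year)."""
    if window.length <= 0:
        raise ValueError("visit density undefined for a zero-length window")
    days = np.asarray(visit_days, dtype=float)
    n = int(np.sum((days > window.start) & (days <= window.end)))
    return n / (window.length / DAYS_PER_YEAR)


def reverse_km_median(followup_days: Sequence[float], event: Sequence[int]):
    """Median follow-up by the reverse Kaplan-Meier method.

    The censoring indicator is inverted so that administrative censoring is
    the "event", accounting for both length and completeness of follow-up.
    Returns ``(median, (lo, hi))``; entries are ``inf`` when not reached.
    """
    t = np.asarray(followup_days, dtype=float)
    e = 1 - np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("no follow-up records")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return median, (lo, hi)


def outcome_table(
    visits: pd.DataFrame,
    relapses: pd.DataFrame,
    baseline: pd.DataFrame,
    windows: pd.DataFrame,
    outcomes: Sequence[str] = OUTCOMES,
    params: ConfirmationParams = ConfirmationParams(),
) -> pd.DataFrame:
    """Derive outcome records for every patient in ``windows``.

    ``windows`` has columns patient_id/start/end/reason; ``baseline`` must
    carry patient_id and baseline_edss.  Returns one row per patient and
    requested outcome with columns patient_id, outcome, followup_days,
    event, event_day, visit_density.
    """
    unknown = set(outcomes) - set(OUTCOMES)
    if unknown:
        raise ValueError(f"unknown outcomes {sorted(unknown)}")
    vis_by_pat = {k: g for k, g in visits.groupby("patient_id")}
    rel_by_pat = {k: g["date"].to_numpy() for k, g in relapses.groupby("patient_id")}
    base_edss = baseline.set_index("patient_id")["baseline_edss"]
    arm = baseline.set_index("patient_id")["arm"] if "arm" in baseline.columns else None
    rows = []
    empty = np.empty(0)
    for rec in windows.itertuples(index=False):
        window = AnalysisWindow(rec.patient_id, rec.start, rec.end, getattr(rec, "reason", ""))
        vgroup = vis_by_pat.get(rec.patient_id)
        if vgroup is not None:
            vdays = vgroup["date"].to_numpy()
            vedss = vgroup["edss"].to_numpy()
        else:
            vdays = vedss = empty
        rdays = rel_by_pat.get(rec.patient_id, empty)
        density = visit_density(vdays, window) if window.length > 0 else 0.0
        for outcome in outcomes:
            if outcome == "relapse_count":
                count, exposure = count_relapses(rdays, window)
                out = OutcomeRecord(rec.patient_id, outcome, exposure, count, None)
            elif outcome == "first_relapse":
                out = time_to_first_relapse(rdays, window)
            else:
                out = detect_confirmed_change(
                    vdays, vedss, rdays, float(base_edss.loc[rec.patient_id]), outcome, window, params
                )
            out.visit_density = density
            row = dict(out.__dict__)
            if arm is not None:
                row["arm"] = int(arm.loc[rec.patient_id])
            rows.append(row)
    return pd.DataFrame(rows)
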