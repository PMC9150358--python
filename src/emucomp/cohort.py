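"""Index-episode selection, eligibility screening and baseline derivation.

The index episode is the earliest exposure to either study drug starting on
or after the control drug's availability date (unless the positivity
sensitivity mode re-admits earlier starts) and persisting at least three
months; prior exposure to therapies with an extended duration of effect
disqualifies the patient.  Eligible patients additionally need a baseline
EDSS visit within six months before the index date, two post-baseline EDSS
visits at least six months apart, and at least one on-treatment EDSS visit.
Each patient contributes once.

Month-based rules are fixed at day resolution: six months = 183 days,
twelve months = 365 days, three months = 90 days.  The baseline window is
closed at the index date (a day-0 visit reflects pre-treatment state), and
the day-0 visit also counts as on-treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outcomes import AnalysisWindow, detect_confirmed_change, ConfirmationParams
from .registry import RegistryTables, EXCLUDED_DRUGS, STUDY_DRUGS, TREATED_DRUG, ORIGIN_YEAR
from .synthetic import ACTIVITY_LEVELS  # canonical activity labels

BASELINE_WINDOW_DAYS = 183
POST_GAP_DAYS = 183
LOOKBACK_DAYS = 365
MIN_EPISODE_DAYS = 90

CRITERIA = ("index_episode", "baseline_visit", "post_visits", "on_treatment_visit")

BASELINE_COLUMNS = [
    "patient_id",
    "arm",
    "index_day",
    "episode_end",
    "sex",
    "age_at_index",
    "ms_duration",
    "baseline_edss",
    "baseline_edss_day",
    "n_prior_treatments",
    "n_relapses_prior_12m",
    "prior_activity",
    "country",
    "source",
]


@dataclass
class EligibilityReport:
    """Per-patient pass/fail per criterion plus exclusion counts."""

    table: pd.DataFrame

    @property
    def excluded_counts(self) -> dict:
        out = {}
        passed = pd.Series(True, index=self.table.index)
        for crit in CRITERIA:  # sequential attribution, first failure counts
            fail = passed & ~self.table[crit]
            out[crit] = int(fail.sum())
            passed &= self.table[crit]
        return out

    @property
    def eligible_ids(self) -> list:
        mask = self.table[list(CRITERIA)].all(axis=1)
        return self.table.loc[mask, "patient_id"].tolist()


def _merge_overlaps(drugs: np.ndarray, starts: np.ndarray, raw_ends: np.ndarray, observation_end: float):
    """Merge overlapping same-drug episodes (warning); open ends run to observation end.

    Returns parallel arrays (drug, start, end, open_ended) sorted by start.
    """
    ends = np.where(np.isnan(raw_ends), observation_end, raw_ends)
    is_open = np.isnan(raw_ends)
    out = []
    warned = False
    for drug in pd.unique(drugs):
        sel = np.flatnonzero(drugs == drug)
        sel = sel[np.argsort(starts[sel], kind="stable")]
        cur_s, cur_e, cur_open = starts[sel[0]], ends[sel[0]], is_open[sel[0]]
        for i in sel[1:]:
            if starts[i] <= cur_e:
                if not warned:
                    warnings.warn(f"overlapping {drug} episodes merged", stacklevel=3)
                    warned = True
                cur_e = max(cur_e, ends[i])
                cur_open = cur_open or is_open[i]
            else:
                out.append((drug, cur_s, cur_e, cur_open))
                cur_s, cur_e, cur_open = starts[i], ends[i], is_open[i]
        out.append((drug, cur_s, cur_e, cur_open))
    out.sort(key=lambda t: t[1])
    d, s, e, o = zip(*out)
    return np.array(d, dtype=object), np.array(s, dtype=float), np.array(e, dtype=float), np.array(o)


def _select_index_arrays(drugs, starts, raw_ends, availability_day, allow_pre_era, observation_end):
    if np.any(~np.isnan(raw_ends) & (raw_ends < starts)):
        raise ValueError("episode with end before start")
    d, s, e, o = _merge_overlaps(drugs, starts, raw_ends, observation_end)
    excluded_starts = s[np.isin(d, list(EXCLUDED_DRUGS))]
    for i in range(len(d)):
        if d[i] not in STUDY_DRUGS:
            continue
        if not allow_pre_era and s[i] < availability_day:
            continue
        if min(e[i], observation_end) - s[i] < MIN_EPISODE_DAYS:
            continue
        if excluded_starts.size and np.any(excluded_starts < s[i]):
            return None
        return {
            "arm": int(d[i] == TREATED_DRUG),
            "index_day": float(s[i]),
            "episode_end": float(e[i]) if not o[i] else np.nan,
        }
    return None


def select_index_episode(
    episodes: pd.DataFrame,
    availability_day: float = 0.0,
    allow_pre_era: bool = False,
    observation_end: float = np.inf,
):
    """Pick one patient's index episode; returns a dict or None.

    The earliest study-drug episode with start on/after the availability
    date (any start when ``allow_pre_era``) and at least 90 days' duration
    qualifies (open-ended episodes qualify once observed for 90 days).  Any
    exposure to an excluded therapy before the candidate start disqualifies
    the patient outright.
    """
    if episodes.empty:
        return None
    return _select_index_arrays(
        episodes["drug"].to_numpy(dtype=object),
        episodes["start_date"].to_numpy(dtype=float),
        episodes["end_date"].to_numpy(dtype=float),
        availability_day,
        allow_pre_era,
        observation_end,
    )


def assign_index(
    registry: RegistryTables, availability_day: float = 0.0, allow_pre_era: bool = False
) -> pd.DataFrame:
    """Index-episode table (patient_id, arm, index_day, episode_end) for a registry."""
    last = registry.last_record_day()
    trt = registry.treatments
    pids = trt["patient_id"].to_numpy()
    drugs = trt["drug"].to_numpy(dtype=object)
    starts = trt["start_date"].to_numpy(dtype=float)
    ends = trt["end_date"].to_numpy(dtype=float)
    order = np.argsort(pids, kind="stable")
    rows = []
    i = 0
    while i < len(order):
        j = i
        pid = pids[order[i]]
        while j < len(order) and pids[order[j]] == pid:
            j += 1
        sel = order[i:j]
        chosen = _select_index_arrays(
            drugs[sel], starts[sel], ends[sel],
            availability_day, allow_pre_era, float(last.get(pid, np.inf)),
        )
        if chosen is not None:
            rows.append({"patient_id": pid, **chosen})
        i = j
    return pd.DataFrame(rows, columns=["patient_id", "arm", "index_day", "episode_end"])


def derive_baseline(
    patient,
    visits,
    relapses: np.ndarray,
    treatments,
    index_day: float,
) -> dict:
    """Baseline covariate record for one (eligible) patient at the index date.

    ``patient`` is a mapping (row of the patients table); ``visits`` a
    DataFrame or a ``(days, edss)`` array pair; ``treatments`` a DataFrame
    or an array of episode start days.
    """
    if pd.isna(patient["onset_date"]):
        raise ValueError(f"missing MS onset date for patient {patient['patient_id']}")
    if isinstance(visits, pd.DataFrame):
        vdays = visits["date"].to_numpy(dtype=float)
        vedss = visits["edss"].to_numpy(dtype=float)
    else:
        vdays, vedss = visits
    tx_starts = (
        treatments["start_date"].to_numpy(dtype=float)
        if isinstance(treatments, pd.DataFrame)
        else np.asarray(treatments, dtype=float)
    )
    pre = (vdays >= index_day - BASELINE_WINDOW_DAYS) & (vdays <= index_day)
    base_i = np.flatnonzero(pre)[np.argmax(vdays[pre])]
    relapses = np.asarray(relapses, dtype=float)
    n_rel = int(np.sum((relapses >= index_day - LOOKBACK_DAYS) & (relapses < index_day)))

    # prior confirmed worsening over the 12-month lookback, anchored on the
    # earliest EDSS in that window (the outcomes detector, re-aimed backwards)
    look = (vdays >= index_day - LOOKBACK_DAYS) & (vdays <= index_day)
    worsened = False
    if look.sum() >= 2:
        ref_i = np.flatnonzero(look)[np.argmin(vdays[look])]
        rec = detect_confirmed_change(
            vdays[look],
            vedss[look],
            relapses,
            float(vedss[ref_i]),
            "worsening",
            AnalysisWindow(patient["patient_id"], float(vdays[ref_i]), float(index_day)),
            ConfirmationParams(),
        )
        worsened = bool(rec.event)
    if n_rel > 0:
        activity = ACTIVITY_LEVELS[3] if worsened else ACTIVITY_LEVELS[2]
    else:
        activity = ACTIVITY_LEVELS[1] if worsened else ACTIVITY_LEVELS[0]

    n_prior = int((tx_starts < index_day).sum())
    age = ORIGIN_YEAR + index_day / 365.25 - float(patient["birth_year"])
    duration = (index_day - float(patient["onset_date"])) / 365.25
    if age < 0 or duration < 0:
        raise ValueError(f"negative age or MS duration for patient {patient['patient_id']}")
    return {
        "patient_id": patient["patient_id"],
        "sex": patient["sex"],
        "age_at_index": age,
        "ms_duration": duration,
        "baseline_edss": float(vedss[base_i]),
        "baseline_edss_day": float(vdays[base_i]),
        "n_prior_treatments": n_prior,
        "n_relapses_prior_12m": n_rel,
        "prior_activity": activity,
        "country": patient["country"],
        "source": patient["source"],
    }


def apply_eligibility(registry: RegistryTables, index: pd.DataFrame):
    """Screen every patient; returns ``(baseline_table, EligibilityReport)``.

    ``index`` is the table from :func:`assign_index`; patients absent from it
    fail the index-episode criterion.  The baseline table has one row per
    eligible patient (columns in :data:`BASELINE_COLUMNS`).
    """
    vis_by_pat = {
        k: (g["date"].to_numpy(dtype=float), g["edss"].to_numpy(dtype=float))
        for k, g in registry.visits.groupby("patient_id")
    }
    rel_by_pat = {k: g["date"].to_numpy(dtype=float) for k, g in registry.relapses.groupby("patient_id")}
    trt_by_pat = {
        k: g["start_date"].to_numpy(dtype=float) for k, g in registry.treatments.groupby("patient_id")
    }
    last = registry.last_record_day()
    idx_by_pat = {
        r.patient_id: (int(r.arm), float(r.index_day), r.episode_end)
        for r in index.itertuples(index=False)
    }

    empty = np.empty(0)
    report_rows, baseline_rows = [], []
    for patient in registry.patients.itertuples(index=False):
        pid = patient.patient_id
        flags = dict.fromkeys(CRITERIA, False)
        flags["index_episode"] = pid in idx_by_pat
        if flags["index_episode"]:
            arm, idx_day, ep_end = idx_by_pat[pid]
            observed_end = float(last.get(pid, idx_day)) if pd.isna(ep_end) else float(ep_end)
            vdays, vedss = vis_by_pat.get(pid, (empty, empty))
            flags["baseline_visit"] = bool(
                np.any((vdays >= idx_day - BASELINE_WINDOW_DAYS) & (vdays <= idx_day))
            )
            post = vdays[vdays > idx_day]
            flags["post_visits"] = post.size >= 2 and (post.max() - post.min()) >= POST_GAP_DAYS
            flags["on_treatment_visit"] = bool(
                np.any((vdays >= idx_day) & (vdays <= observed_end))
            )
        report_rows.append({"patient_id": pid, **flags})
        if all(flags.values()):
            base = derive_baseline(
                patient._asdict(),
                (vdays, vedss),
                rel_by_pat.get(pid, empty),
                trt_by_pat.get(pid, empty),
                idx_day,
            )
            base["arm"] = arm
            base["index_day"] = idx_day
            base["episode_end"] = float(ep_end) if not pd.isna(ep_end) else np.nan
            baseline_rows.append(base)

    baseline = pd.DataFrame(baseline_rows, columns=BASELINE_COLUMNS)
    return baseline, EligibilityReport(pd.DataFrame(report_rows))


def build_cohort(
    registry: RegistryTables, availability_day: float = 0.0, allow_pre_era: bool = False
):
    """Convenience wrapper: index selection + eligibility in one call."""
    index = assign_index(registry, availability_day, allow_pre_era)
    return apply_eligibility(registry, index)
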