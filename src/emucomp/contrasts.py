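"""Causal-contrast analysis windows (ITT, per-protocol, pairwise censoring).

Intention-to-treat keeps every patient under their initial assignment until
the last data entry, regardless of later exposure.  Per-protocol censors at
treatment discontinuation (or the last data entry if earlier).  Pairwise
censoring — matched designs only — truncates both members of each pair to
the pair's shorter follow-up, preserving the balance of analysed time.
Outcome events landing exactly on a window end are inside the window
(closed right endpoint).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .balancing import MatchedCohort
from .outcomes import AnalysisWindow


def censor_itt(patient_id, index_day: float, last_record_day: float) -> AnalysisWindow:
    """Window [index, last record], irrespective of later exposure."""
    if last_record_day < index_day:
        raise ValueError("last record precedes the index date")
    if last_record_day == index_day:
        warnings.warn(f"zero-length ITT window for patient {patient_id}")
    return AnalysisWindow(patient_id, index_day, last_record_day, "last record")


def censor_per_protocol(
    patient_id, index_day: float, episode_end: float, last_record_day: float
) -> AnalysisWindow:
    """Window ending at discontinuation or last record, whichever is earlier."""
    if last_record_day < index_day:
        raise ValueError("last record precedes the index date")
    if np.isnan(episode_end) or episode_end >= last_record_day:
        return AnalysisWindow(patient_id, index_day, last_record_day, "last record")
    return AnalysisWindow(patient_id, index_day, max(episode_end, index_day), "discontinuation")


def make_windows(baseline: pd.DataFrame, last_record: pd.Series, kind: str) -> pd.DataFrame:
    """Per-patient windows under the given contrast ('itt' or 'per_protocol')."""
    if kind not in ("itt", "per_protocol"):
        raise ValueError(f"unknown contrast {kind!r}")
    rows = []
    for rec in baseline.itertuples(index=False):
        last = float(last_record.loc[rec.patient_id])
        if kind == "itt":
            w = censor_itt(rec.patient_id, rec.index_day, last)
        else:
            w = censor_per_protocol(rec.patient_id, rec.index_day, rec.episode_end, last)
        rows.append(
            {"patient_id": w.patient_id, "start": w.start, "end": w.end, "reason": w.reason}
        )
    return pd.DataFrame(rows)


def censor_pairwise(windows: pd.DataFrame, matched: MatchedCohort) -> pd.DataFrame:
    """Truncate both members of every pair to the pair's minimum window length.

    Idempotent; never lengthens a window.  The truncated member's reason
    becomes ``pairwise``.
    """
    win = windows.set_index("patient_id")
    missing = set(matched.matched_ids) - set(win.index)
    if missing:
        raise ValueError(f"matched patients without windows: {sorted(missing)[:5]}")
    out = windows.copy().set_index("patient_id")
    for pair in matched.pairs.itertuples(index=False):
        lt = win.loc[pair.treated_id, "end"] - win.loc[pair.treated_id, "start"]
        lc = win.loc[pair.control_id, "end"] - win.loc[pair.control_id, "start"]
        shared = min(lt, lc)
        for pid, own in ((pair.treated_id, lt), (pair.control_id, lc)):
            if own > shared:
                out.loc[pid, "end"] = out.loc[pid, "start"] + shared
                out.loc[pid, "reason"] = "pairwise"
    return out.reset_index()
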