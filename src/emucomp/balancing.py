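"""Matched and weighted designs realizing ATT or ATE, and balance metrics.

One-to-one greedy nearest-neighbour matching on the PS (random, seeded
processing order; caliper expressed in standard deviations of the pooled
PS, on the probability scale; no replacement) approximates the average
treatment effect in the treated (ATT).  Weighting offers three schemes:
IPTW (1/p, 1/(1-p); ATE), stabilized IPTW (multiplied by the marginal
probability of the treatment actually received; ATE), and weighting by the
odds (treated 1, control p/(1-p); ATT).  Stabilization is used in place of
weight trimming or truncation, so no weights are trimmed anywhere.

Balance is quantified per covariate as the standardized mean difference
(continuous/binary) or the Mahalanobis distance of the category-proportion
vectors (multi-level), with 10% the conventional acceptability threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import edss_band

BALANCE_THRESHOLD = 0.10

WEIGHT_SCHEMES = ("iptw", "siptw", "odds")


@dataclass
class MatchedCohort:
    pairs: pd.DataFrame  # pair_id, treated_id, control_id, ps_distance
    caliper_sd: float
    caliper_absolute: float
    seed: int
    unmatched_treated: list = field(default_factory=list)

    estimand = "ATT"

    @property
    def matched_ids(self) -> np.ndarray:
        return np.concatenate(
            [self.pairs["treated_id"].to_numpy(), self.pairs["control_id"].to_numpy()]
        )

    def pair_of(self) -> pd.Series:
        """patient_id -> pair_id mapping over matched patients."""
        s = pd.concat(
            [
                self.pairs.set_index("treated_id")["pair_id"],
                self.pairs.set_index("control_id")["pair_id"],
            ]
        )
        s.index.name = "patient_id"
        return s


@dataclass
class WeightedCohort:
    weights: pd.Series  # indexed by patient_id, >= 0
    scheme: str
    estimand: str
    marginal_treated: float


def match_greedy(ps: pd.DataFrame, caliper_sd: float = 0.2, seed: int = 0) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour PS matching without replacement.

    Treated patients are processed in a seeded random order; each takes the
    nearest unused control within the caliper (ties broken at random,
    seeded).  The caliper is ``caliper_sd`` times the SD of the pooled PS.
    """
    if caliper_sd <= 0:
        raise ValueError("caliper_sd must be > 0")
    rng = np.random.default_rng(seed)
    treated = ps[ps["arm"] == 1]
    control = ps[ps["arm"] == 0]
    if treated.empty:
        raise ValueError("no treated patients to match")
    caliper_abs = float(caliper_sd * np.std(ps["ps"].to_numpy(), ddof=1))
    if control.empty:
        warnings.warn("empty control pool: matched cohort is empty")
        return MatchedCohort(
            pd.DataFrame(columns=["pair_id", "treated_id", "control_id", "ps_distance"]),
            caliper_sd,
            caliper_abs,
            seed,
            list(treated["patient_id"]),
        )
    t_ids = treated["patient_id"].to_numpy()
    t_ps = treated["ps"].to_numpy(dtype=float)
    c_ids = control["patient_id"].to_numpy()
    c_ps = control["ps"].to_numpy(dtype=float)
    order = rng.permutation(len(t_ids))
    available = np.ones(len(c_ids), dtype=bool)
    rows, unmatched = [], []
    for ti in order:
        dist = np.abs(c_ps - t_ps[ti])
        dist[~available] = np.inf
        best = dist.min()
        if best > caliper_abs or not np.isfinite(best):
            unmatched.append(t_ids[ti])
            continue
        candidates = np.flatnonzero(dist == best)
        pick = candidates[0] if candidates.size == 1 else rng.choice(candidates)
        available[pick] = False
        rows.append((t_ids[ti], c_ids[pick], best))
    pairs = pd.DataFrame(rows, columns=["treated_id", "control_id", "ps_distance"])
    pairs.insert(0, "pair_id", np.arange(len(pairs)))
    return MatchedCohort(pairs, caliper_sd, caliper_abs, seed, unmatched)


def compute_weights(ps: pd.DataFrame, scheme: str) -> WeightedCohort:
    """Per-patient design weights under the iptw / siptw / odds scheme."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    p = ps["ps"].to_numpy(dtype=float)
    arm = ps["arm"].to_numpy(dtype=int)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("propensity score at 0 or 1: positivity assumption violated")
    marginal = float(arm.mean())
    if scheme == "odds":
        w = np.where(arm == 1, 1.0, p / (1.0 - p))
        estimand = "ATT"
    else:
        w = np.where(arm == 1, 1.0 / p, 1.0 / (1.0 - p))
        if scheme == "siptw":
            w = w * np.where(arm == 1, marginal, 1.0 - marginal)
        estimand = "ATE"
    weights = pd.Series(w, index=pd.Index(ps["patient_id"], name="patient_id"), name="weight")
    return WeightedCohort(weights, scheme, estimand, marginal)


def _weighted_smd(x_t, w_t, x_c, w_c):
    m_t = np.average(x_t, weights=w_t)
    m_c = np.average(x_c, weights=w_c)
    v_t = np.average((x_t - m_t) ** 2, weights=w_t)
    v_c = np.average((x_c - m_c) ** 2, weights=w_c)
    pooled = (v_t + v_c) / 2.0
    if pooled == 0.0:
        return 0.0 if m_t == m_c else np.inf
    return abs(m_t - m_c) / np.sqrt(pooled)


def _mahalanobis(levels, x_t, w_t, x_c, w_c, ridge=1e-10):
    """Distance between weighted category-proportion vectors (K-1 dims)."""
    p_t = np.array([np.average(x_t == lv, weights=w_t) for lv in levels])
    p_c = np.array([np.average(x_c == lv, weights=w_c) for lv in levels])
    d = (p_t - p_c)[:-1]
    cov_t = np.diag(p_t) - np.outer(p_t, p_t)
    cov_c = np.diag(p_c) - np.outer(p_c, p_c)
    S = ((cov_t + cov_c) / 2.0)[:-1, :-1] + ridge * np.eye(len(levels) - 1)
    return float(np.sqrt(d @ np.linalg.solve(S, d)))


def _covariate_frame(baseline: pd.DataFrame) -> pd.DataFrame:
    """Covariates on the scales the balance report uses."""
    out = pd.DataFrame(index=baseline.index)
    out["female"] = (baseline["sex"] == "F").astype(float)
    out["age"] = baseline["age_at_index"].astype(float)
    out["ms_duration"] = baseline["ms_duration"].astype(float)
    out["edss_band"] = edss_band(baseline["baseline_edss"].to_numpy())
    out["relapse_band"] = np.minimum(baseline["n_relapses_prior_12m"].to_numpy(dtype=int), 3)
    out["prior_tx_band"] = np.minimum(baseline["n_prior_treatments"].to_numpy(dtype=int), 3)
    out["activity"] = baseline["prior_activity"].to_numpy()
    out["country"] = baseline["country"].to_numpy()
    return out

_CONTINUOUS = ("female", "age", "ms_duration")
_CATEGORICAL = ("edss_band", "relapse_band", "prior_tx_band", "activity", "country")


def _design_weights(baseline: pd.DataFrame, design) -> pd.Series:
    ids = pd.Index(baseline["patient_id"], name="patient_id")
    if design is None:
        return pd.Series(1.0, index=ids)
    if isinstance(design, MatchedCohort):
        w = pd.Series(0.0, index=ids)
        w.loc[w.index.intersection(design.matched_ids)] = 1.0
        return w
    if isinstance(design, WeightedCohort):
        return design.weights.reindex(ids).fillna(0.0)
    raise TypeError(f"unsupported design {type(design).__name__}")


def balance_table(baseline: pd.DataFrame, design=None) -> pd.DataFrame:
    """Per-covariate balance before and after a design.

    Returns a frame with columns covariate, metric, before, after, flagged
    (``after`` exceeding the 10% threshold).  ``design`` may be None (raw
    cohort), a :class:`MatchedCohort` (matched subset, unit weights) or a
    :class:`WeightedCohort`.
    """
    cov = _covariate_frame(baseline)
    arm = baseline["arm"].to_numpy(dtype=int)
    w_before = np.ones(len(baseline))
    w_after = _design_weights(baseline, design).to_numpy(dtype=float)
    rows = []
    for name in _CONTINUOUS + _CATEGORICAL:
        x = cov[name].to_numpy()
        vals = {}
        for label, w in (("before", w_before), ("after", w_after)):
            sel_t = (arm == 1) & (w > 0)
            sel_c = (arm == 0) & (w > 0)
            if not sel_t.any() or not sel_c.any():
                vals[label] = np.nan
                continue
            if name in _CONTINUOUS:
                vals[label] = _weighted_smd(x[sel_t], w[sel_t], x[sel_c], w[sel_c])
            else:
                levels = sorted(pd.unique(x))
                vals[label] = _mahalanobis(levels, x[sel_t], w[sel_t], x[sel_c], w[sel_c])
        rows.append(
            {
                "covariate": name,
                "metric": "smd" if name in _CONTINUOUS else "mahalanobis",
                "before": vals["before"],
                "after": vals["after"],
                "flagged": bool(vals["after"] > BALANCE_THRESHOLD)
                if np.isfinite(vals["after"])
                else True,
            }
        )
    return pd.DataFrame(rows)
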