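"""Outcome models returning treated-vs-control effect estimates.

Relapse counts are modelled by negative-binomial regression of the count on
the arm indicator with a log follow-up offset: weighted designs enter their
weights into independence estimating equations with a robust sandwich
variance, matched designs use pair-clustered estimating equations (GEE).
The NB dispersion is estimated by moments from Pearson residuals; when it
vanishes the model reduces to Poisson with robust variance (recorded in the
diagnostics).  Time-to-event outcomes use Cox proportional hazards (Efron
ties) with a robust sandwich variance — weighted partial likelihood for
weighted designs, pair-clustered robust variance for matched designs —
optionally adjusted for annualized EDSS-visit density (linear on the
log-hazard scale), which is mandatory for the disability outcomes because
event detection depends on how often EDSS is measured.  Confidence
intervals are Wald on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .balancing import MatchedCohort, WeightedCohort

Z975 = 1.959963984540054


@dataclass
class EstimateResult:
    """A single effect estimate with design provenance."""

    measure: str  # "IRR" or "HR"
    point: float
    ci95: tuple
    se_log: float
    n_used: int
    variance_method: str
    design: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.point <= hi) or lo <= 0:
            raise ValueError("invalid confidence interval")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "measure": self.measure,
                    "point": self.point,
                    "ci_lo": self.ci95[0],
                    "ci_hi": self.ci95[1],
                    "se_log": self.se_log,
                    "n": self.n_used,
                    "variance": self.variance_method,
                    **{f"design_{k}": v for k, v in self.design.items()},
                }
            ]
        )


def _prepare(records: pd.DataFrame, design):
    """Attach design weights / pair ids; subset matched cohorts."""
    df = records.copy()
    if isinstance(design, MatchedCohort):
        pair = design.pair_of()
        df = df[df["patient_id"].isin(pair.index)].copy()
        df["pair_id"] = pair.reindex(df["patient_id"]).to_numpy()
        df["weight"] = 1.0
        variance = "cluster-by-pair"
    elif isinstance(design, WeightedCohort):
        df["weight"] = design.weights.reindex(df["patient_id"]).to_numpy()
        df = df[df["weight"] > 0].copy()
        df["pair_id"] = np.arange(len(df))
        variance = "robust sandwich"
    elif design is None:
        df["weight"] = 1.0
        df["pair_id"] = np.arange(len(df))
        variance = "robust sandwich"
    else:
        raise TypeError(
            f"unsupported design {type(design).__name__}: weighted and matched "
            "designs do not combine"
        )
    return df, variance


def _wald(coef: float, se: float):
    return float(np.exp(coef)), (float(np.exp(coef - Z975 * se)), float(np.exp(coef + Z975 * se)))


def fit_nb_irr(records: pd.DataFrame, design=None) -> EstimateResult:
    """Incidence-rate ratio from an offset negative-binomial model.

    ``records`` must carry patient_id, arm, event (the relapse count) and
    followup_days (the exposure).
    """
    df, variance = _prepare(records, design)
    if (df["followup_days"] <= 0).any():
        warnings.warn("dropping records with zero exposure")
        df = df[df["followup_days"] > 0]
    y = df["event"].to_numpy(dtype=float)
    arm = df["arm"].to_numpy(dtype=int)
    for a in (0, 1):
        if y[arm == a].sum() == 0:
            raise ValueError(
                f"all counts are zero in arm {a}; the rate ratio is not identified "
                "(consider exact methods)"
            )
    X = sm.add_constant(pd.DataFrame({"arm": arm.astype(float)}), prepend=True)
    offset = np.log(df["followup_days"].to_numpy(dtype=float))
    w = df["weight"].to_numpy(dtype=float)
    groups = df["pair_id"].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GEE(y, X, groups=groups, family=sm.families.Poisson(), offset=offset, weights=w).fit()
        mu = np.asarray(pois.fittedvalues)
        alpha = float(np.sum(w * ((y - mu) ** 2 - mu)) / np.sum(w * mu**2))
        if alpha > 1e-8:
            family = sm.families.NegativeBinomial(alpha=alpha)
            fit = sm.GEE(y, X, groups=groups, family=family, offset=offset, weights=w).fit()
            dispersion = alpha
        else:
            fit, dispersion = pois, 0.0
    coef = float(fit.params.iloc[1])
    se = float(fit.bse.iloc[1])
    point, ci = _wald(coef, se)
    return EstimateResult(
        measure="IRR",
        point=point,
        ci95=ci,
        se_log=se,
        n_used=len(df),
        variance_method=variance,
        diagnostics={
            "nb_dispersion": dispersion,
            "poisson_fallback": dispersion == 0.0,
            "baseline_log_rate": float(fit.params.iloc[0]),
        },
    )


def fit_cox_hr(
    records: pd.DataFrame, design=None, adjust_visit_density: bool = False
) -> EstimateResult:
    """Hazard ratio from a Cox model of (followup_days, event) on arm.

    ``records`` must carry patient_id, arm, followup_days, event and — when
    ``adjust_visit_density`` — visit_density.
    """
    df, variance = _prepare(records, design)
    if (df["followup_days"] <= 0).any():
        warnings.warn("dropping records with zero follow-up")
        df = df[df["followup_days"] > 0]
    if df["event"].sum() == 0:
        raise ValueError("no events observed; the hazard ratio is not identified")
    event = df["event"].astype(int).to_numpy()
    time = np.where(
        event == 1, df["event_day"].to_numpy(dtype=float), df["followup_days"].to_numpy(dtype=float)
    )
    cols = {"T": time, "E": event, "arm": df["arm"].astype(float)}
    if adjust_visit_density:
        cols["visit_density"] = df["visit_density"].astype(float)
    frame = pd.DataFrame(cols)
    frame["w"] = df["weight"].to_numpy(dtype=float)
    cluster = None
    if isinstance(design, MatchedCohort):
        frame["pair"] = df["pair_id"].to_numpy()
        cluster = "pair"
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            frame,
            duration_col="T",
            event_col="E",
            weights_col="w",
            cluster_col=cluster,
            robust=True,
        )
    coef = float(cph.params_["arm"])
    se = float(cph.standard_errors_["arm"])
    point, ci = _wald(coef, se)
    return EstimateResult(
        measure="HR",
        point=point,
        ci95=ci,
        se_log=se,
        n_used=len(frame),
        variance_method=variance,
        diagnostics={
            "n_events": int(frame["E"].sum()),
            "visit_density_coef": float(cph.params_.get("visit_density", np.nan)),
        },
    )


class TreatmentEffectModel:
    """Model object tying outcome records to a balancing design.

    ``kind`` selects the Table-1 model family: ``"count"`` (negative
    binomial with offset, IRR) or ``"survival"`` (Cox, HR).
    """

    def __init__(self, records: pd.DataFrame, design=None, kind: str = "survival",
                 adjust_visit_density: bool = False):
        if kind not in ("count", "survival"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.records = records
        self.design = design
        self.kind = kind
        self.adjust_visit_density = adjust_visit_density

    def fit(self) -> EstimateResult:
        if self.kind == "count":
            return fit_nb_irr(self.records, self.design)
        return fit_cox_hr(self.records, self.design, self.adjust_visit_density)
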