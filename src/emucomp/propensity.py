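"""Propensity-score estimation and overlap diagnostics.

The propensity score is the probability of starting the treated drug
(natalizumab) conditional on the baseline covariates: sex, age, MS duration
(continuous, linear), EDSS score, prior-relapse count and prior-treatment
count (entered as the categorical bands the balance tables report), and the
nature of clinical activity in the prior 12 months (4-level factor).
Country enters as a random intercept when requested (variational Bayes
mixed logistic), with a documented fall-back to fixed country indicators if
the mixed fit fails; the scientific target is the score, not the variance
component.

Scores are clipped to [1e-6, 1 - 1e-6] before any weight computation so
numeric underflow cannot manufacture infinite weights, while genuine
positivity violations remain visible in the overlap diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .synthetic import edss_band

PS_CLIP = 1e-6

# Prior activity is coded by its worsening component only: the "relapse only"
# level is an exact linear combination of the prior-relapse-count bands
# (activity is relapse-classified iff the count is >= 1), so a full 4-level
# coding is rank-deficient; this parametrization spans the same model space.
_ACTIVITY_DUMMY_LEVELS = ("worsening", "relapse_and_worsening")


def design_matrix(baseline: pd.DataFrame) -> pd.DataFrame:
    """Fixed-order covariate design matrix (no intercept, no country)."""
    X = pd.DataFrame(index=baseline.index)
    X["female"] = (baseline["sex"] == "F").astype(float)
    X["age"] = baseline["age_at_index"].astype(float)
    X["ms_duration"] = baseline["ms_duration"].astype(float)
    eband = edss_band(baseline["baseline_edss"].to_numpy())
    for b in (1, 2):
        X[f"edss_band_{b}"] = (eband == b).astype(float)
    rband = np.minimum(baseline["n_relapses_prior_12m"].to_numpy(dtype=int), 3)
    for b in (1, 2, 3):
        X[f"relapses_{b}"] = (rband == b).astype(float)
    tband = np.minimum(baseline["n_prior_treatments"].to_numpy(dtype=int), 3)
    for b in (1, 2, 3):
        X[f"prior_tx_{b}"] = (tband == b).astype(float)
    for level in _ACTIVITY_DUMMY_LEVELS:
        X[f"activity_{level}"] = (baseline["prior_activity"] == level).astype(float)
    return X


def _check_separation(baseline: pd.DataFrame) -> None:
    arm = baseline["arm"].to_numpy()
    cats = {
        "edss_band": edss_band(baseline["baseline_edss"].to_numpy()),
        "relapses": np.minimum(baseline["n_relapses_prior_12m"].to_numpy(dtype=int), 3),
        "prior_tx": np.minimum(baseline["n_prior_treatments"].to_numpy(dtype=int), 3),
        "activity": baseline["prior_activity"].to_numpy(),
        "country": baseline["country"].to_numpy(),
        "sex": baseline["sex"].to_numpy(),
    }
    for name, values in cats.items():
        for level in pd.unique(values):
            sub = arm[values == level]
            if sub.size and (sub.min() == sub.max()):
                raise ValueError(
                    f"separation: covariate level {name}={level!r} occurs in a single arm"
                )


@dataclass
class PropensityResults:
    """Fitted assignment model; exposes scores via :meth:`predict`."""

    params: pd.Series
    country_effects: pd.Series
    use_random_country: bool
    fell_back_to_fixed: bool
    converged: bool
    n_obs: int
    vcp: float | None = None  # log-sd of the country random intercept, if mixed
    _columns: list = field(default_factory=list)

    def predict(self, baseline: pd.DataFrame) -> pd.DataFrame:
        """Score a baseline table; returns patient_id/arm/ps/linear_predictor."""
        unseen = set(baseline["country"]) - set(self.country_effects.index)
        if unseen:
            raise ValueError(f"unseen country levels: {sorted(unseen)}")
        X = design_matrix(baseline)
        lp = (
            self.params["intercept"]
            + X[self._columns].to_numpy() @ self.params[self._columns].to_numpy()
            + self.country_effects.reindex(baseline["country"]).to_numpy()
        )
        ps = np.clip(1.0 / (1.0 + np.exp(-lp)), PS_CLIP, 1.0 - PS_CLIP)
        return pd.DataFrame(
            {
                "patient_id": baseline["patient_id"].to_numpy(),
                "arm": baseline["arm"].to_numpy(),
                "ps": ps,
                "linear_predictor": lp,
            }
        )

    def summary(self) -> pd.DataFrame:
        rows = [("intercept", self.params["intercept"])]
        rows += [(k, self.params[k]) for k in self._columns]
        rows += [(f"country[{k}]", v) for k, v in self.country_effects.items()]
        return pd.DataFrame(rows, columns=["term", "coef"]).set_index("term")


class PropensityModel:
    """Logistic assignment model for the probability of the treated drug.

    Parameters
    ----------
    baseline : DataFrame
        Output of the cohort stage (one row per eligible patient).
    use_random_country : bool
        Model country as a random intercept (variational mixed logistic);
        otherwise country enters as fixed indicators.
    """

    def __init__(self, baseline: pd.DataFrame, use_random_country: bool = False):
        if baseline["arm"].nunique() < 2 or baseline["arm"].value_counts().min() < 2:
            raise ValueError("need at least two patients in each arm")
        if baseline[["age_at_index", "ms_duration", "baseline_edss"]].isna().any().any():
            raise ValueError("missing covariates in baseline table")
        self.baseline = baseline
        self.use_random_country = use_random_country

    def fit(self) -> PropensityResults:
        _check_separation(self.baseline)
        baseline = self.baseline
        X = design_matrix(baseline)
        # absent factor levels yield all-zero indicator columns; drop them
        X = X.loc[:, X.nunique() > 1]
        y = baseline["arm"].to_numpy(dtype=float)
        countries = pd.unique(baseline["country"])
        if self.use_random_country and len(countries) > 1:
            try:
                return self._fit_mixed(X, y, countries)
            except Exception:
                res = self._fit_fixed(X, y, countries)
                res.fell_back_to_fixed = True
                return res
        return self._fit_fixed(X, y, countries)

    def _fit_fixed(self, X, y, countries) -> PropensityResults:
        dummies = pd.get_dummies(self.baseline["country"], dtype=float)[list(countries)]
        exog = pd.concat([pd.Series(1.0, index=X.index, name="intercept"), X, dummies.iloc[:, 1:]], axis=1)
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.params)):
            raise ValueError("non-finite propensity-model coefficients")
        params = pd.Series(fit.params, index=exog.columns)
        effects = pd.Series(0.0, index=list(countries))
        for c in countries[1:]:
            effects[c] = params[c]
        return PropensityResults(
            params=params,
            country_effects=effects,
            use_random_country=self.use_random_country,
            fell_back_to_fixed=False,
            converged=bool(fit.mle_retvals.get("converged", True)),
            n_obs=len(y),
            _columns=list(X.columns),
        )

    def _fit_mixed(self, X, y, countries) -> PropensityResults:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        exog = np.column_stack([np.ones(len(y)), X.to_numpy()])
        vc = pd.get_dummies(self.baseline["country"], dtype=float)[list(countries)].to_numpy()
        model = BinomialBayesMixedGLM(
            y, exog, exog_vc=vc, ident=np.zeros(vc.shape[1], dtype=int), vcp_p=2.0, fe_p=2.0
        )
        fit = model.fit_vb()
        fe = pd.Series(fit.fe_mean, index=["intercept", *X.columns])
        if not np.all(np.isfinite(fe)):
            raise ValueError("non-finite mixed-model coefficients")
        effects = pd.Series(fit.vc_mean, index=list(countries))
        return PropensityResults(
            params=fe,
            country_effects=effects,
            use_random_country=True,
            fell_back_to_fixed=False,
            converged=True,
            n_obs=len(y),
            vcp=float(fit.vcp_mean[0]),
            _columns=list(X.columns),
        )


def fit_ps_model(baseline: pd.DataFrame, use_random_country: bool = False) -> PropensityResults:
    return PropensityModel(baseline, use_random_country).fit()


def predict_ps(model: PropensityResults, baseline: pd.DataFrame) -> pd.DataFrame:
    return model.predict(baseline)


@dataclass
class OverlapReport:
    """Common-support diagnostics of the per-arm PS distributions."""

    support: tuple  # [max of arm minima, min of arm maxima]
    frac_outside: dict  # per arm, fraction outside the common support
    ks_statistic: float
    ks_pvalue: float
    summaries: dict  # per arm: min/q1/median/q3/max/mean/skewness
    histograms: dict  # per arm: (bin_edges, counts) on [0, 1]

    def to_dict(self) -> dict:
        return {
            "support": list(self.support),
            "frac_outside": self.frac_outside,
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "summaries": self.summaries,
            "histograms": {
                k: {"edges": list(map(float, e)), "counts": list(map(int, c))}
                for k, (e, c) in self.histograms.items()
            },
        }


def assess_overlap(ps: pd.DataFrame, bins: int = 20) -> OverlapReport:
    """Compare the two arms' PS distributions (support, KS, densities)."""
    groups = {int(a): g["ps"].to_numpy() for a, g in ps.groupby("arm")}
    if set(groups) != {0, 1}:
        raise ValueError("both arms must be present")
    lo = max(g.min() for g in groups.values())
    hi = min(g.max() for g in groups.values())
    ks = scipy.stats.ks_2samp(groups[0], groups[1])
    edges = np.linspace(0.0, 1.0, bins + 1)
    summaries, hists, outside = {}, {}, {}
    for a, g in groups.items():
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        summaries[str(a)] = {
            "n": int(g.size),
            "min": float(g.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(g.max()),
            "mean": float(g.mean()),
            "skewness": float(scipy.stats.skew(g)) if g.size > 2 else 0.0,
        }
        hists[str(a)] = (edges, np.histogram(g, bins=edges)[0])
        outside[str(a)] = float(np.mean((g < lo) | (g > hi)))
    return OverlapReport(
        support=(float(lo), float(hi)),
        frac_outside=outside,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        summaries=summaries,
        histograms=hists,
    )
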