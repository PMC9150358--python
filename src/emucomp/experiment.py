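"""End-to-end analysis grid and the positivity sensitivity analysis.

The default grid crosses the four outcomes with every balancing/censoring
strategy of the comparison protocol: three matching calipers (0.02, 0.1,
0.2 SD of the PS) x two causal contrasts x pairwise censoring on/off, plus
two weighting schemes (stabilized IPTW for ATE, odds for ATT) x two
contrasts — 16 designs per outcome, 64 cells in all.  Each cell runs
cohort -> propensity -> balancing -> windows -> outcomes -> estimation;
failures are isolated per cell.

The positivity sensitivity analysis re-runs a grid subset twice on the same
registry: restricted to index dates after the control drug became available
(the primary analysis) and unrestricted (admitting the pre-availability era
in which only the treated drug could be started), and reports how the PS
distributions and the effect estimates shift.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from . import cohort as cohort_mod
from .balancing import MatchedCohort, WeightedCohort, balance_table, compute_weights, match_greedy
from .contrasts import censor_pairwise, make_windows
from .estimation import EstimateResult, fit_cox_hr, fit_nb_irr
from .outcomes import OUTCOMES, outcome_table
from .propensity import assess_overlap, fit_ps_model
from .registry import RegistryTables

CALIPERS = (0.02, 0.1, 0.2)
DEFAULT_WEIGHT_SCHEMES = ("siptw", "odds")
#: outcomes whose models are adjusted for annualized visit density
DENSITY_ADJUSTED = ("worsening", "improvement")


@dataclass(frozen=True)
class AnalysisDesign:
    """One cell of the analysis grid."""

    outcome: str
    ps_method: str  # match | siptw | iptw | odds
    contrast: str  # itt | per_protocol
    caliper: float | None = None  # match only
    pairwise: bool = False  # match only
    seed: int = 0

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.ps_method not in ("match", "siptw", "iptw", "odds"):
            raise ValueError(f"unknown ps_method {self.ps_method!r}")
        if self.contrast not in ("itt", "per_protocol"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.ps_method == "match" and self.caliper is None:
            raise ValueError("matching requires a caliper")
        if self.ps_method != "match" and self.caliper is not None:
            raise ValueError("caliper is only valid with matching")
        if self.pairwise and self.ps_method != "match":
            raise ValueError("pairwise censoring requires a matched design")

    @property
    def estimand(self) -> str:
        return "ATT" if self.ps_method in ("match", "odds") else "ATE"

    def label(self) -> str:
        parts = [self.outcome, self.ps_method]
        if self.ps_method == "match":
            parts.append(f"caliper={self.caliper}")
        parts.append(self.contrast)
        if self.pairwise:
            parts.append("pairwise")
        return "|".join(parts)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["estimand"] = self.estimand
        return d


def default_grid(outcomes=OUTCOMES, calipers=CALIPERS, schemes=DEFAULT_WEIGHT_SCHEMES, seed=0):
    """The full crossing: 16 designs per outcome (64 cells for 4 outcomes)."""
    cells = []
    for outcome in outcomes:
        for caliper in calipers:
            for contrast in ("itt", "per_protocol"):
                for pairwise in (False, True):
                    cells.append(
                        AnalysisDesign(outcome, "match", contrast, caliper, pairwise, seed)
                    )
        for scheme in schemes:
            for contrast in ("itt", "per_protocol"):
                cells.append(AnalysisDesign(outcome, scheme, contrast, seed=seed))
    return cells


@dataclass
class GridResults:
    estimates: list  # (AnalysisDesign, EstimateResult) pairs
    failures: list  # (AnalysisDesign, reason)
    balance: dict  # design-family label -> balance DataFrame
    overlap: object
    ps: pd.DataFrame
    baseline: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for design, est in self.estimates:
            rows.append(
                {
                    **design.to_dict(),
                    "measure": est.measure,
                    "point": est.point,
                    "ci_lo": est.ci95[0],
                    "ci_hi": est.ci95[1],
                    "se_log": est.se_log,
                    "n_used": est.n_used,
                    "variance_method": est.variance_method,
                }
            )
        return pd.DataFrame(rows)

    def estimate(self, **query) -> EstimateResult:
        """The single estimate whose design matches all query fields."""
        hits = [
            est
            for design, est in self.estimates
            if all(getattr(design, k) == v for k, v in query.items())
        ]
        if len(hits) != 1:
            raise KeyError(f"{len(hits)} estimates match {query}")
        return hits[0]


def _match_seed(master: int, caliper_index: int) -> int:
    return (master * 7919 + caliper_index) % (2**31 - 1)


def run_grid(
    registry: RegistryTables,
    grid=None,
    seed: int = 0,
    availability_day: float = 0.0,
    allow_pre_era: bool = False,
    use_random_country: bool = False,
) -> GridResults:
    """Execute the analysis grid on a registry."""
    grid = list(grid) if grid is not None else default_grid(seed=seed)
    baseline, report = cohort_mod.build_cohort(registry, availability_day, allow_pre_era)
    if baseline.empty:
        raise ValueError("no eligible patients")
    ps_model = fit_ps_model(baseline, use_random_country=use_random_country)
    ps = ps_model.predict(baseline)
    overlap = assess_overlap(ps)
    last_record = registry.last_record_day()

    calipers = sorted({d.caliper for d in grid if d.caliper is not None})
    matched = {
        cal: match_greedy(ps, cal, _match_seed(seed, i)) for i, cal in enumerate(calipers)
    }
    schemes = {d.ps_method for d in grid if d.ps_method != "match"}
    weighted = {s: compute_weights(ps, s) for s in schemes}

    balance = {"unadjusted": balance_table(baseline, None)}
    for cal, m in matched.items():
        balance[f"match|caliper={cal}"] = balance_table(baseline, m)
    for s, w in weighted.items():
        balance[s] = balance_table(baseline, w)

    base_windows = {k: make_windows(baseline, last_record, k) for k in ("itt", "per_protocol")}
    outcomes_needed = tuple(o for o in OUTCOMES if any(d.outcome == o for d in grid))
    outcome_cache: dict = {}

    def records_for(contrast: str, pairwise_caliper):
        key = (contrast, pairwise_caliper)
        if key not in outcome_cache:
            win = base_windows[contrast]
            if pairwise_caliper is not None:
                win = censor_pairwise(win, matched[pairwise_caliper])
            outcome_cache[key] = outcome_table(
                registry.visits, registry.relapses, baseline, win, outcomes=outcomes_needed
            )
        return outcome_cache[key]

    estimates, failures = [], []
    for design in grid:
        try:
            pw_cal = design.caliper if design.pairwise else None
            records = records_for(design.contrast, pw_cal)
            records = records[records["outcome"] == design.outcome]
            dsg = matched[design.caliper] if design.ps_method == "match" else weighted[design.ps_method]
            if design.outcome == "relapse_count":
                est = fit_nb_irr(records, dsg)
            else:
                est = fit_cox_hr(
                    records, dsg, adjust_visit_density=design.outcome in DENSITY_ADJUSTED
                )
            est.design = design.to_dict()
            estimates.append((design, est))
        except Exception as exc:  # cell isolation
            failures.append((design, f"{type(exc).__name__}: {exc}"))

    meta = {
        "seed": seed,
        "n_eligible": int(len(baseline)),
        "n_cells": len(grid),
        "n_failures": len(failures),
        "excluded_counts": report.excluded_counts,
        "allow_pre_era": allow_pre_era,
        "grid_hash": hashlib.md5(
            json.dumps([d.to_dict() for d in grid], sort_keys=True).encode()
        ).hexdigest(),
    }
    return GridResults(estimates, failures, balance, overlap, ps, baseline, meta)


@dataclass
class PositivityResult:
    restricted: GridResults
    unrestricted: GridResults
    diagnostics: dict

    def shift_table(self) -> pd.DataFrame:
        """Log-scale estimate shifts between the unrestricted and restricted runs."""
        rows = []
        for (design, est_r) in self.restricted.estimates:
            try:
                est_u = self.unrestricted.estimate(
                    outcome=design.outcome,
                    ps_method=design.ps_method,
                    contrast=design.contrast,
                    caliper=design.caliper,
                    pairwise=design.pairwise,
                )
            except KeyError:
                continue
            rows.append(
                {
                    "label": design.label(),
                    "restricted": est_r.point,
                    "unrestricted": est_u.point,
                    "log_shift": float(np.log(est_u.point) - np.log(est_r.point)),
                }
            )
        return pd.DataFrame(rows)


def sensitivity_grid(seed: int = 0):
    """Table-6-style subset: every outcome x {caliper-0.1 matching, sIPTW} x contrast."""
    cells = []
    for outcome in OUTCOMES:
        for contrast in ("itt", "per_protocol"):
            cells.append(AnalysisDesign(outcome, "match", contrast, 0.1, False, seed))
            cells.append(AnalysisDesign(outcome, "siptw", contrast, seed=seed))
    return cells


def run_positivity_sensitivity(
    registry: RegistryTables,
    grid=None,
    seed: int = 0,
    availability_day: float = 0.0,
    use_random_country: bool = False,
) -> PositivityResult:
    """Paired restricted / unrestricted runs quantifying a positivity violation."""
    index_all = cohort_mod.assign_index(registry, availability_day, allow_pre_era=True)
    if not (index_all["index_day"] < availability_day).any():
        raise ValueError("registry has no pre-availability index episodes")
    grid = list(grid) if grid is not None else sensitivity_grid(seed)
    restricted = run_grid(
        registry, grid, seed, availability_day, allow_pre_era=False,
        use_random_country=use_random_country,
    )
    unrestricted = run_grid(
        registry, grid, seed, availability_day, allow_pre_era=True,
        use_random_country=use_random_country,
    )
    diag = {"ks_between_arms": {
        "restricted": restricted.overlap.ks_statistic,
        "unrestricted": unrestricted.overlap.ks_statistic,
    }}
    for arm in (0, 1):
        r = restricted.ps.loc[restricted.ps["arm"] == arm, "ps"]
        u = unrestricted.ps.loc[unrestricted.ps["arm"] == arm, "ps"]
        ks = scipy.stats.ks_2samp(r, u)
        diag[f"ks_shift_arm{arm}"] = float(ks.statistic)
        diag[f"skewness_arm{arm}"] = {
            "restricted": float(scipy.stats.skew(r)),
            "unrestricted": float(scipy.stats.skew(u)),
        }
    # the Fig-S1-style signature: within the unrestricted cohort, treated
    # patients indexed before availability sit lower on the PS scale than
    # post-availability treated patients (left-skew shift of the treated arm)
    merged = unrestricted.ps.merge(
        unrestricted.baseline[["patient_id", "index_day"]], on="patient_id"
    )
    treated = merged[merged["arm"] == 1]
    pre = treated.loc[treated["index_day"] < availability_day, "ps"]
    post = treated.loc[treated["index_day"] >= availability_day, "ps"]
    diag["treated_pre_vs_post"] = {
        "n_pre": int(pre.size),
        "ks": float(scipy.stats.ks_2samp(pre, post).statistic) if pre.size and post.size else 0.0,
        "median_pre": float(pre.median()) if pre.size else np.nan,
        "median_post": float(post.median()) if post.size else np.nan,
    }
    return PositivityResult(restricted, unrestricted, diag)


def export_reports(results: GridResults, out_dir, plots: bool = False) -> list:
    """Write forest/balance/overlap artifacts; returns the paths written."""
    if not results.estimates:
        raise ValueError("no estimates to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    forest = results.to_frame()
    forest_path = out / "forest.csv"
    forest.to_csv(forest_path, index=False)
    written.append(forest_path)

    bal = pd.concat(
        [frame.assign(design=label) for label, frame in results.balance.items()],
        ignore_index=True,
    )
    bal_path = out / "balance.csv"
    bal.to_csv(bal_path, index=False)
    written.append(bal_path)

    overlap_path = out / "overlap.json"
    overlap_path.write_text(json.dumps(results.overlap.to_dict(), indent=2))
    written.append(overlap_path)

    density = []
    for arm, (edges, counts) in results.overlap.histograms.items():
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            density.append({"arm": arm, "bin_lo": lo, "bin_hi": hi, "count": c})
    density_path = out / "ps_density.csv"
    pd.DataFrame(density).to_csv(density_path, index=False)
    written.append(density_path)

    meta_path = out / "run_metadata.json"
    meta_path.write_text(
        json.dumps({**results.meta, "written_at": time.strftime("%Y-%m-%dT%H:%M:%S")}, indent=2)
    )
    written.append(meta_path)

    if plots:
        written += _render_plots(results, out)
    return written


def _render_plots(results: GridResults, out: Path) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    frame = results.to_frame()
    fig, ax = plt.subplots(figsize=(7, max(4, 0.25 * len(frame))))
    ys = np.arange(len(frame))
    ax.errorbar(
        frame["point"], ys,
        xerr=[frame["point"] - frame["ci_lo"], frame["ci_hi"] - frame["point"]],
        fmt="o", ms=3, lw=1,
    )
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_xscale("log")
    labels = [AnalysisDesign(**{k: r[k] for k in
              ("outcome", "ps_method", "contrast", "caliper", "pairwise")}).label()
              for r in frame.to_dict("records")]
    ax.set_yticks(ys, labels, fontsize=6)
    ax.set_xlabel("effect (ratio scale)")
    fig.tight_layout()
    path = out / "forest.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots()
    for arm, g in results.ps.groupby("arm"):
        ax.hist(g["ps"], bins=30, alpha=0.5, density=True, label=f"arm {arm}")
    ax.set_xlabel("propensity score")
    ax.legend()
    path = out / "ps_density.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)
    return written
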