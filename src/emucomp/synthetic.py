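"""Seeded synthetic two-drug MS registry with known ground truth.

The generator emulates the statistical structure a comparative-effectiveness
analysis of natalizumab-vs-fingolimod registry data must cope with:

* confounding by indication — treatment assignment follows a logistic model
  on the baseline covariate set (sex, age, MS duration, EDSS band, prior
  relapses, prior treatments, prior clinical activity) with country-level
  intercepts, so the treated drug is preferred for active/disabled patients;
* relapses as a (gamma-frailty) Poisson process whose rate is multiplied by
  the true incidence-rate ratio while treated;
* confirmed EDSS worsening/improvement driven by latent proportional-hazards
  event times, realized on the half-point EDSS grid at irregular visits,
  with transient relapse-adjacent EDSS bumps so the 30-day confirmation
  exclusion rule is exercised;
* informative treatment discontinuation whose log-hazard rises with each
  on-treatment relapse;
* an optional pre-availability era in which every indexed patient starts the
  treated drug (structural positivity violation) and relapse rates carry a
  calendar-time shift invisible to the propensity covariates.

Pre-index histories are built so the covariates the cohort stage re-derives
from the tables reproduce the generating covariates exactly: pre-index
visits are noise-free, a drawn prior-worsening is manifested as a sustained
pre-index EDSS step that the confirmed-change detector recovers, and drawn
prior relapse counts are realized inside the 12-month lookback window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig, PSCoefficients, TrueEffects
from .outcomes import worsening_threshold, improvement_threshold, DAYS_PER_YEAR
from .registry import RegistryTables, ORIGIN_YEAR

ACTIVITY_LEVELS = ("none", "worsening", "relapse", "relapse_and_worsening")

_EDSS_BAND_VALUES = (
    np.array([0.0, 1.0, 1.5]),
    np.array([2.0, 2.5, 3.0, 3.5]),
    np.array([4.0, 4.5, 5.0, 5.5, 6.0, 6.5]),
)

_PRIOR_DRUGS = ("interferon_beta", "glatiramer_acetate", "teriflunomide", "dimethyl_fumarate")


@dataclass
class GroundTruth:
    """Per-patient generating quantities, for validating downstream stages."""

    table: pd.DataFrame  # one row per patient
    true_effects: TrueEffects

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def edss_band(edss: np.ndarray) -> np.ndarray:
    """Band index of the balance tables: <2 -> 0, 2-3.5 -> 1, >=4 -> 2."""
    edss = np.asarray(edss, dtype=float)
    return np.where(edss < 2.0, 0, np.where(edss < 4.0, 1, 2))


def linear_predictor(
    coef: PSCoefficients,
    *,
    female,
    age,
    ms_duration,
    edss_band,
    relapse_band,
    prior_tx_band,
    activity,
    country_intercept=0.0,
):
    """Assignment-model linear predictor on the banded covariate coding."""
    edss_band = np.asarray(edss_band, dtype=int)
    relapse_band = np.asarray(relapse_band, dtype=int)
    prior_tx_band = np.asarray(prior_tx_band, dtype=int)
    activity = np.asarray(activity, dtype=int)
    return (
        coef.intercept
        + coef.female * np.asarray(female, dtype=float)
        + coef.age_per_year * (np.asarray(age, dtype=float) - 38.0)
        + coef.ms_duration_per_year * (np.asarray(ms_duration, dtype=float) - 7.0)
        + np.asarray(coef.edss_band)[edss_band]
        + np.asarray(coef.relapse_band)[relapse_band]
        + np.asarray(coef.prior_tx_band)[prior_tx_band]
        + np.asarray(coef.activity)[activity]
        + country_intercept
    )


def assign_treatment(covariates: dict, era_flag: bool, coefficients: PSCoefficients, rng):
    """Draw the treatment arm for one patient; returns ``(arm, true_ps)``.

    ``covariates`` must provide female, age, ms_duration, edss_band,
    relapse_band, prior_tx_band, activity and (optionally)
    country_intercept.  During the pre-availability era the control drug
    cannot be prescribed: the arm is treated with probability one.
    """
    required = {"female", "age", "ms_duration", "edss_band", "relapse_band", "prior_tx_band", "activity"}
    missing = required - set(covariates)
    if missing:
        raise ValueError(f"missing covariates for assignment: {sorted(missing)}")
    if era_flag:
        return 1, 1.0
    lp = float(
        linear_predictor(
            coefficients,
            country_intercept=covariates.get("country_intercept", 0.0),
            **{k: covariates[k] for k in required},
        )
    )
    ps = 1.0 / (1.0 + math.exp(-lp))
    return int(rng.random() < ps), ps


def simulate_relapse_process(
    arm: int,
    rate_per_year: float,
    true_effects: TrueEffects,
    window_days: float,
    rng,
    frailty: float = 1.0,
) -> np.ndarray:
    """Homogeneous Poisson relapse onsets over ``(0, window_days]``.

    The rate is ``rate_per_year * frailty`` multiplied by the true IRR when
    ``arm`` is treated; drawing ``frailty`` from a gamma distribution makes
    the marginal counts negative binomial.
    """
    if window_days <= 0:
        raise ValueError("window_days must be > 0")
    rate = rate_per_year / DAYS_PER_YEAR * frailty
    if arm:
        rate *= true_effects.irr_relapse
    n = rng.poisson(rate * window_days)
    return np.sort(rng.uniform(0.0, window_days, size=n))


def simulate_discontinuation(
    arm: int,
    relapse_days,
    rng,
    *,
    hazard_per_year: float,
    dependence: float = 0.0,
    min_exposure_days: float = 90.0,
):
    """Sample a discontinuation day, or None if treatment never stops.

    The hazard is zero before ``min_exposure_days`` (sub-three-month starts
    are not index episodes), then piecewise constant, multiplied by
    ``exp(dependence)`` for every on-treatment relapse so far.  With
    ``dependence == 0`` censoring is non-informative.
    """
    if hazard_per_year < 0:
        raise ValueError("hazard must be >= 0")
    if hazard_per_year == 0:
        return None
    h0 = hazard_per_year / DAYS_PER_YEAR
    relapses = np.sort(np.asarray(relapse_days, dtype=float))
    target = rng.exponential()
    t = min_exposure_days
    k = int(np.sum(relapses <= t))
    acc = 0.0
    while True:
        h = h0 * math.exp(dependence * k)
        t_next = relapses[k] if k < relapses.size and relapses[k] > t else math.inf
        if t_next is math.inf or acc + h * (t_next - t) >= target:
            return t + (target - acc) / h
        acc += h * (t_next - t)
        t = t_next
        k += 1


def _joint_relapse_disc(rate_on, rate_off, disc_h, dependence, min_exposure, followup, rng):
    """Jointly simulate relapse onsets and discontinuation (per-day rates).

    ``rate_on`` applies before discontinuation, ``rate_off`` after — they
    differ only when the treatment effect ends at discontinuation.  The
    discontinuation log-hazard rises by ``dependence`` per relapse so far.
    """
    t = 0.0
    relapses: list[float] = []
    disc = None
    while t < followup:
        lam = rate_on if disc is None else rate_off
        t_rel = t + rng.exponential() / lam if lam > 0 else math.inf
        if disc is None and disc_h > 0:
            h = disc_h * math.exp(dependence * len(relapses))
            t_disc = max(t, min_exposure) + rng.exponential() / h
        else:
            t_disc = math.inf
        t_next = min(t_rel, t_disc)
        if t_next >= followup:
            break
        if t_rel <= t_disc:
            relapses.append(t_rel)
        else:
            disc = t_disc
        t = t_next
    return np.array(relapses), disc


def _latent_event_time(hazard_per_day: float, multiplier: float, break_day: float, rng) -> float:
    """First event of a two-piece hazard: h*multiplier before ``break_day``, h after."""
    if hazard_per_day <= 0:
        return math.inf
    target = rng.exponential()
    cum_break = hazard_per_day * multiplier * break_day
    if target < cum_break or not math.isfinite(break_day):
        return target / (hazard_per_day * multiplier)
    return break_day + (target - cum_break) / hazard_per_day


def simulate_edss_trajectory(
    baseline_edss: float,
    arm: int,
    true_effects: TrueEffects,
    visit_days,
    relapse_days,
    rng,
    *,
    worsening_hazard_per_year: float = 0.0,
    improvement_hazard_per_year: float = 0.0,
    latent_worsening_day: float | None = None,
    latent_improvement_day: float | None = None,
    noise_prob: float = 0.0,
    relapse_bump: float = 1.0,
    effect_break_day: float = math.inf,
):
    """EDSS scores at the given visits; returns ``(edss, t_worsening, t_improvement)``.

    Latent sustained worsening occurs with hazard scaled by
    ``true_effects.hr_worsening`` while treated (improvement analogously);
    a forced latent day may be supplied instead.  From the latent day on,
    the trajectory steps by exactly the confirmation threshold for the
    baseline score.  Visits within 30 days after a relapse onset receive a
    transient bump, and measurement noise flips scores by half a step with
    probability ``noise_prob``.  Scores are clipped to the 0-10 half-point
    grid.
    """
    if baseline_edss < 0 or baseline_edss > 10 or (baseline_edss * 2) % 1 != 0:
        raise ValueError("baseline EDSS must lie on the half-point grid 0-10")
    days = np.asarray(visit_days, dtype=float)
    if days.size and np.any(np.diff(days) < 0):
        raise ValueError("visit days must be sorted")
    if latent_worsening_day is None:
        latent_worsening_day = _latent_event_time(
            worsening_hazard_per_year / DAYS_PER_YEAR,
            true_effects.hr_worsening if arm else 1.0,
            effect_break_day,
            rng,
        )
    if latent_improvement_day is None:
        latent_improvement_day = _latent_event_time(
            improvement_hazard_per_year / DAYS_PER_YEAR,
            true_effects.hr_improvement if arm else 1.0,
            effect_break_day,
            rng,
        )
    step_i = improvement_threshold(baseline_edss)
    if step_i is None:
        latent_improvement_day = math.inf  # improvement undefined below EDSS 1.5
    # the trajectory realizes whichever latent transition comes first; the
    # later one is masked so each declared hazard ratio remains the truth
    # for the event the trajectory can actually display
    if latent_worsening_day <= latent_improvement_day:
        latent_improvement_day = math.inf
    else:
        latent_worsening_day = math.inf
    edss = np.full(days.size, float(baseline_edss))
    if days.size:
        edss[days >= latent_worsening_day] += worsening_threshold(baseline_edss)
        if step_i is not None:
            edss[days >= latent_improvement_day] -= step_i
    relapses = np.asarray(relapse_days, dtype=float)
    if relapses.size and days.size and relapse_bump:
        since = days[:, None] - relapses[None, :]
        bumped = np.any((since > 0) & (since <= 30.0), axis=1)
        edss[bumped] += relapse_bump
    if noise_prob > 0 and days.size:
        flip = rng.random(days.size) < noise_prob
        edss[flip] += rng.choice([-0.5, 0.5], size=int(flip.sum()))
    edss = np.clip(np.round(edss * 2.0) / 2.0, 0.0, 10.0)
    return edss, latent_worsening_day, latent_improvement_day


def _worsened_from(edss: float) -> float | None:
    """Pre-worsening EDSS whose worsening threshold lands exactly on ``edss``."""
    for pre in np.arange(0.0, 10.01, 0.5):
        thr = worsening_threshold(float(pre))
        if abs(pre + thr - edss) < 1e-9:
            return float(pre)
    return None


def generate_registry(config: SimulationConfig):
    """Generate a seeded synthetic registry; returns ``(RegistryTables, GroundTruth)``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cov = config.covariate_params
    rates = config.event_rates
    disc_cfg = config.discontinuation
    sched = config.visit_schedule
    effects = config.true_effects

    # ---- baseline covariates -------------------------------------------
    country_idx = rng.choice(len(config.countries), size=n, p=[c.proportion for c in config.countries])
    country_labels = np.array([c.label for c in config.countries])[country_idx]
    country_icpt = np.array([c.intercept for c in config.countries])[country_idx]
    female = (rng.random(n) < cov.female_prop).astype(int)
    age = np.clip(rng.normal(cov.age_mean, cov.age_sd, n), *cov.age_range)
    duration = np.clip(
        rng.lognormal(cov.ms_duration_log_mean, cov.ms_duration_log_sd, n), *cov.ms_duration_range
    )
    band = rng.choice(3, size=n, p=cov.edss_band_probs)
    edss0 = np.array([rng.choice(_EDSS_BAND_VALUES[b]) for b in band])
    relapse_band = rng.choice(4, size=n, p=cov.prior_relapse_probs)
    prior_tx = rng.choice(4, size=n, p=cov.prior_treatment_probs)
    w_prob = np.where(relapse_band > 0, cov.worsening_prob_relapse, cov.worsening_prob_no_relapse)
    worsened = rng.random(n) < w_prob
    pre_edss = np.array(
        [
            (lambda p: np.nan if p is None else p)(_worsened_from(e)) if w else np.nan
            for e, w in zip(edss0, worsened)
        ],
        dtype=float,
    )
    worsened &= ~np.isnan(pre_edss)  # worsening must be displayable on the grid
    activity = np.where(
        relapse_band > 0, np.where(worsened, 3, 2), np.where(worsened, 1, 0)
    ).astype(int)

    # ---- era and index dates -------------------------------------------
    pre_era = np.zeros(n, dtype=bool)
    if config.era.enabled and config.era.pre_era_fraction > 0:
        pre_era = rng.random(n) < config.era.pre_era_fraction
    index_day = rng.integers(0, int(config.index_window_days) + 1, size=n).astype(float)
    lo, hi = config.era.pre_era_window_days
    index_day[pre_era] = np.floor(rng.uniform(lo, hi, size=int(pre_era.sum())))

    # ---- treatment assignment ------------------------------------------
    lp = linear_predictor(
        config.ps_coefficients,
        female=female,
        age=age,
        ms_duration=duration,
        edss_band=band,
        relapse_band=relapse_band,
        prior_tx_band=prior_tx,
        activity=activity,
        country_intercept=country_icpt,
    )
    true_ps = 1.0 / (1.0 + np.exp(-lp))
    arm = (rng.random(n) < true_ps).astype(int)
    arm[pre_era] = 1
    true_ps = np.where(pre_era, 1.0, true_ps)

    # ---- outcome-process intensities -----------------------------------
    frailty = (
        rng.gamma(1.0 / rates.frailty_var, rates.frailty_var, n)
        if rates.frailty_var > 0
        else np.ones(n)
    )
    base_rate = (
        rates.relapse_rate_per_year
        * np.exp(
            np.asarray(rates.relapse_log_rate_by_band)[relapse_band]
            + np.asarray(rates.relapse_log_rate_by_edss)[band]
        )
        * frailty
    )
    base_rate = np.where(pre_era, base_rate * config.era.pre_rate_multiplier, base_rate)
    w_hazard = rates.worsening_hazard_per_year * np.exp(
        np.asarray(rates.worsening_log_hazard_by_edss)[band]
    )
    followup = np.round(rng.uniform(*config.followup_years, size=n) * DAYS_PER_YEAR)
    density_mult = rng.uniform(*sched.density_range, size=n)

    patient_rows, visit_rows, relapse_rows, treatment_rows, truth_rows = [], [], [], [], []
    for i in range(n):
        pid = f"P{i + 1:06d}"
        idx = index_day[i]
        fup = followup[i]

        # pre-index visit history (noise-free; reproduces drawn covariates)
        b0 = -float(rng.integers(3, 21))
        jit = rng.integers(-8, 9, size=5).astype(float)
        pre_days = np.array([-350.0, -300.0, -210.0, -120.0, -60.0]) + jit
        if worsened[i]:
            pre_vals = np.array([pre_edss[i], pre_edss[i], edss0[i], edss0[i], edss0[i]])
        else:
            pre_vals = np.full(5, edss0[i])
        pre_days = np.append(pre_days, b0)
        pre_vals = np.append(pre_vals, edss0[i])

        # pre-index relapses inside the 12-month lookback window
        k = int(relapse_band[i])
        pre_relapses = np.sort(rng.integers(-360, -54, size=k)).astype(float)

        # on-study relapses and discontinuation (joint, possibly informative)
        rate = base_rate[i] / DAYS_PER_YEAR
        rate_on = rate * (effects.irr_relapse if arm[i] else 1.0)
        rate_off = rate if config.effect_on_treatment_only else rate_on
        disc_h = (
            disc_cfg.hazard_treated_per_year if arm[i] else disc_cfg.hazard_control_per_year
        ) / DAYS_PER_YEAR
        study_relapses, disc = _joint_relapse_disc(
            rate_on, rate_off, disc_h, disc_cfg.dependence, disc_cfg.min_exposure_days, fup, rng
        )
        study_relapses = np.unique(np.maximum(1.0, np.round(study_relapses)))
        if disc is not None:
            disc = float(np.round(disc))

        # post-index visit schedule
        gap = sched.mean_gap_days * density_mult[i]
        post_days = [float(sched.first_visit_day + rng.integers(-10, 11))]
        while True:
            nxt = post_days[-1] + gap + float(rng.normal(0.0, sched.jitter_days))
            if nxt > fup:
                break
            post_days.append(float(np.round(max(nxt, post_days[-1] + 7.0))))
        post_days = np.array(post_days)

        # EDSS trajectory with latent proportional-hazards events
        break_day = (
            disc
            if (config.effect_on_treatment_only and arm[i] and disc is not None)
            else math.inf
        )
        post_edss, t_w, t_i = simulate_edss_trajectory(
            float(edss0[i]),
            int(arm[i]),
            effects,
            post_days,
            study_relapses,
            rng,
            worsening_hazard_per_year=float(w_hazard[i]),
            improvement_hazard_per_year=rates.improvement_hazard_per_year,
            noise_prob=sched.noise_prob,
            relapse_bump=sched.relapse_bump,
            effect_break_day=break_day,
        )

        # tables (absolute days)
        birth_year = int(np.round(ORIGIN_YEAR + idx / DAYS_PER_YEAR - age[i]))
        onset_day = idx - float(np.round(duration[i] * DAYS_PER_YEAR))
        patient_rows.append(
            (pid, "F" if female[i] else "M", birth_year, onset_day, country_labels[i], country_labels[i])
        )
        for d, v in zip(np.concatenate([pre_days, post_days]), np.concatenate([pre_vals, post_edss])):
            visit_rows.append((pid, idx + d, v))
        for d in np.concatenate([pre_relapses, study_relapses]):
            relapse_rows.append((pid, idx + d))

        # prior DMT episodes, index episode, optional post-discontinuation switch
        for j in range(int(prior_tx[i])):
            end = idx - (30.0 + 330.0 * j)
            treatment_rows.append((pid, _PRIOR_DRUGS[j % len(_PRIOR_DRUGS)], end - 270.0, end))
        drug = "natalizumab" if arm[i] else "fingolimod"
        ep_end = idx + disc if disc is not None else np.nan
        treatment_rows.append((pid, drug, idx, ep_end))
        if disc is not None and rng.random() < disc_cfg.switch_prob:
            switch_start = disc + float(rng.integers(14, 91))
            if switch_start < fup:
                next_drug = (
                    ("fingolimod" if arm[i] else "natalizumab")
                    if rng.random() < 0.5
                    else "dimethyl_fumarate"
                )
                treatment_rows.append((pid, next_drug, idx + switch_start, np.nan))

        truth_rows.append(
            {
                "patient_id": pid,
                "arm": int(arm[i]),
                "true_ps": float(true_ps[i]),
                "pre_era": bool(pre_era[i]),
                "index_day": idx,
                "followup_day": fup,
                "disc_day": disc if disc is not None else np.nan,
                "latent_worsening_day": t_w,
                "latent_improvement_day": t_i,
                "frailty": float(frailty[i]),
                "female": int(female[i]),
                "age": float(age[i]),
                "ms_duration": float(duration[i]),
                "baseline_edss": float(edss0[i]),
                "edss_band": int(band[i]),
                "relapse_band": int(relapse_band[i]),
                "prior_tx_band": int(prior_tx[i]),
                "activity": ACTIVITY_LEVELS[activity[i]],
                "country": country_labels[i],
            }
        )

    tables = RegistryTables(
        patients=pd.DataFrame(
            patient_rows, columns=["patient_id", "sex", "birth_year", "onset_date", "country", "source"]
        ),
        visits=pd.DataFrame(visit_rows, columns=["patient_id", "date", "edss"]),
        relapses=pd.DataFrame(relapse_rows, columns=["patient_id", "date"]),
        treatments=pd.DataFrame(
            treatment_rows, columns=["patient_id", "drug", "start_date", "end_date"]
        ),
        meta={"seed": config.seed, "n_patients": n},
    )
    tables.validate()
    truth = GroundTruth(pd.DataFrame(truth_rows), effects)
    return tables, truth
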