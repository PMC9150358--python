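"""Configuration of the synthetic registry generator.

The defaults encode the study conditions of the combined three-registry
natalizumab-vs-fingolimod cohort they emulate: baseline covariate marginals
(sex, age, MS duration, EDSS band, prior relapses, prior treatments, prior
clinical activity, data source), confounding by indication (the treated drug
preferred for active and disabled patients), a ~39% marginal treated
fraction, irregular visit schedules, informative treatment discontinuation,
and an optional pre-availability era in which only the treated drug could be
prescribed (a structural positivity violation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass
class Country:
    label: str
    intercept: float  # additive log-odds shift in the assignment model
    proportion: float


@dataclass
class CovariateParams:
    """Baseline covariate distribution at the index date."""

    female_prop: float = 0.72
    age_mean: float = 37.5
    age_sd: float = 9.5
    age_range: tuple[float, float] = (18.0, 70.0)
    # Log-normal MS duration (years since first symptoms), median ~6.9 y.
    ms_duration_log_mean: float = 1.93
    ms_duration_log_sd: float = 0.9
    ms_duration_range: tuple[float, float] = (0.3, 35.0)
    # EDSS bands: <2, 2-3.5, >=4
    edss_band_probs: tuple[float, float, float] = (0.30, 0.46, 0.24)
    # Relapses in the prior 12 months: 0, 1, 2, 3+
    prior_relapse_probs: tuple[float, ...] = (0.36, 0.39, 0.19, 0.06)
    # Number of previous DMT episodes: 0, 1, 2, 3+
    prior_treatment_probs: tuple[float, ...] = (0.16, 0.50, 0.23, 0.11)
    # Probability of a confirmed-worsening episode in the prior 12 months,
    # conditional on the prior-relapse indicator (Table-style activity mix).
    worsening_prob_no_relapse: float = 0.22
    worsening_prob_relapse: float = 0.34


@dataclass
class PSCoefficients:
    """Log-odds coefficients of the treatment-assignment (indication) model.

    Age and MS duration enter linearly (centred at 38 y and 7 y); EDSS,
    prior-relapse and prior-treatment counts enter as the categorical bands
    the balance tables use; prior activity is a 4-level factor.
    """

    # calibrated so the marginal treated fraction is ~39%, the study's split
    intercept: float = -1.16
    female: float = 0.05
    age_per_year: float = -0.015
    ms_duration_per_year: float = -0.02
    edss_band: tuple[float, float, float] = (0.0, 0.5, 0.8)
    relapse_band: tuple[float, float, float, float] = (0.0, 0.3, 0.7, 1.0)
    prior_tx_band: tuple[float, float, float, float] = (0.0, -0.25, -0.25, -0.2)
    # activity levels: none, worsening only, relapse only, relapse+worsening
    activity: tuple[float, float, float, float] = (0.0, 0.3, 0.1, 0.4)


@dataclass
class TrueEffects:
    """Treated-vs-control effect ratios used by the generating processes.

    The relapse process is a single point process, so the incidence-rate
    ratio and the first-relapse hazard ratio are one and the same quantity;
    both fields exist for symmetry with the downstream estimators and must
    agree.
    """

    irr_relapse: float = 1.0
    hr_relapse: float = 1.0
    hr_worsening: float = 1.0
    hr_improvement: float = 1.0


@dataclass
class EventRates:
    """Baseline outcome-process intensities (control arm, reference bands)."""

    relapse_rate_per_year: float = 0.35
    # log-rate shifts per prior-relapse band (confounding path to outcome)
    relapse_log_rate_by_band: tuple[float, float, float, float] = (0.0, 0.2, 0.4, 0.6)
    relapse_log_rate_by_edss: tuple[float, float, float] = (0.0, 0.05, 0.10)
    # Gamma frailty variance; >0 gives negative-binomial marginal counts.
    frailty_var: float = 0.2
    worsening_hazard_per_year: float = 0.08
    worsening_log_hazard_by_edss: tuple[float, float, float] = (0.0, 0.10, 0.20)
    improvement_hazard_per_year: float = 0.12


@dataclass
class Discontinuation:
    """Per-drug discontinuation hazards with optional outcome dependence.

    Discontinuation cannot occur before day 90 (patients persisting less
    than three months are not index cases).  ``dependence`` is the log-hazard
    increase per on-treatment relapse; 0 gives non-informative censoring.
    """

    hazard_treated_per_year: float = 0.22
    hazard_control_per_year: float = 0.22
    dependence: float = 0.0
    min_exposure_days: float = 90.0
    # probability of starting some further DMT after discontinuation
    switch_prob: float = 0.5


@dataclass
class VisitSchedule:
    mean_gap_days: float = 90.0
    jitter_days: float = 15.0
    first_visit_day: float = 45.0
    # per-patient multiplicative spread of visit frequency
    density_range: tuple[float, float] = (0.7, 1.4)
    # transient EDSS measurement noise (+/- 0.5 step) at post-index visits
    noise_prob: float = 0.05
    # transient EDSS bump at visits within 30 days after a relapse onset
    relapse_bump: float = 1.0


@dataclass
class Era:
    """Pre-availability era (positivity violation) switch.

    When enabled, ``pre_era_fraction`` of patients are indexed before the
    control drug became available; they can only start the treated drug.
    ``pre_rate_multiplier`` is a calendar-time shift of the relapse rate in
    that era, invisible to the propensity covariates.
    """

    enabled: bool = False
    pre_era_fraction: float = 0.25
    pre_era_window_days: tuple[float, float] = (-1460.0, -90.0)
    pre_rate_multiplier: float = 1.5


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    seed: int = 0
    countries: tuple[Country, ...] = (
        Country("msbase", -0.10, 0.64),
        Country("dmsr", 0.25, 0.28),
        Country("ofsep", 0.45, 0.08),
    )
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    ps_coefficients: PSCoefficients = field(default_factory=PSCoefficients)
    true_effects: TrueEffects = field(default_factory=TrueEffects)
    event_rates: EventRates = field(default_factory=EventRates)
    discontinuation: Discontinuation = field(default_factory=Discontinuation)
    visit_schedule: VisitSchedule = field(default_factory=VisitSchedule)
    era: Era = field(default_factory=Era)
    # index dates uniform on [0, index_window_days] after availability
    index_window_days: float = 2000.0
    # administrative follow-up (years) uniform on this range
    followup_years: tuple[float, float] = (1.5, 5.0)
    # does the treated-drug effect stop at discontinuation?
    effect_on_treatment_only: bool = False

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        props = [c.proportion for c in self.countries]
        if abs(sum(props) - 1.0) > 1e-8 or any(p < 0 for p in props):
            raise ValueError("countries: proportions must be non-negative and sum to 1")
        for name, probs in [
            ("edss_band_probs", self.covariate_params.edss_band_probs),
            ("prior_relapse_probs", self.covariate_params.prior_relapse_probs),
            ("prior_treatment_probs", self.covariate_params.prior_treatment_probs),
        ]:
            if abs(sum(probs) - 1.0) > 1e-8 or any(p < 0 for p in probs):
                raise ValueError(f"covariate_params.{name} must be a probability vector")
        eff = self.true_effects
        for name in ("irr_relapse", "hr_relapse", "hr_worsening", "hr_improvement"):
            if getattr(eff, name) <= 0:
                raise ValueError(f"true_effects.{name} must be > 0")
        if eff.irr_relapse != eff.hr_relapse:
            raise ValueError(
                "true_effects: irr_relapse and hr_relapse describe the same relapse "
                "point process and must be equal"
            )
        if not (0.0 <= self.era.pre_era_fraction <= 1.0):
            raise ValueError("era.pre_era_fraction must be in [0, 1]")
        if self.discontinuation.hazard_treated_per_year < 0 or (
            self.discontinuation.hazard_control_per_year < 0
        ):
            raise ValueError("discontinuation hazards must be >= 0")
        if self.event_rates.frailty_var < 0:
            raise ValueError("event_rates.frailty_var must be >= 0")
        if self.followup_years[0] <= 0 or self.followup_years[1] < self.followup_years[0]:
            raise ValueError("followup_years must be an increasing positive range")
        if self.visit_schedule.mean_gap_days <= 0:
            raise ValueError("visit_schedule.mean_gap_days must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def null_config(n_patients: int = 1000, seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with all treatment effects at the null (ratios 1)."""
    cfg = SimulationConfig(n_patients=n_patients, seed=seed, **overrides)
    cfg.true_effects = TrueEffects(1.0, 1.0, 1.0, 1.0)
    return cfg


def effect_config(
    n_patients: int = 1000,
    seed: int = 0,
    irr_relapse: float = 0.7,
    hr_worsening: float = 0.7,
    hr_improvement: float = 1.3,
    **overrides,
) -> SimulationConfig:
    """A configuration with treated-drug benefit on relapses and disability."""
    cfg = SimulationConfig(n_patients=n_patients, seed=seed, **overrides)
    cfg.true_effects = TrueEffects(irr_relapse, irr_relapse, hr_worsening, hr_improvement)
    return cfg
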