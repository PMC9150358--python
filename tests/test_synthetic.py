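"""Generator: determinism, integrity, and recovery of the generating laws."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from lifelines import CoxPHFitter

from emucomp.config import (
    Discontinuation,
    PSCoefficients,
    SimulationConfig,
    TrueEffects,
    effect_config,
)
from emucomp.synthetic import (
    assign_treatment,
    generate_registry,
    simulate_discontinuation,
    simulate_edss_trajectory,
    simulate_relapse_process,
)

NULL_COEFS = PSCoefficients(
    intercept=0.0,
    female=0.0,
    age_per_year=0.0,
    ms_duration_per_year=0.0,
    edss_band=(0, 0, 0),
    relapse_band=(0, 0, 0, 0),
    prior_tx_band=(0, 0, 0, 0),
    activity=(0, 0, 0, 0),
)

BASE_COV = dict(
    female=1, age=38.0, ms_duration=7.0, edss_band=0, relapse_band=0, prior_tx_band=0, activity=0
)


def test_seeded_determinism_bytewise(tmp_path):
    cfg = SimulationConfig(n_patients=100, seed=1)
    out = []
    for run in ("a", "b"):
        tables, _ = generate_registry(cfg)
        tables.write(tmp_path / run)
        out.append(
            {name: (tmp_path / run / f"{name}.csv").read_bytes() for name in
             ("patients", "visits", "relapses", "treatments")}
        )
    assert out[0] == out[1]


def test_referential_integrity_and_episodes(small_registry):
    _, tables, _ = small_registry
    tables.validate()
    ids = set(tables.patients["patient_id"])
    study = tables.treatments[tables.treatments["drug"].isin(("natalizumab", "fingolimod"))]
    assert set(study["patient_id"]) == ids  # every patient has a study episode


def test_era_disabled_indexes_after_availability():
    tables, truth = generate_registry(SimulationConfig(n_patients=150, seed=3))
    assert (truth.table["index_day"] >= 0).all()
    study = tables.treatments[tables.treatments["drug"].isin(("natalizumab", "fingolimod"))]
    assert (study.groupby("patient_id")["start_date"].min() >= 0).all()


def test_era_enabled_pre_era_patients_all_treated():
    cfg = SimulationConfig(n_patients=400, seed=4)
    cfg.era.enabled = True
    _, truth = generate_registry(cfg)
    pre = truth.table[truth.table["pre_era"]]
    assert len(pre) > 0
    assert (pre["arm"] == 1).all()
    assert (pre["true_ps"] == 1.0).all()
    assert (pre["index_day"] < 0).all()
    post = truth.table[~truth.table["pre_era"]]
    assert ((post["true_ps"] > 0) & (post["true_ps"] < 1)).all()


def _broken(mutate):
    cfg = SimulationConfig()
    mutate(cfg)
    return cfg


@pytest.mark.parametrize(
    "mutate",
    [
        lambda c: setattr(c, "n_patients", 1),
        lambda c: setattr(c.era, "pre_era_fraction", 1.5),
        lambda c: setattr(c.covariate_params, "edss_band_probs", (0.5, 0.5, 0.5)),
        lambda c: setattr(c.discontinuation, "hazard_treated_per_year", -0.1),
        lambda c: setattr(c.visit_schedule, "mean_gap_days", 0.0),
        lambda c: setattr(c, "followup_years", (2.0, 1.0)),
    ],
)
def test_config_validation_rejects_bad_fields(mutate):
    with pytest.raises(ValueError):
        _broken(mutate).validate()


def test_config_requires_coherent_relapse_effects():
    cfg = SimulationConfig()
    cfg.true_effects = TrueEffects(0.7, 0.9, 1.0, 1.0)
    with pytest.raises(ValueError, match="hr_relapse"):
        cfg.validate()
    cfg.true_effects = TrueEffects(0.7, 0.7, -1.0, 1.0)
    with pytest.raises(ValueError, match="hr_worsening"):
        cfg.validate()


def test_assign_treatment_null_model_gives_half():
    rng = np.random.default_rng(0)
    arm, ps = assign_treatment(BASE_COV, False, NULL_COEFS, rng)
    assert ps == 0.5
    assert arm in (0, 1)


def test_assign_treatment_era_forces_treated():
    rng = np.random.default_rng(0)
    for _ in range(20):
        arm, ps = assign_treatment(BASE_COV, True, NULL_COEFS, rng)
        assert arm == 1 and ps == 1.0


def test_assign_treatment_intercept_calibration_anchor():
    # inverse-logit(-0.447) reproduces the study's 39% treated marginal
    coefs = PSCoefficients(**{**NULL_COEFS.__dict__, "intercept": -0.447})
    _, ps = assign_treatment(BASE_COV, False, coefs, np.random.default_rng(1))
    assert ps == pytest.approx(0.39, abs=0.005)


def test_assign_treatment_rejects_missing_covariate():
    cov = dict(BASE_COV)
    del cov["edss_band"]
    with pytest.raises(ValueError, match="edss_band"):
        assign_treatment(cov, False, NULL_COEFS, np.random.default_rng(0))


def test_relapse_process_zero_rate_and_sorted():
    rng = np.random.default_rng(0)
    assert simulate_relapse_process(1, 0.0, TrueEffects(), 365.0, rng).size == 0
    days = simulate_relapse_process(0, 3.0, TrueEffects(), 1000.0, rng)
    assert np.all(np.diff(days) >= 0) and np.all((days > 0) & (days <= 1000.0))


def test_relapse_process_recovers_rate_ratio():
    # 10,000 patient-years per arm at 0.5/yr, IRR 0.7: empirical ratio within 0.05
    rng = np.random.default_rng(5)
    effects = TrueEffects(0.7, 0.7, 1.0, 1.0)
    window = 5 * 365.25
    counts = {0: 0, 1: 0}
    for arm in (0, 1):
        for _ in range(2000):
            counts[arm] += simulate_relapse_process(arm, 0.5, effects, window, rng).size
    ratio = counts[1] / counts[0]
    assert ratio == pytest.approx(0.7, abs=0.05)


def test_relapse_process_null_effect_equal_rates():
    rng = np.random.default_rng(6)
    window = 2 * 365.25
    counts = {0: 0, 1: 0}
    for arm in (0, 1):
        for _ in range(2000):
            counts[arm] += simulate_relapse_process(arm, 0.5, TrueEffects(), window, rng).size
    assert counts[1] / counts[0] == pytest.approx(1.0, abs=0.07)


def test_discontinuation_zero_hazard_never_stops():
    assert simulate_discontinuation(1, [100.0], np.random.default_rng(0), hazard_per_year=0.0) is None


def test_discontinuation_noninformative_when_dependence_zero():
    rng = np.random.default_rng(7)
    times, nrel = [], []
    for _ in range(2000):
        rel = simulate_relapse_process(0, 0.8, TrueEffects(), 1500.0, rng)
        t = simulate_discontinuation(0, rel, rng, hazard_per_year=0.4, dependence=0.0)
        times.append(t if t is not None else 1e6)
        nrel.append(rel.size)
    r = np.corrcoef(times, nrel)[0, 1]
    assert abs(r) < 0.06


def test_discontinuation_informative_shifts_distribution():
    rng = np.random.default_rng(8)
    times, nrel = [], []
    for _ in range(2000):
        rel = simulate_relapse_process(0, 0.8, TrueEffects(), 730.0, rng)
        t = simulate_discontinuation(0, rel, rng, hazard_per_year=0.3, dependence=0.8)
        times.append(t if t is not None else 4000.0)
        nrel.append(rel.size)
    times, nrel = np.array(times), np.array(nrel)
    many, none = times[nrel >= 2], times[nrel == 0]
    stat = scipy.stats.mannwhitneyu(many, none, alternative="less")
    assert stat.pvalue < 1e-6


def test_edss_trajectory_constant_without_events():
    days = np.arange(30, 720, 90.0)
    edss, tw, ti = simulate_edss_trajectory(
        3.0, 1, TrueEffects(), days, [], np.random.default_rng(0)
    )
    assert np.all(edss == 3.0)
    assert not np.isfinite(tw) and not np.isfinite(ti)


def test_edss_trajectory_forced_worsening_steps_up():
    days = np.arange(30, 720, 60.0)
    edss, *_ = simulate_edss_trajectory(
        2.0, 0, TrueEffects(), days, [], np.random.default_rng(0), latent_worsening_day=100.0
    )
    assert np.all(edss[days >= 100] >= 3.0)
    assert np.all(edss[days < 100] == 2.0)


def test_edss_trajectory_rejects_off_grid_baseline():
    with pytest.raises(ValueError):
        simulate_edss_trajectory(2.3, 0, TrueEffects(), [100.0], [], np.random.default_rng(0))


def test_edss_trajectory_relapse_bump_is_transient():
    days = np.array([20.0, 40.0, 100.0])
    edss, *_ = simulate_edss_trajectory(
        2.0, 0, TrueEffects(), days, [15.0], np.random.default_rng(0), relapse_bump=1.0
    )
    assert edss[0] == 3.0 and edss[1] == 3.0 and edss[2] == 2.0


def test_latent_worsening_hazard_ratio_recovered():
    # hr_worsening 0.5: unadjusted Cox on latent times recovers ~0.5
    rng = np.random.default_rng(9)
    effects = TrueEffects(1.0, 1.0, 0.5, 1.0)
    rows = []
    days = np.arange(90, 1100, 90.0)
    for i in range(4000):
        arm = i % 2
        _, tw, _ = simulate_edss_trajectory(
            3.0, arm, effects, days, [], rng,
            worsening_hazard_per_year=0.15, improvement_hazard_per_year=0.0,
        )
        t = min(tw, 1096.0)
        rows.append({"T": t, "E": int(tw <= 1096.0), "arm": float(arm)})
    fit = CoxPHFitter().fit(pd.DataFrame(rows), "T", "E")
    assert np.exp(fit.params_["arm"]) == pytest.approx(0.5, abs=0.08)


def test_assignment_model_recovered_by_refit():
    # refit logistic regression on the generator's own covariates: the
    # confounding coefficients come back within 2 SE and the fitted PS
    # separates the arms in the confounded direction
    cfg = SimulationConfig(n_patients=5000, seed=13)
    _, truth = generate_registry(cfg)
    t = truth.table
    X = pd.DataFrame(
        {
            "female": t["female"],
            "age": t["age"] - 38.0,
            "ms_duration": t["ms_duration"] - 7.0,
            "edss_1": (t["edss_band"] == 1).astype(float),
            "edss_2": (t["edss_band"] == 2).astype(float),
            "rel_1": (t["relapse_band"] == 1).astype(float),
            "rel_2": (t["relapse_band"] == 2).astype(float),
            "rel_3": (t["relapse_band"] == 3).astype(float),
        }
    )
    fit = sm.Logit(t["arm"], sm.add_constant(X)).fit(disp=0)
    coef = cfg.ps_coefficients
    for name, true_val in [
        ("age", coef.age_per_year),
        ("edss_2", coef.edss_band[2]),
        ("rel_2", coef.relapse_band[2]),
        ("rel_3", coef.relapse_band[3]),
    ]:
        assert abs(fit.params[name] - true_val) < 2 * fit.bse[name] + 0.05
    fitted = fit.predict()
    assert fitted[t["arm"] == 1].mean() > fitted[t["arm"] == 0].mean()
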