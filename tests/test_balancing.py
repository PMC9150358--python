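"""Matching, weighting and covariate-balance metrics."""

import numpy as np
import pandas as pd
import pytest

from emucomp.balancing import (
    balance_table,
    compute_weights,
    match_greedy,
)


def _ps_frame(treated_ps, control_ps):
    rows = [("t%d" % i, 1, p) for i, p in enumerate(treated_ps)]
    rows += [("c%d" % i, 0, p) for i, p in enumerate(control_ps)]
    return pd.DataFrame(rows, columns=["patient_id", "arm", "ps"])


def greedy_oracle(ps: pd.DataFrame, caliper_sd: float, seed: int):
    """Step-by-step pure-python greedy matcher (independent of the library path)."""
    rng = np.random.default_rng(seed)
    treated = ps[ps["arm"] == 1].reset_index(drop=True)
    control = ps[ps["arm"] == 0].reset_index(drop=True)
    caliper = caliper_sd * float(np.std(ps["ps"].to_numpy(), ddof=1))
    order = list(rng.permutation(len(treated)))
    used = set()
    pairs = []
    for ti in order:
        tp = float(treated.loc[ti, "ps"])
        best_d, best_j = None, None
        for j in range(len(control)):
            if j in used:
                continue
            d = abs(float(control.loc[j, "ps"]) - tp)
            if best_d is None or d < best_d:
                best_d, best_j = d, j
        if best_d is None or best_d > caliper:
            continue
        used.add(best_j)
        pairs.append((treated.loc[ti, "patient_id"], control.loc[best_j, "patient_id"], best_d))
    return pairs


class TestMatchGreedy:
    def test_nearest_neighbour_chosen(self):
        ps = _ps_frame([0.5], [0.48, 0.6])
        m = match_greedy(ps, caliper_sd=10.0, seed=0)
        assert list(m.pairs["control_id"]) == ["c0"]

    def test_caliper_excludes_distant_controls(self):
        ps = _ps_frame([0.5], [0.8])
        m = match_greedy(ps, caliper_sd=0.1, seed=0)
        assert m.pairs.empty and m.unmatched_treated == ["t0"]

    def test_oracle_equivalence_on_random_instance(self):
        rng = np.random.default_rng(42)
        ps = _ps_frame(rng.uniform(0, 1, 20), rng.uniform(0, 1, 30))
        m = match_greedy(ps, caliper_sd=0.2, seed=7)
        oracle = greedy_oracle(ps, 0.2, seed=7)
        got = set(zip(m.pairs["treated_id"], m.pairs["control_id"]))
        assert got == {(t, c) for t, c, _ in oracle}

    def test_empty_control_pool_warns(self):
        ps = _ps_frame([0.4, 0.6], [])
        with pytest.warns(UserWarning, match="empty control pool"):
            m = match_greedy(ps, caliper_sd=0.2, seed=0)
        assert m.pairs.empty

    def test_each_patient_used_at_most_once(self, small_ps):
        m = match_greedy(small_ps, 0.2, seed=3)
        ids = np.concatenate([m.pairs["treated_id"], m.pairs["control_id"]])
        assert len(ids) == len(set(ids))
        assert (m.pairs["ps_distance"] <= m.caliper_absolute).all()

    def test_stable_under_id_relabeling(self, small_ps):
        m1 = match_greedy(small_ps, 0.2, seed=5)
        mapping = {pid: f"z{i}" for i, pid in enumerate(small_ps["patient_id"])}
        relabeled = small_ps.assign(patient_id=small_ps["patient_id"].map(mapping))
        m2 = match_greedy(relabeled, 0.2, seed=5)
        assert list(m2.pairs["treated_id"]) == [mapping[t] for t in m1.pairs["treated_id"]]
        assert list(m2.pairs["control_id"]) == [mapping[c] for c in m1.pairs["control_id"]]

    def test_tighter_caliper_never_more_pairs(self, small_ps):
        counts = [len(match_greedy(small_ps, cal, seed=1).pairs) for cal in (0.02, 0.1, 0.2)]
        assert counts == sorted(counts)

    def test_deterministic_given_seed(self, small_ps):
        a = match_greedy(small_ps, 0.2, seed=9).pairs
        b = match_greedy(small_ps, 0.2, seed=9).pairs
        assert a.equals(b)


class TestWeights:
    def test_formulas_at_half(self):
        ps = _ps_frame([0.5], [0.5])
        assert compute_weights(ps, "iptw").weights.tolist() == [2.0, 2.0]
        odds = compute_weights(ps, "odds").weights
        assert odds.loc["t0"] == 1.0 and odds.loc["c0"] == pytest.approx(1.0)

    def test_stabilization_arithmetic(self):
        # treated p=0.8 with marginal treated fraction 0.4 -> 0.4/0.8 = 0.5
        ps = _ps_frame([0.8], [0.3, 0.3, 0.3])
        w = compute_weights(ps, "siptw").weights
        assert w.loc["t0"] == pytest.approx(0.25 / 0.8)
        ps2 = pd.concat([_ps_frame([0.8, 0.7], [0.3, 0.3, 0.3])])
        w2 = compute_weights(ps2, "siptw").weights
        assert w2.loc["t0"] == pytest.approx(0.4 / 0.8)

    def test_odds_control_weight(self):
        ps = _ps_frame([0.5], [0.25])
        w = compute_weights(ps, "odds").weights
        assert w.loc["c0"] == pytest.approx(1.0 / 3.0)

    def test_scheme_estimand_mapping(self, small_ps):
        assert compute_weights(small_ps, "iptw").estimand == "ATE"
        assert compute_weights(small_ps, "siptw").estimand == "ATE"
        assert compute_weights(small_ps, "odds").estimand == "ATT"
        with pytest.raises(ValueError):
            compute_weights(small_ps, "trimmed")

    def test_degenerate_ps_cites_positivity(self):
        ps = _ps_frame([1.0], [0.5])
        with pytest.raises(ValueError, match="positivity"):
            compute_weights(ps, "iptw")

    def test_siptw_and_iptw_share_weighted_means(self, small_cohort, small_ps):
        baseline, _ = small_cohort
        x = baseline.set_index("patient_id")["age_at_index"]
        for arm in (0, 1):
            ids = baseline.loc[baseline["arm"] == arm, "patient_id"]
            means = []
            for scheme in ("iptw", "siptw"):
                w = compute_weights(small_ps, scheme).weights.loc[ids]
                means.append(np.average(x.loc[ids], weights=w))
            assert means[0] == pytest.approx(means[1])


class TestBalanceTable:
    def test_identical_arms_have_zero_distance(self):
        block = pd.DataFrame(
            {
                "patient_id": [f"a{i}" for i in range(40)],
                "arm": 0,
                "sex": ["F", "M"] * 20,
                "age_at_index": np.linspace(25, 55, 40),
                "ms_duration": np.linspace(1, 20, 40),
                "baseline_edss": [1.0, 2.0, 4.0, 5.0] * 10,
                "n_relapses_prior_12m": [0, 1, 2, 3] * 10,
                "n_prior_treatments": [0, 1] * 20,
                "prior_activity": ["none", "relapse"] * 20,
                "country": ["msbase", "dmsr"] * 20,
            }
        )
        mirror = block.assign(arm=1, patient_id=[f"b{i}" for i in range(40)])
        table = balance_table(pd.concat([block, mirror], ignore_index=True))
        assert (table["before"].abs() < 1e-9).all()

    def test_smd_formula_unit_difference(self):
        rng = np.random.default_rng(0)
        n = 4000
        base = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(2 * n)],
                "arm": [1] * n + [0] * n,
                "sex": "F",
                "age_at_index": np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)]),
                "ms_duration": 5.0,
                "baseline_edss": 2.0,
                "n_relapses_prior_12m": 0,
                "n_prior_treatments": 0,
                "prior_activity": "none",
                "country": "msbase",
            }
        )
        table = balance_table(base).set_index("covariate")
        assert table.loc["age", "before"] == pytest.approx(1.0, abs=0.08)

    def test_zero_variance_unequal_means_is_infinite(self):
        base = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c", "d"],
                "arm": [1, 1, 0, 0],
                "sex": "F",
                "age_at_index": [40.0, 40.0, 30.0, 30.0],
                "ms_duration": 5.0,
                "baseline_edss": 2.0,
                "n_relapses_prior_12m": 0,
                "n_prior_treatments": 0,
                "prior_activity": "none",
                "country": "msbase",
            }
        )
        table = balance_table(base).set_index("covariate")
        assert np.isinf(table.loc["age", "before"]) and table.loc["age", "flagged"]

    def test_designs_improve_balance_on_confounded_cohort(self, small_cohort, small_ps):
        baseline, _ = small_cohort
        before = balance_table(baseline)["before"]
        for design in (
            compute_weights(small_ps, "siptw"),
            compute_weights(small_ps, "odds"),
            match_greedy(small_ps, 0.2, seed=0),
        ):
            table = balance_table(baseline, design)
            assert table["after"].mean() < before.mean()


def test_odds_weighting_targets_treated_distribution():
    # ATT property: odds-weighted control covariate means approach the
    # unweighted treated means on a large correctly-specified cohort
    from emucomp.config import SimulationConfig
    from emucomp.cohort import build_cohort
    from emucomp.propensity import fit_ps_model
    from emucomp.synthetic import generate_registry

    tables, _ = generate_registry(SimulationConfig(n_patients=4000, seed=23))
    baseline, _ = build_cohort(tables)
    ps = fit_ps_model(baseline).predict(baseline)
    w = compute_weights(ps, "odds").weights
    merged = baseline.set_index("patient_id")
    treated = merged[merged["arm"] == 1]
    control = merged[merged["arm"] == 0]
    t_mean = treated["n_relapses_prior_12m"].mean()
    c_mean = np.average(control["n_relapses_prior_12m"], weights=w.loc[control.index])
    c_raw = control["n_relapses_prior_12m"].mean()
    assert abs(c_mean - t_mean) < 0.1
    assert abs(c_mean - t_mean) < abs(c_raw - t_mean)
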