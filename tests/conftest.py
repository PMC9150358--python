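import pytest

from emucomp.config import effect_config
from emucomp.cohort import build_cohort
from emucomp.propensity import fit_ps_model
from emucomp.synthetic import generate_registry


@pytest.fixture(scope="session")
def small_registry():
    """A modest effectful registry shared by read-only tests."""
    cfg = effect_config(n_patients=400, seed=11)
    tables, truth = generate_registry(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def small_cohort(small_registry):
    _, tables, _ = small_registry
    baseline, report = build_cohort(tables)
    return baseline, report


@pytest.fixture(scope="session")
def small_ps(small_cohort):
    baseline, _ = small_cohort
    return fit_ps_model(baseline).predict(baseline)
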