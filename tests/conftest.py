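import numpy as np
import pytest
from hypothesis import settings

from qepsgrowth import run_pipeline, simulate_cohort
from qepsgrowth.fitting import predict_weight
from qepsgrowth.qeps_model import age_p5
from qepsgrowth.reference import IndividualCurve
from qepsgrowth.synthetic_cohort import CohortConfig, draw_individual

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, 30 subjects per sex."""
    return simulate_cohort(CohortConfig(n_per_sex=30, seed=7))


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    cohort, _ = small_cohort
    return run_pipeline(cohort)


@pytest.fixture(scope="session")
def recovery_pipeline():
    """Default-condition cohort at study scale (200/sex) plus its fits."""
    cohort, truth = simulate_cohort(CohortConfig(n_per_sex=200, seed=4))
    return cohort, truth, run_pipeline(cohort)


@pytest.fixture(scope="session")
def truth_weight_curves_500():
    """500 ground-truth female weight curves (no fitting, no noise)."""
    config = CohortConfig(n_per_sex=500, seed=5)
    curves = []
    for i in range(500):
        hp, whf = draw_individual(config, "F", i)
        wp = predict_weight(hp, config.female.alphas)
        curves.append(IndividualCurve(
            subject_id=f"F{i:04d}", params=wp, shape=config.shape["F"],
            whf=whf, age_p5=age_p5(hp)))
    return curves
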