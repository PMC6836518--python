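import math

import numpy as np
import pytest

from bridgesurv.baseline_lifetable import WeibullBaseline
from bridgesurv.cohort_synthesis import CohortSpec
from bridgesurv.hazard_model import Coefficient, CoefficientSet

# Published component hazard-ratio summaries (median and 95% interval) used
# throughout as lognormal calibration anchors: dysphagia presence and the
# walking-distance deficit contribution of a typical cohort (281 m).
DYS_HR = (1.61, 0.84, 3.50)
SIXMWD_HR = (2.48, 1.27, 5.00)
TYPICAL_DEFICIT_M = 281.0


def lognormal_params(median, lo, hi):
    """(mu, sigma) of a lognormal matched to a median and 95% interval."""
    mu = math.log(median)
    sigma = (math.log(hi) - math.log(lo)) / (2 * 1.96)
    return mu, sigma


@pytest.fixture(scope="session")
def weibull_585():
    return WeibullBaseline(sex="male", shape=5.0, scale=85.0)


@pytest.fixture(scope="session")
def baselines_pair():
    return {"male": WeibullBaseline(sex="male", shape=5.0, scale=85.0),
            "female": WeibullBaseline(sex="female", shape=5.2, scale=88.0)}


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def calibrated_coeffs():
    """Coefficient set with posterior-style samples calibrated to the
    published component summaries; six_mwd stored per metre of deficit."""
    rng = np.random.default_rng(2024)
    mu_d, sd_d = lognormal_params(*DYS_HR)
    mu_w, sd_w = lognormal_params(*SIXMWD_HR)
    n = 4000
    return CoefficientSet({
        "dysphagia": Coefficient(point=mu_d, samples=rng.normal(mu_d, sd_d, n)),
        "six_mwd": Coefficient(point=mu_w / TYPICAL_DEFICIT_M,
                               samples=rng.normal(mu_w, sd_w, n) / TYPICAL_DEFICIT_M,
                               per_unit="per metre lost"),
    })


@pytest.fixture
def effects_csv(tmp_path):
    path = tmp_path / "effects.csv"
    path.write_text(
        "study_label,predictor,hr,ci_lower,ci_upper,population_tag\n"
        "studyA,dysphagia,1.8,0.9,3.6,elderly\n"
        "studyB,dysphagia,1.4,0.7,2.8,neurodegenerative\n"
        "studyC,dysphagia,2.1,1.1,4.0,elderly\n"
        "studyD,dysphagia,1.5,0.6,3.7,elderly\n"
        "studyE,six_mwd,2.5,1.3,4.8,elderly\n"
        "studyF,falls,1.3,0.8,2.1,elderly\n"
    )
    return path
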