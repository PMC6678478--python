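import numpy as np
import pytest
from hypothesis import settings

from bloomlasso.design import FeatureDesign, Term
from bloomlasso.schema import FACTORS
from bloomlasso.survey_io import SurveyTable
from bloomlasso.synthetic import SyntheticConfig, generate_survey

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_survey() -> SurveyTable:
    """A 58-site synthetic survey with the published moment targets."""
    return generate_survey(SyntheticConfig(n=58, seed=11))


@pytest.fixture(scope="session")
def big_survey() -> SurveyTable:
    """A large synthetic survey for moment-convergence checks."""
    return generate_survey(SyntheticConfig(n=100_000, seed=11))


def toy_design(n=120, p=4, beta=None, noise=0.5, seed=0) -> FeatureDesign:
    """Small standardised regression design with known coefficients."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    if beta is None:
        beta = np.zeros(p)
    y = X @ np.asarray(beta, dtype=float) + rng.normal(0.0, noise, n)
    terms = [
        Term.of(FACTORS[3 + i]) if 3 + i < len(FACTORS) else Term.of(f"X{i:02d}")
        for i in range(p)
    ]
    return FeatureDesign(response_name="y", y=y, X=X, terms=terms)
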