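import numpy as np
import pandas as pd
import pytest

from growthtraj.growth_models import GrowthModel
from growthtraj.synthetic_data import DEFAULT_AGES
from growthtraj.trajectory_qtl import GenotypeMatrix

#: the irregular field-trial measurement schedule (years 4 and 8 skipped)
AGES = np.asarray(DEFAULT_AGES)

#: one representative valid parameter vector per growth law
REFERENCE_PARAMS = {
    GrowthModel.RICHARD: (30.0, 0.2, 2.0),
    GrowthModel.GOMPERTZ: (25.0, 3.0, 0.7),
    GrowthModel.LOGISTIC: (28.0, 6.0, 2.0),
    GrowthModel.ASYMPTOTIC: (30.0, 2.0, -1.5),
}


def random_params(model: GrowthModel, rng: np.random.Generator) -> np.ndarray:
    """Draw a random valid parameter vector in a realistic range."""
    if model is GrowthModel.RICHARD:
        return np.array([rng.uniform(5, 50), rng.uniform(0.05, 0.6), rng.uniform(0.3, 4.0)])
    if model is GrowthModel.GOMPERTZ:
        return np.array([rng.uniform(5, 50), rng.uniform(0.5, 5.0), rng.uniform(0.3, 0.95)])
    if model is GrowthModel.LOGISTIC:
        return np.array([rng.uniform(5, 50), rng.uniform(2, 9), rng.uniform(0.8, 4.0)])
    a = rng.uniform(5, 50)
    return np.array([a, rng.uniform(0.0, 0.5) * a, rng.uniform(-2.5, 0.5)])


def two_class_panel(n_per_class: int = 12) -> GenotypeMatrix:
    """A fixed balanced two-class genotype panel (ref-hom vs het) at one SNP."""
    n = 2 * n_per_class
    calls = pd.DataFrame(
        {"SNP1": ["A/A"] * n_per_class + ["A/G"] * n_per_class},
        index=[f"C{i + 1:03d}" for i in range(n)],
    )
    return GenotypeMatrix(calls=calls, alleles={"SNP1": ("A", "G")})


@pytest.fixture(scope="session")
def ages():
    return AGES.copy()


@pytest.fixture(scope="session")
def reference_params():
    return dict(REFERENCE_PARAMS)
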