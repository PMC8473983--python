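import numpy as np
import pandas as pd
import pytest

from gxereverse import ConfounderSpec, DesignSpec, GxEDataset, SplineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def toy_dataset():
    """n=4, no confounders, binary G crossed with D."""
    return GxEDataset(
        x=np.array([0.1, 0.7, -0.3, 1.2]),
        d=np.array([0, 1, 0, 1]),
        g=np.array([0.0, 0.0, 1.0, 1.0]),
    )


@pytest.fixture
def random_dataset(rng):
    """n=400 dataset with one continuous and one binary confounder."""
    n = 400
    z1 = rng.standard_normal(n)
    z2 = (rng.random(n) < 0.5).astype(float)
    g = rng.binomial(1, 0.3, n).astype(float)
    d = rng.binomial(1, 0.4, n).astype(float)
    x = 0.2 + 0.1 * z1 + 0.3 * z2 + 0.2 * g + 0.4 * d + 0.3 * g * d + rng.standard_normal(n)
    return GxEDataset(x=x, d=d.astype(int), g=g, covariates=pd.DataFrame({"z1": z1, "z2": z2}))


@pytest.fixture
def spline_design_spec():
    return DesignSpec(
        confounders=(
            ConfounderSpec("z1", is_continuous=True, spline=SplineConfig(3)),
            ConfounderSpec("z2", is_continuous=False),
        )
    )
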