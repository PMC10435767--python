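import numpy as np
import pandas as pd
import pytest

from glycanclock import simulate
from glycanclock.simulate import (
    CohortSpec,
    GroupLine,
    TraitTrendParams,
    default_weights,
)


def noiseless_trends(base: str = "FRA") -> TraitTrendParams:
    src = simulate.DEFAULT_TRENDS[base]
    return TraitTrendParams(
        lines={t: dict(g) for t, g in src.lines.items()},
        noise_sd={t: 0.0 for t in src.noise_sd},
        peak_log_sd=0.0,
        batch_sd=0.0,
    )


@pytest.fixture
def fra_spec() -> CohortSpec:
    return simulate.DEFAULT_COHORTS["FRA"]


@pytest.fixture
def small_spec() -> CohortSpec:
    return CohortSpec(
        name="FRA", n_control=40, n_ds=40,
        age_range_control=(22.0, 67.0), age_range_ds=(30.0, 67.0),
        n_plates=3,
    )


@pytest.fixture
def small_cohort(small_spec):
    return simulate.simulate_cohort(small_spec, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def toy_peak_table(n: int = 6, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.5, 10.0, size=(n, 24))
    df = pd.DataFrame(values, columns=[f"GP{i}" for i in range(1, 25)])
    df.index = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    return df
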