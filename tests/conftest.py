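import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nbsheets.io import run_analysis
from nbsheets.synthetic import WorldSpec, generate_world

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    """A 3-country × 2-year world with a 90%-of-requirement vitamin A target."""
    return generate_world(
        WorldSpec(seed=1, adequacy_targets={("C02", "vitamin_a"): 90.0})
    )


@pytest.fixture(scope="session")
def default_world():
    """The default (targetless) world: exact FCO shares, natural deficits."""
    return generate_world(WorldSpec(seed=7))


@pytest.fixture(scope="session")
def results(world):
    """Full pipeline outputs for the targeted world."""
    return run_analysis(
        world.flows,
        world.population,
        world.balance_inputs(),
        world.demographics,
        world.reproductive,
        world.drvs,
        world.body_weights,
    )


def merge_on(engine: pd.DataFrame, truth: pd.DataFrame, keys, col: str):
    """Align engine and ground-truth tables and return max relative error."""
    m = engine.merge(truth, on=list(keys), suffixes=("_e", "_g"))
    assert len(m) == len(engine) == len(truth), (
        f"row mismatch: engine={len(engine)} truth={len(truth)} joined={len(m)}"
    )
    denom = np.maximum(np.abs(m[f"{col}_g"]), 1e-12)
    return float((np.abs(m[f"{col}_e"] - m[f"{col}_g"]) / denom).max())
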