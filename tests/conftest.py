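import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lipidsens as ls

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_study() -> ls.SimulatedStudy:
    """One fully simulated two-mode study at the default conditions."""
    return ls.simulate_study(ls.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def positive_training(default_study):
    """Calibrated positive-mode training table of the default study."""
    cal = ls.calibrate_mode(default_study.panel, default_study.responses, "positive")
    X, y = ls.build_training_table(cal, default_study.descriptors)
    return cal, X, y


@pytest.fixture(scope="session")
def noise_free_study() -> ls.SimulatedStudy:
    from dataclasses import replace

    return ls.simulate_study(replace(ls.SimulationConfig(), noise_sd=0.0, seed=3))


@pytest.fixture()
def toy_panel_frame() -> pd.DataFrame:
    """Minimal hand-written two-mode panel table."""
    concs = {f"level_{i}": v for i, v in enumerate([1.0, 2.5, 7.5, 15.0, 30.0, 50.0], start=1)}
    rows = [
        dict(lipid_id="meth", name="methane", smiles="C", mode="positive",
             is_reference=False, **{"class": "X"}, **concs),
        dict(lipid_id="etoh", name="ethanol", smiles="CCO", mode="positive",
             is_reference=True, **{"class": "X"}, **concs),
        dict(lipid_id="prop", name="propane", smiles="CCC", mode="negative",
             is_reference=True, **{"class": "Y"}, **concs),
    ]
    return pd.DataFrame(rows)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
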