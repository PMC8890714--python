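from pathlib import Path

import numpy as np
import pytest

from capsulepk import PKParameters, load_parameters

REPO_ROOT = Path(__file__).resolve().parents[1]
CONFIG_DIR = REPO_ROOT / "configs"


def random_params(rng: np.random.Generator) -> PKParameters:
    """Log-uniform draw over a physiologically wide positive box."""
    return PKParameters(
        k_prod=10 ** rng.uniform(3.0, 5.0),
        k_trans=10 ** rng.uniform(-2.0, 1.0),
        k_clr=10 ** rng.uniform(2.0, 5.5),
        lambda_decay=10 ** rng.uniform(-1.3, 0.3),
        V1=10 ** rng.uniform(-0.3, 1.7),
        V2=10 ** rng.uniform(0.0, 3.7),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def human_config():
    params, thresholds = load_parameters(CONFIG_DIR / "human_synthetic_s6.yaml")
    return params, thresholds


@pytest.fixture(scope="session")
def nhp_config():
    params, thresholds = load_parameters(CONFIG_DIR / "nhp_synthetic_s6.yaml")
    return params, thresholds


@pytest.fixture(scope="session")
def mouse_config():
    params, thresholds = load_parameters(CONFIG_DIR / "mouse_synthetic_true.yaml")
    return params, thresholds
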