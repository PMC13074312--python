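import numpy as np
import pytest

from hspfit import FitConfig, load_library
from hspfit.datasets import (
    HESPERETIN_SPHERE,
    RESVERATROL_SPHERE,
    hesperetin_labels,
    resveratrol_labels,
)


@pytest.fixture(scope="session")
def study_library():
    return load_library("study")


@pytest.fixture(scope="session")
def resveratrol_sphere():
    return RESVERATROL_SPHERE


@pytest.fixture(scope="session")
def hesperetin_sphere():
    return HESPERETIN_SPHERE


@pytest.fixture(scope="session")
def resveratrol_label_set():
    return resveratrol_labels()


@pytest.fixture(scope="session")
def hesperetin_label_set():
    return hesperetin_labels()


@pytest.fixture()
def quick_fit_config():
    """Reduced optimizer budget: ample for the small problems in the suite."""

    def _make(seed: int = 42, **kw) -> FitConfig:
        kw.setdefault("n_restarts", 2)
        kw.setdefault("maxiter", 150)
        kw.setdefault("popsize", 15)
        return FitConfig(seed=seed, **kw)

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
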