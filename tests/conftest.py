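import numpy as np
import pytest

from morphofronts import (GradientSpec, HillParams, ScalarBistableParams,
                          ToggleParams, build_model)
from morphofronts.workbench import FIG5_FIXTURE, TOGGLE1_FIXTURE


def toggle1_params() -> ToggleParams:
    fx = TOGGLE1_FIXTURE
    return ToggleParams(a1=fx["a1"], a2=fx["a2"], beta=fx["beta"],
                        act=HillParams(fx["K_a"], fx["n_a"]),
                        rep=HillParams(fx["K_r"], fx["n_r"]))


@pytest.fixture(scope="session")
def toggle1_static():
    """Single-gradient toggle with the frozen fixture parameters (static)."""
    fx = TOGGLE1_FIXTURE
    g = GradientSpec(kind="static_exp", b=fx["b"], lam=fx["lam"])
    return build_model("toggle1", toggle1_params(), (g,), fx["L"])


@pytest.fixture(scope="session")
def toggle1_emerging():
    fx = TOGGLE1_FIXTURE
    g = GradientSpec(kind="emerging", b=fx["b"], lam=fx["lam"], gamma=0.5)
    return build_model("toggle1", toggle1_params(), (g,), fx["L"])


@pytest.fixture(scope="session")
def toggle1_decaying():
    fx = TOGGLE1_FIXTURE
    g = GradientSpec(kind="decaying", b=fx["b"], lam=fx["lam"], gamma=0.1)
    return build_model("toggle1", toggle1_params(), (g,), fx["L"])


@pytest.fixture(scope="session")
def fig5_model():
    """Symmetric two-morphogen toggle with antiparallel gradients."""
    fx = FIG5_FIXTURE
    p = ToggleParams(a1=fx["a"], a2=fx["a"], beta=fx["beta"],
                     act=HillParams(fx["K_a"], fx["n_a"]),
                     rep=HillParams(fx["K_r"], fx["n_r"]),
                     D1=fx["D1"], D2=fx["D2"])
    g1 = GradientSpec(kind="static_exp", b=fx["b"], lam=fx["lam"], source=0.0)
    g2 = GradientSpec(kind="static_exp", b=fx["b"], lam=fx["lam"],
                      source=fx["L"])
    return build_model("toggle2", p, (g1, g2), fx["L"])


@pytest.fixture()
def scalar_model():
    """Cubic bistable reaction with constant threshold (analytic oracle)."""
    return build_model("scalar",
                       ScalarBistableParams(D=0.1, alpha_field=0.3), (), 30.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
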