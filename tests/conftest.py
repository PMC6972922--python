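import numpy as np
import pytest

from marinefutures import (
    FoodWeb,
    FunctionalGroup,
    calibrate_dynamics,
    compute_ecopath_balance,
    kimberley_fixture,
)


def make_web(groups, diets):
    """Build a FoodWeb from (name, role, kwargs) tuples and a
    predator -> {prey: fraction} mapping."""
    gs = [FunctionalGroup(name, role, **kw) for name, role, kw in groups]
    idx = {g.name: i for i, g in enumerate(gs)}
    diet = np.zeros((len(gs), len(gs)))
    for pred, d in diets.items():
        for prey, f in d.items():
            diet[idx[prey], idx[pred]] = f
    return FoodWeb(gs, diet)


@pytest.fixture
def two_group_web():
    """Textbook hand-balanceable web: phyto eaten only by zooplankton."""
    return make_web(
        [
            ("phyto", "producer", dict(B0=10, PB=20)),
            ("zoop", "consumer", dict(B0=2, PB=5, QB=40, unassim=0.3)),
            ("detritus", "detritus", dict(B0=50)),
        ],
        {"zoop": {"phyto": 1.0}},
    )


@pytest.fixture
def chain_web():
    """Three-level chain (producer -> grazer -> predator) plus detritus."""
    return make_web(
        [
            ("algae", "producer", dict(B0=30, PB=25)),
            ("grazer", "consumer", dict(B0=8, PB=4, QB=16, unassim=0.3)),
            ("predator", "consumer",
             dict(B0=1.5, PB=0.8, QB=3.2, unassim=0.2,
                  F0_commercial=0.1, site_attachment=0.8)),
            ("detritus", "detritus", dict(B0=60)),
        ],
        {
            "grazer": {"algae": 0.8, "detritus": 0.2},
            "predator": {"grazer": 1.0},
        },
    )


@pytest.fixture(scope="session")
def fixture_web():
    web, indicators, sens = kimberley_fixture()
    return web, indicators, sens


@pytest.fixture(scope="session")
def fixture_balanced(fixture_web):
    web, indicators, sens = fixture_web
    bw = compute_ecopath_balance(web)
    dp = calibrate_dynamics(bw, 1.5)
    return web, bw, dp, indicators, sens
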