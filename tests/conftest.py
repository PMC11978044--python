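import numpy as np
import pytest

from stenoflow import FluidProperties, make_case, solve_steady


@pytest.fixture(scope="session")
def newtonian_tube():
    """Converged Newtonian Poiseuille flow in a straight tube (small grid)."""
    cfg = make_case("healthy", fluid=FluidProperties.newtonian(0.00345),
                    resolution=(24, 96))
    flow, hist = solve_steady(cfg)
    assert hist.converged
    return cfg, flow, hist


@pytest.fixture(scope="session")
def stenosed_s60():
    """Converged Williamson flow through a 60% stenosis (small grid)."""
    cfg = make_case("s60", resolution=(24, 96))
    flow, hist = solve_steady(cfg)
    assert hist.converged
    return cfg, flow, hist
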