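import numpy as np
import pytest

from allokit.exchange import ExchangeParams, FieldContext, r2eff_bloch_mcconnell
from allokit.dispersion import DispersionCurve
from allokit.simulate import ScenarioSpec


@pytest.fixture
def field_900() -> FieldContext:
    return FieldContext(900.0)


@pytest.fixture
def field_600() -> FieldContext:
    return FieldContext(600.0)


@pytest.fixture
def nu_grid() -> np.ndarray:
    """Refocusing grid starting at the 50 Hz reporting point."""
    return np.arange(50.0, 1001.0, 50.0)


@pytest.fixture
def scenario() -> ScenarioSpec:
    return ScenarioSpec(seed=0)


def make_curves(
    truth: ExchangeParams,
    seed: int,
    nu_grid: np.ndarray,
    sigma: float = 0.3,
    fields=(600.0, 900.0),
    residue_id: str = "X1",
) -> list[DispersionCurve]:
    """Noisy curves from the numerical propagator (never the closed form)."""
    rng = np.random.default_rng(seed)
    curves = []
    for mhz in fields:
        fctx = FieldContext(mhz)
        clean = r2eff_bloch_mcconnell(truth, nu_grid, fctx)
        curves.append(
            DispersionCurve(
                residue_id, fctx, nu_grid,
                clean + rng.normal(0.0, sigma, nu_grid.size),
                np.full(nu_grid.size, sigma),
            )
        )
    return curves
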