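import numpy as np
import pytest

from methanokinetics.gas_model import GasComposition, VesselSpec
from methanokinetics.synthetic import SimParams, simulate_closed_batch


@pytest.fixture
def vessel() -> VesselSpec:
    """160 mL vessel, 60 mL liquid, 65 degC incubation."""
    return VesselSpec(v_total=0.160, v_liquid=0.060, t_incubation=338.15)


@pytest.fixture
def four_to_one() -> GasComposition:
    return GasComposition()


@pytest.fixture(scope="session")
def clean_run():
    """One noise-free simulated conversion with its truth record (shared)."""
    params = SimParams(sigma_noise=0.0)
    series, od, truth = simulate_closed_batch(params, duration=48.0)
    return params, series, od, truth


def species_oracle(n0: float, comp: GasComposition, xi: float) -> dict[str, float]:
    """Independent species table for 4 H2 + CO2 -> CH4 + 2 H2O at extent xi.

    Tracks every species explicitly (water condensed, so it leaves the gas
    phase); used to cross-check the pressure-based shortcuts in gas_model.
    """
    return {
        "h2": n0 * comp.x_h2 - 4.0 * xi,
        "co2": n0 * comp.x_co2 - xi,
        "ch4": n0 * comp.x_ch4 + xi,
        "other": n0 * comp.x_other,
        "h2o_liquid": 2.0 * xi,
    }


def gas_moles(table: dict[str, float]) -> float:
    return table["h2"] + table["co2"] + table["ch4"] + table["other"]
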