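import numpy as np
import pytest

import mitoscreen as ms


@pytest.fixture(scope="session")
def default_field():
    """One default-noise synthetic field with 12 cells and its truth."""
    return ms.simulate_field(12, seed=42)


@pytest.fixture(scope="session")
def separated_field():
    """A sparse field whose perinuclear networks cannot overlap."""
    params = ms.SimulationParams(min_separation_px=40.0,
                                 border_margin_px=20.0)
    return ms.simulate_field(6, params=params, seed=11), params


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def two_condition_layout(fields_per_well=10, with_background=True):
    wells = [
        ms.WellSpec("B02", "basal", "negative_control"),
        ms.WellSpec("B03", "basal", "negative_control"),
        ms.WellSpec("C02", "oxldl", "treatment"),
        ms.WellSpec("C03", "oxldl", "treatment"),
    ]
    if with_background:
        wells.append(ms.WellSpec("G02", "background", "background_well"))
    return ms.PlateLayout(wells=tuple(wells), fields_per_well=fields_per_well)
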