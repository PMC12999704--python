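import numpy as np
import pytest

import polyauxic as px


@pytest.fixture
def diauxic_truth() -> px.KineticModel:
    """Well-separated two-phase Gompertz reference model."""
    return px.KineticModel(
        "gompertz",
        0.0,
        1.0,
        [px.PhaseParams(0.4, 5.0, 0.05), px.PhaseParams(0.6, 40.0, 0.02)],
    )


@pytest.fixture
def mono_gompertz() -> px.KineticModel:
    return px.KineticModel("gompertz", 0.0, 1.0, [px.PhaseParams(1.0, 5.0, 0.05)])


@pytest.fixture
def mono_boltzmann() -> px.KineticModel:
    return px.KineticModel("boltzmann", 0.0, 1.0, [px.PhaseParams(1.0, 5.0, 0.05)])


def make_dataset(model, noise_sd=0.01, seed=0, n_points=60, t_end=None, **kw):
    grid = (
        np.linspace(0.0, t_end, n_points)
        if t_end is not None
        else px.default_grid(model, n_points)
    )
    spec = px.SyntheticSpec(model, grid, noise_sd=noise_sd, seed=seed, **kw)
    return px.simulate(spec)
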