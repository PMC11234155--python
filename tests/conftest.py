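"""Shared fixtures: expensive synthetic images and fields are built once."""

import numpy as np
import pytest

from bypassflow.fields import make_wall_mesh
from bypassflow.geometry import default_windows
from bypassflow.synthimage import MonolayerSpec, generate_monolayer
from bypassflow.synthwss import default_regime_specs, generate_field


@pytest.fixture(scope="session")
def windows():
    return default_windows()


@pytest.fixture(scope="session")
def default_field(windows):
    """Default four-regime field on a ~2000-node mesh with its mesh."""
    mesh = make_wall_mesh(windows, nodes_per_mm=32, n_circ=8)
    field = generate_field(mesh, windows, default_regime_specs(0))
    return mesh, field


@pytest.fixture(scope="session")
def monolayer_100():
    """100-cell monolayer at default pixel size and SNR, with truth."""
    spec = MonolayerSpec(n_cells=100, seed=1)
    image, truth = generate_monolayer(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def monolayer_faj30():
    """100-cell monolayer with 30% FAJ length fraction target."""
    spec = MonolayerSpec(n_cells=100, seed=2, faj_fraction=0.30)
    image, truth = generate_monolayer(spec)
    return spec, image, truth
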