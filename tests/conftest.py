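"""Shared fixtures: expensive geometry and BEM systems built once per session.

Problem sizes here are chosen for test runtime; the phantom's physical
parameters (tissue geometry, conductivities, coil, noise levels) are the
package defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

from ratfield.bem import assemble_double_layer, build_deflated_system
from ratfield.coil import CoilPlacement, build_figure8_quadrature, place_coil_tangential
from ratfield.model import single_compartment
from ratfield.phantom import PhantomSpec, make_icosphere, make_rat_phantom


@pytest.fixture(scope="session")
def coarse_spec() -> PhantomSpec:
    """Rat phantom at coarse mesh density (fast enough for the suite)."""
    return PhantomSpec(
        skull_edge=1.6, body_edge=3.0, eval_subdivisions=3, grid_spacing=0.25
    )


@pytest.fixture(scope="session")
def coarse_phantom(coarse_spec):
    model, evaluation, scalp = make_rat_phantom(coarse_spec)
    return model, evaluation, scalp


@pytest.fixture(scope="session")
def sphere4_model():
    """Homogeneous 15-mm sphere, icosphere subdivision 4."""
    return single_compartment(make_icosphere(15.0, 4), 0.33)


@pytest.fixture(scope="session")
def sphere4_system(sphere4_model):
    return build_deflated_system(assemble_double_layer(sphere4_model))


@pytest.fixture(scope="session")
def placed_coil():
    """Default coil tangential at the north pole of a 15-mm sphere, PA, 2 mm off."""
    coil = build_figure8_quadrature()
    placement = CoilPlacement(np.array([0.0, 0.0, 15.0]), 0.0, np.array([0.0, 0.0, 1.0]))
    return place_coil_tangential(coil, placement, standoff=2.0)
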