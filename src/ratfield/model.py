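"""Piecewise-homogeneous volume-conductor model description.

A :class:`CompartmentModel` is an ordered list of closed boundary surfaces,
each carrying the conductivity immediately inside (``sigma_in``) and outside
(``sigma_out``) of it, in S/m.  The outermost surface must have
``sigma_out = 0`` (air).  A "floating skull" — one closed surface bounding
the whole bone volume, holes included, placed inside the body surface — is
admissible exactly when the conductivities on both sides of its holes are
equal, i.e. the intracranial and body conductivities coincide; this is the
standard equal-conductivity assumption and is asserted here.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import TriMesh, validate_mesh

__all__ = ["BoundarySurface", "CompartmentModel", "SIGMA_BODY", "SIGMA_SKULL"]

#: default tissue conductivities (S/m); skull:body ratio 1/50
SIGMA_BODY = 0.33
SIGMA_SKULL = 6.6e-3


@dataclasses.dataclass
class BoundarySurface:
    mesh: TriMesh
    sigma_in: float
    sigma_out: float

    @property
    def jump(self) -> float:
        return self.sigma_in - self.sigma_out


@dataclasses.dataclass
class CompartmentModel:
    """Ordered surfaces, outermost first."""

    surfaces: list[BoundarySurface]

    def __post_init__(self) -> None:
        if not self.surfaces:
            raise ValueError("model needs at least one surface")
        if abs(self.surfaces[0].sigma_out) > 0:
            raise ValueError("outermost surface must have sigma_out = 0")

    @property
    def n_vertices(self) -> int:
        return sum(s.mesh.n_vertices for s in self.surfaces)

    def validate(self) -> None:
        for i, s in enumerate(self.surfaces):
            rep = validate_mesh(s.mesh, require_closed=True)
            if not rep.closed:
                raise ValueError(f"surface {i} ({s.mesh.label}) is not closed: {rep.defects}")
            if not rep.oriented:
                raise ValueError(f"surface {i} ({s.mesh.label}) is not outward-oriented: {rep.defects}")

    def labels(self) -> list[str]:
        return [s.mesh.label or f"surface{i}" for i, s in enumerate(self.surfaces)]


def single_compartment(mesh: TriMesh, sigma: float = SIGMA_BODY) -> CompartmentModel:
    return CompartmentModel([BoundarySurface(mesh, sigma, 0.0)])


def body_with_floating_skull(
    body: TriMesh,
    skull: TriMesh,
    sigma_body: float = SIGMA_BODY,
    sigma_skull: float = SIGMA_SKULL,
) -> CompartmentModel:
    """Two-compartment model: body outline + closed skull surface inside it.

    The intracranial conductivity is taken equal to the body conductivity,
    which is what makes the skull-with-holes surface a valid closed boundary.
    """
    return CompartmentModel(
        [
            BoundarySurface(body, sigma_body, 0.0),
            BoundarySurface(skull, sigma_skull, sigma_body),
        ]
    )


def stacked_vertices(model: CompartmentModel) -> np.ndarray:
    """All surface vertices stacked in model order (mm)."""
    return np.vstack([s.mesh.vertices for s in model.surfaces])
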