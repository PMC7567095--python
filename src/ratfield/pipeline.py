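"""Config-driven end-to-end runs: placement grids, multi-model solves,
comparison reports.

A run builds several volume-conductor models of increasing simplification
from the same head (synthetic phantom, or a CT volume through the
segmentation recipe), places the coil on a scalp grid of positions and
tangential orientations, computes the induced cortical E-field with every
model, and compares each against the designated reference model with the
standard metrics.
"""

from __future__ import annotations

import dataclasses
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bem import assemble_double_layer, bem_efield, build_deflated_system
from .coil import (
    DEFAULT_DIDT,
    CoilModel,
    CoilPlacement,
    CoilSpec,
    build_figure8_quadrature,
    place_coil_tangential,
    primary_efield,
)
from .geometry import TriMesh
from .metrics import ComparisonReport, FieldSet, compare_fields, projected_orientation_angle
from .model import CompartmentModel, single_compartment
from .phantom import PhantomSpec, make_rat_phantom
from .proximity import SurfaceDistance
from .sphere import SphereModel, fit_local_sphere, sphere_efield
from .vtkio import write_vtk_points

__all__ = ["RunConfig", "placement_grid", "run_comparison", "export_report"]

KNOWN_MODELS = ("2C", "2C-spine", "1C", "sphere", "infinite")


@dataclasses.dataclass
class RunConfig:
    """Parameters of a comparison run (lengths mm, angles degrees)."""

    phantom: PhantomSpec = dataclasses.field(default_factory=PhantomSpec)
    models: tuple[str, ...] = ("2C", "1C", "sphere", "infinite")
    reference: str = "2C"
    coil: CoilSpec = dataclasses.field(default_factory=CoilSpec)
    dIdt: float = DEFAULT_DIDT
    region_extent: tuple[float, float] = (15.0, 10.0)
    position_spacing: float = 2.5
    angle_step_deg: float = 10.0
    orientation_equivalence: bool = True
    standoff: float = 2.0
    grid_center: tuple[float, float, float] | None = None
    sphere_fit_region_radius: float = 8.0
    quad_depth: int = 1
    seed: int = 0
    vtk_placement_cap: int = 3

    def __post_init__(self) -> None:
        if self.region_extent[0] <= 0 or self.region_extent[1] <= 0:
            raise ValueError("region extent must be positive")
        if abs((180.0 / self.angle_step_deg) - round(180.0 / self.angle_step_deg)) > 1e-9:
            raise ValueError("angle step must divide 180 degrees")
        unknown = set(self.models) - set(KNOWN_MODELS)
        if unknown:
            raise ValueError(f"unknown model variants: {sorted(unknown)}")
        if self.reference not in self.models:
            raise ValueError("reference model must be among the run's models")

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        d["coil"] = dataclasses.asdict(self.coil)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "phantom" in d:
            d["phantom"] = PhantomSpec.from_dict(d["phantom"])
        if "coil" in d:
            d["coil"]["layers"] = tuple(d["coil"]["layers"])
            d["coil"] = CoilSpec(**d["coil"])
        for key in ("models", "region_extent"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("grid_center") is not None:
            d["grid_center"] = tuple(d["grid_center"])
        return cls(**d)


# ---------------------------------------------------------------------------
# placement grid
# ---------------------------------------------------------------------------

def placement_grid(scalp: TriMesh, config: RunConfig) -> list[CoilPlacement]:
    """Regular scalp grid of positions x tangential orientations.

    Positions form a regular grid in the tangent plane of the grid centre
    (defaults to the topmost scalp point), projected onto the scalp.
    Orientations cover [0, 180) when theta and theta+180 are treated as one
    placement (figure-of-eight field reversal), else [0, 360).  The default
    15 x 10 mm extent at 2.5 mm spacing gives 7 x 5 = 35 positions and,
    with a 10-degree step, 630 placements.
    """
    vn = scalp.vertex_normals()
    if config.grid_center is None:
        ci = int(np.argmax(scalp.vertices[:, 2]))
        center = scalp.vertices[ci]
        n0 = vn[ci]
    else:
        center = np.asarray(config.grid_center, dtype=float)
        from scipy.spatial import cKDTree

        ci = int(cKDTree(scalp.vertices).query(center)[1])
        center = scalp.vertices[ci]
        n0 = vn[ci]
    pa = np.array([1.0, 0.0, 0.0])
    pa = pa - (pa @ n0) * n0
    pa /= np.linalg.norm(pa)
    left = np.cross(n0, pa)

    ex, ey = config.region_extent
    h = config.position_spacing
    nx = int(round(ex / h)) + 1
    ny = int(round(ey / h)) + 1
    us = (np.arange(nx) - (nx - 1) / 2.0) * h
    vs = (np.arange(ny) - (ny - 1) / 2.0) * h

    sd = SurfaceDistance(scalp)
    from scipy.spatial import cKDTree

    vtree = cKDTree(scalp.vertices)
    positions = []
    failed = []
    for i, u in enumerate(us):
        for j, v in enumerate(vs):
            nominal = center + u * pa + v * left
            p = sd.project(nominal[None, :])[0]
            if np.linalg.norm(p - nominal) > max(ex, ey):
                failed.append((i, j))
                continue
            ni = int(vtree.query(p)[1])
            positions.append((p, vn[ni]))
    if failed:
        raise ValueError(f"grid positions could not be projected onto the scalp: {failed}")

    span = 180.0 if config.orientation_equivalence else 360.0
    angles = np.arange(0.0, span, config.angle_step_deg)
    return [
        CoilPlacement(p, float(a), n) for (p, n) in positions for a in angles
    ]


# ---------------------------------------------------------------------------
# model variants
# ---------------------------------------------------------------------------

def _inner_sheet_vertices(skull: TriMesh, region_center, region_radius: float) -> np.ndarray:
    """Vertices of the inner skull sheet within a crown region.

    The skull surface contains both sheets of the bone shell; within the
    region the two sheets separate cleanly by radial distance from the
    region centroid, and the nearer-to-brain (inner) group is returned.
    """
    pts = skull.vertices
    sel = np.linalg.norm(pts - np.asarray(region_center, dtype=float), axis=1) <= region_radius
    pts = pts[sel]
    if len(pts) < 10:
        raise ValueError("sphere-fit region contains too few skull vertices")
    r = np.linalg.norm(pts - pts.mean(axis=0) * 0.0, axis=1)  # distance from head origin
    thr = 0.5 * (r.min() + r.max())
    return pts[r < thr]


@dataclasses.dataclass
class BuiltModels:
    """All solver-ready model variants sharing one evaluation surface."""

    evaluation: TriMesh
    scalp: TriMesh
    bem: dict[str, tuple[CompartmentModel, object]]  # name -> (model, factorised system)
    sphere: SphereModel | None


def build_models(config: RunConfig) -> BuiltModels:
    spec = config.phantom
    model2c, evaluation, scalp = make_rat_phantom(spec)
    bem: dict[str, tuple[CompartmentModel, object]] = {}
    sphere_model = None
    for name in config.models:
        if name == "2C":
            bem[name] = (model2c, build_deflated_system(assemble_double_layer(model2c)))
        elif name == "2C-spine":
            mspine, _, _ = make_rat_phantom(dataclasses.replace(spec, spine=True))
            bem[name] = (mspine, build_deflated_system(assemble_double_layer(mspine)))
        elif name == "1C":
            m1 = single_compartment(scalp, model2c.surfaces[0].sigma_in)
            bem[name] = (m1, build_deflated_system(assemble_double_layer(m1)))
        elif name == "sphere":
            skull = model2c.surfaces[1].mesh
            top = np.array([0.0, 0.0, skull.vertices[:, 2].max()])
            pts = _inner_sheet_vertices(skull, top, config.sphere_fit_region_radius)
            patch = TriMesh(pts, np.zeros((0, 3), dtype=np.int64))
            sphere_model = _fit_sphere_to_points(pts)
        elif name == "infinite":
            pass
    return BuiltModels(evaluation, scalp, bem, sphere_model)


def _fit_sphere_to_points(pts: np.ndarray) -> SphereModel:
    mesh = TriMesh(pts, np.zeros((0, 3), dtype=np.int64))
    center = pts.mean(axis=0)
    return fit_local_sphere(mesh, center, np.inf)


def _field_for(
    name: str,
    built: BuiltModels,
    coil: CoilModel,
    dIdt: float,
    points: np.ndarray,
    quad_depth: int,
) -> np.ndarray:
    if name == "infinite":
        return primary_efield(coil, dIdt, points)
    if name == "sphere":
        if built.sphere is None:
            raise ValueError("sphere model was not built")
        return sphere_efield(built.sphere, coil, dIdt, points)
    model, system = built.bem[name]
    return bem_efield(model, system, coil, dIdt, points, quad_depth=quad_depth)


# ---------------------------------------------------------------------------
# comparison run
# ---------------------------------------------------------------------------

def run_comparison(
    config: RunConfig, keep_fields: bool = True
) -> tuple[ComparisonReport, dict[tuple[str, str], FieldSet], list[str]]:
    """Execute the full placement-grid comparison.

    Returns the report, the archived fields keyed (model, placement id) and
    a list of per-placement error strings (the run continues past failures).
    """
    built = build_models(config)
    placements = placement_grid(built.scalp, config)
    base_coil = build_figure8_quadrature(config.coil)
    points = built.evaluation.vertices
    rows = []
    fields: dict[tuple[str, str], FieldSet] = {}
    errors: list[str] = []
    for pl in placements:
        pid = (
            f"x{pl.position[0]:+.2f}_y{pl.position[1]:+.2f}"
            f"_z{pl.position[2]:+.2f}_a{pl.angle_deg:05.1f}"
        )
        try:
            coil = place_coil_tangential(base_coil, pl, config.standoff)
            per_model: dict[str, FieldSet] = {}
            for name in config.models:
                E = _field_for(name, built, coil, config.dIdt, points, config.quad_depth)
                per_model[name] = FieldSet(points, E, pid)
            ref = per_model[config.reference]
            coil_n = coil.transform[:3, 2]
            coil_e = coil.transform[:3, 1]
            for name in config.models:
                fs = per_model[name]
                row = {
                    "placement": pid,
                    "angle_deg": pl.angle_deg,
                    "model": name,
                    "peak_e": float(fs.magnitudes().max()),
                    "proj_orientation_deg": projected_orientation_angle(fs, coil_e, coil_n),
                }
                row.update(compare_fields(fs, ref))
                rows.append(row)
                if keep_fields:
                    fields[(name, pid)] = fs
        except Exception as exc:
            errors.append(f"{pid}: {exc!r}")
            if len(errors) <= 3:
                traceback.print_exc()
    table = pd.DataFrame(rows)
    return ComparisonReport(table, config.reference), fields, errors


def export_report(
    report: ComparisonReport,
    fields: dict[tuple[str, str], FieldSet],
    outdir: str | Path,
    vtk_placement_cap: int = 3,
) -> list[Path]:
    """Write CSV + JSON tables and VTK field snapshots (capped)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = [
        report.to_csv(outdir / "placements.csv"),
        report.to_json(outdir / "report.json"),
    ]
    report.summary().to_csv(outdir / "summary.csv", index=False, float_format="%.10g")
    written.append(outdir / "summary.csv")
    placement_ids: list[str] = []
    for (_, pid) in fields:
        if pid not in placement_ids:
            placement_ids.append(pid)
    for pid in placement_ids[:vtk_placement_cap]:
        for (name, p), fs in fields.items():
            if p != pid:
                continue
            path = outdir / f"field_{name}_{pid}.vtk"
            write_vtk_points(
                fs.points, path, {"E": fs.vectors, "Emag": fs.magnitudes()}
            )
            written.append(path)
    return written
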