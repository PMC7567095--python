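"""Error metrics and hotspot/peak analyses for comparing E-field predictions.

Given a test field E and a reference field E_ref sampled at the same N
cortical points:

* relative error   RE  = ||E - E_ref|| / ||E_ref||  over the pooled
  3N-component vectors — sensitive to magnitude and direction;
* correlation error CCE = 1 - cos(E~, E_ref~) of the component-wise
  de-meaned pooled vectors — insensitive to a global positive scale;
* mean angular error — unweighted mean of per-point angles, degrees;
* peak displacement — distance between the argmax-|E| points;
* hotspot restriction — points where |E_ref| exceeds sqrt(0.5) of its peak
  (E-field energy density above 50% of maximum); the mask is always taken
  from the reference field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FieldSet",
    "relative_error",
    "correlation_error",
    "mean_angular_error",
    "hotspot_restrict",
    "peak_distance",
    "compare_fields",
    "ComparisonReport",
    "HOTSPOT_FRACTION",
]

#: magnitude fraction of the per-placement peak defining the hotspot
HOTSPOT_FRACTION = float(np.sqrt(0.5))

#: percentiles reported in grid summaries (+-1 and +-2 sd for normal data)
SUMMARY_PERCENTILES = (2.3, 16.0, 50.0, 84.0, 97.7)


@dataclasses.dataclass
class FieldSet:
    """E-field 3-vectors (V/m) at shared evaluation points (mm)."""

    points: np.ndarray
    vectors: np.ndarray
    placement_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.points.shape != self.vectors.shape:
            raise ValueError("points and vectors must both be (N, 3)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("field values must be finite")

    @property
    def n(self) -> int:
        return len(self.points)

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def subset(self, idx: np.ndarray) -> "FieldSet":
        return FieldSet(self.points[idx], self.vectors[idx], self.placement_id)


def _check_same_points(a: FieldSet, b: FieldSet) -> None:
    if a.points.shape != b.points.shape or not np.allclose(a.points, b.points):
        raise ValueError("fields must share the same evaluation points and ordering")


def relative_error(field: FieldSet, reference: FieldSet) -> float:
    """RE = ||E - E_ref|| / ||E_ref|| over pooled 3N components."""
    _check_same_points(field, reference)
    nref = np.linalg.norm(reference.vectors)
    if nref == 0:
        raise ValueError("reference field is identically zero")
    return float(np.linalg.norm(field.vectors - reference.vectors) / nref)


def correlation_error(field: FieldSet, reference: FieldSet) -> float:
    """CCE = 1 - cosine of the component-wise de-meaned pooled vectors."""
    _check_same_points(field, reference)
    a = field.vectors - field.vectors.mean(axis=0)
    b = reference.vectors - reference.vectors.mean(axis=0)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("constant field: correlation error undefined")
    return float(1.0 - (a.ravel() @ b.ravel()) / (na * nb))


def mean_angular_error(field: FieldSet, reference: FieldSet) -> float:
    """Mean per-point angle (degrees); zero-magnitude points are excluded."""
    _check_same_points(field, reference)
    na = field.magnitudes()
    nb = reference.magnitudes()
    ok = (na > 0) & (nb > 0)
    if not ok.any():
        raise ValueError("no points with nonzero field in both sets")
    cosang = np.einsum("ij,ij->i", field.vectors[ok], reference.vectors[ok]) / (
        na[ok] * nb[ok]
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(ang.mean())


def hotspot_restrict(reference: FieldSet, fraction: float = HOTSPOT_FRACTION) -> np.ndarray:
    """Indices where |E_ref| strictly exceeds ``fraction`` of its maximum.

    The peak point itself is always included (|E| = max is included via the
    strict comparison against fraction*max < max).
    """
    if reference.n == 0:
        raise ValueError("empty field")
    mags = reference.magnitudes()
    return np.nonzero(mags > fraction * mags.max())[0]


def peak_distance(field_a: FieldSet, field_b: FieldSet) -> float:
    """Distance (mm) between the |E| maxima; ties broken by lowest index."""
    _check_same_points(field_a, field_b)
    ia = int(np.argmax(field_a.magnitudes()))  # argmax returns lowest index on ties
    ib = int(np.argmax(field_b.magnitudes()))
    return float(np.linalg.norm(field_a.points[ia] - field_b.points[ib]))


def projected_orientation_angle(
    field: FieldSet, coil_e_direction: np.ndarray, coil_normal: np.ndarray
) -> float:
    """Signed angle (deg) between the coil's field axis and E at the peak.

    E at the peak point is projected onto the coil-face plane; positive
    angles rotate from the coil axis towards coil_normal x axis.
    """
    i = int(np.argmax(field.magnitudes()))
    e = field.vectors[i]
    n = coil_normal / np.linalg.norm(coil_normal)
    e_proj = e - (e @ n) * n
    if np.linalg.norm(e_proj) == 0:
        return float("nan")
    a = coil_e_direction / np.linalg.norm(coil_e_direction)
    s = np.cross(a, e_proj) @ n
    c = a @ e_proj
    return float(np.degrees(np.arctan2(s, c)))


def compare_fields(field: FieldSet, reference: FieldSet) -> dict[str, float]:
    """All-points and hotspot-restricted metrics for one placement."""
    hot = hotspot_restrict(reference)
    out = {
        "re": relative_error(field, reference),
        "cce": correlation_error(field, reference),
        "angular_error_deg": mean_angular_error(field, reference),
        "peak_distance_mm": peak_distance(field, reference),
        "re_hotspot": relative_error(field.subset(hot), reference.subset(hot)),
        "angular_error_deg_hotspot": mean_angular_error(
            field.subset(hot), reference.subset(hot)
        ),
        "n_hotspot": float(len(hot)),
    }
    try:
        out["cce_hotspot"] = correlation_error(field.subset(hot), reference.subset(hot))
    except ValueError:  # single-point hotspot has no variance
        out["cce_hotspot"] = float("nan")
    return out


@dataclasses.dataclass
class ComparisonReport:
    """Per-placement metrics for each model variant plus grid summaries."""

    table: pd.DataFrame  # one row per (placement, model)
    reference_model: str

    def summary(self) -> pd.DataFrame:
        """mean +- sd, median and 2.3/16/84/97.7 percentiles per model/metric."""
        metrics = [
            c
            for c in self.table.columns
            if c not in ("placement", "model") and self.table[c].dtype.kind == "f"
        ]
        rows = []
        for model, grp in self.table.groupby("model"):
            for m in metrics:
                v = grp[m].dropna().to_numpy()
                if len(v) == 0:
                    continue
                pct = np.percentile(v, SUMMARY_PERCENTILES)
                rows.append(
                    {
                        "model": model,
                        "metric": m,
                        "mean": v.mean(),
                        "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                        "p2.3": pct[0],
                        "p16": pct[1],
                        "median": pct[2],
                        "p84": pct[3],
                        "p97.7": pct[4],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        self.table.to_csv(path, index=False, float_format="%.10g")
        return Path(path)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "reference_model": self.reference_model,
            "placements": self.table.to_dict(orient="records"),
            "summary": self.summary().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "ComparisonReport":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["placements"]), payload["reference_model"])
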