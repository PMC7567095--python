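"""CT volume -> labelled masks -> boundary surfaces -> evaluation surface.

The recipe is deliberately simple and robust, relying on the strong
air/soft-tissue/bone contrast of small-animal CT:

1. thresholds from the intensity histogram — the air/soft threshold halfway
   between the two dominant modes, the soft/bone threshold at the first bin
   after the soft-tissue mode falls below a stated fraction (default 1%) of
   its peak height;
2. body = largest 26-connected component above the air/soft threshold,
   bone = above the soft/bone threshold within the body;
3. morphological closure with spherical kernels (2 mm body, 1 mm skull) to
   smooth the masks and fill narrow channels;
4. boundary surfaces by marching cubes on a lightly smoothed level set,
   then isotropic remeshing to the per-surface target edge length;
5. the cortical evaluation surface as the boundary of
   (brain mask - skull mask dilated by the margin).

The brain mask is an input (painted manually for real data; supplied by the
phantom ground truth for synthetic data) — no automatic brain segmentation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import measure

from .geometry import TriMesh, validate_mesh, weld_vertices
from .remesh import remesh_to_target_edge
from .volume import CTVolume, LabelVolume, LABEL_AIR, LABEL_BODY, LABEL_BONE

__all__ = [
    "SegmentationParams",
    "find_thresholds",
    "segment_volume",
    "morph_close",
    "extract_boundary_surface",
    "make_evaluation_surface",
    "segment_to_surfaces",
]


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    """Thresholds (HU; None = automatic) and geometric parameters (mm)."""

    t_air_soft: float | None = None
    t_soft_bone: float | None = None
    body_closure_radius: float = 2.0
    skull_closure_radius: float = 1.0
    body_target_edge: float = 1.4
    skull_target_edge: float = 0.67
    eval_margin: float = 1.0
    peak_fraction: float = 0.01  # "end of the soft-tissue peak" criterion

    def __post_init__(self) -> None:
        if (
            self.t_air_soft is not None
            and self.t_soft_bone is not None
            and self.t_air_soft >= self.t_soft_bone
        ):
            raise ValueError("t_air_soft must be below t_soft_bone")
        if self.body_closure_radius < 0 or self.skull_closure_radius < 0:
            raise ValueError("closure radii must be >= 0")
        if self.eval_margin < 0:
            raise ValueError("evaluation margin must be >= 0")


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def find_thresholds(
    ct: CTVolume, peak_fraction: float = 0.01, smooth_hu: float = 5.0
) -> tuple[float, float]:
    """Automatic air/soft and soft/bone thresholds from the HU histogram.

    Air/soft: midpoint of the two dominant histogram modes.  Soft/bone: the
    first 1-HU bin after the soft-tissue mode whose (smoothed) count falls
    below ``peak_fraction`` of the mode height.
    """
    vals = ct.data.ravel()
    lo, hi = float(vals.min()), float(vals.max())
    edges = np.arange(np.floor(lo) - 0.5, np.ceil(hi) + 1.5)
    hist, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # pad so modes at the data range ends are still detected as peaks
    pad = int(np.ceil(4 * smooth_hu)) + 1
    hist = np.pad(hist, pad)
    centers = np.concatenate(
        [centers[0] - np.arange(pad, 0, -1), centers, centers[-1] + np.arange(1, pad + 1)]
    )
    smooth = ndimage.gaussian_filter1d(hist.astype(float), smooth_hu)
    peaks, props = find_peaks(smooth, prominence=smooth.max() * 1e-3)
    if len(peaks) < 2:
        raise ValueError(
            "HU histogram has fewer than two detectable modes; "
            "supply fixed thresholds in SegmentationParams"
        )
    # two dominant modes by height = air and soft tissue
    order = np.argsort(smooth[peaks])[::-1]
    two = np.sort(peaks[order[:2]])
    air_mode, soft_mode = centers[two[0]], centers[two[1]]
    t_air_soft = 0.5 * (air_mode + soft_mode)

    level = smooth[two[1]] * peak_fraction
    after = np.nonzero(smooth[two[1] :] < level)[0]
    if len(after) == 0:
        raise ValueError("soft-tissue mode does not decay; cannot place bone threshold")
    t_soft_bone = centers[two[1] + after[0]]
    return float(t_air_soft), float(t_soft_bone)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    # 26-connectivity for reproducibility
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise ValueError("empty mask: no connected component found")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def segment_volume(ct: CTVolume, params: SegmentationParams = SegmentationParams()) -> LabelVolume:
    """Label the CT into air / body / bone.

    body = largest connected component above the air/soft threshold;
    bone = above the soft/bone threshold, restricted to the body.
    """
    if params.t_air_soft is None or params.t_soft_bone is None:
        t1, t2 = find_thresholds(ct, params.peak_fraction)
        t1 = params.t_air_soft if params.t_air_soft is not None else t1
        t2 = params.t_soft_bone if params.t_soft_bone is not None else t2
    else:
        t1, t2 = params.t_air_soft, params.t_soft_bone
    if t1 >= t2:
        raise ValueError("thresholds out of order")
    body = _largest_component(ct.data > t1)
    bone = (ct.data > t2) & body
    labels = np.full(ct.data.shape, LABEL_AIR, dtype=np.int8)
    labels[body] = LABEL_BODY
    labels[bone] = LABEL_BONE
    return LabelVolume(labels, ct.spacing, ct.origin)


def _radius_voxels(radius_mm: float, spacing: float) -> int:
    # round half up, stated for cross-spacing reproducibility
    return int(np.floor(radius_mm / spacing + 0.5))


def morph_close(mask: np.ndarray, radius_mm: float, spacing: float) -> np.ndarray:
    """Morphological closure with a spherical kernel of physical radius.

    Implemented through exact Euclidean distance transforms (equivalent to
    a discrete ball structuring element of ``round(radius/spacing)`` voxels,
    but fast for large kernels): dilation = EDT(~mask) <= r, then erosion.
    Fills channels narrower than twice the radius; idempotent.
    """
    r = _radius_voxels(radius_mm, spacing)
    if r <= 0:
        return mask.copy()
    pad = r + 1
    m = np.pad(mask, pad)
    # dilation: within r of the mask; erosion of the result: farther than r
    # from its complement (both with the same closed discrete ball)
    dil = ndimage.distance_transform_edt(~m) <= r
    closed = ndimage.distance_transform_edt(dil) > r
    sl = (slice(pad, -pad),) * 3
    return closed[sl]


def dilate(mask: np.ndarray, radius_mm: float, spacing: float) -> np.ndarray:
    """Dilation by a spherical kernel of physical radius (EDT-based)."""
    r = _radius_voxels(radius_mm, spacing)
    if r <= 0:
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= r


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def extract_boundary_surface(
    mask: np.ndarray,
    spacing: float,
    origin: np.ndarray,
    target_edge: float,
    smooth_sigma_vox: float = 0.6,
    keep_largest: bool = False,
) -> TriMesh:
    """Triangulated 0.5-level surface of a binary mask, remeshed.

    The mask is smoothed slightly (Gaussian, sub-voxel sigma) before
    marching cubes to suppress staircase artefacts; the surface therefore
    stays within about half a voxel of the binary boundary.
    """
    if not mask.any():
        raise ValueError("empty mask")
    from .remesh import TopologyChangeError

    border = (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    if border:
        raise ValueError("mask touches the volume border; pad the volume first")
    # noisy masks yield rough level sets that block isotropic remeshing;
    # retry with progressively stronger smoothing before giving up
    last_exc: Exception | None = None
    for sigma in (smooth_sigma_vox, 1.5 * smooth_sigma_vox + 0.3, 2.5 * smooth_sigma_vox + 0.6):
        field = ndimage.gaussian_filter(mask.astype(np.float32), sigma)
        # tiny masks may smooth below the nominal iso-level
        level = min(0.5, 0.5 * float(field.max()))
        verts, faces, _, _ = measure.marching_cubes(
            field, level=level, spacing=(spacing,) * 3
        )
        mesh = weld_vertices(
            TriMesh(verts + np.asarray(origin), faces.astype(np.int64)), tol=1e-7
        )
        if keep_largest:
            mesh = _largest_surface_component(mesh)
        if mesh.signed_volume() < 0:
            mesh = mesh.flipped()
        extent = float((mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)).max())
        if mesh.n_faces > 40 and extent > 3 * target_edge:
            try:
                mesh = remesh_to_target_edge(mesh, target_edge, feature_check=False)
            except TopologyChangeError as exc:
                last_exc = exc
                continue
        # degenerate few-voxel blobs are returned at marching-cubes resolution
        rep = validate_mesh(mesh, require_closed=True)
        if not rep.closed:
            raise ValueError(f"extracted surface is not closed: {rep.defects}")
        return mesh
    raise ValueError(f"surface extraction failed even with extra smoothing: {last_exc}")


def _largest_surface_component(mesh: TriMesh) -> TriMesh:
    """Keep the largest connected face component (drops noise speckle)."""
    import scipy.sparse as sp

    e = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    n = mesh.n_vertices
    adj = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    ncomp, lab = sp.csgraph.connected_components(adj, directed=False)
    if ncomp <= 1:
        return mesh
    areas = np.zeros(ncomp)
    fl = lab[mesh.faces[:, 0]]
    np.add.at(areas, fl, mesh.face_areas())
    keep = fl == int(np.argmax(areas))
    return TriMesh(mesh.vertices, mesh.faces[keep], mesh.label)


def make_evaluation_surface(
    brain_mask: np.ndarray,
    skull_mask: np.ndarray,
    margin_mm: float,
    spacing: float,
    origin: np.ndarray,
    target_edge: float = 0.8,
) -> TriMesh:
    """Cortex surface: boundary of (brain - dilate(skull, margin)).

    The margin keeps evaluation points away from the skull boundary for
    numerical stability of the BEM solve.
    """
    if brain_mask.shape != skull_mask.shape:
        raise ValueError("brain and skull masks must share the grid")
    core = brain_mask & ~dilate(skull_mask, margin_mm, spacing)
    if not core.any():
        raise ValueError("margin too large: no brain volume left")
    pad = 2
    core_p = np.pad(core, pad)
    mesh = extract_boundary_surface(
        core_p, spacing, np.asarray(origin) - pad * spacing, target_edge
    )
    mesh.label = "evaluation"
    return mesh


# ---------------------------------------------------------------------------
# end-to-end surface extraction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SegmentedSurfaces:
    body: TriMesh
    skull: TriMesh
    evaluation: TriMesh | None
    labels: LabelVolume
    thresholds: tuple[float, float]


def segment_to_surfaces(
    ct: CTVolume,
    params: SegmentationParams = SegmentationParams(),
    brain_mask: np.ndarray | None = None,
) -> SegmentedSurfaces:
    """Full recipe: thresholds, masks, closures, surfaces, evaluation surface."""
    if params.t_air_soft is None or params.t_soft_bone is None:
        t1, t2 = find_thresholds(ct, params.peak_fraction)
    else:
        t1, t2 = params.t_air_soft, params.t_soft_bone
    labels = segment_volume(
        ct, dataclasses.replace(params, t_air_soft=t1, t_soft_bone=t2)
    )
    body = morph_close(labels.mask(LABEL_BODY) | labels.mask(LABEL_BONE),
                       params.body_closure_radius, ct.spacing)
    bone = morph_close(labels.mask(LABEL_BONE), params.skull_closure_radius, ct.spacing)
    body_mesh = extract_boundary_surface(
        body, ct.spacing, ct.origin, params.body_target_edge
    )
    body_mesh.label = "body"
    skull_mesh = extract_boundary_surface(
        bone, ct.spacing, ct.origin, params.skull_target_edge, keep_largest=True
    )
    skull_mesh.label = "skull"
    eval_mesh = None
    if brain_mask is not None:
        eval_mesh = make_evaluation_surface(
            brain_mask, bone, params.eval_margin, ct.spacing, ct.origin
        )
    return SegmentedSurfaces(body_mesh, skull_mesh, eval_mesh, labels, (t1, t2))
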