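"""Numerical kernels (numba-compiled) shared across modules.

Everything here is unit-agnostic except where noted; callers keep units
consistent.  The double-layer kernels implement analytically integrated
linear (hat) collocation elements: for a planar triangle with corners
``p1 p2 p3`` seen from a collocation point ``x`` the weight of hat
function ``i`` is

    W_i = a_i * Omega + d * (b_i . I1),
    I1  = Omega * n_hat - sum_k f_k * m_hat_k,

where ``Omega`` is the signed solid angle (van Oosterom & Strackee),
``d`` the signed distance from ``x`` to the triangle plane, ``b_i`` the
in-plane gradient of the hat function, ``a_i`` its affine offset at the
projection of ``x``, ``f_k`` the analytic edge integrals of 1/r and
``m_hat_k`` the in-plane outward edge normals.  A collocation point lying
in the plane of a triangle (in particular at one of its own corners)
contributes exactly zero and is skipped.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "double_layer_block",
    "point_triangle_distances",
    "ray_thickness",
    "voxelize_parity",
    "coil_flux_face_weights",
]


@njit(cache=True, fastmath=True)
def _solid_angle_weights(x, p1, p2, p3, out3):
    """Linear-collocation double-layer weights of one triangle at point x.

    Writes the three hat-function weights into out3; returns the plain
    solid angle (for row-sum diagnostics).  Zero if x is in the triangle
    plane (guard 1e-9 length units).
    """
    y1x = p1[0] - x[0]
    y1y = p1[1] - x[1]
    y1z = p1[2] - x[2]
    y2x = p2[0] - x[0]
    y2y = p2[1] - x[1]
    y2z = p2[2] - x[2]
    y3x = p3[0] - x[0]
    y3y = p3[1] - x[1]
    y3z = p3[2] - x[2]

    # triangle normal (non-unit) from edge vectors
    e1x = p2[0] - p1[0]
    e1y = p2[1] - p1[1]
    e1z = p2[2] - p1[2]
    e2x = p3[0] - p1[0]
    e2y = p3[1] - p1[1]
    e2z = p3[2] - p1[2]
    nx = e1y * e2z - e1z * e2y
    ny = e1z * e2x - e1x * e2z
    nz = e1x * e2y - e1y * e2x
    a2 = np.sqrt(nx * nx + ny * ny + nz * nz)  # 2*area
    out3[0] = 0.0
    out3[1] = 0.0
    out3[2] = 0.0
    if a2 < 1e-300:
        return 0.0
    nhx = nx / a2
    nhy = ny / a2
    nhz = nz / a2

    d = y1x * nhx + y1y * nhy + y1z * nhz
    if abs(d) < 1e-9:
        return 0.0

    l1 = np.sqrt(y1x * y1x + y1y * y1y + y1z * y1z)
    l2 = np.sqrt(y2x * y2x + y2y * y2y + y2z * y2z)
    l3 = np.sqrt(y3x * y3x + y3y * y3y + y3z * y3z)
    d12 = y1x * y2x + y1y * y2y + y1z * y2z
    d13 = y1x * y3x + y1y * y3y + y1z * y3z
    d23 = y2x * y3x + y2y * y3y + y2z * y3z
    # triple product y1 . (y2 x y3)
    tp = (
        y1x * (y2y * y3z - y2z * y3y)
        + y1y * (y2z * y3x - y2x * y3z)
        + y1z * (y2x * y3y - y2y * y3x)
    )
    den = l1 * l2 * l3 + d12 * l3 + d13 * l2 + d23 * l1
    omega = 2.0 * np.arctan2(tp, den)

    # analytic edge integrals f_k = int 1/|y| dl over edge k
    # edge 1: y1->y2, edge 2: y2->y3, edge 3: y3->y1
    # I1 = omega*n_hat - sum f_k m_hat_k ; only the in-plane part matters.
    gx = 0.0
    gy = 0.0
    gz = 0.0
    for k in range(3):
        if k == 0:
            ax, ay, az, la = y1x, y1y, y1z, l1
            bx, by, bz, lb = y2x, y2y, y2z, l2
        elif k == 1:
            ax, ay, az, la = y2x, y2y, y2z, l2
            bx, by, bz, lb = y3x, y3y, y3z, l3
        else:
            ax, ay, az, la = y3x, y3y, y3z, l3
            bx, by, bz, lb = y1x, y1y, y1z, l1
        sx = bx - ax
        sy = by - ay
        sz = bz - az
        ls = np.sqrt(sx * sx + sy * sy + sz * sz)
        if ls < 1e-300:
            continue
        num = ls * lb + sx * bx + sy * by + sz * bz
        dnm = ls * la + sx * ax + sy * ay + sz * az
        if num < 1e-300 or dnm < 1e-300:
            continue
        f = np.log(num / dnm)
        # m_hat = unit(s x n_hat)
        mx = (sy * nhz - sz * nhy) / ls
        my = (sz * nhx - sx * nhz) / ls
        mz = (sx * nhy - sy * nhx) / ls
        gx += f * mx
        gy += f * my
        gz += f * mz
    # I1 (in-plane part) = -g ; full I1 = omega*nhat - g
    i1x = omega * nhx - gx
    i1y = omega * nhy - gy
    i1z = omega * nhz - gz

    # hat-function gradients b_i = (n_hat x opposite_edge) / (2A)
    # opposite edge of vertex 1 is p3-p2, of vertex 2 is p1-p3, of vertex 3 is p2-p1
    cxx = (p1[0] + p2[0] + p3[0]) / 3.0 - x[0]
    cxy = (p1[1] + p2[1] + p3[1]) / 3.0 - x[1]
    cxz = (p1[2] + p2[2] + p3[2]) / 3.0 - x[2]
    for i in range(3):
        if i == 0:
            ox = p3[0] - p2[0]
            oy = p3[1] - p2[1]
            oz = p3[2] - p2[2]
        elif i == 1:
            ox = p1[0] - p3[0]
            oy = p1[1] - p3[1]
            oz = p1[2] - p3[2]
        else:
            ox = p2[0] - p1[0]
            oy = p2[1] - p1[1]
            oz = p2[2] - p1[2]
        bx = (nhy * oz - nhz * oy) / a2
        by = (nhz * ox - nhx * oz) / a2
        bz = (nhx * oy - nhy * ox) / a2
        a_i = 1.0 / 3.0 - (bx * cxx + by * cxy + bz * cxz)
        out3[i] = a_i * omega + d * (bx * i1x + by * i1y + bz * i1z)
    return omega


@njit(cache=True, fastmath=True)
def double_layer_block(colloc, verts, faces, out):
    """Accumulate linear-collocation double-layer weights.

    colloc : (C, 3) collocation points
    verts  : (V, 3) source-surface vertices
    faces  : (F, 3) int
    out    : (C, V) preallocated, accumulated in place
    """
    w = np.empty(3, dtype=np.float64)
    for t in range(faces.shape[0]):
        i1 = faces[t, 0]
        i2 = faces[t, 1]
        i3 = faces[t, 2]
        p1 = verts[i1]
        p2 = verts[i2]
        p3 = verts[i3]
        for c in range(colloc.shape[0]):
            _solid_angle_weights(colloc[c], p1, p2, p3, w)
            out[c, i1] += w[0]
            out[c, i2] += w[1]
            out[c, i3] += w[2]


@njit(cache=True, fastmath=True)
def solid_angle_sum(x, verts, faces):
    """Signed solid angle of the whole surface seen from point x."""
    w = np.empty(3, dtype=np.float64)
    total = 0.0
    for t in range(faces.shape[0]):
        total += _solid_angle_weights(
            x, verts[faces[t, 0]], verts[faces[t, 1]], verts[faces[t, 2]], w
        )
    return total


# ---------------------------------------------------------------------------
# point-triangle distance (Eberly-style region decomposition)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _pt_tri_sq(px, py, pz, a, b, c):
    abx = b[0] - a[0]
    aby = b[1] - a[1]
    abz = b[2] - a[2]
    acx = c[0] - a[0]
    acy = c[1] - a[1]
    acz = c[2] - a[2]
    apx = px - a[0]
    apy = py - a[1]
    apz = pz - a[2]

    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return apx * apx + apy * apy + apz * apz

    bpx = px - b[0]
    bpy = py - b[1]
    bpz = pz - b[2]
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bpx * bpx + bpy * bpy + bpz * bpz

    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        qx = apx - v * abx
        qy = apy - v * aby
        qz = apz - v * abz
        return qx * qx + qy * qy + qz * qz

    cpx = px - c[0]
    cpy = py - c[1]
    cpz = pz - c[2]
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cpx * cpx + cpy * cpy + cpz * cpz

    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        qx = apx - w * acx
        qy = apy - w * acy
        qz = apz - w * acz
        return qx * qx + qy * qy + qz * qz

    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        qx = bpx - w * (c[0] - b[0])
        qy = bpy - w * (c[1] - b[1])
        qz = bpz - w * (c[2] - b[2])
        return qx * qx + qy * qy + qz * qz

    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    qx = apx - v * abx - w * acx
    qy = apy - v * aby - w * acy
    qz = apz - v * abz - w * acz
    return qx * qx + qy * qy + qz * qz


@njit(cache=True, fastmath=True)
def point_triangle_distances(points, verts, faces, cand, cand_start, cand_count):
    """Min distance from each point to its candidate triangles.

    cand is a flat array of face indices; point i uses
    cand[cand_start[i] : cand_start[i] + cand_count[i]].
    """
    n = points.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        best = 1e300
        px = points[i, 0]
        py = points[i, 1]
        pz = points[i, 2]
        for j in range(cand_start[i], cand_start[i] + cand_count[i]):
            f = cand[j]
            d2 = _pt_tri_sq(
                px, py, pz, verts[faces[f, 0]], verts[faces[f, 1]], verts[faces[f, 2]]
            )
            if d2 < best:
                best = d2
        out[i] = np.sqrt(best)
    return out


@njit(cache=True, fastmath=True)
def _pt_tri_closest(px, py, pz, a, b, c, out):
    """Closest point on triangle abc to p; writes xyz into out, returns d^2."""
    abx = b[0] - a[0]
    aby = b[1] - a[1]
    abz = b[2] - a[2]
    acx = c[0] - a[0]
    acy = c[1] - a[1]
    acz = c[2] - a[2]
    apx = px - a[0]
    apy = py - a[1]
    apz = pz - a[2]
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        out[0], out[1], out[2] = a[0], a[1], a[2]
    else:
        bpx = px - b[0]
        bpy = py - b[1]
        bpz = pz - b[2]
        d3 = abx * bpx + aby * bpy + abz * bpz
        d4 = acx * bpx + acy * bpy + acz * bpz
        if d3 >= 0.0 and d4 <= d3:
            out[0], out[1], out[2] = b[0], b[1], b[2]
        else:
            vc = d1 * d4 - d3 * d2
            if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                t = d1 / (d1 - d3)
                out[0] = a[0] + t * abx
                out[1] = a[1] + t * aby
                out[2] = a[2] + t * abz
            else:
                cpx = px - c[0]
                cpy = py - c[1]
                cpz = pz - c[2]
                d5 = abx * cpx + aby * cpy + abz * cpz
                d6 = acx * cpx + acy * cpy + acz * cpz
                if d6 >= 0.0 and d5 <= d6:
                    out[0], out[1], out[2] = c[0], c[1], c[2]
                else:
                    vb = d5 * d2 - d1 * d6
                    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                        t = d2 / (d2 - d6)
                        out[0] = a[0] + t * acx
                        out[1] = a[1] + t * acy
                        out[2] = a[2] + t * acz
                    else:
                        va = d3 * d6 - d5 * d4
                        if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                            t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                            out[0] = b[0] + t * (c[0] - b[0])
                            out[1] = b[1] + t * (c[1] - b[1])
                            out[2] = b[2] + t * (c[2] - b[2])
                        else:
                            denom = 1.0 / (va + vb + vc)
                            v = vb * denom
                            w = vc * denom
                            out[0] = a[0] + v * abx + w * acx
                            out[1] = a[1] + v * aby + w * acy
                            out[2] = a[2] + v * abz + w * acz
    dx = px - out[0]
    dy = py - out[1]
    dz = pz - out[2]
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, fastmath=True)
def closest_points_on_surface(points, verts, faces, cand, cand_start, cand_count):
    """Closest surface point per query point over its candidate triangles."""
    n = points.shape[0]
    out = np.empty((n, 3), dtype=np.float64)
    tmp = np.empty(3, dtype=np.float64)
    best_pt = np.empty(3, dtype=np.float64)
    for i in range(n):
        best = 1e300
        px = points[i, 0]
        py = points[i, 1]
        pz = points[i, 2]
        for j in range(cand_start[i], cand_start[i] + cand_count[i]):
            f = cand[j]
            d2 = _pt_tri_closest(
                px, py, pz, verts[faces[f, 0]], verts[faces[f, 1]], verts[faces[f, 2]], tmp
            )
            if d2 < best:
                best = d2
                best_pt[0] = tmp[0]
                best_pt[1] = tmp[1]
                best_pt[2] = tmp[2]
        out[i, 0] = best_pt[0]
        out[i, 1] = best_pt[1]
        out[i, 2] = best_pt[2]
    return out


# ---------------------------------------------------------------------------
# ray-cast thickness (brute force over faces; used on small samples)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def ray_thickness(origins, directions, verts, faces, skip_face):
    """First positive ray-triangle hit distance per ray (inf if none).

    skip_face[i] is a face index excluded for ray i (its source face).
    """
    n = origins.shape[0]
    out = np.full(n, np.inf, dtype=np.float64)
    for i in range(n):
        ox = origins[i, 0]
        oy = origins[i, 1]
        oz = origins[i, 2]
        dx = directions[i, 0]
        dy = directions[i, 1]
        dz = directions[i, 2]
        best = np.inf
        for f in range(faces.shape[0]):
            if f == skip_face[i]:
                continue
            a = verts[faces[f, 0]]
            b = verts[faces[f, 1]]
            c = verts[faces[f, 2]]
            e1x = b[0] - a[0]
            e1y = b[1] - a[1]
            e1z = b[2] - a[2]
            e2x = c[0] - a[0]
            e2y = c[1] - a[1]
            e2z = c[2] - a[2]
            px = dy * e2z - dz * e2y
            py = dz * e2x - dx * e2z
            pz = dx * e2y - dy * e2x
            det = e1x * px + e1y * py + e1z * pz
            if abs(det) < 1e-14:
                continue
            inv = 1.0 / det
            tx = ox - a[0]
            ty = oy - a[1]
            tz = oz - a[2]
            u = (tx * px + ty * py + tz * pz) * inv
            if u < -1e-9 or u > 1.0 + 1e-9:
                continue
            qx = ty * e1z - tz * e1y
            qy = tz * e1x - tx * e1z
            qz = tx * e1y - ty * e1x
            v = (dx * qx + dy * qy + dz * qz) * inv
            if v < -1e-9 or u + v > 1.0 + 1e-9:
                continue
            t = (e2x * qx + e2y * qy + e2z * qz) * inv
            if t > 1e-9 and t < best:
                best = t
        out[i] = best
    return out


# ---------------------------------------------------------------------------
# batched edge-collapse round for isotropic remeshing
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def collapse_round(
    V, F, E, order, adj_ptr, adj, vf_ptr, vf, boundary, lt, min_dot
):
    """One greedy round of 1-ring-locked edge collapses.

    E[order] are candidate edges (ascending length).  For each accepted
    collapse the second vertex is remapped onto the first, which moves to
    the edge midpoint.  Checks: link condition (exactly two common
    neighbours), no boundary vertices, no new edge longer than 4/3 of the
    local admissible length ``lt`` (per-vertex sizing field), no incident
    face folding (normal dot < ``min_dot``) or degenerating.
    Returns the vertex remap array (identity where untouched).
    """
    n = V.shape[0]
    locked = np.zeros(n, dtype=np.bool_)
    remap = np.arange(n)
    for oi in range(order.shape[0]):
        e = order[oi]
        u = E[e, 0]
        v = E[e, 1]
        if locked[u] or locked[v] or boundary[u] or boundary[v]:
            continue
        # link condition: sorted adjacency intersection must have size 2
        common = 0
        i = adj_ptr[u]
        j = adj_ptr[v]
        while i < adj_ptr[u + 1] and j < adj_ptr[v + 1]:
            a = adj[i]
            b = adj[j]
            if a == b:
                common += 1
                i += 1
                j += 1
            elif a < b:
                i += 1
            else:
                j += 1
        if common != 2:
            continue
        mx = 0.5 * (V[u, 0] + V[v, 0])
        my = 0.5 * (V[u, 1] + V[v, 1])
        mz = 0.5 * (V[u, 2] + V[v, 2])
        ltuv = min(lt[u], lt[v])
        # no new over-long edges (w.r.t. the local sizing field)
        ok = True
        for side in range(2):
            w0 = u if side == 0 else v
            for ii in range(adj_ptr[w0], adj_ptr[w0 + 1]):
                w = adj[ii]
                if w == u or w == v:
                    continue
                dx = mx - V[w, 0]
                dy = my - V[w, 1]
                dz = mz - V[w, 2]
                cap = 4.0 / 3.0 * min(ltuv, lt[w])
                if dx * dx + dy * dy + dz * dz > cap * cap:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        # fold / degeneration check over incident faces
        for side in range(2):
            w0 = u if side == 0 else v
            for ii in range(vf_ptr[w0], vf_ptr[w0 + 1]):
                f = vf[ii]
                a = F[f, 0]
                b = F[f, 1]
                c = F[f, 2]
                has_u = a == u or b == u or c == u
                has_v = a == v or b == v or c == v
                if has_u and has_v:
                    continue  # face disappears
                # old normal
                ax, ay, az = V[a, 0], V[a, 1], V[a, 2]
                bx, by, bz = V[b, 0], V[b, 1], V[b, 2]
                cx, cy, cz = V[c, 0], V[c, 1], V[c, 2]
                ox = (by - ay) * (cz - az) - (bz - az) * (cy - ay)
                oy = (bz - az) * (cx - ax) - (bx - ax) * (cz - az)
                oz = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
                # new positions with u/v replaced by midpoint
                if a == u or a == v:
                    ax, ay, az = mx, my, mz
                if b == u or b == v:
                    bx, by, bz = mx, my, mz
                if c == u or c == v:
                    cx, cy, cz = mx, my, mz
                nx = (by - ay) * (cz - az) - (bz - az) * (cy - ay)
                ny = (bz - az) * (cx - ax) - (bx - ax) * (cz - az)
                nz = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
                no = np.sqrt(ox * ox + oy * oy + oz * oz)
                nn = np.sqrt(nx * nx + ny * ny + nz * nz)
                if nn < 1e-14 or (ox * nx + oy * ny + oz * nz) < min_dot * no * nn:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        V[u, 0] = mx
        V[u, 1] = my
        V[u, 2] = mz
        remap[v] = u
        locked[u] = True
        locked[v] = True
        for ii in range(adj_ptr[u], adj_ptr[u + 1]):
            locked[adj[ii]] = True
        for ii in range(adj_ptr[v], adj_ptr[v + 1]):
            locked[adj[ii]] = True
    return remap


# ---------------------------------------------------------------------------
# surface voxelization by z-column crossing parity
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def voxelize_parity(verts, faces, origin, spacing, nx, ny, nz):
    """Containment mask of a closed surface on a regular grid.

    Voxel centre (i,j,k) is at origin + spacing*(i,j,k).  For every grid
    column (i,j) the triangle crossings along z are accumulated; a voxel is
    inside iff an odd number of crossings lies below its centre.
    """
    toggles = np.zeros((nx, ny, nz + 1), dtype=np.int8)
    for f in range(faces.shape[0]):
        a = verts[faces[f, 0]]
        b = verts[faces[f, 1]]
        c = verts[faces[f, 2]]
        xmin = min(a[0], min(b[0], c[0]))
        xmax = max(a[0], max(b[0], c[0]))
        ymin = min(a[1], min(b[1], c[1]))
        ymax = max(a[1], max(b[1], c[1]))
        i0 = int(np.ceil((xmin - origin[0]) / spacing))
        i1 = int(np.floor((xmax - origin[0]) / spacing))
        j0 = int(np.ceil((ymin - origin[1]) / spacing))
        j1 = int(np.floor((ymax - origin[1]) / spacing))
        if i1 < 0 or j1 < 0 or i0 >= nx or j0 >= ny:
            continue
        if i0 < 0:
            i0 = 0
        if j0 < 0:
            j0 = 0
        if i1 >= nx:
            i1 = nx - 1
        if j1 >= ny:
            j1 = ny - 1
        # 2D edge functions in the xy-plane
        d1x = b[0] - a[0]
        d1y = b[1] - a[1]
        d2x = c[0] - a[0]
        d2y = c[1] - a[1]
        det = d1x * d2y - d1y * d2x
        if abs(det) < 1e-300:
            continue  # triangle vertical in z: no z-crossing contribution
        inv = 1.0 / det
        for i in range(i0, i1 + 1):
            px = origin[0] + spacing * i - a[0]
            for j in range(j0, j1 + 1):
                py = origin[1] + spacing * j - a[1]
                u = (px * d2y - py * d2x) * inv
                v = (d1x * py - d1y * px) * inv
                if u < 0.0 or v < 0.0 or u + v > 1.0:
                    continue
                zc = a[2] + u * (b[2] - a[2]) + v * (c[2] - a[2])
                # first voxel whose centre lies strictly above the crossing
                k = int(np.floor((zc - origin[2]) / spacing)) + 1
                if k < 0:
                    k = 0
                if k > nz:
                    k = nz
                toggles[i, j, k] += 1
    mask = np.zeros((nx, ny, nz), dtype=np.bool_)
    for i in range(nx):
        for j in range(ny):
            par = 0
            for k in range(nz):
                par += toggles[i, j, k]
                mask[i, j, k] = (par % 2) == 1
    return mask


# ---------------------------------------------------------------------------
# Geselowitz flux weights for a coil (adjoint right-hand side)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def coil_flux_face_weights(dip_pos, dip_nrm, dip_w, centroids, normals):
    """g_f = sum_k w_k n_k . (n_f x (r_k - c_f)) / |r_k - c_f|^3.

    All quantities SI.  Together with the face areas and conductivity jumps
    this gives the linear functional mapping surface potentials to the
    magnetic flux through the coil (Geselowitz surface term, one-point rule).
    """
    nf = centroids.shape[0]
    nk = dip_pos.shape[0]
    g = np.zeros(nf, dtype=np.float64)
    for k in range(nk):
        rx = dip_pos[k, 0]
        ry = dip_pos[k, 1]
        rz = dip_pos[k, 2]
        nxk = dip_nrm[k, 0]
        nyk = dip_nrm[k, 1]
        nzk = dip_nrm[k, 2]
        wk = dip_w[k]
        for f in range(nf):
            ax = rx - centroids[f, 0]
            ay = ry - centroids[f, 1]
            az = rz - centroids[f, 2]
            r3 = (ax * ax + ay * ay + az * az) ** 1.5
            if r3 < 1e-300:
                continue
            cxx = normals[f, 1] * az - normals[f, 2] * ay
            cxy = normals[f, 2] * ax - normals[f, 0] * az
            cxz = normals[f, 0] * ay - normals[f, 1] * ax
            g[f] += wk * (nxk * cxx + nyk * cxy + nzk * cxz) / r3
    return g
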