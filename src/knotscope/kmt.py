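"""KMT chain reduction: triangle elimination that preserves knot type.

The reduction sweeps consecutive vertex triples of a closed polygonal curve
and deletes the middle vertex whenever the triangle it spans is pierced by no
non-adjacent chain segment.  Sweeps repeat until none removes a vertex.  The
output is a (usually much) shorter curve of the same topological type, which
makes the subsequent projection/invariant step cheap.

Intersection predicates use signed distances and barycentric coordinates with
tolerances relative to the curve's spatial extent; touching contacts within
tolerance count as intersections (conservative: a vertex is kept whenever its
removal could change topology).  The inner loop is compiled with numba — it
runs once per candidate vertex per sweep against every chain segment, and is
the hot path of the whole stochastic-closure pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .curves import ClosedCurve

__all__ = ["GeomTolerances", "triangle_blocked", "kmt_reduce"]


@dataclass(frozen=True)
class GeomTolerances:
    """Tolerances relative to the curve's bounding-box extent.

    eps_point: coincidence / collinearity distance tolerance.
    eps_det:   tolerance of orientation (inside/outside) predicates.
    """

    eps_point: float = 1e-7
    eps_det: float = 1e-9

    def __post_init__(self):
        if self.eps_point <= 0 or self.eps_det <= 0:
            raise ValueError("tolerances must be positive")


DEFAULT_TOL = GeomTolerances()


@njit(cache=True, fastmath=False)
def _seg_tri_hit(ax, ay, az, bx, by, bz, cx, cy, cz,
                 px, py, pz, qx, qy, qz, eps_len, eps_bary):  # pragma: no cover
    """Closed segment p-q vs closed triangle a-b-c, inclusive of touching.

    eps_len is an absolute length tolerance; eps_bary a relative barycentric
    tolerance.  Near-coplanar cases fall back to a 2D overlap test.
    """
    # triangle normal
    ux, uy, uz = bx - ax, by - ay, bz - az
    vx, vy, vz = cx - ax, cy - ay, cz - az
    nx = uy * vz - uz * vy
    ny = uz * vx - ux * vz
    nz = ux * vy - uy * vx
    nn = (nx * nx + ny * ny + nz * nz) ** 0.5
    if nn < 1e-300:
        return False  # degenerate triangle; handled by the caller
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    dp = (px - ax) * nx + (py - ay) * ny + (pz - az) * nz
    dq = (qx - ax) * nx + (qy - ay) * ny + (qz - az) * nz

    if dp > eps_len and dq > eps_len:
        return False
    if dp < -eps_len and dq < -eps_len:
        return False

    if abs(dp) <= eps_len and abs(dq) <= eps_len:
        # coplanar: 2D overlap in the plane spanned by the triangle
        return _coplanar_hit(ax, ay, az, bx, by, bz, cx, cy, cz,
                             px, py, pz, qx, qy, qz,
                             nx, ny, nz, eps_len, eps_bary)

    den = dp - dq
    if abs(den) < 1e-300:
        return False
    t = dp / den
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    xx = px + t * (qx - px)
    xy = py + t * (qy - py)
    xz = pz + t * (qz - pz)
    return _in_triangle(ax, ay, az, ux, uy, uz, vx, vy, vz,
                        xx - ax, xy - ay, xz - az, eps_bary)


@njit(cache=True)
def _in_triangle(ax, ay, az, ux, uy, uz, vx, vy, vz,
                 wx, wy, wz, eps):  # pragma: no cover
    """Barycentric inside-test of point a+w against triangle spanned by u, v."""
    d00 = ux * ux + uy * uy + uz * uz
    d01 = ux * vx + uy * vy + uz * vz
    d11 = vx * vx + vy * vy + vz * vz
    d20 = wx * ux + wy * uy + wz * uz
    d21 = wx * vx + wy * vy + wz * vz
    den = d00 * d11 - d01 * d01
    if den <= 0.0:
        return False
    s = (d11 * d20 - d01 * d21) / den
    r = (d00 * d21 - d01 * d20) / den
    return s >= -eps and r >= -eps and s + r <= 1.0 + eps


@njit(cache=True)
def _coplanar_hit(ax, ay, az, bx, by, bz, cx, cy, cz,
                  px, py, pz, qx, qy, qz,
                  nx, ny, nz, eps_len, eps_bary):  # pragma: no cover
    ux, uy, uz = bx - ax, by - ay, bz - az
    vx, vy, vz = cx - ax, cy - ay, cz - az
    # endpoint inside the triangle?
    if _in_triangle(ax, ay, az, ux, uy, uz, vx, vy, vz,
                    px - ax, py - ay, pz - az, eps_bary):
        return True
    if _in_triangle(ax, ay, az, ux, uy, uz, vx, vy, vz,
                    qx - ax, qy - ay, qz - az, eps_bary):
        return True
    # segment vs each triangle edge, in 2D coordinates of the plane
    e1n = (ux * ux + uy * uy + uz * uz) ** 0.5
    e1x, e1y, e1z = ux / e1n, uy / e1n, uz / e1n
    e2x = ny * e1z - nz * e1y
    e2y = nz * e1x - nx * e1z
    e2z = nx * e1y - ny * e1x

    p0 = (px - ax) * e1x + (py - ay) * e1y + (pz - az) * e1z
    p1 = (px - ax) * e2x + (py - ay) * e2y + (pz - az) * e2z
    q0 = (qx - ax) * e1x + (qy - ay) * e1y + (qz - az) * e1z
    q1 = (qx - ax) * e2x + (qy - ay) * e2y + (qz - az) * e2z
    t0a, t1a = 0.0, 0.0
    t0b = (bx - ax) * e1x + (by - ay) * e1y + (bz - az) * e1z
    t1b = (bx - ax) * e2x + (by - ay) * e2y + (bz - az) * e2z
    t0c = (cx - ax) * e1x + (cy - ay) * e1y + (cz - az) * e1z
    t1c = (cx - ax) * e2x + (cy - ay) * e2y + (cz - az) * e2z
    if _seg2d(p0, p1, q0, q1, t0a, t1a, t0b, t1b, eps_len):
        return True
    if _seg2d(p0, p1, q0, q1, t0b, t1b, t0c, t1c, eps_len):
        return True
    if _seg2d(p0, p1, q0, q1, t0c, t1c, t0a, t1a, eps_len):
        return True
    return False


@njit(cache=True)
def _seg2d(px, py, qx, qy, ux, uy, vx, vy, eps):  # pragma: no cover
    rx, ry = qx - px, qy - py
    sx, sy = vx - ux, vy - uy
    den = rx * sy - ry * sx
    wx, wy = ux - px, uy - py
    if abs(den) <= 1e-300:
        # parallel; collinear overlap counts as touching
        if abs(wx * ry - wy * rx) > eps * max(abs(rx) + abs(ry), 1e-300):
            return False
        rr = rx * rx + ry * ry
        if rr <= 1e-300:
            return False
        t0 = (wx * rx + wy * ry) / rr
        t1 = ((vx - px) * rx + (vy - py) * ry) / rr
        lo = min(t0, t1)
        hi = max(t0, t1)
        return hi >= 0.0 and lo <= 1.0
    t = (wx * sy - wy * sx) / den
    u = (wx * ry - wy * rx) / den
    return -1e-9 <= t <= 1.0 + 1e-9 and -1e-9 <= u <= 1.0 + 1e-9


@njit(cache=True)
def _removable(pts, idx, m, i, eps_len, eps_bary):  # pragma: no cover
    """Can vertex idx[i] of the closed polygon idx[:m] be deleted safely?"""
    ia = idx[(i - 1) % m]
    ib = idx[i]
    ic = idx[(i + 1) % m]
    ax, ay, az = pts[ia, 0], pts[ia, 1], pts[ia, 2]
    bx, by, bz = pts[ib, 0], pts[ib, 1], pts[ib, 2]
    cx, cy, cz = pts[ic, 0], pts[ic, 1], pts[ic, 2]

    acx, acy, acz = cx - ax, cy - ay, cz - az
    lac = (acx * acx + acy * acy + acz * acz) ** 0.5
    if lac <= eps_len:
        return False  # a and c coincide; removal would degenerate the curve
    # near-degenerate triangle: removable iff b lies on the segment a-c
    crx = (by - ay) * acz - (bz - az) * acy
    cry = (bz - az) * acx - (bx - ax) * acz
    crz = (bx - ax) * acy - (by - ay) * acx
    area2 = (crx * crx + cry * cry + crz * crz) ** 0.5
    if area2 <= eps_len * lac:
        t = ((bx - ax) * acx + (by - ay) * acy + (bz - az) * acz) / (lac * lac)
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        fx = ax + t * acx - bx
        fy = ay + t * acy - by
        fz = az + t * acz - bz
        return (fx * fx + fy * fy + fz * fz) ** 0.5 <= eps_len

    for k in range(m):
        # skip the four segments adjacent to vertices i-1, i, i+1
        if k == i or k == (i - 1) % m or k == (i - 2) % m or k == (i + 1) % m:
            continue
        ip = idx[k]
        iq = idx[(k + 1) % m]
        if _seg_tri_hit(ax, ay, az, bx, by, bz, cx, cy, cz,
                        pts[ip, 0], pts[ip, 1], pts[ip, 2],
                        pts[iq, 0], pts[iq, 1], pts[iq, 2],
                        eps_len, eps_bary):
            return False
    return True


@njit(cache=True)
def _kmt_core(pts, eps_len, eps_bary):  # pragma: no cover
    n = pts.shape[0]
    idx = np.arange(n)
    m = n
    changed = True
    while changed and m > 3:
        changed = False
        i = 0
        while i < m and m > 3:
            if _removable(pts, idx, m, i, eps_len, eps_bary):
                for k in range(i, m - 1):
                    idx[k] = idx[k + 1]
                m -= 1
                changed = True
            else:
                i += 1
    return idx[:m]


def _extent(pts: np.ndarray) -> float:
    span = float(np.max(pts.max(axis=0) - pts.min(axis=0)))
    if span <= 0:
        raise ValueError("degenerate curve: zero spatial extent")
    return span


def triangle_blocked(a, b, c, segment: tuple[np.ndarray, np.ndarray],
                     tol: GeomTolerances = DEFAULT_TOL) -> bool:
    """True iff the closed segment intersects the closed triangle a-b-c.

    Touching within tolerance counts as blocked; tolerances are taken
    relative to the bounding box of the five points.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    p, q = (np.asarray(x, dtype=float) for x in segment)
    span = _extent(np.vstack([a, b, c, p, q]))
    return bool(_seg_tri_hit(a[0], a[1], a[2], b[0], b[1], b[2],
                             c[0], c[1], c[2], p[0], p[1], p[2],
                             q[0], q[1], q[2],
                             tol.eps_point * span, tol.eps_det))


def kmt_reduce(curve: ClosedCurve, tol: GeomTolerances = DEFAULT_TOL) -> ClosedCurve:
    """Reduce a closed curve by repeated triangle elimination.

    Sweeps vertices in ascending index order; a removal shortens the working
    polygon immediately and the sweep continues from the same position.  The
    procedure stops when a full sweep removes nothing, and never reduces the
    curve below 3 vertices.
    """
    pts = np.ascontiguousarray(curve.points, dtype=float)
    span = _extent(pts)
    keep = _kmt_core(pts, tol.eps_point * span, tol.eps_det)
    return ClosedCurve(pts[keep])
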