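"""Independent oracles used by the test suite.

Nothing here shares code with the package's topology stack: Alexander
polynomial values come from sympy symbolics (torus-knot closed form and
published coefficient lists), and 2D crossing counts from shapely's segment
intersection machinery.
"""

from __future__ import annotations

import numpy as np
import sympy as sp
from shapely.geometry import LineString, Polygon

_t = sp.symbols("t")


def torus_alexander(p: int, q: int) -> sp.Expr:
    """Closed-form Alexander polynomial of the (p, q) torus knot."""
    num = (_t ** (p * q) - 1) * (_t - 1)
    den = (_t ** p - 1) * (_t ** q - 1)
    return sp.cancel(num / den)


ALEXANDER_POLYS: dict[str, sp.Expr] = {
    "0_1": sp.Integer(1),
    "3_1": torus_alexander(2, 3),
    "4_1": _t**2 - 3 * _t + 1,
    "5_1": torus_alexander(2, 5),
    "5_2": 2 * _t**2 - 3 * _t + 2,
    "6_1": 2 * _t**2 - 5 * _t + 2,
    "6_2": _t**4 - 3 * _t**3 + 3 * _t**2 - 3 * _t + 1,
    "6_3": _t**4 - 3 * _t**3 + 5 * _t**2 - 3 * _t + 1,
    "7_1": torus_alexander(2, 7),
}


def odd_part(x: int) -> int:
    x = abs(int(x))
    if x == 0:
        return 0
    while x % 2 == 0:
        x //= 2
    return x


def det_pair(label: str) -> tuple[int, int]:
    """(|Delta(-1)|, odd part of |Delta(-2)|) from the symbolic polynomial."""
    poly = ALEXANDER_POLYS[label]
    d1 = abs(int(poly.subs(_t, -1)))
    d2 = odd_part(int(poly.subs(_t, -2)))
    return d1, d2


def count_crossings_2d(uv: np.ndarray) -> int:
    """Brute-force transversal crossing count of a closed 2D polygon via
    shapely segment intersections (non-adjacent segment pairs only)."""
    m = len(uv)
    segs = [LineString([uv[i], uv[(i + 1) % m]]) for i in range(m)]
    count = 0
    for i in range(m):
        for j in range(i + 2, m):
            if i == 0 and j == m - 1:
                continue
            inter = segs[i].intersection(segs[j])
            if not inter.is_empty and inter.geom_type == "Point":
                count += 1
    return count


def segment_crosses_triangle_2d(tri: np.ndarray, p: np.ndarray,
                                q: np.ndarray) -> bool:
    """Coplanar segment-vs-triangle overlap oracle (2D, via shapely)."""
    return Polygon(tri).intersects(LineString([p, q]))
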