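"""Closed polygonal curves — the input objects of topological analysis."""

from __future__ import annotations

import numpy as np

__all__ = ["ClosedCurve", "random_unit_vector", "random_rotation"]


class ClosedCurve:
    """A closed polygonal curve: vertices plus an implied last-to-first segment."""

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(pts) < 3:
            raise ValueError("a closed curve needs >= 3 vertices")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "ClosedCurve":
        pts = self.points
        if rotation is not None:
            pts = pts @ np.asarray(rotation).T
        if translation is not None:
            pts = pts + np.asarray(translation)
        return ClosedCurve(pts)


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere."""
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q
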