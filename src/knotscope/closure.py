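"""Chain closure: turning an open backbone trace into a closed curve.

An open protein chain has no well-defined knot type; it acquires one through
closure.  The stochastic method draws a point uniformly on a large sphere
centred at the chain centroid and connects both termini to it, repeats the
procedure many times, and reports the frequency of each knot type over the
closures.  The dominant type (majority rule, frequency > 0.5) is taken as the
chain's knot type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .chain_io import Chain
from .curves import ClosedCurve, random_unit_vector
from . import invariants

__all__ = [
    "ClosureParams",
    "KnotSpectrum",
    "close_direct",
    "close_random",
    "knot_spectrum",
]

# simpler knots first; used for tie-breaking toward fewer crossings
_SIMPLICITY = ["0_1", "3_1", "4_1", "5_1", "5_2", "6_1", "6_2", "6_3", "unknown"]


def _simplicity_rank(label: str) -> int:
    try:
        return _SIMPLICITY.index(label)
    except ValueError:  # pragma: no cover - table is closed
        return len(_SIMPLICITY)


@dataclass(frozen=True)
class ClosureParams:
    """Stochastic-closure settings.

    method:        "random_sphere" (default) or "direct" (single closing segment).
    n_closures:    independent closures per typing.
    radius_factor: closure-sphere radius as a multiple of the maximum
                   point-to-centroid distance (> 1 keeps the sphere outside
                   the chain; the spectra plateau well before 10).
    seed:          RNG seed; typing is fully deterministic given it.
    """

    method: str = "random_sphere"
    n_closures: int = 100
    radius_factor: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_closures < 1:
            raise ValueError("n_closures must be >= 1")
        if self.radius_factor <= 1:
            raise ValueError("radius_factor must be > 1")
        if self.method not in ("random_sphere", "direct"):
            raise ValueError(f"unknown closure method {self.method!r}")

    def with_seed(self, seed: int) -> "ClosureParams":
        return replace(self, seed=int(seed))


@dataclass
class KnotSpectrum:
    """Knot-type frequencies observed over an ensemble of closures."""

    freqs: dict[str, float]
    n_closures: int
    dominant: str = field(init=False)
    dominant_freq: float = field(init=False)

    def __post_init__(self):
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")
        best = max(
            self.freqs.items(),
            key=lambda kv: (kv[1], -_simplicity_rank(kv[0])),
        )
        self.dominant = best[0]
        self.dominant_freq = best[1]

    @property
    def knotted(self) -> bool:
        """Majority rule: a dominant non-trivial type with frequency > 0.5."""
        return self.dominant not in ("0_1", "unknown") and self.dominant_freq > 0.5


def close_direct(chain: Chain) -> ClosedCurve:
    """Close by a single segment from the last point back to the first."""
    return ClosedCurve(chain.points)


def _collinear(pts: np.ndarray, rel_tol: float = 1e-9) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[0] <= 0 or s[1] / s[0] <= rel_tol)


def close_random(chain: Chain, rng: np.random.Generator,
                 radius_factor: float = 10.0) -> ClosedCurve:
    """Connect both termini to one random point on a far sphere.

    The point is uniform on a sphere of radius ``radius_factor`` times the
    maximal point-to-centroid distance, centred at the chain centroid.  A
    degenerate (collinear) chain falls back to direct closure with a warning.
    """
    pts = chain.points
    if _collinear(pts):
        warnings.warn("collinear chain: falling back to direct closure")
        return close_direct(chain)
    centroid = pts.mean(axis=0)
    radius = radius_factor * float(np.max(np.linalg.norm(pts - centroid, axis=1)))
    p = centroid + radius * random_unit_vector(rng)
    return ClosedCurve(np.vstack([pts, p]))


def knot_spectrum(
    chain: Chain | ClosedCurve,
    params: ClosureParams,
    rng: np.random.Generator | None = None,
) -> KnotSpectrum:
    """Type a chain by tallying knot types over independent random closures.

    A closed input is typed once and returns a point mass on its type
    (``n_closures`` is ignored).  Passing ``rng`` continues an existing
    stream; otherwise a fresh generator is seeded from ``params.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)

    if isinstance(chain, ClosedCurve) or getattr(chain, "closed", False):
        curve = chain if isinstance(chain, ClosedCurve) else ClosedCurve(chain.points)
        label = invariants.detect_knot(curve, rng)
        return KnotSpectrum({label.label: 1.0}, 1)

    counts: dict[str, int] = {}
    for _ in range(params.n_closures):
        if params.method == "direct":
            curve = close_direct(chain)
        else:
            curve = close_random(chain, rng, params.radius_factor)
        label = invariants.detect_knot(curve, rng)
        counts[label.label] = counts.get(label.label, 0) + 1
    n = params.n_closures
    return KnotSpectrum({k: v / n for k, v in counts.items()}, n)
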