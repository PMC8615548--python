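"""Synthetic knotted-curve fixtures with known ground truth.

All knot-detection machinery in this package is exercised on curves whose
topology is known by construction: torus knots and the figure-eight knot from
their standard parametrizations, open chains with planted straight tails,
trajectories in which a trefoil unties by loop loosening or translates along
the chain (the sliding phenomenology of a knot pushed along an unfolded
backbone), and a two-domain structure whose domains separate on a schedule.

Chains use one point per "residue" at a virtual Cα-Cα bond length of 3.8 Å so
residue-unit outputs match protein conventions.  Every stochastic fixture is
fully determined by its RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain_io import Chain, ResidueLabel, Trajectory
from .curves import ClosedCurve

__all__ = [
    "BOND_LENGTH",
    "FixtureSpec",
    "torus_knot",
    "figure_eight",
    "circle",
    "random_walk",
    "open_knot",
    "open_torus_arc",
    "untie_traj",
    "slide_block_chain",
    "two_domain_traj",
    "synthetic_ybea_model",
    "half_broken_ladder",
]

BOND_LENGTH = 3.8  # Å, virtual Cα-Cα bond



@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one fixture, with its ground truth."""

    kind: str
    params: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)


def _rescale_bonds(pts: np.ndarray, bond: float, closed: bool) -> np.ndarray:
    segs = np.diff(pts, axis=0)
    if closed:
        segs = np.vstack([segs, pts[0] - pts[-1]])
    mean = float(np.mean(np.linalg.norm(segs, axis=1)))
    return pts * (bond / mean)


def torus_knot(p: int = 2, q: int = 3, n: int = 120, R: float = 3.0,
               r: float = 1.0, bond: float = BOND_LENGTH) -> ClosedCurve:
    """Sample the standard (p, q) torus-knot parametrization.

    (2,3) gives the trefoil, (2,5) the 5_1 knot; p = 1 or q = 0 degenerates
    to an unknotted circle.  Coordinates are rescaled so the mean bond length
    is ``bond`` Å.
    """
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    rad = R + r * np.cos(q * t)
    pts = np.column_stack([rad * np.cos(p * t), rad * np.sin(p * t),
                           r * np.sin(q * t)])
    return ClosedCurve(_rescale_bonds(pts, bond, closed=True))


def figure_eight(n: int = 160, bond: float = BOND_LENGTH) -> ClosedCurve:
    """Harmonic parametrization of the figure-eight knot 4_1."""
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([
        (2 + np.cos(2 * t)) * np.cos(3 * t),
        (2 + np.cos(2 * t)) * np.sin(3 * t),
        np.sin(4 * t),
    ])
    return ClosedCurve(_rescale_bonds(pts, bond, closed=True))


def circle(n: int = 40, radius: float | None = None,
           bond: float = BOND_LENGTH) -> ClosedCurve:
    if radius is None:
        radius = n * bond / (2 * np.pi)
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                           np.zeros(n)])
    return ClosedCurve(pts)


def random_walk(n: int, step: float = BOND_LENGTH,
                rng: np.random.Generator | None = None) -> Chain:
    """Freely jointed chain; mostly unknotted at small n (null fixture)."""
    rng = rng or np.random.default_rng(0)
    dirs = rng.normal(size=(n - 1, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = np.vstack([np.zeros(3), np.cumsum(step * dirs, axis=0)])
    return Chain(pts)


def jitter(points: np.ndarray, sigma: float,
           rng: np.random.Generator) -> np.ndarray:
    return points + rng.normal(scale=sigma, size=points.shape) if sigma > 0 else points


# ---------------------------------------------------------------------------
# Open chains with tails


def _straight_tail(anchor: np.ndarray, direction: np.ndarray, n: int,
                   bond: float) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    return anchor + bond * d * np.arange(1, n + 1)[:, None]


def open_knot(curve: ClosedCurve, gap: int = 1, tail_n: int = 0,
              tail_c: int = 0, direction: str = "radial",
              bond: float = BOND_LENGTH) -> tuple[Chain, FixtureSpec]:
    """Open a closed curve and append straight tails outward.

    ``gap`` consecutive vertices (starting at index 0) are removed; straight
    tails of ``tail_n``/``tail_c`` points extend from the termini, pointing
    away from the curve centroid ("radial") or along the terminal bond
    ("tangent").  Ground truth records the surviving knotted span in residue
    numbers (1-based over the new chain).
    """
    if gap < 1 or gap >= len(curve) - 2:
        raise ValueError("gap must remove at least 1 and keep >= 3 points")
    core = curve.points[gap:]
    centroid = curve.points.mean(axis=0)

    def tail_dir(anchor, inward):
        if direction == "radial":
            return anchor - centroid
        return anchor - inward

    parts = []
    if tail_n:
        tail = _straight_tail(core[0], tail_dir(core[0], core[1]), tail_n, bond)
        parts.append(tail[::-1])
    parts.append(core)
    if tail_c:
        parts.append(_straight_tail(core[-1], tail_dir(core[-1], core[-2]),
                                    tail_c, bond))
    pts = np.vstack(parts)
    chain = Chain(pts)
    m = len(core)
    spec = FixtureSpec(
        kind="open_knot",
        params={"gap": gap, "tail_n": tail_n, "tail_c": tail_c},
        ground_truth={"span_start": tail_n + 1, "span_end": tail_n + m},
    )
    return chain, spec


def open_torus_arc(half_gap: float, n: int, p: int = 2, q: int = 3,
                   R: float = 3.0, r: float = 1.0,
                   bond: float = BOND_LENGTH) -> np.ndarray:
    """Arc of the (p, q) torus knot over t in [half_gap, 2*pi - half_gap],
    resampled to n points and bond-rescaled.  With a small ``half_gap`` and
    outward tails appended, a (2, 3) arc is a deeply knotted open trefoil."""
    t = np.linspace(half_gap, 2 * np.pi - half_gap, n)
    rad = R + r * np.cos(q * t)
    pts = np.column_stack([rad * np.cos(p * t), rad * np.sin(p * t),
                           r * np.sin(q * t)])
    return _rescale_bonds(pts, bond, closed=False)


# ---------------------------------------------------------------------------
# Untying / sliding trajectories


def untie_traj(mode: str, n_frames: int = 30, untie_frame: int = 20,
               sigma: float = 0.0, rng: np.random.Generator | None = None,
               n_res: int = 60) -> tuple[Trajectory, FixtureSpec]:
    """Trajectory of a trefoil that loosens until untied, or slides intact.

    ``loosen``: the knotted arc expands into both straight tails (knot termini
    move toward opposite chain ends) while the loop gap widens; at
    ``untie_frame`` the gap crosses the unknotting threshold of the torus-arc
    family and the chain is unknotted from then on.  ``slide_N``/``slide_C``:
    a fixed-size knotted block is translated along an extended chain one
    residue per frame (no untying; ``untie_frame`` is ignored).

    Gaussian jitter of width ``sigma`` Å is added to every point.
    """
    rng = rng or np.random.default_rng(0)
    if mode == "loosen":
        return _loosen_traj(n_frames, untie_frame, sigma, rng, n_res)
    if mode in ("slide_N", "slide_C"):
        return _slide_traj(mode, n_frames, sigma, rng, n_res)
    raise ValueError(f"unknown untie mode {mode!r}")


def _arc_with_tails(half_gap: float, m: int, tail_n: int, tail_c: int
                    ) -> np.ndarray:
    """Trefoil subarc with straight radial tails (decisively knotted)."""
    arc = open_torus_arc(half_gap, m)
    centroid = arc.mean(axis=0)
    parts = []
    if tail_n:
        t = _straight_tail(arc[0], arc[0] - centroid, tail_n, BOND_LENGTH)
        parts.append(t[::-1])
    parts.append(arc)
    if tail_c:
        parts.append(_straight_tail(arc[-1], arc[-1] - centroid, tail_c,
                                    BOND_LENGTH))
    return np.vstack(parts)


def _planar_open_curve(n: int) -> np.ndarray:
    """Simple (non-self-intersecting) planar curve: certainly unknotted."""
    # gentle sinusoid in the xy-plane, bond-rescaled
    x = np.arange(n, dtype=float)
    pts = np.column_stack([x, 6.0 * np.sin(x / 6.0), np.zeros(n)])
    return _rescale_bonds(pts, BOND_LENGTH, closed=False)


def _loosen_traj(n_frames, untie_frame, sigma, rng, n_res):
    """Loop loosening: the knotted span grows toward both chain ends, then
    the knot is gone.

    Knotted frames are trefoil subarcs (small fixed gap) whose residue span
    m(f) grows at the expense of both straight tails — the knot termini move
    toward opposite chain ends, the loosening signature.  Frames from
    ``untie_frame`` on use a simple planar curve, which cannot be knotted
    under any closure; the per-frame topology is therefore known by
    construction on both sides of the event.
    """
    if not (4 <= untie_frame < n_frames):
        raise ValueError("untie_frame must allow a knotted lead-in and an "
                         "unknotted terminal run")
    g0 = 0.35
    min_tail = 4          # keeps the termini exposed for decisive typing
    m0 = max(24, int(0.55 * n_res))
    m_max = n_res - 2 * min_tail
    frames = []
    truth_core = []
    knotted = []
    for f in range(n_frames):
        if f < untie_frame:
            frac = f / max(untie_frame - 1, 1)
            m = int(round(m0 + frac * (m_max - m0)))
            tail_n = (n_res - m) // 2
            tail_c = n_res - m - tail_n
            pts = _arc_with_tails(g0, m, tail_n, tail_c)
            truth_core.append((tail_n + 1, tail_n + m))
            knotted.append(True)
        else:
            pts = _planar_open_curve(n_res)
            truth_core.append(None)
            knotted.append(False)
        frames.append(Chain(jitter(pts, sigma, rng)))
    traj = Trajectory(frames)
    spec = FixtureSpec(
        kind="untie_traj",
        params={"mode": "loosen", "n_frames": n_frames, "sigma": sigma,
                "n_res": n_res},
        ground_truth={"mode": "loosening", "untie_frame": untie_frame,
                      "knotted": knotted, "core": truth_core},
    )
    return traj, spec


# rotation placing the arc's end-to-end vector along +x, solved once at import
def _block_geometry(block_len: int) -> tuple[np.ndarray, float]:
    arc = open_torus_arc(0.45, block_len)
    arc = arc - arc[0]
    v = arc[-1] - arc[0]
    vn = v / np.linalg.norm(v)
    # rotate vn onto +x (Rodrigues)
    x = np.array([1.0, 0.0, 0.0])
    axis = np.cross(vn, x)
    s = np.linalg.norm(axis)
    c = float(vn @ x)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        axis = axis / s
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + s * K + (1 - c) * (K @ K)
    arc = arc @ rot.T
    return arc, float(np.linalg.norm(v))


def slide_block_chain(block_start: int, n_res: int, block_len: int = 24,
                      bond: float = BOND_LENGTH) -> np.ndarray:
    """Straight chain with a tight trefoil block at residues
    [block_start, block_start + block_len - 1] (1-based)."""
    arc, span = _block_geometry(block_len)
    p0 = block_start - 1  # points before the block
    n_after = n_res - p0 - block_len
    if p0 < 0 or n_after < 0:
        raise ValueError("block does not fit in the chain")
    entry = np.array([p0 * bond, 0.0, 0.0])
    prefix = np.column_stack([bond * np.arange(p0), np.zeros(p0), np.zeros(p0)])
    block = arc + entry
    exit_pt = block[-1]
    suffix = exit_pt + np.column_stack([
        bond * np.arange(1, n_after + 1), np.zeros(n_after), np.zeros(n_after)])
    return np.vstack([prefix, block, suffix])


def _slide_traj(mode, n_frames, sigma, rng, n_res):
    block_len = 24
    travel = n_frames - 1  # one residue per frame
    margin = 6
    if 2 * margin + block_len + travel > n_res:
        raise ValueError("chain too short for the requested slide")
    if mode == "slide_C":
        starts = [margin + f for f in range(n_frames)]
    else:
        starts = [margin + travel - f for f in range(n_frames)]
    frames = []
    truth_core = []
    for f in range(n_frames):
        s = starts[f] + 1  # 1-based residue
        pts = jitter(slide_block_chain(s, n_res, block_len), sigma, rng)
        frames.append(Chain(pts))
        truth_core.append((s, s + block_len - 1))
    traj = Trajectory(frames)
    spec = FixtureSpec(
        kind="untie_traj",
        params={"mode": mode, "n_frames": n_frames, "sigma": sigma,
                "n_res": n_res, "block_len": block_len},
        ground_truth={"mode": "sliding_C" if mode == "slide_C" else "sliding_N",
                      "untie_frame": None,
                      "knotted": [True] * n_frames, "core": truth_core},
    )
    return traj, spec


# ---------------------------------------------------------------------------
# Two-domain contact fixture


def _helix(n: int, origin: np.ndarray, bond: float = BOND_LENGTH) -> np.ndarray:
    """Idealised alpha-helical Cα trace advancing along +x."""
    k = np.arange(n)
    radius, rise, turn = 2.3, 1.5, 100.0 * np.pi / 180
    pts = np.column_stack([rise * k, radius * np.cos(turn * k),
                           radius * np.sin(turn * k)])
    return pts + origin


def two_domain_traj(n_res_per_domain: int = 20,
                    separation_per_frame: float = 2.0,
                    n_frames: int = 10, sigma: float = 0.0,
                    rng: np.random.Generator | None = None,
                    contact_cutoff: float = 8.0
                    ) -> tuple[Trajectory, list[tuple[int, int, float]], FixtureSpec]:
    """Two rigid helical blocks; block 2 translates along +z on a schedule.

    Returns the trajectory, the planted native contacts (all inter-block
    residue pairs within ``contact_cutoff`` Å at frame 0, as
    (res_i, res_j, distance)), and the fixture spec.
    """
    rng = rng or np.random.default_rng(0)
    m = n_res_per_domain
    a = _helix(m, np.zeros(3))
    b = _helix(m, np.array([0.0, 7.0, 0.0]))
    contacts = []
    for i in range(m):
        for j in range(m):
            d = float(np.linalg.norm(a[i] - b[j]))
            if d < contact_cutoff:
                contacts.append((i + 1, m + j + 1, d))
    frames = []
    for f in range(n_frames):
        shift = np.array([0.0, 0.0, separation_per_frame * f])
        pts = jitter(np.vstack([a, b + shift]), sigma, rng)
        frames.append(Chain(pts))
    traj = Trajectory(frames)
    spec = FixtureSpec(
        kind="two_domain_traj",
        params={"n_res_per_domain": m, "separation_per_frame": separation_per_frame,
                "n_frames": n_frames, "sigma": sigma,
                "contact_cutoff": contact_cutoff},
        ground_truth={"n_contacts": len(contacts),
                      "domain_a": (1, m), "domain_b": (m + 1, 2 * m)},
    )
    return traj, contacts, spec


def half_broken_ladder(n_pairs: int = 12, rung: float = 6.5,
                       bond: float = BOND_LENGTH) -> tuple[Chain, Chain]:
    """Reference and half-broken frames with exactly countable contacts.

    Two parallel strands ``rung`` Å apart form one native contact per rung
    (with a Cα cutoff of 7 Å the diagonal neighbours at ~7.5 Å are excluded).
    In the second frame the far half of strand B is displaced 60 Å, breaking
    exactly half of the contacts, so Q = 0.5 holds by construction.
    """
    if n_pairs % 2:
        raise ValueError("n_pairs must be even for an exact half")
    x = bond * np.arange(n_pairs, dtype=float)
    a = np.column_stack([x, np.zeros(n_pairs), np.zeros(n_pairs)])
    b = np.column_stack([x, np.full(n_pairs, rung), np.zeros(n_pairs)])
    ref = Chain(np.vstack([a, b]))
    b2 = b.copy()
    b2[n_pairs // 2:, 2] += 60.0
    return ref, Chain(np.vstack([a, b2]))


# ---------------------------------------------------------------------------
# Synthetic stand-in for the trefoil-knotted methyltransferase model


def synthetic_ybea_model(bond: float = BOND_LENGTH) -> tuple[Chain, FixtureSpec]:
    """Synthetic 155-residue Cα model emulating YbeA's knot architecture.

    This is a geometric stand-in, not the crystal structure: a trefoil arc is
    planted over residues 70-120 (the loop-plus-crossing region through which
    the C-terminal helix threads), with an unknotted 69-residue N-arm and a
    35-residue straight C-tail, so that the chain reproduces the protein's
    described topology - a shallow trefoil whose core ends ~35 residues
    before the C-terminus and begins near residue 70.
    """
    # small gap: the cut sits at the torus outer equator, keeping both arc
    # termini exposed so subchain typing stays decisive during trimming
    arc = open_torus_arc(0.08, 51)  # residues 70..120
    centroid = arc.mean(axis=0)
    n_dir = arc[0] - centroid
    c_dir = arc[-1] - centroid
    # keep the two tails from running parallel
    c_dir = c_dir + 0.6 * np.cross(n_dir, c_dir) / np.linalg.norm(n_dir)
    n_tail = _straight_tail(arc[0], n_dir, 69, bond)[::-1]
    c_tail = _straight_tail(arc[-1], c_dir, 35, bond)
    pts = np.vstack([n_tail, arc, c_tail])
    labels = [ResidueLabel(i + 1, "A", "ALA") for i in range(len(pts))]
    chain = Chain(pts, labels)
    spec = FixtureSpec(
        kind="synthetic_ybea",
        params={"n_res": 155},
        ground_truth={"knot_type": "3_1", "span_start": 70, "span_end": 120,
                      "c_tail": 35},
    )
    return chain, spec
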