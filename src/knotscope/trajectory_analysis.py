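"""Per-frame knot tracking, untying-mode classification, and structural
observables (native-contact ratios, contact maps, backbone angles, H-bonds).

The tracking output is the per-frame series of knot termini and mid-position
from which untying by loosening (termini moving toward opposite chain ends)
is distinguished from untying by sliding (a constant-size core drifting
toward one terminus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as struc

from .chain_io import Chain, DomainMap, Trajectory
from .closure import ClosureParams
from .knot_core import KnotRecord, find_core

__all__ = [
    "KnotSeries",
    "ContactSet",
    "UntieEvent",
    "track_knot",
    "classify_untie",
    "native_contacts",
    "contact_ratio",
    "contact_map",
    "angle_series",
    "hbond_count",
]


@dataclass
class KnotSeries:
    """Per-frame knot records over a trajectory."""

    records: list[KnotRecord]
    times: np.ndarray | None = None
    chain_length: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, r in enumerate(self.records):
            rows.append({
                "frame": f,
                "time": float(self.times[f]) if self.times is not None else float(f),
                "type": r.knot_type,
                "start": r.core_start if r.core_start is not None else np.nan,
                "end": r.core_end if r.core_end is not None else np.nan,
                "mid": r.mid if r.mid is not None else np.nan,
                "size": r.size,
                "dominance": r.dominance,
            })
        return pd.DataFrame(rows)


def track_knot(traj: Trajectory, closure_params: ClosureParams,
               warm_start: bool = True) -> KnotSeries:
    """Locate the knotted core in every frame.

    Each frame gets an independent RNG substream (seed = base seed + frame
    index) so results are reproducible regardless of stride or restarts.
    With ``warm_start``, trimming begins near the previous frame's core
    (verified, with fallback to the full search) — per-frame core motion in
    trajectories is a few residues, so this saves most subchain typings.
    """
    records: list[KnotRecord] = []
    prev: KnotRecord | None = None
    for f, frame in enumerate(traj.frames):
        params = closure_params.with_seed(closure_params.seed + f)
        rec = None
        if warm_start and prev is not None and prev.knotted:
            rec = _warm_find_core(frame, params, prev)
        if rec is None:
            rec = find_core(frame, params)
        records.append(rec)
        prev = rec
    return KnotSeries(records, traj.times, len(traj.frames[0]))


def _warm_find_core(chain: Chain, params: ClosureParams,
                    prev: KnotRecord, margin: int = 4) -> KnotRecord | None:
    """Trim starting near the previous core; None signals fallback."""
    from .closure import knot_spectrum
    from .knot_core import _keeps_type, _trim_gallop

    rng = np.random.default_rng(params.seed)
    full = knot_spectrum(chain, params, rng)
    if full.dominant in ("0_1", "unknown") or full.dominant_freq <= 0.5:
        return None  # unknotted / indeterminate: let find_core handle it
    target = full.dominant
    res = chain.res_ids
    n = len(chain)
    try:
        s0 = max(0, chain.index_of(prev.core_start) - margin)
        e0 = min(n - 1, chain.index_of(prev.core_end) + margin)
    except KeyError:
        return None
    # the widened previous window must still carry the knot, else fall back
    if not _keeps_type(chain, s0, e0, target, params, rng):
        return None
    s = _trim_gallop(chain, s0, e0, target, params, rng, "start")
    e = _trim_gallop(chain, s0, e0, target, params, rng, "end")
    if e - s < 2:
        return None
    return KnotRecord(target, int(res[s]), int(res[e]),
                      dominance=full.dominant_freq, n_tail=int(res[-1] - res[e]))


# ---------------------------------------------------------------------------
# Untying-mode classification


@dataclass(frozen=True)
class UntieEvent:
    """Outcome of a trajectory: maintained, loosening, or sliding (N/C).

    ``untie_frame`` is the first frame of a terminal run of unknotted frames
    (None when the knot survives).  ``default_mode`` flags events typed as
    loosening only because the chain untied without a clear geometric
    signature in the preceding frames.
    """

    mode: str
    untie_frame: int | None = None
    default_mode: bool = False


def _median_ends(values: np.ndarray, k: int) -> tuple[float, float]:
    k = max(1, min(k, len(values) // 2)) if len(values) > 1 else 1
    return float(np.median(values[:k])), float(np.median(values[-k:]))


def classify_untie(series: KnotSeries, K: int = 5, W: int = 20,
                   delta: float = 3.0) -> UntieEvent:
    """Classify how (whether) the knot left the chain.

    untie_frame: first frame of a terminal unknotted run of >= K frames.
    Mode over the last W knotted frames (median-smoothed to resist closure
    noise): loosening if the start moved >= delta residues N-ward AND the end
    >= delta C-ward; sliding toward a terminus if the mid-position moved
    >= delta that way with the size changing by < delta; otherwise maintained,
    or loosening-by-default when the chain untied without a clear signature.
    """
    knotted = np.array([r.knotted for r in series.records])
    n = len(knotted)

    untie_frame = None
    if not knotted[-1]:
        f = n
        while f > 0 and not knotted[f - 1]:
            f -= 1
        run = n - f
        if run >= min(K, n):
            untie_frame = f

    idx = np.nonzero(knotted)[0]
    if len(idx) == 0:
        return UntieEvent("loosening", untie_frame, default_mode=True)
    window = idx[-W:]
    starts = np.array([series.records[i].core_start for i in window], float)
    ends = np.array([series.records[i].core_end for i in window], float)
    mids = np.array([series.records[i].mid for i in window], float)
    sizes = np.array([series.records[i].size for i in window], float)
    k = max(2, len(window) // 4)
    s0, s1 = _median_ends(starts, k)
    e0, e1 = _median_ends(ends, k)
    m0, m1 = _median_ends(mids, k)
    z0, z1 = _median_ends(sizes, k)
    d_start, d_end, d_mid, d_size = s1 - s0, e1 - e0, m1 - m0, z1 - z0

    if d_start <= -delta and d_end >= delta:
        return UntieEvent("loosening", untie_frame)
    if abs(d_size) < delta:
        if d_mid >= delta:
            return UntieEvent("sliding_C", untie_frame)
        if d_mid <= -delta:
            return UntieEvent("sliding_N", untie_frame)
    if untie_frame is not None:
        return UntieEvent("loosening", untie_frame, default_mode=True)
    return UntieEvent("maintained", None)


# ---------------------------------------------------------------------------
# Native contacts


@dataclass
class ContactSet:
    """Native residue-pair contacts with reference distances (Å)."""

    pairs: pd.DataFrame  # columns: res_i, res_j, ref_dist
    cutoff: float
    min_seq_sep: int
    ca_only: bool = False

    def __len__(self) -> int:
        return len(self.pairs)

    def select(self, domains: DomainMap, name_a: str, name_b: str) -> "ContactSet":
        """Contacts with one residue in each named domain."""
        a0, a1 = domains.ranges[name_a]
        b0, b1 = domains.ranges[name_b]
        p = self.pairs
        in_ab = (p.res_i.between(a0, a1) & p.res_j.between(b0, b1)) | (
            p.res_i.between(b0, b1) & p.res_j.between(a0, a1))
        return ContactSet(p[in_ab].reset_index(drop=True), self.cutoff,
                          self.min_seq_sep, self.ca_only)


def _residue_min_distances(atoms: struc.AtomArray, cutoff: float
                           ) -> dict[tuple[int, int], float]:
    heavy = atoms[atoms.element != "H"]
    tree = cKDTree(heavy.coord)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    res = heavy.res_id
    out: dict[tuple[int, int], float] = {}
    if len(pairs) == 0:
        return out
    d = np.linalg.norm(heavy.coord[pairs[:, 0]] - heavy.coord[pairs[:, 1]], axis=1)
    for (i, j), dist in zip(pairs, d):
        ri, rj = int(res[i]), int(res[j])
        if ri == rj:
            continue
        key = (min(ri, rj), max(ri, rj))
        if dist < out.get(key, np.inf):
            out[key] = float(dist)
    return out


def native_contacts(ref: struc.AtomArray | Chain, cutoff: float | None = None,
                    min_seq_sep: int = 4) -> ContactSet:
    """Native contacts of a reference structure.

    All-atom input: residue pairs whose minimum heavy-atom distance is below
    ``cutoff`` (default 4.5 Å).  Cα-only input (a Chain) falls back to the
    Cα-Cα distance with a larger default cutoff (8.0 Å).  Pairs closer than
    ``min_seq_sep`` in sequence are excluded.
    """
    if isinstance(ref, Chain):
        cutoff = 8.0 if cutoff is None else cutoff
        res = ref.res_ids
        tree = cKDTree(ref.points)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        rows = []
        for i, j in pairs:
            ri, rj = int(res[i]), int(res[j])
            if abs(ri - rj) >= min_seq_sep:
                d = float(np.linalg.norm(ref.points[i] - ref.points[j]))
                rows.append((min(ri, rj), max(ri, rj), d))
        df = pd.DataFrame(rows, columns=["res_i", "res_j", "ref_dist"])
        return ContactSet(df.sort_values(["res_i", "res_j"]).reset_index(drop=True),
                          cutoff, min_seq_sep, ca_only=True)
    cutoff = 4.5 if cutoff is None else cutoff
    dists = _residue_min_distances(ref, cutoff)
    rows = [(i, j, d) for (i, j), d in sorted(dists.items())
            if abs(i - j) >= min_seq_sep]
    df = pd.DataFrame(rows, columns=["res_i", "res_j", "ref_dist"])
    return ContactSet(df, cutoff, min_seq_sep, ca_only=False)


def contact_ratio(traj: Trajectory, contacts: ContactSet,
                  scale: float = 1.2) -> np.ndarray:
    """Per-frame fraction Q of native contacts still formed.

    A contact counts as formed when the frame's Cα-Cα distance is below
    ``scale`` times the native-contact cutoff; the reference frame therefore
    scores exactly 1.
    """
    if len(contacts) == 0:
        raise ValueError("empty contact set")
    ref_chain = traj.frames[0]
    idx_of = {int(r): k for k, r in enumerate(ref_chain.res_ids)}
    ii = np.array([idx_of[r] for r in contacts.pairs.res_i])
    jj = np.array([idx_of[r] for r in contacts.pairs.res_j])
    thresh = scale * contacts.cutoff
    q = np.empty(len(traj))
    for f, frame in enumerate(traj.frames):
        d = np.linalg.norm(frame.points[ii] - frame.points[jj], axis=1)
        q[f] = float(np.mean(d < thresh))
    return q


def contact_map(ref: struc.AtomArray | Chain) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrix of minimum inter-residue distances (Å).

    Returns (matrix, residue ids).  All-atom input uses minimum heavy-atom
    distances; Cα input uses Cα-Cα distances.
    """
    if isinstance(ref, Chain):
        res = ref.res_ids
        diff = ref.points[:, None, :] - ref.points[None, :, :]
        return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)), res
    heavy = ref[ref.element != "H"]
    res = np.unique(heavy.res_id)
    pos = {int(r): heavy.coord[heavy.res_id == r] for r in res}
    n = len(res)
    mat = np.zeros((n, n))
    for a in range(n):
        pa = pos[int(res[a])]
        for b in range(a + 1, n):
            pb = pos[int(res[b])]
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1).min()
            mat[a, b] = mat[b, a] = d
    return mat, res


def angle_series(traj: Trajectory, a: int, b: int, c: int) -> np.ndarray:
    """Planar angle (degrees) at residue ``b`` between rays b->a and b->c."""
    ch0 = traj.frames[0]
    ia, ib, ic = ch0.index_of(a), ch0.index_of(b), ch0.index_of(c)
    out = np.empty(len(traj))
    for f, frame in enumerate(traj.frames):
        v1 = frame.points[ia] - frame.points[ib]
        v2 = frame.points[ic] - frame.points[ib]
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        out[f] = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return out


def hbond_count(frame: struc.AtomArray, d_cut: float = 3.5) -> int:
    """Geometric H-bond count: N/O donor-acceptor pairs (different residues)
    within ``d_cut`` Å.  Requires an all-atom frame."""
    if isinstance(frame, Chain):
        raise TypeError("hbond_count requires all-atom input, got a Cα trace")
    no = frame[np.isin(frame.element, ["N", "O"])]
    if no.array_length() == 0:
        raise ValueError("no N/O atoms present; requires all-atom input")
    tree = cKDTree(no.coord)
    pairs = tree.query_pairs(d_cut, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    res = no.res_id
    return int(np.sum(res[pairs[:, 0]] != res[pairs[:, 1]]))
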