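"""Knot tracking, untying classification, and structural observables."""

import numpy as np
import pytest
import biotite.structure as struc

from knotscope import (ClosureParams, Trajectory, angle_series, classify_untie,
                       contact_map, contact_ratio, hbond_count, native_contacts,
                       track_knot)
from knotscope.chain_io import Chain, DomainMap
from knotscope.knot_core import KnotRecord
from knotscope.trajectory_analysis import KnotSeries
from knotscope import synthetic_data as sd

PARAMS = ClosureParams(n_closures=25, seed=42)


def series_from(types_and_cores):
    recs = []
    for t, core in types_and_cores:
        if core is None:
            recs.append(KnotRecord("0_1"))
        else:
            recs.append(KnotRecord(t, core[0], core[1], dominance=1.0))
    return KnotSeries(recs)


class TestTrackKnot:
    def test_static_trajectory_records_stable(self):
        frame = Chain(sd.slide_block_chain(10, 52))
        traj = Trajectory([frame] * 6)
        series = track_knot(traj, PARAMS)
        starts = [r.core_start for r in series.records]
        ends = [r.core_end for r in series.records]
        assert all(r.knot_type == "3_1" for r in series.records)
        assert max(starts) - min(starts) <= 2
        assert max(ends) - min(ends) <= 2

    def test_low_noise_knotted_trajectory_stays_trefoil(self):
        """A gently jittered knotted chain keeps its trefoil in every frame —
        the knot is stable under normal conditions."""
        rng = np.random.default_rng(5)
        base = sd.slide_block_chain(12, 52)
        frames = [Chain(sd.jitter(base, 0.1, rng)) for _ in range(10)]
        series = track_knot(Trajectory(frames), PARAMS)
        assert all(r.knot_type == "3_1" for r in series.records)

    def test_per_frame_seeding_reproducible(self):
        frame = Chain(sd.slide_block_chain(10, 52))
        traj = Trajectory([frame] * 3)
        a = track_knot(traj, PARAMS).to_frame()
        b = track_knot(traj, PARAMS).to_frame()
        assert a.equals(b)


class TestClassifyUntie:
    def test_all_knotted_is_maintained(self):
        s = series_from([("3_1", (10, 30))] * 10)
        ev = classify_untie(s)
        assert ev.mode == "maintained" and ev.untie_frame is None

    def test_unknotted_from_start_flags_default_loosening(self):
        s = series_from([("0_1", None)] * 8)
        ev = classify_untie(s)
        assert ev.untie_frame == 0
        assert ev.mode == "loosening" and ev.default_mode

    def test_loosening_signature(self):
        rows = [("3_1", (20 - k, 40 + k)) for k in range(10)]
        rows += [("0_1", None)] * 6
        ev = classify_untie(series_from(rows))
        assert ev.mode == "loosening" and not ev.default_mode
        assert ev.untie_frame == 10

    def test_sliding_signatures(self):
        rows = [("3_1", (10 + k, 30 + k)) for k in range(12)]
        ev = classify_untie(series_from(rows))
        assert ev.mode == "sliding_C" and ev.untie_frame is None
        rows = [("3_1", (30 - k, 50 - k)) for k in range(12)]
        assert classify_untie(series_from(rows)).mode == "sliding_N"

    def test_short_terminal_blip_not_an_untie(self):
        rows = [("3_1", (10, 30))] * 10 + [("0_1", None)] * 2
        ev = classify_untie(series_from(rows), K=5)
        assert ev.untie_frame is None

    def test_loosen_fixture_recovered(self):
        rng = np.random.default_rng(21)
        traj, spec = sd.untie_traj("loosen", n_frames=26, untie_frame=18,
                                   sigma=0.05 * sd.BOND_LENGTH, rng=rng)
        ev = classify_untie(track_knot(traj, PARAMS))
        assert ev.mode == "loosening"
        assert abs(ev.untie_frame - 18) <= 2

    def test_slide_fixture_recovered(self):
        rng = np.random.default_rng(22)
        traj, spec = sd.untie_traj("slide_C", n_frames=17,
                                   sigma=0.05 * sd.BOND_LENGTH, rng=rng)
        series = track_knot(traj, PARAMS)
        ev = classify_untie(series)
        assert ev.mode == "sliding_C" and ev.untie_frame is None
        df = series.to_frame()
        drift = df["mid"].iloc[-3:].median() - df["mid"].iloc[:3].median()
        size_change = df["size"].iloc[-3:].median() - df["size"].iloc[:3].median()
        assert drift >= 10
        assert abs(size_change) < 3


class TestContacts:
    def test_reference_frame_q_is_exactly_one(self):
        traj, _, _ = sd.two_domain_traj(n_frames=6)
        cset = native_contacts(traj.frames[0])
        q = contact_ratio(traj, cset)
        assert q[0] == 1.0

    def test_full_separation_reaches_zero(self):
        traj, _, spec = sd.two_domain_traj(n_frames=14, separation_per_frame=5.0)
        cset = native_contacts(traj.frames[0])
        m = spec.ground_truth["domain_a"][1]
        dm = DomainMap({"A": (1, m), "B": (m + 1, 2 * m)})
        q = contact_ratio(traj, cset.select(dm, "A", "B"))
        assert q[-1] == 0.0  # every inter-domain pair far beyond the cutoff

    def test_half_broken_is_exactly_half(self):
        ref, half = sd.half_broken_ladder(n_pairs=12)
        cset = native_contacts(ref, cutoff=7.0)
        assert len(cset) == 12
        q = contact_ratio(Trajectory([ref, half]), cset)
        assert q[1] == 0.5

    def test_monotone_separation_gives_non_increasing_smoothed_q(self):
        traj, _, _ = sd.two_domain_traj(n_frames=12, separation_per_frame=2.0)
        cset = native_contacts(traj.frames[0])
        q = contact_ratio(traj, cset)
        sm = np.convolve(q, np.ones(3) / 3, mode="valid")
        assert np.all(np.diff(sm) <= 1e-12)

    def test_q_invariant_under_rigid_motion(self):
        traj, _, _ = sd.two_domain_traj(n_frames=4)
        cset = native_contacts(traj.frames[0])
        from knotscope.curves import random_rotation
        rng = np.random.default_rng(3)
        rot, shift = random_rotation(rng), rng.uniform(-30, 30, 3)
        moved = Trajectory([f.transformed(rot, shift) for f in traj.frames])
        assert np.array_equal(contact_ratio(traj, cset),
                              contact_ratio(moved, cset))

    def test_domain_selection(self):
        traj, planted, spec = sd.two_domain_traj(n_frames=3)
        cset = native_contacts(traj.frames[0])
        m = spec.ground_truth["domain_a"][1]
        dm = DomainMap({"A": (1, m), "B": (m + 1, 2 * m)})
        inter = cset.select(dm, "A", "B")
        intra = cset.select(dm, "A", "A")
        assert len(inter) > 0
        # inter-domain selection keeps exactly the pairs spanning both blocks
        assert ((inter.pairs.res_i <= m) & (inter.pairs.res_j > m)).all()
        assert ((intra.pairs.res_i <= m) & (intra.pairs.res_j <= m)).all()

    def test_contact_map_symmetric_with_zero_diagonal(self):
        chain = Chain(sd.slide_block_chain(5, 30))
        mat, res = contact_map(chain)
        assert mat.shape == (30, 30)
        assert np.allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)


def make_atoms(coords, elements, res_ids):
    atoms = struc.AtomArray(len(coords))
    atoms.coord = np.asarray(coords, dtype=float)
    atoms.element = np.asarray(elements)
    atoms.res_id = np.asarray(res_ids)
    atoms.atom_name = np.asarray(elements)
    atoms.res_name = np.asarray(["ALA"] * len(coords))
    atoms.chain_id = np.asarray(["A"] * len(coords))
    atoms.hetero = np.zeros(len(coords), bool)
    return atoms


class TestAllAtom:
    def test_native_contacts_heavy_atom_min_distance(self):
        # residues 1 and 6: closest heavy atoms 4.0 Å apart; H must be ignored
        atoms = make_atoms(
            [[0, 0, 0], [1.0, 0, 0], [5.0, 0, 0], [9.0, 0, 0], [4.2, 0, 0]],
            ["N", "C", "O", "C", "H"],
            [1, 1, 6, 6, 1],
        )
        cset = native_contacts(atoms, cutoff=4.5, min_seq_sep=4)
        assert len(cset) == 1
        row = cset.pairs.iloc[0]
        assert (row.res_i, row.res_j) == (1, 6)
        assert row.ref_dist == pytest.approx(4.0)

    def test_hbond_count_geometric(self):
        atoms = make_atoms(
            [[0, 0, 0], [3.0, 0, 0], [3.0, 3.0, 0], [20.0, 0, 0]],
            ["N", "O", "N", "O"],
            [1, 5, 5, 9],
        )
        # pairs under 3.5 Å between different residues: N1-O5 only
        # (O5-N5 same residue, distances to O9 are huge)
        assert hbond_count(atoms, d_cut=3.5) == 1

    def test_hbond_requires_all_atom(self):
        with pytest.raises(TypeError, match="all-atom"):
            hbond_count(Chain(sd.slide_block_chain(5, 30)))


class TestAngles:
    def test_reference_constructions(self):
        def traj_of(points):
            return Trajectory([Chain(np.asarray(points, float))])

        collinear = traj_of([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert angle_series(collinear, 1, 2, 3)[0] == pytest.approx(180.0)
        right = traj_of([[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        assert angle_series(right, 1, 2, 3)[0] == pytest.approx(90.0)
        equilateral = traj_of([[1, 0, 0], [0, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        assert angle_series(equilateral, 1, 2, 3)[0] == pytest.approx(60.0)
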