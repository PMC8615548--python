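"""Fixture generators: determinism and ground-truth fidelity."""

import numpy as np
import pytest

from knotscope import ClosureParams, detect_knot, knot_spectrum
from knotscope.chain_io import Chain
from knotscope import synthetic_data as sd


class TestCurveGenerators:
    @pytest.mark.parametrize("maker,label", [
        (lambda: sd.torus_knot(2, 3, 120), "3_1"),
        (lambda: sd.torus_knot(2, 5, 200), "5_1"),
        (lambda: sd.torus_knot(1, 0, 60), "0_1"),
        (lambda: sd.figure_eight(160), "4_1"),
        (lambda: sd.circle(40), "0_1"),
    ])
    def test_known_knot_types(self, maker, label, rng):
        assert detect_knot(maker(), rng).label == label

    def test_bond_rescaling(self):
        curve = sd.torus_knot(2, 3, 120)
        segs = np.diff(np.vstack([curve.points, curve.points[:1]]), axis=0)
        assert np.mean(np.linalg.norm(segs, axis=1)) == pytest.approx(3.8)

    def test_random_walk_determinism(self):
        a = sd.random_walk(30, rng=np.random.default_rng(9))
        b = sd.random_walk(30, rng=np.random.default_rng(9))
        assert np.array_equal(a.points, b.points)


class TestOpenKnot:
    def test_span_ground_truth(self):
        chain, spec = sd.open_knot(sd.torus_knot(2, 3, 60), gap=3,
                                   tail_n=7, tail_c=5)
        assert len(chain) == 57 + 12
        gt = spec.ground_truth
        assert (gt["span_start"], gt["span_end"]) == (8, 64)

    def test_gap_bounds(self):
        with pytest.raises(ValueError):
            sd.open_knot(sd.torus_knot(2, 3, 20), gap=0)
        with pytest.raises(ValueError):
            sd.open_knot(sd.torus_knot(2, 3, 20), gap=19)


class TestUntieTrajectories:
    def test_seeded_determinism(self):
        a, _ = sd.untie_traj("loosen", 12, 8, 0.1, np.random.default_rng(4))
        b, _ = sd.untie_traj("loosen", 12, 8, 0.1, np.random.default_rng(4))
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.points, fb.points)

    def test_loosen_per_frame_topology_matches_ground_truth(self):
        """At sigma = 0 every frame types exactly as the generator claims:
        trefoil strictly before the untie frame, unknot from it onward."""
        traj, spec = sd.untie_traj("loosen", n_frames=16, untie_frame=10,
                                   sigma=0.0, rng=np.random.default_rng(0))
        knotted = spec.ground_truth["knotted"]
        assert knotted == [f < 10 for f in range(16)]
        params = ClosureParams(n_closures=25, seed=3)
        for f, frame in enumerate(traj.frames):
            spec_f = knot_spectrum(frame, params.with_seed(3 + f))
            want = "3_1" if knotted[f] else "0_1"
            assert spec_f.dominant == want, f"frame {f}"
            assert spec_f.dominant_freq > 0.7

    def test_loosen_core_expands_toward_both_ends(self):
        _, spec = sd.untie_traj("loosen", n_frames=16, untie_frame=12,
                                sigma=0.0, rng=np.random.default_rng(0))
        cores = [c for c in spec.ground_truth["core"] if c is not None]
        starts = [c[0] for c in cores]
        ends = [c[1] for c in cores]
        assert starts[0] - starts[-1] >= 3
        assert ends[-1] - ends[0] >= 3

    def test_slide_ground_truth_geometry(self):
        traj, spec = sd.untie_traj("slide_C", n_frames=10, sigma=0.0,
                                   rng=np.random.default_rng(1))
        cores = spec.ground_truth["core"]
        mids = [(a + b) / 2 for a, b in cores]
        sizes = [b - a + 1 for a, b in cores]
        assert np.all(np.diff(mids) == 1.0)
        assert len(set(sizes)) == 1
        assert spec.ground_truth["untie_frame"] is None
        # frames are the same block rigidly translated by one bond along x
        d01 = traj.frames[1].points[20] - traj.frames[0].points[19]
        assert np.allclose(d01, [3.8, 0.0, 0.0])

    def test_slide_block_is_trefoil_every_frame(self):
        traj, _ = sd.untie_traj("slide_N", n_frames=6, sigma=0.0,
                                rng=np.random.default_rng(2))
        params = ClosureParams(n_closures=25, seed=8)
        for f, frame in enumerate(traj.frames):
            assert knot_spectrum(frame, params.with_seed(8 + f)).dominant == "3_1"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown untie mode"):
            sd.untie_traj("melt", 10, 5)


class TestTwoDomain:
    def test_planted_contacts_counted(self):
        traj, contacts, spec = sd.two_domain_traj(n_res_per_domain=15,
                                                  n_frames=4)
        assert spec.ground_truth["n_contacts"] == len(contacts) > 0
        m = spec.ground_truth["domain_a"][1]
        for i, j, d in contacts:
            assert i <= m < j
            assert d < 8.0

    def test_ladder_requires_even_pairs(self):
        with pytest.raises(ValueError):
            sd.half_broken_ladder(n_pairs=7)


class TestYbeaModel:
    def test_architecture(self):
        chain, spec = sd.synthetic_ybea_model()
        assert len(chain) == 155
        gt = spec.ground_truth
        assert gt["span_start"] == 70 and gt["span_end"] == 120
        assert gt["c_tail"] == 35
        # deterministic: same call, same coordinates
        chain2, _ = sd.synthetic_ybea_model()
        assert np.array_equal(chain.points, chain2.points)

    def test_model_is_trefoil(self):
        chain, _ = sd.synthetic_ybea_model()
        spec = knot_spectrum(chain, ClosureParams(n_closures=50, seed=5))
        assert spec.dominant == "3_1"
        assert spec.dominant_freq > 0.8
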