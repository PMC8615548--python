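"""Chain/trajectory containers and the PDB / XYZ / TSV plumbing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from knotscope import (Chain, DomainMap, ResidueLabel, Trajectory,
                       read_backbone, read_series, read_trajectory, read_xyz,
                       write_series, write_xyz)


def make_chain(n=5, jump=3.8):
    pts = np.column_stack([np.arange(n) * jump, np.zeros(n), np.zeros(n)])
    return Chain(pts)


PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       8.600   0.000   0.000  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       4.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       8.600   0.000   0.000  1.00  0.00           C
END
"""

PDB_GAP = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   6       7.600   0.000   0.000  1.00  0.00           C
END
"""

PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   1.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   1.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   1.000  1.00  0.00           C
ENDMDL
END
"""


class TestChain:
    def test_invariants(self):
        with pytest.raises(ValueError, match=">= 3"):
            Chain(np.zeros((2, 3)) + np.arange(2)[:, None])
        with pytest.raises(ValueError, match="coincide"):
            Chain(np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, 0]]))
        with pytest.raises(ValueError, match="increasing"):
            Chain(np.eye(3) * 5, [ResidueLabel(2), ResidueLabel(1),
                                  ResidueLabel(3)])

    def test_subchain_and_lookup(self):
        ch = make_chain(6)
        sub = ch.subchain(1, 4)
        assert len(sub) == 4
        assert sub.labels == ch.labels[1:5]
        assert ch.index_of(3) == 2
        with pytest.raises(KeyError):
            ch.index_of(99)

    def test_trajectory_validation(self):
        a, b = make_chain(), make_chain()
        Trajectory([a, b], times=[0.0, 1.0])
        with pytest.raises(ValueError, match="increasing"):
            Trajectory([a, b], times=[1.0, 1.0])
        other = Chain(make_chain().points + 1.0,
                      [ResidueLabel(i + 10) for i in range(5)])
        with pytest.raises(ValueError, match="labels"):
            Trajectory([a, other])

    def test_domain_map(self):
        dm = DomainMap({"a1": (1, 3), "a5": (4, 5)})
        assert list(dm.residues("a1")) == [1, 2, 3]
        dm.validate_against(make_chain())
        with pytest.raises(ValueError, match="empty"):
            DomainMap({"bad": (5, 4)})
        with pytest.raises(ValueError, match="outside"):
            DomainMap({"far": (80, 90)}).validate_against(make_chain())


class TestReadBackbone:
    def test_reads_minimal_chain(self, tmp_path):
        p = tmp_path / "tiny.pdb"
        p.write_text(PDB_3RES)
        ch = read_backbone(p, "A")
        assert len(ch) == 3
        assert [l.res_id for l in ch.labels] == [1, 2, 3]
        assert ch.points[0] == pytest.approx([1.0, 0, 0])  # CA, not N

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(PDB_ALTLOC)
        ch = read_backbone(p, "A")
        assert ch.points[0] == pytest.approx([1.0, 0, 0])

    def test_gap_reported(self, tmp_path):
        p = tmp_path / "gap.pdb"
        p.write_text(PDB_GAP)
        with pytest.warns(UserWarning, match="gaps.*2->6"):
            ch = read_backbone(p, "A")
        assert [l.res_id for l in ch.labels] == [1, 2, 6]

    def test_missing_chain_names_available(self, tmp_path):
        p = tmp_path / "tiny.pdb"
        p.write_text(PDB_3RES)
        with pytest.raises(ValueError, match="available chains: A"):
            read_backbone(p, "Z")

    def test_record_order_irrelevant(self, tmp_path):
        lines = PDB_3RES.strip().splitlines()
        shuffled = "\n".join([lines[2], lines[3], lines[0], lines[1], "END"])
        a, b = tmp_path / "a.pdb", tmp_path / "b.pdb"
        a.write_text(PDB_3RES)
        b.write_text(shuffled + "\n")
        assert np.array_equal(read_backbone(a, "A").points,
                              read_backbone(b, "A").points)


class TestTrajectoryIO:
    def test_multi_model_pdb(self, tmp_path):
        p = tmp_path / "traj.pdb"
        p.write_text(PDB_TWO_MODELS)
        traj = read_trajectory(p, "A")
        assert len(traj) == 2
        assert traj.frames[1].points[0][2] == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_xyz_round_trip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        frames = [Chain(rng.uniform(-100, 100, (6, 3))) for _ in range(3)]
        traj = Trajectory(frames, times=[0.0, 0.5, 1.0])
        path = tmp_path_factory.mktemp("xyz") / "t.xyz"
        write_xyz(traj, path)
        back = read_xyz(path)
        assert len(back) == 3
        assert np.array_equal(back.times, traj.times)
        for a, b in zip(traj.frames, back.frames):
            assert np.allclose(a.points, b.points, atol=1e-6)


class TestSeries:
    def test_empty_series_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_series(pd.DataFrame(columns=["frame", "time", "size"]), path)
        text = path.read_text().strip().splitlines()
        assert text == ["frame\ttime\tsize"]

    def test_round_trip_to_precision(self, tmp_path):
        df = pd.DataFrame({"frame": [0, 1], "mid": [12.34567, 13.5]})
        path = tmp_path / "s.tsv"
        write_series(df, path)
        back = read_series(path)
        assert len(back) == 2
        assert back["mid"][0] == pytest.approx(12.34567, abs=1e-4)
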