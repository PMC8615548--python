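#!/usr/bin/env python
"""Generate the synthetic fixture set used throughout the analysis.

Writes XYZ trajectories plus ground-truth JSON sidecars for: the four
reference curves (unknot, trefoil, figure-eight, 5_1), an open trefoil with
straight tails, one loosening and one sliding trajectory, the two-domain
separation fixture, and the synthetic 155-residue YbeA-like model.
"""

import json
from pathlib import Path

import numpy as np

from knotscope.chain_io import Chain, Trajectory, write_xyz
from knotscope import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"
SEED = 2024


def dump(name: str, traj: Trajectory, meta: dict) -> None:
    write_xyz(traj, OUT / f"{name}.xyz")
    (OUT / f"{name}.json").write_text(json.dumps(meta, indent=2, default=str))
    print(f"  {name}: {len(traj)} frame(s), {len(traj.frames[0])} residues")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    print("reference curves:")
    for name, curve, label in [
        ("circle", sd.circle(40), "0_1"),
        ("trefoil", sd.torus_knot(2, 3, 120), "3_1"),
        ("figure_eight", sd.figure_eight(160), "4_1"),
        ("cinquefoil", sd.torus_knot(2, 5, 200), "5_1"),
    ]:
        dump(name, Trajectory([Chain(curve.points)]),
             {"kind": "closed_curve", "ground_truth": {"knot_type": label}})

    print("open chains:")
    chain, spec = sd.open_knot(sd.torus_knot(2, 3, 120), gap=4,
                               tail_n=20, tail_c=20)
    dump("open_trefoil_tails", Trajectory([chain]),
         {"kind": spec.kind, "params": spec.params,
          "ground_truth": spec.ground_truth})

    ybea, yspec = sd.synthetic_ybea_model()
    dump("synthetic_ybea", Trajectory([ybea]),
         {"kind": yspec.kind, "ground_truth": yspec.ground_truth})

    print("trajectories:")
    sigma = 0.05 * sd.BOND_LENGTH
    traj, spec = sd.untie_traj("loosen", n_frames=28, untie_frame=20,
                               sigma=sigma, rng=rng)
    dump("untie_loosening", traj,
         {"kind": spec.kind, "params": spec.params,
          "ground_truth": {k: v for k, v in spec.ground_truth.items()
                           if k != "core"}})

    traj, spec = sd.untie_traj("slide_C", n_frames=21, sigma=sigma, rng=rng)
    dump("slide_toward_C", traj,
         {"kind": spec.kind, "params": spec.params,
          "ground_truth": {k: v for k, v in spec.ground_truth.items()
                           if k != "core"}})

    traj, contacts, spec = sd.two_domain_traj(n_frames=12, rng=rng)
    dump("two_domain_separation", traj,
         {"kind": spec.kind, "params": spec.params,
          "ground_truth": spec.ground_truth})
    print(f"done -> {OUT}")


if __name__ == "__main__":
    main()
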