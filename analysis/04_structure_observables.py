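#!/usr/bin/env python
"""Knot architecture and structural observables of the synthetic YbeA model.

Locates the knotted core of the 155-residue trefoil stand-in (planted span
70-120 with a 35-residue C-tail), writes its contact map, and follows the
inter-domain native-contact ratio of the two-domain separation fixture —
the observable that signals hydrophobic-core opening before knot untying.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from knotscope import (ClosureParams, contact_map, contact_ratio, find_core,
                       native_contacts)
from knotscope.chain_io import DomainMap, write_series
from knotscope import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    chain, fspec = sd.synthetic_ybea_model()
    params = ClosureParams(n_closures=50, seed=SEED)
    rec = find_core(chain, params)
    row = {"type": rec.knot_type, "start": rec.core_start, "end": rec.core_end,
           "size": rec.size, "mid": rec.mid, "dominance": rec.dominance,
           "n_tail": rec.n_tail}
    write_series([row], OUT / "ybea_model_core.tsv")
    gt = fspec.ground_truth
    print("synthetic YbeA model (planted span "
          f"{gt['span_start']}-{gt['span_end']}, C-tail {gt['c_tail']}):")
    print(f"  detected {rec.knot_type} core [{rec.core_start}, {rec.core_end}] "
          f"(size {rec.size}, mid {rec.mid}), C-tail {rec.n_tail} residues")

    mat, res = contact_map(chain)
    np.savetxt(OUT / "ybea_model_contact_map.tsv", mat, delimiter="\t",
               fmt="%.2f")
    close = (mat < 8.0).sum() // 2 - len(chain) + 1
    print(f"  contact map {mat.shape[0]}x{mat.shape[0]} -> "
          f"ybea_model_contact_map.tsv ({close} pairs under 8 A)")

    traj, _, spec = sd.two_domain_traj(n_frames=12, separation_per_frame=2.0,
                                       rng=np.random.default_rng(SEED))
    cset = native_contacts(traj.frames[0])
    m = spec.ground_truth["domain_a"][1]
    dm = DomainMap({"A": (1, m), "B": (m + 1, 2 * m)})
    inter = cset.select(dm, "A", "B")
    q = contact_ratio(traj, inter)
    write_series(pd.DataFrame({"frame": np.arange(len(q)), "Q_A_B": q}),
                 OUT / "two_domain_contact_ratio.tsv")
    print(f"  two-domain fixture: {len(inter)} inter-domain native contacts, "
          f"Q falls {q[0]:.2f} -> {q[-1]:.2f} over {len(q)} frames")


if __name__ == "__main__":
    main()
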