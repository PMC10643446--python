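#!/usr/bin/env python
"""Extract the excited-state relaxation coordinate from trajectories.

Generates the mock amide-dimer ensemble with one planted gap-closing
stretch, reconstructs the diabatic gap by swapping state identities at
the crossing, evaluates the weighted-fluctuation relaxation vector, and
compares it with the exactly known planted direction; the vector is also
projected onto named internal coordinates (both CO stretches, the amide
plane, the shared-proton transfer coordinate).  Writes
results/relaxation_pathway.json and results/relaxation_mode.xyz.
"""
import argparse
import json
import os

import numpy as np

from nonrad import mockdimer as md, pathway as pw, trajio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-traj", type=int, default=50)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    spec = md.MockDimerSpec(seed=args.seed)
    trajs = md.generate_mock_dimer_trajectories(spec, args.n_traj)
    ens = pw.pool_ensemble(trajs)
    vec = pw.relaxation_vector(ens)
    truth = md.planted_direction(spec)

    ref = md.reference_structure()
    proj = pw.project_vector(vec, [md.CO_A, md.CO_B, md.AMIDE_PLANE_B, md.PT_AB], ref)
    trajio.write_mode_file(ref, vec.unit, os.path.join(args.out, "relaxation_mode.xyz"),
                           scale=0.5)

    out = {
        "n_trajectories": args.n_traj,
        "n_pooled_frames": ens.n_frames,
        "cosine_to_planted_direction": vec.cosine_to(truth),
        "max_abs_component": float(np.abs(vec.c).max()),
        "projections": proj["projection"],
        "shares": proj["share"],
    }
    trajio.write_results(out, os.path.join(args.out, "relaxation_pathway.json"),
                         seed=args.seed)
    print(json.dumps(out, indent=2))
    print(
        f"\nThe recovered relaxation vector points along the planted decay stretch "
        f"(cosine {out['cosine_to_planted_direction']:.3f}); the planted mode takes a "
        f"{out['shares']['CO_A']:.0%} share of the projection, spectators the rest."
    )


if __name__ == "__main__":
    main()
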