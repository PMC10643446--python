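#!/usr/bin/env python
"""Decay suppression by lock stiffness.

Runs paired-seed 250 fs hopping swarms on the gap-closing model for the
lock family (none / weak / strong) and reports the ground-state decay
fraction and decay-time quartiles of each, the model-scale analogue of
comparing a freely decaying aggregate with its hydrogen-bond-locked,
fluorescent counterpart.  Writes results/lock_scan.json.
"""
import argparse
import json
import os

import numpy as np

from nonrad import models, stats, trajio, tsh

LOCK_FAMILY = {"none": 0.0, "weak": 0.02, "strong": 0.04}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-traj", type=int, default=200)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    rows = []
    for tag, k_lock in LOCK_FAMILY.items():
        model = models.build_carbonyl_lock_model(models.CarbonylLockParams(k_lock=k_lock))
        pos, vel = models.sample_ground_state(model, args.n_traj, seed=args.seed)
        swarm = tsh.run_swarm(model, (pos, vel), tsh.IntegratorConfig(seed=args.seed + 1))
        summary = stats.decay_fraction(swarm)
        times = np.array(summary.decay_times_fs)
        rows.append({
            "lock": tag,
            "k_lock_hartree_bohr2": k_lock,
            "n_traj": summary.n_traj,
            "decay_fraction": summary.decay_fraction,
            "decay_time_quartiles_fs": (
                np.percentile(times, [25, 50, 75]).tolist() if times.size else None
            ),
        })
    trajio.write_results(rows, os.path.join(args.out, "lock_scan.json"), seed=args.seed)
    print(json.dumps(rows, indent=2))
    fr = {r["lock"]: r["decay_fraction"] for r in rows}
    print(
        f"\nDecay fraction falls from {fr['none']:.2f} (free) through {fr['weak']:.2f} "
        f"(weak lock) to {fr['strong']:.2f} (strong lock): stiffening the gap-closing "
        "stretch traps the excited state."
    )


if __name__ == "__main__":
    main()
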