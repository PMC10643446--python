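"""Swarm-level statistics over nonadiabatic trajectory ensembles.

Decay fractions and times, crossing-frame (near-degeneracy) extraction,
S0/S1/crossing coordinate histograms, the standardized excited-state-to-
crossing displacement statistic D, and the constrained-dynamics variance
hierarchy used to rank the degrees of freedom of the decay pathway.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.stats import binomtest

from .geometry import CoordinateDefinition, evaluate
from .trajectory import Trajectory

Coordinate = Union[int, CoordinateDefinition, Callable[[Trajectory], np.ndarray]]


def coordinate_values(traj: Trajectory, coordinate: Coordinate) -> np.ndarray:
    """Per-frame values of a coordinate on a trajectory.

    Integer -> model degree of freedom (bohr); CoordinateDefinition ->
    internal coordinate on Cartesian frames (angstrom / degrees);
    callable -> arbitrary user series.
    """
    if isinstance(coordinate, int):
        return traj.positions[:, coordinate]
    if isinstance(coordinate, CoordinateDefinition):
        x = traj.positions_angstrom()
        return np.array([evaluate(coordinate, f) for f in x])
    return np.asarray(coordinate(traj), dtype=float)


@dataclass
class CoInCriterion:
    """A crossing is flagged when the adiabatic gap drops below
    gap_threshold_ev (default 0.1 eV)."""

    gap_threshold_ev: float = 0.1

    def __post_init__(self) -> None:
        if self.gap_threshold_ev <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class SwarmSummary:
    n_traj: int
    n_decayed: int
    decay_times_fs: list
    coin_frames: list               # (trajectory index, frame index, flagged_by_hop)

    @property
    def decay_fraction(self) -> float:
        return self.n_decayed / self.n_traj


@dataclass
class CoInDistanceStat:
    """Standardized separation between the excited-state distribution of
    a coordinate and its values at the crossings:
    D = (mean_CoIn - mean_S1) / sd_S1 (population sd by default)."""

    mean_s1: float
    mean_coin: float
    sd_s1: float
    D: float
    label: str = ""


@dataclass
class EnsembleHistogram:
    label: str                      # "S0" | "S1" | "CoIn"
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    n: int
    empty: bool = False


@dataclass
class VarianceHierarchy:
    """Var(Y_i^j): variance of DoF i under a constraint on DoF j;
    column 0-analogue ``baseline`` is the unconstrained swarm.

    ``reduction`` = (V_0 - V_j)/V_0 (1 = fully suppressed, 0 = no effect);
    ``printed_form`` = 1 - [Var(Y_i^j) - Var(Y_i^0)]/Var(Y_i^0), which
    equals 1 + reduction and therefore ranges up to 2.  Both are reported;
    neither is a correction of the other.
    """

    dof_labels: list
    constrained_labels: list
    var_matrix: np.ndarray          # (n_dof, n_constraints)
    baseline: np.ndarray            # (n_dof,)
    reduction: np.ndarray
    printed_form: np.ndarray


# ----------------------------------------------------------------------


def detect_coin_frames(traj: Trajectory, crit: Optional[CoInCriterion] = None) -> list[tuple[int, bool]]:
    """Frames of the first excited-to-ground passage with gap below the
    criterion, as (frame index, flagged) pairs.

    If the trajectory hopped without the gap ever dipping below the
    threshold (coarse stepping), the hop frame is returned flagged=True.
    Non-decaying trajectories give an empty list.  The threshold must be
    below the initial vertical gap.
    """
    crit = crit or CoInCriterion()
    fc = traj.first_crossing
    if fc is None:
        return []
    thr = crit.gap_threshold_ev
    if traj.gap_ev[0] <= thr:
        raise ValueError("gap threshold must be below the vertical gap at excitation")
    gap = traj.gap_ev
    # search a window around the crossing: from the last pre-crossing frame on
    lo = max(fc - 1, 0)
    below = np.nonzero(gap[lo:] < thr)[0]
    if below.size:
        return [(int(lo + below[0]), False)]
    return [(int(fc), True)]


def decay_fraction(swarm: Sequence[Trajectory], crit: Optional[CoInCriterion] = None) -> SwarmSummary:
    """Count trajectories whose active state reaches the ground surface."""
    if not swarm:
        raise ValueError("empty swarm")
    crit = crit or CoInCriterion()
    n_dec = 0
    times = []
    coins = []
    for i, t in enumerate(swarm):
        fc = t.first_crossing
        if fc is None:
            continue
        n_dec += 1
        times.append(float(t.times_fs[fc]))
        for frame, flagged in detect_coin_frames(t, crit):
            coins.append((i, frame, flagged))
    return SwarmSummary(
        n_traj=len(swarm), n_decayed=n_dec, decay_times_fs=times, coin_frames=coins
    )


def coin_distance_stat(
    s1_values: np.ndarray, coin_values: np.ndarray, label: str = "", sample_sd: bool = False
) -> CoInDistanceStat:
    """D = (mean(coin) - mean(s1)) / sd(s1); population sd by default."""
    s1 = np.asarray(s1_values, dtype=float)
    co = np.asarray(coin_values, dtype=float)
    if s1.size == 0 or co.size == 0:
        raise ValueError("empty input distribution")
    sd = float(np.std(s1, ddof=1 if sample_sd else 0))
    if sd == 0:
        raise ValueError("excited-state distribution has zero spread")
    D = (float(np.mean(co)) - float(np.mean(s1))) / sd
    return CoInDistanceStat(
        mean_s1=float(np.mean(s1)), mean_coin=float(np.mean(co)), sd_s1=sd, D=D, label=label
    )


def pool_ensemble_values(
    trajs: Sequence[Trajectory],
    coordinate: Coordinate,
    crit: Optional[CoInCriterion] = None,
    s0_frames: Optional[Sequence[np.ndarray]] = None,
) -> dict:
    """Coordinate values pooled by ensemble.

    "S1": excited-state frames strictly before the first crossing;
    "CoIn": the crossing frames of each decaying trajectory;
    "S0": frames after decay (active = 0), or externally supplied
    ground-state sampling values.
    """
    crit = crit or CoInCriterion()
    s1, s0, coin = [], [], []
    for t in trajs:
        vals = coordinate_values(t, coordinate)
        fc = t.first_crossing
        if fc is None:
            s1.append(vals)
        else:
            s1.append(vals[:fc])
            s0.append(vals[fc:])
            for frame, _ in detect_coin_frames(t, crit):
                coin.append(vals[frame])
    out = {
        "S1": np.concatenate(s1) if s1 else np.array([]),
        "S0": np.concatenate(s0) if s0 else np.array([]),
        "CoIn": np.array(coin),
    }
    if s0_frames is not None:
        out["S0"] = np.asarray(s0_frames, dtype=float).ravel()
    return out


def ensemble_histograms(
    trajs: Sequence[Trajectory],
    coordinate: Coordinate,
    crit: Optional[CoInCriterion] = None,
    bins: int = 40,
    s0_frames: Optional[Sequence[np.ndarray]] = None,
) -> dict[str, EnsembleHistogram]:
    """S0/S1/CoIn histograms of one coordinate with shared binning."""
    pools = pool_ensemble_values(trajs, coordinate, crit, s0_frames)
    nonempty = np.concatenate([v for v in pools.values() if v.size]) if any(
        v.size for v in pools.values()
    ) else np.array([0.0])
    edges = np.histogram_bin_edges(nonempty, bins=bins)
    out = {}
    for label, vals in pools.items():
        counts, _ = np.histogram(vals, bins=edges)
        out[label] = EnsembleHistogram(
            label=label,
            bin_edges=edges,
            counts=counts,
            mean=float(np.mean(vals)) if vals.size else float("nan"),
            sd=float(np.std(vals)) if vals.size else float("nan"),
            n=int(vals.size),
            empty=vals.size == 0,
        )
    return out


def excited_state_values(traj: Trajectory, coordinate: Coordinate) -> np.ndarray:
    """Coordinate values on excited-state frames only (pre-crossing)."""
    vals = coordinate_values(traj, coordinate)
    fc = traj.first_crossing
    return vals if fc is None else vals[:fc]


def variance_hierarchy(
    unconstrained: Sequence[Trajectory],
    constrained: dict[str, Sequence[Trajectory]],
    dof_list: dict[str, Coordinate],
) -> VarianceHierarchy:
    """Variance of each measured DoF (rows) under each constraint (columns),
    over pooled excited-state frames, against the unconstrained baseline."""
    for j in constrained:
        if not constrained[j]:
            raise ValueError(f"no swarm supplied for constrained DoF {j!r}")

    def pooled_var(swarm, coord) -> float:
        vals = np.concatenate([excited_state_values(t, coord) for t in swarm])
        if vals.size == 0:
            raise ValueError("no excited-state frames available")
        return float(np.var(vals))

    labels = list(dof_list)
    cons_labels = list(constrained)
    base = np.array([pooled_var(unconstrained, dof_list[i]) for i in labels])
    V = np.empty((len(labels), len(cons_labels)))
    for jj, j in enumerate(cons_labels):
        for ii, i in enumerate(labels):
            V[ii, jj] = pooled_var(constrained[j], dof_list[i])
    reduction = (base[:, None] - V) / base[:, None]
    return VarianceHierarchy(
        dof_labels=labels,
        constrained_labels=cons_labels,
        var_matrix=V,
        baseline=base,
        reduction=reduction,
        printed_form=1.0 + reduction,
    )


def paired_decay_test(
    reference: Sequence[Trajectory], treated: Sequence[Trajectory]
) -> dict:
    """One-sided exact test that a treatment (e.g. a constraint) reduces
    the decay fraction, on seed-paired swarms (McNemar-style: discordant
    pairs against a fair coin)."""
    if len(reference) != len(treated):
        raise ValueError("paired swarms must have equal size")
    ref_dec = np.array([t.decayed for t in reference])
    tre_dec = np.array([t.decayed for t in treated])
    n_ref_only = int(np.sum(ref_dec & ~tre_dec))
    n_tre_only = int(np.sum(~ref_dec & tre_dec))
    n_disc = n_ref_only + n_tre_only
    if n_disc == 0:
        p = 1.0
    else:
        p = binomtest(n_ref_only, n_disc, 0.5, alternative="greater").pvalue
    return {
        "n_pairs": len(reference),
        "decay_fraction_reference": float(ref_dec.mean()),
        "decay_fraction_treated": float(tre_dec.mean()),
        "discordant_reference_only": n_ref_only,
        "discordant_treated_only": n_tre_only,
        "p_value": float(p),
    }
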