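"""Data-driven extraction of the excited-state relaxation coordinate.

A modified principal-component construction: each Cartesian coordinate's
fluctuation is correlated with a sign term that orients the vector from
excited-state toward ground-state configurations and an Arrhenius-like
weight exp(-|dE_D| / (alpha k T)) that concentrates the average on
near-degeneracy frames.  The diabatic gap dE_D is reconstructed from the
adiabatic one by swapping the state identities after the first crossing.
Each component is normalized by the root product of the coordinate's
fluctuation variance and the weight's second moment, so every component
is a correlation-like quantity bounded by 1 in magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import units
from .geometry import CoordinateDefinition, Structure, align_frames_to_mean, coordinate_gradient
from .trajectory import Trajectory

VARIANCE_FLOOR = 1e-12  # A^2; below this a coordinate is constant, c_i = 0


@dataclass
class PathwayConfig:
    """alpha widens the Arrhenius window (dimensionless, default 100);
    temperature in K; align superposes every frame on the pooled mean
    before fluctuations are taken; mass_weight uses mass-weighted
    fluctuations; include_nondecaying admits trajectories that never
    cross (their gap is then never swapped)."""

    alpha: float = 100.0
    temperature: float = 300.0
    align: bool = True
    mass_weight: bool = False
    include_nondecaying: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.temperature <= 0:
            raise ValueError("alpha and temperature must be positive")

    @property
    def alpha_kt_ev(self) -> float:
        return self.alpha * units.KB_EV_PER_K * self.temperature


@dataclass
class PooledEnsemble:
    """Pooled, centered Cartesian fluctuations with per-frame diabatic gaps."""

    fluctuations: np.ndarray       # (n_pooled, 3N), angstrom, column means 0
    deltaE_D: np.ndarray           # signed diabatic gap per frame, eV
    means: np.ndarray              # per-coordinate time averages, angstrom
    provenance: list               # (trajectory index, n_frames) per member
    elements: Optional[list] = None

    @property
    def n_frames(self) -> int:
        return len(self.fluctuations)


@dataclass
class RelaxationVector:
    c: np.ndarray                  # 3N, dimensionless, |c_i| <= 1
    config: PathwayConfig
    provenance: list = field(default_factory=list)

    @property
    def unit(self) -> np.ndarray:
        n = np.linalg.norm(self.c)
        if n == 0:
            return self.c
        return self.c / n

    def cosine_to(self, direction: np.ndarray) -> float:
        d = np.asarray(direction, dtype=float)
        nd = np.linalg.norm(d)
        nc = np.linalg.norm(self.c)
        if nd == 0 or nc == 0:
            return 0.0
        return float(self.c @ d / (nc * nd))


def reconstruct_diabatic_gap(traj: Trajectory) -> np.ndarray:
    """Signed diabatic gap dE_D = E1_D - E0_D per frame, eV.

    Adiabatic before the first crossing; identities swapped (sign
    flipped) from the first-crossing frame on, so Sign[-dE_D] points
    from excited-state toward ground-state configurations.  Without a
    crossing the adiabatic gap is returned unswapped.
    """
    gap = traj.gap_ev.copy()
    fc = traj.first_crossing
    if fc is not None:
        gap[fc:] *= -1.0
    return gap


def pool_ensemble(trajs: Sequence[Trajectory], config: Optional[PathwayConfig] = None) -> PooledEnsemble:
    """Pool frames of all admitted trajectories and center fluctuations.

    Decaying trajectories contribute every frame (both sides of the
    crossing); non-decaying ones only when include_nondecaying is set.
    With align=True each frame is Kabsch-superposed onto the pooled mean
    (one fixed-point iteration).
    """
    config = config or PathwayConfig()
    frames = []
    gaps = []
    prov = []
    elements = None
    for i, t in enumerate(trajs):
        if t.first_crossing is None and not config.include_nondecaying:
            continue
        x = t.positions_angstrom()
        if config.mass_weight:
            if not t.is_cartesian:
                raise ValueError("mass weighting requires a Cartesian trajectory")
            w = np.sqrt(np.repeat(_masses(t.elements), 3))
            x = x * w
        frames.append(x)
        gaps.append(reconstruct_diabatic_gap(t))
        prov.append((i, t.n_frames))
        if elements is None:
            elements = t.elements
    if not frames:
        raise ValueError("no admitted trajectories (none decayed?)")
    pooled = np.concatenate(frames, axis=0)
    gap = np.concatenate(gaps)
    if config.align and elements is not None and not config.mass_weight:
        pooled = align_frames_to_mean(pooled)
    means = pooled.mean(axis=0)
    return PooledEnsemble(
        fluctuations=pooled - means, deltaE_D=gap, means=means,
        provenance=prov, elements=elements,
    )


def relaxation_vector(ens: PooledEnsemble, config: Optional[PathwayConfig] = None) -> RelaxationVector:
    """Componentwise estimator:

        c_i = < f_i Sign[-dE_D] w > / sqrt(< f_i^2 > < w^2 >),

    with f_i the centered coordinate fluctuation and
    w = exp(-|dE_D| / (alpha k T)).  Constant coordinates get c_i = 0.
    """
    config = config or PathwayConfig()
    if ens.n_frames == 0:
        raise ValueError("empty ensemble")
    w = np.exp(-np.abs(ens.deltaE_D) / config.alpha_kt_ev)
    if np.max(w) < 1e-300:
        import warnings

        warnings.warn("all Arrhenius weights vanish (gaps far larger than alpha kT)")
    sw = np.sign(-ens.deltaE_D) * w
    f = ens.fluctuations
    num = f.T @ sw / len(f)
    var = np.mean(f * f, axis=0)
    w2 = float(np.mean(w * w))
    denom = np.sqrt(var * w2)
    c = np.zeros_like(num)
    ok = var > VARIANCE_FLOOR
    c[ok] = num[ok] / denom[ok]
    return RelaxationVector(c=c, config=config, provenance=ens.provenance)


def project_vector(
    vec: RelaxationVector,
    coords: Sequence[CoordinateDefinition],
    reference: Structure,
) -> dict:
    """Contribution of each named internal coordinate to the pathway.

    Signed normalized inner product between the (unit) relaxation vector
    and the coordinate's unit Cartesian gradient at the reference, plus
    relative magnitude shares over the requested set.
    """
    c = vec.unit
    if len(c) != 3 * reference.n_atoms:
        raise ValueError(
            f"vector has {len(c)} components but reference has {reference.n_atoms} atoms"
        )
    raw = {}
    for coord in coords:
        g = coordinate_gradient(coord, reference).ravel()
        ng = np.linalg.norm(g)
        raw[coord.label or coord.kind] = float(c @ g / ng) if ng > 0 else 0.0
    total = sum(abs(v) for v in raw.values())
    shares = {k: (abs(v) / total if total > 0 else 0.0) for k, v in raw.items()}
    return {"projection": raw, "share": shares}


def _masses(elements: Sequence[str]) -> np.ndarray:
    table = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
    return np.array([table[e] for e in elements])
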