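"""Decoherence-corrected fewest-switches trajectory surface hopping.

Two adiabatic states obtained on the fly from a :class:`DiabaticModel`;
classical nuclei on the active surface (velocity Verlet), electronic
amplitudes propagated by sub-stepped RK4 along the nuclear path, hops
decided once per nuclear step from the accumulated fewest-switches
probability, energy-based decoherence damping of the inactive amplitude,
and velocity rescaling along the nonadiabatic coupling vector on
accepted hops.  Harmonic bias constraints on generalized coordinates
support the trapping experiments.  Atomic units throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from . import geometry, units
from .models import DiabaticModel
from .trajectory import Trajectory

NACV_GAP_FLOOR = 1e-8  # hartree; NACV magnitude capped below this gap


# ----------------------------------------------------------------------
# records
# ----------------------------------------------------------------------

@dataclass
class AdiabaticFrame:
    """Electronic-structure snapshot at one nuclear configuration."""

    R: np.ndarray                 # positions, bohr
    vel: np.ndarray               # velocities, bohr / a.u.
    energies: np.ndarray          # (E0, E1), hartree
    grads: np.ndarray             # (2, n_dof) adiabatic gradients
    nacv: np.ndarray              # d_01, (n_dof,), 1/bohr  (d_10 = -d_01)
    U: np.ndarray                 # diabatic -> adiabatic transform, columns
    kinetic_energy: float
    time: float = 0.0
    nacv_capped: bool = False
    constraint_energy: float = 0.0

    @property
    def gap(self) -> float:
        return float(self.energies[1] - self.energies[0])

    def total_energy(self, active: int) -> float:
        return float(self.energies[active]) + self.kinetic_energy + self.constraint_energy


@dataclass
class ElectronicState:
    c: np.ndarray                 # complex amplitudes, adiabatic basis
    active: int

    def populations(self) -> np.ndarray:
        return np.abs(self.c) ** 2


@dataclass
class DecoherenceParams:
    """Energy-based decoherence damping; C is the kinetic-energy ratio
    parameter of the damping time (0.1 by default)."""

    C: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class ConstraintSpec:
    """Harmonic bias ``(k/2)(y - target)^2`` on a generalized coordinate.

    ``coordinate`` is either an integer model degree of freedom or a
    Cartesian :class:`~nonrad.geometry.CoordinateDefinition` (evaluated
    on R interpreted as 3N Cartesian bohr).  ``k`` is in kcal/mol/A^2
    for distance-like coordinates and kcal/mol/rad^2 for angles
    (default 100); ``target`` (angstrom/bohr for dof coordinates, or
    degrees) defaults to the coordinate value at excitation.
    """

    coordinate: Union[int, geometry.CoordinateDefinition]
    k: float = 100.0
    target: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant must be non-negative")

    def energy_force(self, R: np.ndarray) -> tuple[float, np.ndarray]:
        """Constraint energy (hartree) and force (hartree/bohr) on R."""
        if isinstance(self.coordinate, int):
            k_au = units.force_constant_to_au(self.k)
            target = self.target if self.target is not None else 0.0
            dy = R[self.coordinate] - target
            F = np.zeros_like(R)
            F[self.coordinate] = -k_au * dy
            return 0.5 * k_au * dy * dy, F
        coord = self.coordinate
        x_ang = R.reshape(-1, 3) * units.BOHR_TO_ANGSTROM
        val = geometry.evaluate(coord, x_ang)
        grad = geometry.coordinate_gradient(coord, x_ang).ravel()
        tgt = self.target if self.target is not None else 0.0
        if coord.kind == "improper_dihedral":
            # value deg, gradient deg/A -> radians, k in kcal/mol/rad^2
            dy = math.radians(val - tgt)
            k_au = self.k * units.KCALMOL_TO_HARTREE
            g_au = np.radians(grad) * units.BOHR_TO_ANGSTROM  # rad/bohr
        else:
            dy = (val - tgt) * units.ANGSTROM_TO_BOHR
            k_au = units.force_constant_to_au(self.k)
            g_au = grad  # dimensionless d(bohr)/d(bohr)
        return 0.5 * k_au * dy * dy, -k_au * dy * g_au

    def resolve_target(self, R: np.ndarray) -> "ConstraintSpec":
        """Fill in a missing target with the coordinate value at R."""
        if self.target is not None:
            return self
        if isinstance(self.coordinate, int):
            return replace(self, target=float(R[self.coordinate]))
        val = geometry.evaluate(self.coordinate, R.reshape(-1, 3) * units.BOHR_TO_ANGSTROM)
        return replace(self, target=float(val))


@dataclass
class IntegratorConfig:
    dt_fs: float = 0.5
    n_substeps_electronic: int = 20
    t_max_fs: float = 250.0
    gap_stop_ev: float = 0.1
    forbid_recrossing: bool = True
    seed: int = 0
    decoherence: DecoherenceParams = field(default_factory=DecoherenceParams)
    stop_on_decay_gap: bool = True
    exit_abs_position: Optional[float] = None   # stop when |R| leaves this radius
    reverse_velocity_on_frustrated: bool = False
    store_velocities: bool = True

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.n_substeps_electronic < 1:
            raise ValueError("need at least one electronic substep")

    @property
    def dt(self) -> float:
        return self.dt_fs * units.FS_TO_AU_TIME

    @property
    def gap_stop(self) -> float:
        return self.gap_stop_ev * units.EV_TO_HARTREE


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------

def adiabatize(
    model: DiabaticModel, R: np.ndarray, prev: Optional[AdiabaticFrame] = None,
    vel: Optional[np.ndarray] = None, time: float = 0.0,
) -> AdiabaticFrame:
    """Diagonalize the 2x2 diabatic matrix at R.

    Returns sorted adiabatic energies, Hellmann-Feynman adiabatic
    gradients g_i = u_i^T (dV/dR) u_i and the nonadiabatic coupling
    d_01 = u_0^T (dV/dR) u_1 / (E1 - E0), with the denominator floored
    at ``NACV_GAP_FLOOR`` (capped flag set).  Eigenvector phases follow
    the previous frame (overlap kept non-negative).
    """
    R = np.asarray(R, dtype=float)
    V = model.potential(R)
    dV = model.gradient(R)
    h = 0.5 * (V[1, 1] - V[0, 0])
    off = V[0, 1]
    rad = math.hypot(h, off)
    mean = 0.5 * (V[0, 0] + V[1, 1])
    if rad < 1e-14 and prev is None:
        raise ValueError(
            "states degenerate at machine precision with no previous frame for "
            "phase continuity; use a smaller step"
        )
    if h >= 0.0:
        a0, a1 = -(h + rad), off
    else:
        a0, a1 = off, h - rad
    n = math.hypot(a0, a1)
    if n > 0.0:
        a0, a1 = a0 / n, a1 / n
    else:
        a0, a1 = 1.0, 0.0
    if prev is not None:
        pU = prev.U
        if a0 * pU[0, 0] + a1 * pU[1, 0] < 0.0:
            a0, a1 = -a0, -a1
    b0, b1 = -a1, a0
    if prev is not None and b0 * pU[0, 1] + b1 * pU[1, 1] < 0.0:
        b0, b1 = -b0, -b1
    U = np.array([[a0, b0], [a1, b1]])
    energies = np.array([mean - rad, mean + rad])
    dv00 = dV[:, 0, 0]
    dv11 = dV[:, 1, 1]
    dv01 = dV[:, 0, 1]
    g0 = dv00 * (a0 * a0) + 2.0 * dv01 * (a0 * a1) + dv11 * (a1 * a1)
    g1 = dv00 * (b0 * b0) + 2.0 * dv01 * (b0 * b1) + dv11 * (b1 * b1)
    coupling = dv00 * (a0 * b0) + dv01 * (a0 * b1 + a1 * b0) + dv11 * (a1 * b1)
    gap = max(2.0 * rad, NACV_GAP_FLOOR)
    nacv = coupling / gap
    vel = np.zeros_like(R) if vel is None else np.asarray(vel, dtype=float)
    ekin = 0.5 * float(np.dot(model.masses * vel, vel))
    return AdiabaticFrame(
        R=R, vel=vel, energies=energies, grads=np.array([g0, g1]), nacv=nacv,
        U=U, kinetic_energy=ekin, time=time, nacv_capped=2.0 * rad < NACV_GAP_FLOOR,
    )


def _force(frame_grads: np.ndarray, active: int, R: np.ndarray,
           constraints: Sequence[ConstraintSpec]) -> tuple[np.ndarray, float]:
    F = -frame_grads[active]
    e_con = 0.0
    for con in constraints:
        e, f = con.energy_force(R)
        e_con += e
        F = F + f
    return F, e_con


def propagate_nuclei(
    model: DiabaticModel, frame: AdiabaticFrame, state: ElectronicState,
    config: IntegratorConfig, constraints: Sequence[ConstraintSpec] = (),
) -> AdiabaticFrame:
    """One velocity-Verlet step on the active surface plus constraints."""
    dt = config.dt
    m = model.masses
    F0, _ = _force(frame.grads, state.active, frame.R, constraints)
    if not math.isfinite(float(F0.sum())):
        raise FloatingPointError(f"non-finite force at R={frame.R}")
    v_half = frame.vel + 0.5 * dt * F0 / m
    R_new = frame.R + dt * v_half
    new = adiabatize(model, R_new, prev=frame, time=frame.time + dt)
    F1, e_con = _force(new.grads, state.active, R_new, constraints)
    if not math.isfinite(float(F1.sum())):
        raise FloatingPointError(f"non-finite force at R={R_new}")
    new.vel = v_half + 0.5 * dt * F1 / m
    new.kinetic_energy = 0.5 * float(np.dot(m * new.vel, new.vel))
    new.constraint_energy = e_con
    return new


def fs_probability_increment(ci: complex, cj: complex, sigma_ij: float, dt: float) -> float:
    """Fewest-switches integrand of the hop probability i->j over dt:
    -2 Re(c_i* c_j sigma_ij) dt / |c_i|^2 (real part taken; the printed
    integral is only real under this reading)."""
    pop = ci.real * ci.real + ci.imag * ci.imag
    if pop < 1e-12:
        return 0.0
    return -2.0 * ((ci.conjugate() * cj).real * sigma_ij) * dt / pop


def propagate_coefficients(
    state: ElectronicState,
    frames: tuple[AdiabaticFrame, AdiabaticFrame],
    config: IntegratorConfig,
) -> tuple[ElectronicState, float, float]:
    """RK4 propagation of the electronic amplitudes across one nuclear step.

    Energies and the scalar coupling sigma = vel . d_01 are linearly
    interpolated between the frame endpoints; a mean-energy gauge shift
    (pure global phase) keeps the RK4 norm drift far below 1e-8 per
    step.  Returns (new state, accumulated hop probability active->other,
    norm deviation before renormalization).
    """
    prev, cur = frames
    n_sub = config.n_substeps_electronic
    h = (cur.time - prev.time) / n_sub
    # gauge-shifted endpoint energies
    mean_p = 0.5 * (prev.energies[0] + prev.energies[1])
    mean_c = 0.5 * (cur.energies[0] + cur.energies[1])
    e0p, e1p = prev.energies[0] - mean_p, prev.energies[1] - mean_p
    e0c, e1c = cur.energies[0] - mean_c, cur.energies[1] - mean_c
    sp = float(prev.vel @ prev.nacv)
    sc = float(cur.vel @ cur.nacv)
    a = state.active
    t = 1 - a
    c0 = complex(state.c[0])
    c1 = complex(state.c[1])
    p_accum = 0.0

    de0 = e0c - e0p
    de1 = e1c - e1p
    ds = sc - sp

    # TDSE in the paper's index convention (source index first in d_ij):
    # dc_j = -i e_j c_j - sum_i c_i sigma_ij ; with d_10 = -d_01:
    # dc0 = -i e0 c0 + s c1 ; dc1 = -i e1 c1 - s c0
    inv = 1.0 / n_sub
    half_h = 0.5 * h
    sixth_h = h / 6.0
    for k in range(n_sub):
        f0 = k * inv
        fm = (k + 0.5) * inv
        f1 = (k + 1.0) * inv
        e0_0 = e0p + f0 * de0; e1_0 = e1p + f0 * de1; s_0 = sp + f0 * ds
        e0_m = e0p + fm * de0; e1_m = e1p + fm * de1; s_m = sp + fm * ds
        e0_1 = e0p + f1 * de0; e1_1 = e1p + f1 * de1; s_1 = sp + f1 * ds
        # hop-probability increment from start-of-substep values (Eq-1 form)
        if a == 0:
            pop = c0.real * c0.real + c0.imag * c0.imag
            if pop >= 1e-12:
                p_accum += -2.0 * ((c0.conjugate() * c1).real * s_0) * h / pop
        else:
            pop = c1.real * c1.real + c1.imag * c1.imag
            if pop >= 1e-12:
                p_accum += 2.0 * ((c1.conjugate() * c0).real * s_0) * h / pop
        k10 = -1j * e0_0 * c0 + s_0 * c1
        k11 = -1j * e1_0 * c1 - s_0 * c0
        a0 = c0 + half_h * k10; a1 = c1 + half_h * k11
        k20 = -1j * e0_m * a0 + s_m * a1
        k21 = -1j * e1_m * a1 - s_m * a0
        b0 = c0 + half_h * k20; b1 = c1 + half_h * k21
        k30 = -1j * e0_m * b0 + s_m * b1
        k31 = -1j * e1_m * b1 - s_m * b0
        d0 = c0 + h * k30; d1 = c1 + h * k31
        k40 = -1j * e0_1 * d0 + s_1 * d1
        k41 = -1j * e1_1 * d1 - s_1 * d0
        c0 = c0 + sixth_h * (k10 + 2.0 * k20 + 2.0 * k30 + k40)
        c1 = c1 + sixth_h * (k11 + 2.0 * k21 + 2.0 * k31 + k41)

    norm = math.sqrt(abs(c0) ** 2 + abs(c1) ** 2)
    drift = abs(norm - 1.0)
    c_new = np.array([c0, c1]) / norm
    p_accum = min(max(p_accum, 0.0), 1.0)
    return ElectronicState(c=c_new, active=a), p_accum, drift


def hop_probability(
    state: ElectronicState, frames: tuple[AdiabaticFrame, AdiabaticFrame],
    config: IntegratorConfig,
) -> np.ndarray:
    """Per-step hop probability from the active state, as a length-2
    array indexed by target state (active entry 0)."""
    _, p, _ = propagate_coefficients(state, frames, config)
    out = np.zeros(2)
    out[1 - state.active] = p
    return out


def apply_decoherence(
    state: ElectronicState, frame: AdiabaticFrame, params: DecoherenceParams, dt: float,
) -> ElectronicState:
    """Damp the inactive amplitude with tau = (1/|dE|)(1 + C/E_kin) and
    rescale the active amplitude to restore the norm."""
    if not params.enabled:
        return state
    if frame.kinetic_energy <= 0.0:
        return state  # tau -> infinity limit
    a = state.active
    j = 1 - a
    gap = abs(frame.energies[j] - frame.energies[a])
    if gap <= 0.0:
        return state
    tau = (1.0 / gap) * (1.0 + params.C / frame.kinetic_energy)
    c = state.c.copy()
    c[j] *= math.exp(-dt / tau)
    pj = abs(c[j]) ** 2
    pa = abs(c[a]) ** 2
    if pa > 1e-30:
        c[a] *= math.sqrt(max(1.0 - pj, 0.0) / pa)
    return ElectronicState(c=c, active=a)


def attempt_hop(
    p_hop: float, u: float, frame: AdiabaticFrame, state: ElectronicState,
    masses: np.ndarray, config: IntegratorConfig,
) -> tuple[ElectronicState, Optional[dict]]:
    """Stochastic hop decision with NACV-direction velocity rescaling.

    Returns the (possibly) updated state and a hop record; frustrated
    upward attempts leave the state unchanged (record flags them).
    Mutates frame.vel and kinetic energy on an accepted hop.
    """
    a = state.active
    t = 1 - a
    if config.forbid_recrossing and a == 0:
        return state, None
    if u >= p_hop:
        return state, None
    d = frame.nacv if a == 0 else -frame.nacv
    gap = frame.energies[t] - frame.energies[a]
    aa = 0.5 * float(np.sum(d * d / masses))
    bb = float(np.sum(frame.vel * d))
    cc = float(gap)
    if aa <= 0.0:
        return state, {"frustrated": True, "from": a, "to": t}
    disc = bb * bb - 4.0 * aa * cc
    if disc < 0.0:
        if config.reverse_velocity_on_frustrated:
            dn = d / np.linalg.norm(d)
            frame.vel = frame.vel - 2.0 * float(frame.vel @ dn) * dn
        return state, {"frustrated": True, "from": a, "to": t}
    r1 = (-bb + math.sqrt(disc)) / (2.0 * aa)
    r2 = (-bb - math.sqrt(disc)) / (2.0 * aa)
    gamma = r1 if abs(r1) < abs(r2) else r2
    frame.vel = frame.vel + gamma * d / masses
    frame.kinetic_energy = 0.5 * float(np.sum(masses * frame.vel * frame.vel))
    return ElectronicState(c=state.c.copy(), active=t), {"frustrated": False, "from": a, "to": t}


# ----------------------------------------------------------------------
# drivers
# ----------------------------------------------------------------------

def run_trajectory(
    model: DiabaticModel,
    R0: np.ndarray,
    V0: np.ndarray,
    config: IntegratorConfig,
    constraints: Sequence[ConstraintSpec] = (),
    initial_state: int = 1,
    seed: Optional[int] = None,
) -> Trajectory:
    """Evolve one vertically excited trajectory (NVE).

    Per-step order: nuclei -> adiabatize -> electronic coefficients ->
    decoherence -> hop attempt.  Terminates at t_max, or (default) once
    the trajectory has decayed (active=0) and the adiabatic gap is below
    ``gap_stop_ev``, or when |R| exceeds ``exit_abs_position``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    constraints = [c.resolve_target(np.asarray(R0, dtype=float)) for c in constraints]
    frame = adiabatize(model, R0, vel=np.asarray(V0, dtype=float))
    _, e_con = _force(frame.grads, initial_state, frame.R, constraints)
    frame.constraint_energy = e_con
    c_init = np.zeros(2, dtype=complex)
    c_init[initial_state] = 1.0
    state = ElectronicState(c=c_init, active=initial_state)

    n_max = int(round(config.t_max_fs / config.dt_fs))
    ndof = model.n_dof
    pos = np.empty((n_max + 1, ndof))
    vel = np.empty((n_max + 1, ndof)) if config.store_velocities else None
    ene = np.empty((n_max + 1, 2))
    act = np.empty(n_max + 1, dtype=int)
    coe = np.empty((n_max + 1, 2), dtype=complex)
    etot = np.empty(n_max + 1)
    hops: list = []
    max_norm_drift = 0.0
    norm_warnings = 0
    frustrated = 0
    nacv_capped = False

    def record(i: int) -> None:
        pos[i] = frame.R
        if vel is not None:
            vel[i] = frame.vel
        ene[i] = frame.energies
        act[i] = state.active
        coe[i] = state.c
        etot[i] = frame.total_energy(state.active)

    record(0)
    n_done = 0
    for i in range(1, n_max + 1):
        new_frame = propagate_nuclei(model, frame, state, config, constraints)
        nacv_capped |= new_frame.nacv_capped
        state, p_hop, drift = propagate_coefficients(state, (frame, new_frame), config)
        max_norm_drift = max(max_norm_drift, drift)
        if drift > 1e-4:
            norm_warnings += 1
        state = apply_decoherence(state, new_frame, config.decoherence, config.dt)
        u = rng.random()
        state, hop = attempt_hop(p_hop, u, new_frame, state, model.masses, config)
        if hop is not None:
            if hop["frustrated"]:
                frustrated += 1
            else:
                hops.append((i, hop["from"], hop["to"]))
        frame = new_frame
        record(i)
        n_done = i
        if config.stop_on_decay_gap and state.active == 0 and frame.gap < config.gap_stop:
            break
        if config.exit_abs_position is not None and np.max(np.abs(frame.R)) > config.exit_abs_position:
            break

    n = n_done + 1
    return Trajectory(
        positions=pos[:n],
        velocities=None if vel is None else vel[:n],
        energies=ene[:n],
        active=act[:n],
        coeffs=coe[:n],
        hops=hops,
        dt=config.dt,
        metadata=dict(
            model=model.label,
            seed=int(config.seed if seed is None else seed),
            dt_fs=config.dt_fs,
            max_norm_drift=max_norm_drift,
            norm_warnings=norm_warnings,
            frustrated_hops=frustrated,
            nacv_capped=nacv_capped,
            total_energy=etot[:n],
            n_constraints=len(constraints),
        ),
    )


def run_swarm(
    model: DiabaticModel,
    initial_conditions: tuple[np.ndarray, np.ndarray],
    config: IntegratorConfig,
    constraints: Sequence[ConstraintSpec] = (),
    base_seed: Optional[int] = None,
) -> list[Trajectory]:
    """Independent trajectories seeded ``base_seed + index``; member k
    uses the k-th row of the initial-condition arrays."""
    R, V = initial_conditions
    base = config.seed if base_seed is None else base_seed
    return [
        run_trajectory(model, R[k], V[k], config, constraints, seed=base + k)
        for k in range(len(R))
    ]
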