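"""Analytic two-state diabatic model surfaces and ground-state sampling.

These models stand in for ab initio potential-energy surfaces: a 1-DoF
single avoided crossing used to validate the hopping engine against exact
wavepacket dynamics, and a 2-3 DoF "carbonyl-lock" surface in which a
gap-closing stretch coordinate r (the CO-stretch analogue) drives the
system toward a crossing seam, a proton-transfer-like coordinate q
modulates the gap, and a harmonic lock of stiffness k_lock added to both
diabats along r suppresses the large-amplitude elongation that reaches
the seam.  Everything is in Hartree atomic units.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize

from . import units


@dataclass
class DiabaticModel:
    """Two-state diabatic potential matrix over n_dof nuclear coordinates.

    ``potential(R) -> (2, 2)`` symmetric matrix (hartree);
    ``gradient(R) -> (n_dof, 2, 2)`` its derivative w.r.t. R (hartree/bohr).
    """

    n_dof: int
    masses: np.ndarray
    potential: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    label: str = "model"
    n_states: int = 2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.n_dof,):
            raise ValueError("masses must have one entry per degree of freedom")

    def adiabatic_energies(self, R: np.ndarray) -> tuple[float, float]:
        """Eigenvalues of the diabatic matrix, sorted ascending."""
        V = self.potential(np.asarray(R, dtype=float))
        mean = 0.5 * (V[0, 0] + V[1, 1])
        rad = np.hypot(0.5 * (V[1, 1] - V[0, 0]), V[0, 1])
        return mean - rad, mean + rad

    def ground_force(self, R: np.ndarray) -> np.ndarray:
        """-dE0/dR via the Hellmann-Feynman theorem (exact for 2x2)."""
        V = self.potential(R)
        dV = self.gradient(R)
        u = _ground_eigvec(V)
        return -np.einsum("i,kij,j->k", u, dV, u)


def _ground_eigvec(V: np.ndarray) -> np.ndarray:
    h = 0.5 * (V[1, 1] - V[0, 0])
    off = V[0, 1]
    rad = np.hypot(h, off)
    # eigenvector for eigenvalue mean - rad
    if rad < 1e-300:
        return np.array([1.0, 0.0])
    # robust branch: avoid cancellation
    if h >= 0.0:
        u = np.array([-(h + rad), off])
    else:
        u = np.array([off, h - rad])
    n = np.linalg.norm(u)
    if n == 0.0:  # off == 0, h == 0 handled above; h==0, off!=0:
        u = np.array([1.0, -1.0]) / np.sqrt(2.0)
        return u
    return u / n


# ----------------------------------------------------------------------
# 1-DoF single avoided crossing (engine-validation surface)
# ----------------------------------------------------------------------

def build_tully_single_crossing(
    A: float = 0.01, B: float = 1.6, C: float = 0.005, D: float = 1.0, mass: float = 2000.0
) -> DiabaticModel:
    """Single avoided crossing: V11 = A(1-exp(-B|x|))·sign(x), V22 = -V11,
    V12 = C·exp(-D x^2).  Defaults in atomic units."""

    def potential(R: np.ndarray) -> np.ndarray:
        x = float(R[0])
        if x >= 0.0:
            v11 = A * (1.0 - np.exp(-B * x))
        else:
            v11 = -A * (1.0 - np.exp(B * x))
        v12 = C * np.exp(-D * x * x)
        return np.array([[v11, v12], [v12, -v11]])

    def gradient(R: np.ndarray) -> np.ndarray:
        x = float(R[0])
        dv11 = A * B * np.exp(-B * abs(x))
        dv12 = -2.0 * D * x * C * np.exp(-D * x * x)
        return np.array([[[dv11, dv12], [dv12, -dv11]]])

    return DiabaticModel(
        n_dof=1,
        masses=np.array([mass]),
        potential=potential,
        gradient=gradient,
        label="tully_single_crossing",
        metadata=dict(A=A, B=B, C=C, D=D, mass=mass),
    )


# ----------------------------------------------------------------------
# Carbonyl-lock model
# ----------------------------------------------------------------------

@dataclass
class CarbonylLockParams:
    """Parameters of the gap-closing / proton-transfer / lock surface.

    r: CO-stretch-like gap-closing coordinate (harmonic, stiffness k_r,
       reduced mass of a CO oscillator), along which the diabatic gap
       closes at rate slope_r.
    q: proton-transfer-like coordinate (stiffness k_q, proton mass)
       modulating the gap with strength couple_q.
    s: optional uncoupled spectator coordinate (included when
       include_spectator is true) used for constraint-specificity checks.
    k_lock >= 0 is added harmonically along r to BOTH diabats: it stiffens
    the stretch without shifting the gap, emulating a strong local
    interaction that blocks large-amplitude elongations.
    """

    r0: float = 2.3            # bohr
    q0: float = 0.0            # bohr
    gap0: float = 0.147        # hartree (~4 eV vertical gap)
    slope_r: float = 0.085     # hartree/bohr
    couple_q: float = 0.03     # hartree/bohr
    v12: float = 0.004         # hartree
    k_lock: float = 0.0        # hartree/bohr^2
    k_r: float = 0.08          # hartree/bohr^2 (~560 cm^-1; deliberately
                               # softer than a real CO stretch so that 300 K
                               # sampling, 250 fs runs and ~100 kcal/mol/A^2
                               # biases all act on one energy scale)
    k_q: float = 0.34          # hartree/bohr^2 (~3000 cm^-1 X-H stretch)
    mass_r: float = 6.86 * units.AMU_TO_AU_MASS
    mass_q: float = 1.0 * units.AMU_TO_AU_MASS
    temperature: float = 300.0  # K
    include_spectator: bool = True
    k_s: float = 0.2           # hartree/bohr^2
    s0: float = 0.0
    mass_s: float = 3.0 * units.AMU_TO_AU_MASS
    coupling_width: Optional[float] = None  # bohr; None = constant v12

    def __post_init__(self) -> None:
        if self.gap0 <= 0.0:
            raise ValueError("gap0 must be positive")
        if self.k_lock < 0.0:
            raise ValueError("k_lock must be non-negative")

    @property
    def seam_displacement(self) -> float:
        """Diabatic-crossing displacement along r at q=q0 (k_lock-independent)."""
        return self.gap0 / self.slope_r

    @property
    def k_lock_critical(self) -> float:
        """Lock stiffness above which a vertically excited trajectory started
        at the ground-state minimum cannot classically reach the seam
        (energy argument; thermal sampling softens the edge)."""
        return 2.0 * self.slope_r**2 / self.gap0 - self.k_r


def build_carbonyl_lock_model(p: Optional[CarbonylLockParams] = None) -> DiabaticModel:
    """Diabats V11 = sum of harmonic wells (+ lock), V22 = V11 + gap,
    gap = gap0 - slope_r (r - r0) - couple_q (q0 - q); V12 = v12
    (optionally Gaussian-damped around the seam)."""
    p = p or CarbonylLockParams()
    ndof = 3 if p.include_spectator else 2
    masses = [p.mass_r, p.mass_q] + ([p.mass_s] if p.include_spectator else [])

    def potential(R: np.ndarray) -> np.ndarray:
        dr = R[0] - p.r0
        dq = R[1] - p.q0
        v11 = 0.5 * (p.k_r + p.k_lock) * dr * dr + 0.5 * p.k_q * dq * dq
        if p.include_spectator:
            ds = R[2] - p.s0
            v11 += 0.5 * p.k_s * ds * ds
        gap = p.gap0 - p.slope_r * dr - p.couple_q * (p.q0 - R[1])
        v12 = p.v12
        if p.coupling_width is not None:
            v12 *= np.exp(-(gap / (p.slope_r * p.coupling_width)) ** 2)
        return np.array([[v11, v12], [v12, v11 + gap]])

    def gradient(R: np.ndarray) -> np.ndarray:
        dr = R[0] - p.r0
        dq = R[1] - p.q0
        g = np.zeros((ndof, 2, 2))
        dv11_r = (p.k_r + p.k_lock) * dr
        dv11_q = p.k_q * dq
        g[0, 0, 0] = dv11_r
        g[0, 1, 1] = dv11_r - p.slope_r
        g[1, 0, 0] = dv11_q
        g[1, 1, 1] = dv11_q + p.couple_q
        if p.include_spectator:
            dv11_s = p.k_s * (R[2] - p.s0)
            g[2, 0, 0] = dv11_s
            g[2, 1, 1] = dv11_s
        if p.coupling_width is not None:
            gap = p.gap0 - p.slope_r * dr - p.couple_q * (p.q0 - R[1])
            w = p.slope_r * p.coupling_width
            v12 = p.v12 * np.exp(-((gap / w) ** 2))
            dv12_dgap = v12 * (-2.0 * gap / w**2)
            g[0, 0, 1] = g[0, 1, 0] = dv12_dgap * (-p.slope_r)
            g[1, 0, 1] = g[1, 1, 0] = dv12_dgap * p.couple_q
        return g

    return DiabaticModel(
        n_dof=ndof,
        masses=np.array(masses),
        potential=potential,
        gradient=gradient,
        label="carbonyl_lock",
        metadata=dict(params=p),
    )


def build_uncoupled_harmonic(
    omega: float = 3.0e-3, mass: float = 2000.0, gap: float = 0.2
) -> DiabaticModel:
    """1-DoF pair of parallel harmonic surfaces with zero coupling.

    A soft mode (default ~660 cm^-1) whose period is well resolved at a
    0.5 fs step; used for closed-form integrator checks (adiabatic =
    diabatic everywhere since V12 = 0)."""
    k = mass * omega * omega

    def potential(R: np.ndarray) -> np.ndarray:
        v = 0.5 * k * R[0] * R[0]
        return np.array([[v, 0.0], [0.0, v + gap]])

    def gradient(R: np.ndarray) -> np.ndarray:
        dv = k * R[0]
        return np.array([[[dv, 0.0], [0.0, dv]]])

    return DiabaticModel(
        n_dof=1, masses=np.array([mass]), potential=potential, gradient=gradient,
        label="uncoupled_harmonic", metadata=dict(omega=omega, k=k, gap=gap),
    )


def sample_wigner_gaussian(
    x0: float, k0: float, sigma_x: float, n: int, mass: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Initial conditions matched to a Gaussian wavepacket's Wigner
    distribution: x ~ N(x0, sigma_x), p ~ N(k0, 1/(2 sigma_x)).
    Returns (positions, velocities) of shape (n, 1)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(x0, sigma_x, n)
    p = rng.normal(k0, 0.5 / sigma_x, n)
    return x[:, None], (p / mass)[:, None]


# ----------------------------------------------------------------------
# Thermal ground-state sampling (Langevin) and vertical excitation
# ----------------------------------------------------------------------

def find_ground_minimum(model: DiabaticModel, guess: Optional[np.ndarray] = None) -> np.ndarray:
    if guess is None:
        p = model.metadata.get("params")
        if isinstance(p, CarbonylLockParams):
            guess = np.array([p.r0, p.q0] + ([p.s0] if p.include_spectator else []))
        else:
            guess = np.zeros(model.n_dof)
    res = minimize(lambda R: model.adiabatic_energies(R)[0], guess, method="Nelder-Mead",
                   options=dict(xatol=1e-10, fatol=1e-14))
    return res.x


def sample_ground_state(
    model: DiabaticModel,
    n_samples: int,
    temperature: float = 300.0,
    dt_fs: float = 0.5,
    friction_ps: float = 20.0,
    burn_in_fs: float = 1000.0,
    stride_fs: float = 100.0,
    seed: int = 0,
    start: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann-sample (R, V) on the ground adiabatic surface.

    BAOAB Langevin integration at the requested temperature; friction
    20/ps by default -- strong enough that the single-chain energy
    decorrelates within the 100 fs sampling stride, yet still underdamped
    for every mode of the default models -- with a 1 ps burn-in.
    Returns (positions, velocities) of shape (n_samples, n_dof).
    """
    rng = np.random.default_rng(seed)
    dt = dt_fs * units.FS_TO_AU_TIME
    gamma = friction_ps / (1000.0 * units.FS_TO_AU_TIME)  # 1/ps -> 1/a.u.
    kT = units.KB_HARTREE_PER_K * temperature
    m = model.masses

    R = np.array(start if start is not None else find_ground_minimum(model), dtype=float)
    V = rng.normal(0.0, np.sqrt(kT / m))
    F = model.ground_force(R)

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT / m * (1.0 - c1 * c1))

    n_burn = int(round(burn_in_fs / dt_fs))
    stride = max(1, int(round(stride_fs / dt_fs)))
    pos = np.empty((n_samples, model.n_dof))
    vel = np.empty((n_samples, model.n_dof))
    collected = 0
    step = 0
    total = n_burn + n_samples * stride
    while collected < n_samples:
        # BAOAB
        V = V + 0.5 * dt * F / m
        R = R + 0.5 * dt * V
        V = c1 * V + c2 * rng.standard_normal(model.n_dof)
        R = R + 0.5 * dt * V
        F = model.ground_force(R)
        V = V + 0.5 * dt * F / m
        step += 1
        if step > n_burn and (step - n_burn) % stride == 0:
            pos[collected] = R
            vel[collected] = V
            collected += 1
        if step > 10 * total:  # pragma: no cover - safety valve
            raise RuntimeError("sampler failed to collect requested samples")
    return pos, vel
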