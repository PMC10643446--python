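"""Mock Cartesian trajectories of a small amide-dimer toy.

A fixture factory for the relaxation-coordinate estimator and the
ensemble statistics: internal-coordinate time series with one *planted*
decay mode (a drift that closes the electronic gap) and stationary
spectator modes are mapped onto a fixed 12-atom reference geometry (a
cyclic formamide-like dimer with two N-H...O hydrogen bonds) by
displacing the atoms of each coordinate along its Cartesian gradient
direction.  The planted decay direction is therefore known exactly in
Cartesian space, which is what makes recovery testable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import units
from .geometry import CoordinateDefinition, Structure, coordinate_gradient, evaluate
from .trajectory import Trajectory

#: element symbols of the reference dimer (molecule A then molecule B)
DIMER_ELEMENTS = ["C", "O", "N", "H", "H", "H"] * 2

#: reference Cartesian coordinates, angstrom (planar cyclic dimer,
#: N-H...O bonds of 1.90 A, heavy-atom N...O 2.91 A)
DIMER_COORDS = np.array([
    [0.0000, 0.0000, 0.0],   # 0  C_A
    [1.2190, 0.0000, 0.0],   # 1  O_A
    [-0.6640, 1.1500, 0.0],  # 2  N_A
    [-0.5220, -0.9430, 0.0], # 3  H(C)_A
    [-1.6720, 1.1550, 0.0],  # 4  H(N)_A trans
    [-0.1700, 2.0300, 0.0],  # 5  H(N)_A cis (H-bonded)
    [1.9990, 3.6754, 0.0],   # 6  C_B
    [0.7800, 3.6754, 0.0],   # 7  O_B
    [2.6630, 2.5254, 0.0],   # 8  N_B
    [2.5210, 4.6184, 0.0],   # 9  H(C)_B
    [3.6710, 2.5204, 0.0],   # 10 H(N)_B trans
    [2.1690, 1.6454, 0.0],   # 11 H(N)_B cis (H-bonded)
])

CO_A = CoordinateDefinition("distance", (0, 1), "CO_A")
CO_B = CoordinateDefinition("distance", (6, 7), "CO_B")
AMIDE_PLANE_B = CoordinateDefinition("improper_dihedral", (7, 6, 8, 9), "amide_plane_B")
#: proton-transfer coordinate of the A->B hydrogen bond: d(O_B-H) - d(N_A... )
PT_AB = CoordinateDefinition("distance_difference", (7, 5, 2, 5), "PT_A_to_B")


def reference_structure() -> Structure:
    return Structure(elements=list(DIMER_ELEMENTS), coords=DIMER_COORDS.copy())


@dataclass
class PlantedMode:
    coordinate: CoordinateDefinition
    amplitude: float       # A (or degrees for dihedrals); see MockDimerSpec
    role: str              # "decay" | "spectator"

    def __post_init__(self) -> None:
        if self.role not in ("decay", "spectator"):
            raise ValueError("role must be 'decay' or 'spectator'")


def default_modes() -> list[PlantedMode]:
    """One gap-closing CO stretch on molecule A; the CO stretch and the
    amide-plane dihedral of molecule B as spectators."""
    return [
        PlantedMode(CO_A, 0.15, "decay"),
        PlantedMode(CO_B, 1.0, "spectator"),
        PlantedMode(AMIDE_PLANE_B, 40.0, "spectator"),
    ]


@dataclass
class MockDimerSpec:
    """Generator settings.

    The decay mode starts ``decay_start`` below the diabatic seam and
    drifts linearly at rate 2*amplitude per run length (plus white noise
    of width noise_sigma), so a larger amplitude closes the gap sooner.
    The signed diabatic gap is ``gap_function(v)`` of the decay
    displacement v, by default linear with gap0 at v = -decay_start and
    crossing zero at v = 0.  Spectator displacements are i.i.d. normal,
    amplitude * N(0, noise_sigma).  The active state flips to the ground
    state at the first frame whose absolute gap is below gap_threshold_ev.
    """

    n_atoms: int = 12
    planted_modes: list = field(default_factory=default_modes)
    noise_sigma: float = 0.05         # angstrom
    n_frames: int = 500
    dt_fs: float = 0.5
    gap0_ev: float = 4.0
    gap_threshold_ev: float = 0.1
    decay_start: float = 0.15         # angstrom below the seam
    gap_function: Optional[Callable[[float], float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise ValueError("need at least 10 frames")
        decays = [m for m in self.planted_modes if m.role == "decay"]
        if len(decays) != 1:
            raise ValueError("exactly one planted mode must have role='decay'")
        if self.n_atoms != 12:
            raise ValueError("the reference dimer has 12 atoms")

    @property
    def decay_mode(self) -> PlantedMode:
        return next(m for m in self.planted_modes if m.role == "decay")

    def signed_gap(self, v: float) -> float:
        """Signed diabatic gap (eV) at decay displacement v; monotone
        decreasing, positive before the seam."""
        if self.gap_function is not None:
            return self.gap_function(v)
        return self.gap0_ev * (-v) / self.decay_start


def _mode_directions(modes: Sequence[PlantedMode]) -> list[np.ndarray]:
    """Per-mode Cartesian displacement patterns (3N), scaled so that a
    pattern step of v changes the coordinate value by v to first order
    (Moore-Penrose direction g/|g|^2)."""
    ref = DIMER_COORDS
    out = []
    for m in modes:
        g = coordinate_gradient(m.coordinate, ref).ravel()
        out.append(g / float(g @ g))
    return out


def planted_direction(spec: MockDimerSpec) -> np.ndarray:
    """Unit 3N vector of the decay mode's Cartesian drift direction
    (the ground truth that the relaxation-vector estimator must find)."""
    g = coordinate_gradient(spec.decay_mode.coordinate, DIMER_COORDS).ravel()
    return g / np.linalg.norm(g)


def generate_trajectory(spec: MockDimerSpec, seed: Optional[int] = None) -> Trajectory:
    """One mock trajectory; fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_frames
    modes = spec.planted_modes
    dirs = _mode_directions(modes)
    a = spec.decay_mode.amplitude

    # internal-coordinate displacement series
    series = []
    decay_v = None
    for m in modes:
        if m.role == "decay":
            drift = -spec.decay_start + 2.0 * a * np.linspace(0.0, 1.0, n)
            v = drift + rng.normal(0.0, spec.noise_sigma, n)
            decay_v = v
        else:
            v = m.amplitude * rng.normal(0.0, spec.noise_sigma, n)
        series.append(v)

    gaps_ev = np.array([spec.signed_gap(v) for v in decay_v])
    # flip on the signed gap: the first frame at (or past) the seam region
    below = gaps_ev < spec.gap_threshold_ev
    first = int(np.argmax(below)) if below.any() else None
    active = np.ones(n, dtype=int)
    if first is not None:
        active[first:] = 0

    ref_flat = DIMER_COORDS.ravel()
    pos_ang = np.tile(ref_flat, (n, 1))
    for v, d in zip(series, dirs):
        pos_ang += np.outer(v, d)

    energies = np.zeros((n, 2))
    energies[:, 1] = np.abs(gaps_ev) * units.EV_TO_HARTREE

    return Trajectory(
        positions=pos_ang * units.ANGSTROM_TO_BOHR,
        energies=energies,
        active=active,
        dt=spec.dt_fs * units.FS_TO_AU_TIME,
        elements=list(DIMER_ELEMENTS),
        hops=[(first, 1, 0)] if first is not None else [],
        metadata=dict(
            model="mock_dimer",
            seed=int(spec.seed if seed is None else seed),
            dt_fs=spec.dt_fs,
            noise_sigma=spec.noise_sigma,
            decay_label=spec.decay_mode.coordinate.label,
        ),
    )


def generate_mock_dimer_trajectories(spec: MockDimerSpec, n_traj: int) -> list[Trajectory]:
    """Independent trajectories seeded spec.seed + index."""
    return [generate_trajectory(spec, seed=spec.seed + i) for i in range(n_traj)]
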