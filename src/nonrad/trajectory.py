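"""The universal trajectory record.

A :class:`Trajectory` is produced either by the surface-hopping engine
(model-space coordinates, n_dof columns) or by the mock-dimer generator /
file readers (Cartesian coordinates, 3N columns plus element symbols).
All internal quantities are in Hartree atomic units; accessor properties
provide the interface units (fs, angstrom, eV).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from . import units


@dataclass
class Trajectory:
    """Per-frame record of a two-state nonadiabatic trajectory.

    Attributes
    ----------
    positions : (n_frames, n_dof) array, bohr. For Cartesian trajectories
        n_dof = 3 * n_atoms (row-flattened) and ``elements`` is set.
    velocities : optional (n_frames, n_dof) array, bohr / a.u. time.
    energies : (n_frames, 2) adiabatic energies (E0, E1), hartree.
    active : (n_frames,) int array; adiabatic surface the nuclei move on.
    coeffs : optional (n_frames, 2) complex electronic amplitudes.
    hops : list of (frame_index, from_state, to_state).
    dt : nuclear time step, a.u.
    """

    positions: np.ndarray
    energies: np.ndarray
    active: np.ndarray
    dt: float
    velocities: Optional[np.ndarray] = None
    coeffs: Optional[np.ndarray] = None
    hops: list = field(default_factory=list)
    elements: Optional[list] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.active = np.asarray(self.active, dtype=int)
        n = len(self.positions)
        if self.energies.shape != (n, 2):
            raise ValueError(f"energies must be (n_frames, 2), got {self.energies.shape}")
        if self.active.shape != (n,):
            raise ValueError("active must have one entry per frame")

    # -- basic shape ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def n_dof(self) -> int:
        return self.positions.shape[1]

    @property
    def is_cartesian(self) -> bool:
        return self.elements is not None

    @property
    def n_atoms(self) -> int:
        if not self.is_cartesian:
            raise ValueError("not a Cartesian trajectory")
        return len(self.elements)

    # -- derived series ------------------------------------------------
    @property
    def gap(self) -> np.ndarray:
        """Adiabatic gap E1 - E0, hartree (>= 0)."""
        return self.energies[:, 1] - self.energies[:, 0]

    @property
    def gap_ev(self) -> np.ndarray:
        return self.gap * units.HARTREE_TO_EV

    @property
    def times(self) -> np.ndarray:
        """Frame times, a.u."""
        return np.arange(self.n_frames) * self.dt

    @property
    def times_fs(self) -> np.ndarray:
        return self.times * units.AU_TIME_TO_FS

    @property
    def first_crossing(self) -> Optional[int]:
        """Earliest frame on the ground surface after excitation, or None."""
        idx = np.nonzero(self.active == 0)[0]
        return int(idx[0]) if idx.size else None

    @property
    def decayed(self) -> bool:
        return self.first_crossing is not None

    def positions_angstrom(self) -> np.ndarray:
        return self.positions * units.BOHR_TO_ANGSTROM

    def frame_xyz(self, i: int) -> np.ndarray:
        """Cartesian coordinates of frame i as (n_atoms, 3), angstrom."""
        if not self.is_cartesian:
            raise ValueError("not a Cartesian trajectory")
        return self.positions[i].reshape(-1, 3) * units.BOHR_TO_ANGSTROM

    def validate(self) -> None:
        """Cheap internal-consistency checks (hops vs active-state series)."""
        for frame, src, dst in self.hops:
            if self.active[frame] != dst:
                raise ValueError(f"hop record at frame {frame} inconsistent with active series")
        if not np.all(self.energies[:, 1] >= self.energies[:, 0] - 1e-12):
            raise ValueError("adiabatic energies out of order")


def summarize_metadata(traj: Trajectory) -> dict[str, Any]:
    md = dict(traj.metadata)
    md.update(
        n_frames=traj.n_frames,
        n_dof=traj.n_dof,
        decayed=traj.decayed,
        first_crossing=traj.first_crossing,
        n_hops=len(traj.hops),
    )
    return md
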