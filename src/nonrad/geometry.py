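"""Internal-coordinate kernels over Cartesian structures.

Distances, difference-of-distances (proton-transfer coordinates such as
d(O-H) - d(N-H)), improper dihedrals (amide planarity), hydrogen-bond
heavy-atom distances, and Kabsch superposition / RMSD.  All take
coordinates in angstrom and return angstrom or degrees; gradients are
analytic and verified against finite differences in the test suite.

Atom indices are 0-based throughout the API; configuration files may use
1-based indices with an explicit ``index_base`` key (see `nonrad.config`).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class CoordinateDefinition:
    """A generalized internal coordinate.

    kind:
      - "distance": d(a, b); atom_indices = (a, b)
      - "distance_difference": d(a, b) - d(c, d); atom_indices = (a, b, c, d)
      - "improper_dihedral": dihedral of planes (a,b,c) and (b,c,d), degrees
    """

    kind: str
    atom_indices: tuple
    label: str = ""

    def __post_init__(self) -> None:
        kinds = {"distance": 2, "distance_difference": 4, "improper_dihedral": 4}
        if self.kind not in kinds:
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        idx = tuple(int(i) for i in self.atom_indices)
        object.__setattr__(self, "atom_indices", idx)
        if len(idx) != kinds[self.kind]:
            raise ValueError(f"{self.kind} needs {kinds[self.kind]} atom indices")
        if self.kind == "distance" and len(set(idx)) != 2:
            raise ValueError("distance atoms must be distinct")
        if self.kind == "distance_difference" and (idx[0] == idx[1] or idx[2] == idx[3]):
            raise ValueError("each distance pair must use distinct atoms")
        if self.kind == "improper_dihedral" and len(set(idx)) != 4:
            raise ValueError("dihedral atoms must be distinct")


@dataclass
class Structure:
    """Element symbols plus Cartesian coordinates in angstrom."""

    elements: list
    coords: np.ndarray
    masses: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def _as_coords(s) -> np.ndarray:
    if isinstance(s, Structure):
        return s.coords
    x = np.asarray(s, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 3)
    return x


def _check_indices(coord: CoordinateDefinition, n_atoms: int) -> None:
    for i in coord.atom_indices:
        if not 0 <= i < n_atoms:
            raise IndexError(
                f"coordinate {coord.label or coord.kind!r}: atom index {i} "
                f"out of range for {n_atoms} atoms"
            )


def evaluate(coord: CoordinateDefinition, s) -> float:
    """Value of the coordinate: angstrom for distances, degrees in
    (-180, 180] for improper dihedrals."""
    x = _as_coords(s)
    _check_indices(coord, len(x))
    i = coord.atom_indices
    if coord.kind == "distance":
        return float(np.linalg.norm(x[i[0]] - x[i[1]]))
    if coord.kind == "distance_difference":
        return float(
            np.linalg.norm(x[i[0]] - x[i[1]]) - np.linalg.norm(x[i[2]] - x[i[3]])
        )
    # improper dihedral between planes (a,b,c) and (b,c,d)
    a, b, c, d = (x[k] for k in i)
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def planarity_deviation(coord: CoordinateDefinition, s) -> float:
    """Deviation of an improper dihedral from planarity: |180 - |phi||, degrees."""
    if coord.kind != "improper_dihedral":
        raise ValueError("planarity deviation is defined for improper dihedrals")
    return abs(180.0 - abs(evaluate(coord, s)))


def coordinate_gradient(coord: CoordinateDefinition, s) -> np.ndarray:
    """Analytic per-atom Cartesian gradient, shape (n_atoms, 3).

    Units: dimensionless for distances (A/A), degrees/angstrom for
    dihedrals.  Degenerate geometries (zero bond vectors, collinear
    dihedral frames) raise.
    """
    x = _as_coords(s)
    _check_indices(coord, len(x))
    g = np.zeros_like(x)
    i = coord.atom_indices
    if coord.kind in ("distance", "distance_difference"):
        pairs = [(i[0], i[1], 1.0)]
        if coord.kind == "distance_difference":
            pairs.append((i[2], i[3], -1.0))
        for a, b, sign in pairs:
            v = x[a] - x[b]
            r = np.linalg.norm(v)
            if r < 1e-10:
                raise ValueError(f"degenerate geometry: atoms {a},{b} coincide")
            u = sign * v / r
            g[a] += u
            g[b] -= u
        return g
    a, b, c, d = i
    b1, b2, b3 = x[b] - x[a], x[c] - x[b], x[d] - x[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    if lb2 < 1e-10 or n1sq < 1e-20 or n2sq < 1e-20:
        raise ValueError("degenerate dihedral geometry")
    # standard analytic dihedral gradient (radians), then convert to degrees
    da = lb2 / n1sq * n1
    dd = -lb2 / n2sq * n2
    f1 = float(np.dot(b1, b2)) / lb2**2
    f3 = float(np.dot(b3, b2)) / lb2**2
    db = -(1.0 + f1) * da + f3 * dd
    dc = f1 * da - (1.0 + f3) * dd
    for idx, grad in zip((a, b, c, d), (da, db, dc, dd)):
        g[idx] += np.degrees(grad)
    return g


def hydrogen_bond_length(s, donor: int, acceptor: int) -> float:
    """Heavy-atom donor-acceptor distance in angstrom."""
    return float(np.linalg.norm(_as_coords(s)[donor] - _as_coords(s)[acceptor]))


def kabsch_rmsd(
    a, b, selection: Optional[Sequence[int]] = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal proper-rotation superposition of b onto a.

    Returns (rmsd_angstrom, rotation_matrix, translation) such that
    ``b[sel] @ R.T + t`` best matches ``a[sel]``.  Reflections are
    excluded (scipy's Kabsch implementation enforces det(R) = +1).
    """
    xa, xb = _as_coords(a), _as_coords(b)
    if isinstance(a, Structure) and isinstance(b, Structure):
        if a.elements != b.elements:
            raise ValueError("element lists differ")
    if xa.shape != xb.shape:
        raise ValueError("structures have different sizes")
    sel = np.arange(len(xa)) if selection is None else np.asarray(selection, dtype=int)
    if len(sel) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    pa = xa[sel] - xa[sel].mean(axis=0)
    pb = xb[sel] - xb[sel].mean(axis=0)
    rot, _ = Rotation.align_vectors(pa, pb)
    R = rot.as_matrix()
    t = xa[sel].mean(axis=0) - xb[sel].mean(axis=0) @ R.T
    diff = pb @ R.T - pa
    rmsd = float(np.sqrt((diff**2).sum() / len(sel)))
    return rmsd, R, t


def align_frames_to_mean(frames: np.ndarray, n_iter: int = 1) -> np.ndarray:
    """Kabsch-superpose every frame onto the ensemble mean structure.

    frames: (n_frames, 3N) angstrom.  One fixed-point iteration by
    default: mean -> align -> re-mean.  Returns the aligned copy.
    """
    out = np.array(frames, dtype=float)
    n = out.shape[1] // 3
    for _ in range(n_iter):
        ref = out.mean(axis=0).reshape(n, 3)
        ref0 = ref - ref.mean(axis=0)
        for k in range(len(out)):
            xb = out[k].reshape(n, 3)
            cb = xb.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref0, xb - cb)
            out[k] = ((xb - cb) @ rot.as_matrix().T + ref.mean(axis=0)).ravel()
    return out
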