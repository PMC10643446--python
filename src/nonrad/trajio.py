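"""Trajectory and results I/O.

Interchange formats are deliberately plain text: extended XYZ with
``key=value`` pairs on the comment line (time_fs, E0_eV, E1_eV, state)
for Cartesian trajectories, a parallel TSV time series (frame, time_fs,
E0_eV, E1_eV, state, gap_eV, coordinates...) that also serves model-space
trajectories, and JSON for summaries.  Every writer embeds the seed and
a hash of the configuration it was produced with.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Optional

import numpy as np

from . import units
from .trajectory import Trajectory

_VERSION = "0.1.0"


# ----------------------------------------------------------------------
# extended XYZ
# ----------------------------------------------------------------------

def write_trajectory_xyz(traj: Trajectory, path: str) -> None:
    """Extended-XYZ writer (Cartesian trajectories only)."""
    if not traj.is_cartesian:
        raise ValueError("only Cartesian trajectories can be written as XYZ")
    times = traj.times_fs
    e_ev = traj.energies * units.HARTREE_TO_EV
    seed = traj.metadata.get("seed", "")
    x = traj.positions_angstrom()
    n = traj.n_atoms
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(
                f"time_fs={times[i]:.6f} E0_eV={e_ev[i, 0]:.8f} "
                f"E1_eV={e_ev[i, 1]:.8f} state={int(traj.active[i])} seed={seed}\n"
            )
            frame = x[i].reshape(n, 3)
            for el, row in zip(traj.elements, frame):
                fh.write(f"{el} {row[0]:.8f} {row[1]:.8f} {row[2]:.8f}\n")


def read_trajectory(path: str) -> Trajectory:
    """Read an extended-XYZ trajectory back into internal atomic units.

    Malformed frames are reported with their frame index and line number;
    inconsistent atom counts and missing energy fields are errors.
    """
    frames = []
    energies = []
    active = []
    times = []
    elements: Optional[list] = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_idx = 0
    required = ("time_fs", "E0_eV", "E1_eV", "state")
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"line {i + 1}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 + n >= len(lines) + 1:
            raise ValueError(f"frame {frame_idx}: truncated at line {i + 1}")
        fields = {}
        for tok in lines[i + 1].split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                fields[k] = v
        for key in required:
            if key not in fields:
                raise ValueError(f"frame {frame_idx}: missing {key!r} on comment line")
        els = []
        coords = np.empty((n, 3))
        for a in range(n):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise ValueError(f"frame {frame_idx}: bad atom line {i + 3 + a}")
            els.append(parts[0])
            coords[a] = [float(p) for p in parts[1:4]]
        if elements is None:
            elements = els
        elif len(els) != len(elements):
            raise ValueError(
                f"frame {frame_idx}: atom count {len(els)} differs from first frame "
                f"({len(elements)})"
            )
        frames.append(coords.ravel() * units.ANGSTROM_TO_BOHR)
        energies.append(
            [float(fields["E0_eV"]) * units.EV_TO_HARTREE,
             float(fields["E1_eV"]) * units.EV_TO_HARTREE]
        )
        active.append(int(fields["state"]))
        times.append(float(fields["time_fs"]))
        i += 2 + n
        frame_idx += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    dt = (times[1] - times[0]) * units.FS_TO_AU_TIME if len(times) > 1 else 1.0
    return Trajectory(
        positions=np.array(frames),
        energies=np.array(energies),
        active=np.array(active, dtype=int),
        dt=dt,
        elements=elements,
        metadata=dict(source=os.path.basename(path)),
    )


# ----------------------------------------------------------------------
# TSV time series
# ----------------------------------------------------------------------

def write_trajectory_tsv(traj: Trajectory, path: str, include_positions: bool = None) -> None:
    if include_positions is None:
        include_positions = not traj.is_cartesian
    e_ev = traj.energies * units.HARTREE_TO_EV
    times = traj.times_fs
    cols = ["frame", "time_fs", "E0_eV", "E1_eV", "state", "gap_eV"]
    if include_positions:
        cols += [f"dof{k}" for k in range(traj.n_dof)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(traj.n_frames):
            row = [
                str(i), f"{times[i]:.6f}", f"{e_ev[i, 0]:.8f}", f"{e_ev[i, 1]:.8f}",
                str(int(traj.active[i])), f"{e_ev[i, 1] - e_ev[i, 0]:.8f}",
            ]
            if include_positions:
                row += [f"{v:.10f}" for v in traj.positions[i]]
            fh.write("\t".join(row) + "\n")


# ----------------------------------------------------------------------
# JSON summaries
# ----------------------------------------------------------------------

def config_hash(config) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


def write_results(summary, path: str, fmt: str = "json", config=None, seed=None) -> None:
    """Serialize a summary object with stable key order; JSON embeds the
    configuration hash, seed and package version."""
    if fmt == "json":
        doc = {
            "version": _VERSION,
            "seed": seed,
            "config_hash": config_hash(config) if config is not None else None,
            "config": _jsonable(config) if config is not None else None,
            "results": _jsonable(summary),
        }
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)
    elif fmt == "tsv":
        rows = summary if isinstance(summary, list) else [summary]
        if not rows:
            raise ValueError("nothing to write")
        keys = list(_jsonable(rows[0]).keys())
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for r in rows:
                d = _jsonable(r)
                fh.write("\t".join(str(d.get(k, "")) for k in keys) + "\n")
        os.replace(tmp, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_histograms_tsv(hists: dict, coordinate_label: str, path: str) -> None:
    """TSV histogram table: coordinate, ensemble, bin_lo, bin_hi, count."""
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write("coordinate\tensemble\tbin_lo\tbin_hi\tcount\n")
        for label, h in hists.items():
            for lo, hi, c in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
                fh.write(f"{coordinate_label}\t{label}\t{lo:.6f}\t{hi:.6f}\t{int(c)}\n")
    os.replace(tmp, path)


def write_mode_file(reference, direction: np.ndarray, path: str, scale: float = 1.0) -> None:
    """XYZ "mode file": the reference structure with per-atom displacement
    vectors appended as extra columns (for visualization)."""
    d = np.asarray(direction, dtype=float).reshape(-1, 3) * scale
    with open(path, "w") as fh:
        fh.write(f"{reference.n_atoms}\n")
        fh.write("relaxation_mode displacement_columns=dx,dy,dz\n")
        for el, row, dv in zip(reference.elements, reference.coords, d):
            fh.write(
                f"{el} {row[0]:.6f} {row[1]:.6f} {row[2]:.6f} "
                f"{dv[0]:.6f} {dv[1]:.6f} {dv[2]:.6f}\n"
            )
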