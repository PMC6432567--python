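"""Trajectory container and file I/O (HDF5 bulk storage, XYZ/PDB snapshots)."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

from .model import SPECIES_LABELS

__all__ = ["Trajectory", "write_trajectory", "read_trajectory", "write_xyz_frame", "write_pdb_frame"]

_XYZ_SYMBOL = {0: "M", 1: "C", 2: "P", 3: "A", 4: "W"}


@dataclass
class Trajectory:
    """Saved frames of one run: wrapped positions, per-frame times, species.

    ``species`` holds the integer codes of :data:`peltrans.model.SPECIES_CODES`;
    monomers are the first ``n_monomers`` indices in chain order.  ``attrs``
    carries run metadata (seed, dt, E, tau, completed, ...).
    """

    times: np.ndarray  # (F,)
    positions: np.ndarray  # (F, n, 3)
    species: np.ndarray  # (n,)
    charge_valence: np.ndarray  # (n,)
    box: np.ndarray  # (3,)
    n_monomers: int
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[0] != len(self.times):
            raise ValueError("positions must have shape (n_frames, n_beads, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def tau(self):
        return self.attrs.get("tau")

    def monomer_positions(self, frame: int) -> np.ndarray:
        return self.positions[frame, : self.n_monomers]

    def unwrapped_chain(self, frame: int) -> np.ndarray:
        """Contiguous monomer coordinates rebuilt by minimum-image bond walking.

        Wrapped coordinates can split the chain across a periodic boundary;
        chain-shape observables (R_g, contour length, end positions) use
        this reconstruction, anchored at the head monomer's wrapped position.
        """
        pos = self.positions[frame, : self.n_monomers]
        steps = pos[1:] - pos[:-1]
        steps -= self.box * np.round(steps / self.box)
        out = np.empty_like(pos)
        out[0] = pos[0]
        np.cumsum(steps, axis=0, out=out[1:])
        out[1:] += pos[0]
        return out


def write_trajectory(traj: Trajectory, path) -> None:
    """Store a trajectory in HDF5.

    Layout: datasets ``times`` (F,), ``positions`` (F, n, 3), ``species``
    (n,), ``charge_valence`` (n,), ``box`` (3,); scalar ``n_monomers`` and a
    JSON-encoded ``attrs`` string live in the file attributes.
    """
    path = os.fspath(path)
    tmp = path + ".tmp"
    with h5py.File(tmp, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("positions", data=traj.positions)
        f.create_dataset("species", data=np.asarray(traj.species, dtype=np.int64))
        f.create_dataset("charge_valence", data=np.asarray(traj.charge_valence, dtype=np.int64))
        f.create_dataset("box", data=np.asarray(traj.box, dtype=np.float64))
        f.attrs["n_monomers"] = int(traj.n_monomers)
        f.attrs["attrs_json"] = json.dumps(traj.attrs)
    os.replace(tmp, path)


def read_trajectory(path) -> Trajectory:
    try:
        with h5py.File(path, "r") as f:
            required = ["times", "positions", "species", "charge_valence", "box"]
            missing = [k for k in required if k not in f]
            if missing:
                raise IOError(f"corrupt trajectory file {path}: missing {missing}")
            return Trajectory(
                times=f["times"][...],
                positions=f["positions"][...],
                species=f["species"][...],
                charge_valence=f["charge_valence"][...],
                box=f["box"][...],
                n_monomers=int(f.attrs["n_monomers"]),
                attrs=json.loads(f.attrs.get("attrs_json", "{}")),
            )
    except OSError as exc:
        raise IOError(f"cannot read trajectory file {path}: {exc}") from exc


def write_xyz_frame(path, positions, symbols, comment: str = "", append: bool = False) -> None:
    positions = np.asarray(positions)
    mode = "a" if append else "w"
    with open(path, mode) as f:
        f.write(f"{len(positions)}\n{comment}\n")
        for sym, (x, y, z) in zip(symbols, positions):
            f.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")


def export_xyz(traj: Trajectory, path, every: int = 1) -> None:
    """Export trajectory frames as a concatenated XYZ file."""
    symbols = [_XYZ_SYMBOL[int(s)] for s in traj.species]
    first = True
    for i in range(0, traj.n_frames, every):
        write_xyz_frame(path, traj.positions[i], symbols, comment=f"t={traj.times[i]:.4f}", append=not first)
        first = False


def write_pdb_frame(path, positions, species, box) -> None:
    """Minimal single-frame PDB export (HETATM records, CRYST1 box)."""
    positions = np.asarray(positions)
    with open(path, "w") as f:
        f.write(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}  90.00  90.00  90.00 P 1           1\n")
        for i, (sp, (x, y, z)) in enumerate(zip(species, positions), start=1):
            name = SPECIES_LABELS.get(int(sp), "X")[:3].upper()
            f.write(
                f"HETATM{i % 100000:5d} {name:<4s}{name:<3s} A{i % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
        f.write("END\n")
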