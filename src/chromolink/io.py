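"""File formats: topology JSON, extended-XYZ, dump dialect, HDF5, CSV tables.

The canonical structure/trajectory text format is extended-XYZ with four
extra per-bead quaternion columns (scalar-first).  A minimal LAMMPS-style
dump reader/writer is provided for interoperability; HDF5 containers hold
production trajectories.  Every writer/reader pair round-trips exactly at
the printed precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fiber import FiberTopology

__all__ = [
    "save_topology",
    "load_topology",
    "write_xyz",
    "read_xyz",
    "write_dump",
    "read_dump",
    "save_trajectory_h5",
    "load_trajectory_h5",
    "windows_to_csv",
    "windows_from_csv",
    "pmf_to_csv",
    "binodal_to_csv",
    "binodal_from_csv",
    "RunConfig",
    "config_hash",
]

_SPECIES = {0: "L", 1: "N", 2: "C"}  # linker DNA, nucleosomal DNA, histone core
_SPECIES_INV = {v: k for k, v in _SPECIES.items()}


def save_topology(topology: FiberTopology, path) -> None:
    Path(path).write_text(json.dumps(topology.to_dict(), indent=1, sort_keys=True))


def load_topology(path) -> FiberTopology:
    return FiberTopology.from_dict(json.loads(Path(path).read_text()))


def write_xyz(path, positions, quats, bead_class, box=None, comment: str = "", append: bool = False) -> None:
    """Extended-XYZ with quaternion columns (scalar-first), one frame."""
    positions = np.asarray(positions)
    quats = np.asarray(quats)
    lines = [str(len(positions))]
    props = 'Properties=species:S:1:pos:R:3:quat:R:4'
    lattice = ""
    if box is not None:
        b = np.asarray(box, dtype=float)
        lattice = f' Lattice="{b[0]:.6f} 0 0 0 {b[1]:.6f} 0 0 0 {b[2]:.6f}"'
    lines.append(f"{props}{lattice} {comment}".rstrip())
    for p, q, c in zip(positions, quats, np.asarray(bead_class)):
        lines.append(
            f"{_SPECIES[int(c)]} "
            + " ".join(f"{x:.8f}" for x in p)
            + " "
            + " ".join(f"{x:.10f}" for x in q)
        )
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path):
    """Read one extended-XYZ frame -> (positions, quats, bead_class, box)."""
    text = Path(path).read_text().splitlines()
    n = int(text[0])
    header = text[1]
    box = None
    if 'Lattice="' in header:
        nums = [float(x) for x in header.split('Lattice="')[1].split('"')[0].split()]
        box = np.array([nums[0], nums[4], nums[8]])
    pos, quat, cls = [], [], []
    for line in text[2 : 2 + n]:
        parts = line.split()
        cls.append(_SPECIES_INV[parts[0]])
        pos.append([float(x) for x in parts[1:4]])
        quat.append([float(x) for x in parts[4:8]])
    return np.array(pos), np.array(quat), np.array(cls, dtype=int), box


def write_pdb(path, positions, bead_class, rigid_group=None) -> None:
    """Pseudo-atom PDB export (one atom per bead; rigid groups as chains)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    atoms = struc.AtomArray(n)
    atoms.coord = positions
    names = {0: "DL", 1: "DN", 2: "HC"}
    atoms.atom_name = np.array([names[int(c)] for c in np.asarray(bead_class)])
    atoms.res_name = np.array(["BED"] * n)
    atoms.res_id = np.arange(1, n + 1)
    atoms.element = np.array(["P"] * n)
    if rigid_group is None:
        atoms.chain_id = np.array(["A"] * n)
    else:
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        atoms.chain_id = np.array([letters[(g + 1) % 26] for g in np.asarray(rigid_group, dtype=int)])
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def write_dump(path, step, positions, quats, bead_class, box) -> None:
    """Minimal LAMMPS-style dump frame with quaternion columns."""
    b = np.asarray(box, dtype=float)
    lines = [
        "ITEM: TIMESTEP",
        str(int(step)),
        "ITEM: NUMBER OF ATOMS",
        str(len(positions)),
        "ITEM: BOX BOUNDS pp pp pp",
        f"0.0 {b[0]:.6f}",
        f"0.0 {b[1]:.6f}",
        f"0.0 {b[2]:.6f}",
        "ITEM: ATOMS id type x y z qw qx qy qz",
    ]
    for i, (p, q, c) in enumerate(zip(positions, quats, np.asarray(bead_class)), start=1):
        lines.append(
            f"{i} {int(c) + 1} " + " ".join(f"{x:.8f}" for x in p) + " " + " ".join(f"{x:.10f}" for x in q)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_dump(path):
    """Read one dump frame -> (step, positions, quats, bead_class, box)."""
    text = Path(path).read_text().splitlines()
    step = int(text[1])
    n = int(text[3])
    box = np.array([float(text[5].split()[1]), float(text[6].split()[1]), float(text[7].split()[1])])
    pos, quat, cls = [], [], []
    for line in text[9 : 9 + n]:
        parts = line.split()
        cls.append(int(parts[1]) - 1)
        pos.append([float(x) for x in parts[2:5]])
        quat.append([float(x) for x in parts[5:9]])
    order = np.argsort([int(l.split()[0]) for l in text[9 : 9 + n]])
    return step, np.array(pos)[order], np.array(quat)[order], np.array(cls, dtype=int)[order], box


def save_trajectory_h5(traj, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["schema"] = "chromolink-trajectory-1"
        h5.create_dataset("steps", data=np.array([f.step for f in traj.frames]))
        h5.create_dataset("positions", data=np.stack([f.positions for f in traj.frames]))
        h5.create_dataset("quats", data=np.stack([f.quats for f in traj.frames]))
        h5.create_dataset("energies", data=np.array([f.energy for f in traj.frames]))
        h5.create_dataset("bead_class", data=traj.bead_class)
        h5.create_dataset("fiber_id", data=traj.fiber_id)
        if traj.box is not None:
            h5.create_dataset("box", data=traj.box)


def load_trajectory_h5(path) -> dict:
    import h5py

    with h5py.File(path, "r") as h5:
        out = {k: np.array(h5[k]) for k in h5.keys()}
    return out


def windows_to_csv(windows, prefix) -> None:
    """One CSV (cv, energy) per window plus a JSON metadata sidecar."""
    meta = []
    prefix = Path(prefix)
    for i, w in enumerate(windows):
        df = pd.DataFrame(w.samples, columns=["cv", "energy"])
        df.to_csv(f"{prefix}_window{i:03d}.csv", index=False)
        meta.append({"index": i, "cv_center": w.cv_center, "force_constant": w.force_constant, "temperature": w.temperature})
    Path(f"{prefix}_windows.json").write_text(json.dumps(meta, indent=1))


def windows_from_csv(prefix):
    from .free_energy import UmbrellaWindow

    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}_windows.json").read_text())
    out = []
    for m in meta:
        df = pd.read_csv(f"{prefix}_window{m['index']:03d}.csv")
        out.append(UmbrellaWindow(m["cv_center"], m["force_constant"], df.to_numpy(), temperature=m["temperature"]))
    return out


def pmf_to_csv(profile, path) -> None:
    err = profile.uncertainty if profile.uncertainty is not None else np.full_like(profile.cv, np.nan)
    pd.DataFrame({"cv": profile.cv, "free_energy": profile.free_energy, "err": err}).to_csv(path, index=False)


def binodal_to_csv(points, path) -> None:
    pd.DataFrame(
        [
            {
                "salt": p.salt,
                "rho_low": p.rho_low,
                "rho_high": p.rho_high,
                "err_low": p.err_low,
                "err_high": p.err_high,
                "two_phase": p.two_phase,
            }
            for p in points
        ]
    ).to_csv(path, index=False)


def binodal_from_csv(path):
    from .phase import BinodalPoint

    df = pd.read_csv(path)
    return [
        BinodalPoint(
            salt=r.salt,
            rho_low=r.rho_low,
            rho_high=r.rho_high,
            err_low=r.err_low,
            err_high=r.err_high,
            two_phase=bool(r.two_phase),
        )
        for r in df.itertuples()
    ]


_KNOWN_KEYS = {
    "seed",
    "forcefield",
    "topology",
    "dynamics",
    "umbrella",
    "analysis",
    "output",
    "schema",
}


@dataclass
class RunConfig:
    """Top-level run configuration; unknown keys are rejected."""

    seed: int = 0
    forcefield: str | None = None
    topology: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    umbrella: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    schema: str = "chromolink-run-1"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "schema": self.schema,
            "seed": self.seed,
            "forcefield": self.forcefield,
            "topology": self.topology,
            "dynamics": self.dynamics,
            "umbrella": self.umbrella,
            "analysis": self.analysis,
            "output": self.output,
        }


def config_hash(config) -> str:
    """Stable short hash of a run configuration, embedded in outputs."""
    doc = config.to_dict() if hasattr(config, "to_dict") else dict(config)
    return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:12]
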