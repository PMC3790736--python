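"""Structure, topology-sidecar and trajectory I/O.

Canonical on-disk representation:

* coordinates — XYZ (single frame) or PDB (via biotite, preserving chain
  and 1-based residue numbering);
* everything the coordinate formats cannot carry — charges, molecule and
  residue assignments, named groups, exclusions, masses — lives in a JSON
  "topology sidecar";
* trajectories — multi-frame extended XYZ whose comment lines carry
  ``time=<ps>`` (and ``box=`` on the first frame).

All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .system import ParticleSystem
from .traj import Trajectory

__all__ = [
    "write_topology",
    "read_topology",
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "read_pdb",
    "write_structure",
    "read_structure",
    "write_trajectory",
    "read_trajectory",
]

PathLike = Union[str, Path]


def _atomic_write(path: PathLike, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ----------------------------------------------------------------------
# topology sidecar


def write_topology(system: ParticleSystem, path: PathLike) -> None:
    payload = {
        "n_particles": system.n_particles,
        "charges": system.charges.tolist(),
        "molecule_id": system.molecule_id.tolist(),
        "residue_id": system.residue_id.tolist(),
        "group_labels": {k: v.tolist() for k, v in system.group_labels.items()},
        "exclusions": system.exclusions.tolist(),
        "scaled_pairs": system.scaled_pairs.tolist(),
        "scale14": system.scale14,
        "masses": system.masses.tolist(),
        "names": list(system.names) if system.names else None,
        "box": None if system.box is None else system.box.tolist(),
        "bonded_terms": system.bonded_terms,
    }
    _atomic_write(path, json.dumps(payload))


def read_topology(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ----------------------------------------------------------------------
# XYZ


def write_xyz(system: ParticleSystem, path: PathLike, comment: str = "") -> None:
    names = system.names or ["X"] * system.n_particles
    lines = [str(system.n_particles), comment]
    for name, p in zip(names, system.positions):
        lines.append(f"{name} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}")
    _atomic_write(path, "\n".join(lines) + "\n")


def _read_xyz_frames(path: PathLike):
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frames = []
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: line {pos + 1}: expected atom count") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) != n:
            raise ValueError(f"{path}: truncated frame at line {pos + 1}")
        names, coords = [], []
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {pos + 3 + k}: malformed atom record")
            names.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append((names, np.asarray(coords), comment))
        pos += 2 + n
    if not frames:
        raise ValueError(f"{path}: empty XYZ file")
    return frames


def read_xyz(path: PathLike):
    """First frame of an XYZ file: (names, positions, comment)."""
    return _read_xyz_frames(path)[0]


# ----------------------------------------------------------------------
# PDB (via biotite)


def write_pdb(system: ParticleSystem, path: PathLike) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = system.n_particles
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(system.positions, np.float32)
    names = system.names or ["X"] * n
    atoms.atom_name = np.array([str(s)[:4] for s in names])
    atoms.element = np.array([str(s)[:1].upper() for s in names])
    atoms.res_id = np.asarray(system.residue_id) + 1  # 1-based in PDB
    chains = np.asarray(system.molecule_id)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    atoms.chain_id = np.array([letters[int(c) % 26] for c in chains])
    atoms.res_name = np.array(["UNK"] * n)
    atoms.hetero = np.array([True] * n)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    fd, tmp = tempfile.mkstemp(dir=Path(path).parent, suffix=".tmp")
    os.close(fd)
    pdb.write(tmp)
    os.replace(tmp, path)


def read_pdb(path: PathLike):
    """(positions, res_id_zero_based, chain_index, atom_names) from a PDB."""
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(str(path)).get_structure(model=1)
    chains = atoms.chain_id
    _, chain_index = np.unique(chains, return_inverse=True)
    return (
        np.asarray(atoms.coord, float),
        np.asarray(atoms.res_id, np.int64) - 1,
        chain_index.astype(np.int64),
        list(atoms.atom_name),
    )


# ----------------------------------------------------------------------
# structure = coordinates + sidecar


def write_structure(system: ParticleSystem, path: PathLike, topology_path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        write_pdb(system, path)
    else:
        write_xyz(system, path)
    write_topology(system, topology_path)


def read_structure(path: PathLike, topology_path: PathLike) -> ParticleSystem:
    """Rebuild a ParticleSystem from coordinates plus the JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        positions, _, _, _ = read_pdb(path)
    else:
        _, positions, _ = read_xyz(path)
    top = read_topology(topology_path)
    if len(positions) != top["n_particles"]:
        raise ValueError(
            f"{path} has {len(positions)} atoms but sidecar {topology_path} "
            f"declares {top['n_particles']}"
        )
    return ParticleSystem(
        positions=positions,
        charges=np.asarray(top["charges"]),
        box=None if top["box"] is None else np.asarray(top["box"]),
        molecule_id=np.asarray(top["molecule_id"], np.int64),
        residue_id=np.asarray(top["residue_id"], np.int64),
        group_labels={k: np.asarray(v, np.int64) for k, v in top["group_labels"].items()},
        exclusions=np.asarray(top["exclusions"], np.int64).reshape(-1, 2),
        scaled_pairs=np.asarray(top["scaled_pairs"], np.int64).reshape(-1, 2),
        scale14=top["scale14"],
        masses=np.asarray(top["masses"]),
        names=top["names"],
        bonded_terms={
            k: [tuple(t) for t in v] for k, v in (top.get("bonded_terms") or {}).items()
        },
    )


# ----------------------------------------------------------------------
# trajectories (multi-frame extended XYZ)


def write_trajectory(traj: Trajectory, path: PathLike, names=None) -> None:
    if names is None:
        names = (traj.topology.names if traj.topology is not None else None) or [
            "X"
        ] * traj.frames.shape[1]
    chunks = []
    for f, (frame, t) in enumerate(zip(traj.frames, traj.times_ps)):
        comment = f"time={t:.6f} ps"
        if f == 0 and traj.topology is not None and traj.topology.box is not None:
            b = traj.topology.box
            comment += f" box={b[0]:.6f},{b[1]:.6f},{b[2]:.6f}"
        chunks.append(str(len(frame)))
        chunks.append(comment)
        for name, p in zip(names, frame):
            chunks.append(f"{name} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}")
    _atomic_write(path, "\n".join(chunks) + "\n")


def read_trajectory(path: PathLike, topology: Optional[ParticleSystem] = None) -> Trajectory:
    raw = _read_xyz_frames(path)
    n0 = len(raw[0][0])
    frames, times = [], []
    for k, (names, coords, comment) in enumerate(raw):
        if len(names) != n0:
            raise ValueError(f"{path}: frame {k} has {len(names)} atoms, expected {n0}")
        t = float(k)
        for token in comment.split():
            if token.startswith("time="):
                t = float(token[5:].rstrip("ps").rstrip())
        frames.append(coords)
        times.append(t)
    return Trajectory(frames=np.asarray(frames), times_ps=np.asarray(times), topology=topology)
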