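"""Seeded generators for every synthetic test-system class.

All generators are pure functions of their arguments plus an explicit RNG
seed: the same spec and seed reproduce a bit-identical
:class:`~zdsum.system.ParticleSystem`. They emulate, at desk scale, the
system classes the method was developed on — ionic crystals, random
electrolytes, three-site water lattices with TIP3P-style charges, and a
coarse double-helical polyelectrolyte (two antiparallel strands of −1
"phosphate" beads) neutralized by +1 counterions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Tuple

import numpy as np

from .system import ParticleSystem, merge_systems

__all__ = [
    "GeneratorSpec",
    "make_rocksalt",
    "make_electrolyte",
    "make_water_lattice",
    "make_coarse_duplex",
    "make_cluster",
    "make_solvated_duplex",
]

# TIP3P-like 3-site geometry/charges
WATER_R_OH = 0.9572  # Å
WATER_ANGLE = math.radians(104.52)
WATER_Q_O = -0.834
WATER_Q_H = 0.417


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of a synthetic system, for provenance files."""

    kind: str  # rocksalt | electrolyte | water_lattice | coarse_duplex | cluster
    size: dict
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def make_rocksalt(cells_per_edge: int, lattice_constant: float = 5.64) -> ParticleSystem:
    """Periodic rock-salt arrangement of alternating ±1 charges.

    One conventional cell holds 8 ions on a simple-cubic grid of spacing
    a/2 with charge (−1)^(i+j+k); the box edge is
    ``cells_per_edge × lattice_constant``.
    """
    if cells_per_edge < 1:
        raise ValueError("cells_per_edge must be >= 1")
    m = 2 * cells_per_edge
    h = lattice_constant / 2.0
    idx = np.arange(m)
    ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
    pos = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * h
    parity = (ii + jj + kk).reshape(-1) % 2
    charges = np.where(parity == 0, 1.0, -1.0)
    box = np.full(3, cells_per_edge * lattice_constant)
    names = ["Na" if q > 0 else "Cl" for q in charges]
    return ParticleSystem(
        positions=pos,
        charges=charges,
        box=box,
        group_labels={
            "cation": np.flatnonzero(charges > 0),
            "anion": np.flatnonzero(charges < 0),
        },
        masses=np.where(charges > 0, 22.99, 35.45),
        names=names,
    )


def _place_points(
    rng: np.random.Generator,
    n: int,
    box: np.ndarray,
    min_sep: float,
    fixed: Optional[np.ndarray] = None,
    fixed_sep: Optional[float] = None,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Uniform rejection sampling of points with hard minimum separations."""
    placed = []
    fixed_sep = min_sep if fixed_sep is None else fixed_sep
    for _ in range(n):
        for attempt in range(max_attempts):
            p = rng.uniform(0.0, box, size=3)
            ok = True
            if fixed is not None and fixed.size:
                d = fixed - p
                d -= np.round(d / box) * box
                if np.min(np.linalg.norm(d, axis=1)) < fixed_sep:
                    ok = False
            if ok and placed:
                d = np.asarray(placed) - p
                d -= np.round(d / box) * box
                if np.min(np.linalg.norm(d, axis=1)) < min_sep:
                    ok = False
            if ok:
                placed.append(p)
                break
        else:
            raise RuntimeError(
                f"could not place point {len(placed) + 1}/{n} after {max_attempts} attempts"
            )
    return np.asarray(placed).reshape(n, 3)


def make_electrolyte(
    n_pairs: int,
    box: Sequence[float] = (40.0, 40.0, 40.0),
    min_separation: float = 3.0,
    rng_seed: int = 0,
) -> ParticleSystem:
    """Random neutral 1:1 electrolyte: n_pairs each of ±1 point charges."""
    box = np.asarray(box, float)
    rng = np.random.default_rng(rng_seed)
    if n_pairs == 0:
        return ParticleSystem(positions=np.empty((0, 3)), charges=np.empty(0), box=box)
    pos = _place_points(rng, 2 * n_pairs, box, min_separation)
    charges = np.concatenate([np.ones(n_pairs), -np.ones(n_pairs)])
    return ParticleSystem(
        positions=pos,
        charges=charges,
        box=box,
        group_labels={
            "cation": np.arange(n_pairs),
            "anion": np.arange(n_pairs, 2 * n_pairs),
        },
        masses=np.where(charges > 0, 22.99, 35.45),
        names=["Na"] * n_pairs + ["Cl"] * n_pairs,
    )


def _water_sites() -> np.ndarray:
    """Local-frame 3-site geometry: O at origin, H's in the xy plane."""
    half = WATER_ANGLE / 2.0
    h1 = WATER_R_OH * np.array([math.cos(half), math.sin(half), 0.0])
    h2 = WATER_R_OH * np.array([math.cos(half), -math.sin(half), 0.0])
    return np.vstack([[0.0, 0.0, 0.0], h1, h2])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_water_lattice(
    n_per_edge: int, spacing: float = 3.1, rng_seed: int = 0
) -> ParticleSystem:
    """Cubic lattice of randomly oriented rigid-geometry 3-site waters.

    TIP3P-style charges (O −0.834 e, H +0.417 e); each molecule is one
    residue and one molecule; the three intramolecular pairs are excluded.
    """
    if n_per_edge < 1:
        raise ValueError("n_per_edge must be >= 1")
    rng = np.random.default_rng(rng_seed)
    sites = _water_sites()
    positions, exclusions = [], []
    nmol = n_per_edge**3
    centers = (
        np.stack(
            np.meshgrid(*[np.arange(n_per_edge)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        + 0.5
    ) * spacing
    for mol, c in enumerate(centers):
        rot = _random_rotation(rng)
        positions.append(sites @ rot.T + c)
        o, h1, h2 = 3 * mol, 3 * mol + 1, 3 * mol + 2
        exclusions += [(o, h1), (o, h2), (h1, h2)]
    pos = np.vstack(positions)
    charges = np.tile([WATER_Q_O, WATER_Q_H, WATER_Q_H], nmol)
    mol_id = np.repeat(np.arange(nmol), 3)
    bonds = []
    angles = []
    for mol in range(nmol):
        o, h1, h2 = 3 * mol, 3 * mol + 1, 3 * mol + 2
        bonds += [(o, h1, 450.0, WATER_R_OH), (o, h2, 450.0, WATER_R_OH)]
        angles.append((h1, o, h2, 55.0, WATER_ANGLE))
    return ParticleSystem(
        positions=pos,
        charges=charges,
        box=np.full(3, n_per_edge * spacing),
        molecule_id=mol_id,
        residue_id=mol_id.copy(),
        group_labels={
            "water": np.arange(3 * nmol),
            "O": np.arange(0, 3 * nmol, 3),
            "H": np.setdiff1d(np.arange(3 * nmol), np.arange(0, 3 * nmol, 3)),
        },
        exclusions=np.asarray(exclusions, np.int64),
        masses=np.tile([15.999, 1.008, 1.008], nmol),
        names=["O", "H", "H"] * nmol,
        bonded_terms={"bonds": bonds, "angles": angles},
    )


def make_coarse_duplex(
    n_per_strand: int = 11,
    rise: float = 3.4,
    radius: float = 9.0,
    beads_per_turn: float = 10.0,
    counterions: bool = True,
    box: Sequence[float] = (40.0, 40.0, 40.0),
    rng_seed: int = 0,
    bond_k: float = 20.0,
    pair_k: float = 4.0,
    ion_exclusion: float = 2.0,
) -> ParticleSystem:
    """Coarse double-helical polyelectrolyte with neutralizing counterions.

    Two antiparallel helical strands of −1 "phosphate" beads (B-DNA-like
    rise and ~10 beads per turn, strands offset by half a turn), harmonic
    bonds along each strand, cross-strand "base-pair" restraints between
    opposed beads, and +1 counterions placed by uniform rejection sampling
    with a hard exclusion radius around every bead. Each bead and each ion
    is its own residue; each strand is one molecule.
    """
    if n_per_strand < 2:
        raise ValueError("n_per_strand must be >= 2")
    box = np.asarray(box, float)
    rng = np.random.default_rng(rng_seed)
    m = np.arange(n_per_strand)
    twist = 2.0 * math.pi / beads_per_turn
    z = (m - (n_per_strand - 1) / 2.0) * rise
    a = np.stack(
        [radius * np.cos(twist * m), radius * np.sin(twist * m), z], axis=1
    )
    # antiparallel partner strand: same heights, half-turn phase offset,
    # listed 3'->5' so that index order runs opposite to strand A
    b = np.stack(
        [
            radius * np.cos(twist * m + math.pi),
            radius * np.sin(twist * m + math.pi),
            z,
        ],
        axis=1,
    )[::-1]
    beads = np.vstack([a, b]) + box / 2.0
    nb = 2 * n_per_strand

    def _bond(i, j, k_spring):
        return (i, j, k_spring, float(np.linalg.norm(beads[i] - beads[j])))

    bonds = []
    for s, offset in ((0, 0), (1, n_per_strand)):
        for k in range(n_per_strand - 1):
            bonds.append(_bond(offset + k, offset + k + 1, bond_k))
        # next-nearest restraints stand in for stacking stiffness
        for k in range(n_per_strand - 2):
            bonds.append(_bond(offset + k, offset + k + 2, bond_k / 2.0))
    # cross-strand "base-pair" restraints between opposed beads (A_m with
    # B's partner) plus diagonals, a light elastic network holding the
    # native duplex shape the way pairing + stacking do
    for k in range(n_per_strand):
        partner = n_per_strand + (n_per_strand - 1 - k)
        bonds.append(_bond(k, partner, pair_k))
        if k + 1 < n_per_strand:
            bonds.append(_bond(k, partner - 1, pair_k / 2.0))
            bonds.append(_bond(k + 1, partner, pair_k / 2.0))

    charges = [-1.0] * nb
    positions = beads
    names = ["P"] * nb
    groups = {
        "strand_A": np.arange(n_per_strand),
        "strand_B": np.arange(n_per_strand, nb),
        "phosphate": np.arange(nb),
    }
    mol_id = np.repeat([0, 1], n_per_strand)
    if counterions:
        ions = _place_points(
            rng, nb, box, min_sep=ion_exclusion, fixed=beads, fixed_sep=ion_exclusion
        )
        positions = np.vstack([beads, ions])
        charges += [1.0] * nb
        names += ["Na"] * nb
        groups["counterion"] = np.arange(nb, 2 * nb)
        mol_id = np.concatenate([mol_id, np.arange(2, 2 + nb)])
    charges = np.asarray(charges)
    return ParticleSystem(
        positions=positions,
        charges=charges,
        box=box,
        molecule_id=mol_id,
        residue_id=np.arange(len(charges)),
        group_labels=groups,
        masses=np.where(charges < 0, 95.0, 22.99),
        names=names,
        bonded_terms={"bonds": bonds},
    )


def make_cluster(spec: Sequence[Tuple[float, Sequence[float]]]) -> ParticleSystem:
    """Open-boundary (non-periodic) cluster from a (charge, position) list."""
    spec = list(spec)
    if not spec:
        return ParticleSystem(positions=np.empty((0, 3)), charges=np.empty(0))
    charges = np.asarray([q for q, _ in spec], float)
    pos = np.asarray([p for _, p in spec], float)
    return ParticleSystem(positions=pos, charges=charges, box=None)


def make_solvated_duplex(
    n_per_strand: int = 11,
    n_waters: int = 100,
    box: Sequence[float] = (40.0, 40.0, 40.0),
    rng_seed: int = 0,
    **duplex_kwargs,
) -> ParticleSystem:
    """Coarse duplex with counterions plus randomly placed 3-site waters.

    The solvent emulates an explicit-water environment around the charged
    duplex: water molecules are dropped at random positions/orientations
    with a hard-core separation from solute beads, ions and each other.
    """
    box = np.asarray(box, float)
    duplex = make_coarse_duplex(
        n_per_strand=n_per_strand, box=box, rng_seed=rng_seed, **duplex_kwargs
    )
    rng = np.random.default_rng(rng_seed + 1)
    centers = _place_points(
        rng, n_waters, box, min_sep=2.9, fixed=duplex.positions, fixed_sep=2.9
    )
    sites = _water_sites()
    positions, exclusions, bonds, angles = [], [], [], []
    for mol, c in enumerate(centers):
        rot = _random_rotation(rng)
        positions.append(sites @ rot.T + c - sites.mean(axis=0) @ rot.T)
        o, h1, h2 = 3 * mol, 3 * mol + 1, 3 * mol + 2
        exclusions += [(o, h1), (o, h2), (h1, h2)]
        bonds += [(o, h1, 450.0, WATER_R_OH), (o, h2, 450.0, WATER_R_OH)]
        angles.append((h1, o, h2, 55.0, WATER_ANGLE))
    mol_id = np.repeat(np.arange(n_waters), 3)
    water = ParticleSystem(
        positions=np.vstack(positions) if n_waters else np.empty((0, 3)),
        charges=np.tile([WATER_Q_O, WATER_Q_H, WATER_Q_H], n_waters),
        box=box,
        molecule_id=mol_id,
        residue_id=mol_id.copy(),
        group_labels={"water": np.arange(3 * n_waters)},
        exclusions=np.asarray(exclusions, np.int64).reshape(-1, 2),
        masses=np.tile([15.999, 1.008, 1.008], n_waters),
        names=["O", "H", "H"] * n_waters,
        bonded_terms={"bonds": bonds, "angles": angles},
    )
    return merge_systems(duplex, water)
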