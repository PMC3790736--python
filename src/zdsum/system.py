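"""Particle-system data model and composition arithmetic.

A :class:`ParticleSystem` carries everything the energy evaluators need:
positions (Å), partial charges (e), an orthorhombic box (or ``None`` for an
open, non-periodic cluster), the molecule/residue partition used by the
residue-based cutoff and the per-molecule deviation partitions, named atom
groups, and the bonded-exclusion bookkeeping (fully excluded 1–2/1–3 pairs
plus a scaled 1–4 set).

The module also provides the composition arithmetic for nucleic-acid boxes:
counting atoms of a duplex-plus-solvent system from per-residue templates,
counting nucleotides, and the neutralizing-counterion arithmetic for a
polyanion in salt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ParticleSystem",
    "ResidueTemplateTable",
    "load_nucleic_templates",
    "net_charge",
    "dipole_moment",
    "composition_count",
    "nucleotide_count",
    "neutralizing_cation_count",
    "merge_systems",
]


def _as_pair_array(pairs: Iterable[Tuple[int, int]]) -> np.ndarray:
    arr = np.asarray(sorted({(min(i, j), max(i, j)) for i, j in pairs}), dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return arr


@dataclass
class ParticleSystem:
    """Positions, charges, periodicity and structural grouping of a system.

    Parameters
    ----------
    positions
        (n, 3) array, Å.
    charges
        (n,) array, elementary charges.
    box
        Three orthorhombic edge lengths (Å), or ``None`` for an open
        (non-periodic) cluster.
    molecule_id, residue_id
        Integer labels per particle. Residues must nest inside molecules.
    group_labels
        Map from group name (e.g. ``"backbone"``, ``"water"``, ``"Na+"``)
        to particle index arrays.
    exclusions
        Unordered 1–2/1–3 pairs fully excluded from bare Coulomb.
    scaled_pairs
        Unordered 1–4 pairs whose bare Coulomb part is scaled by
        ``scale14``.
    masses
        (n,) array, amu; defaults to unit masses.
    """

    positions: np.ndarray
    charges: np.ndarray
    box: Optional[np.ndarray] = None
    molecule_id: Optional[np.ndarray] = None
    residue_id: Optional[np.ndarray] = None
    group_labels: Dict[str, np.ndarray] = field(default_factory=dict)
    exclusions: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    scaled_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    scale14: float = 1.0 / 1.2
    masses: Optional[np.ndarray] = None
    names: Optional[list] = None
    #: generator-supplied bonded terms: {"bonds": [(i, j, k_b, r0)], "angles":
    #: [(i, j, k, k_theta, theta0_rad)]}; consumed by the MD force field.
    bonded_terms: Dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        n = self.n_particles
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} incompatible with {n} charges"
            )
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.charges))):
            raise ValueError("positions and charges must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).ravel()
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three strictly positive edge lengths")
        if self.molecule_id is None:
            self.molecule_id = np.arange(n, dtype=np.int64)
        else:
            self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64).ravel()
        if self.residue_id is None:
            self.residue_id = np.arange(n, dtype=np.int64)
        else:
            self.residue_id = np.asarray(self.residue_id, dtype=np.int64).ravel()
        if self.molecule_id.shape != (n,) or self.residue_id.shape != (n,):
            raise ValueError("molecule_id/residue_id must have one entry per particle")
        # residues nest inside molecules: one molecule per residue id
        if n:
            res_to_mol: Dict[int, int] = {}
            for rid, mid in zip(self.residue_id, self.molecule_id):
                prev = res_to_mol.setdefault(int(rid), int(mid))
                if prev != int(mid):
                    raise ValueError(
                        f"residue {rid} spans molecules {prev} and {mid}; "
                        "residues must nest inside molecules"
                    )
        self.group_labels = {
            k: np.asarray(v, dtype=np.int64).ravel() for k, v in self.group_labels.items()
        }
        self.exclusions = _as_pair_array(map(tuple, np.atleast_2d(np.asarray(self.exclusions, np.int64)).reshape(-1, 2)))
        self.scaled_pairs = _as_pair_array(map(tuple, np.atleast_2d(np.asarray(self.scaled_pairs, np.int64)).reshape(-1, 2)))
        for pairs, what in ((self.exclusions, "exclusions"), (self.scaled_pairs, "scaled_pairs")):
            if pairs.size and (np.any(pairs[:, 0] == pairs[:, 1])):
                raise ValueError(f"{what} contain a self-pair")
            if pairs.size and (pairs.min() < 0 or pairs.max() >= n):
                raise ValueError(f"{what} reference out-of-range particle indices")
        if self.masses is None:
            self.masses = np.ones(n)
        else:
            self.masses = np.asarray(self.masses, dtype=float).ravel()
            if self.masses.shape != (n,) or np.any(self.masses <= 0):
                raise ValueError("masses must be positive, one per particle")

    # ------------------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return self.charges.shape[0]

    @property
    def periodic(self) -> bool:
        return self.box is not None

    def with_positions(self, positions: np.ndarray) -> "ParticleSystem":
        """Shallow topology copy with replaced coordinates (same shape)."""
        positions = np.asarray(positions, float)
        if positions.shape != self.positions.shape:
            raise ValueError("replacement positions must match shape")
        out = ParticleSystem.__new__(ParticleSystem)
        out.__dict__ = dict(self.__dict__)
        out.positions = positions.copy()
        return out

    def net_charge(self) -> float:
        return net_charge(self)

    def dipole_moment(self, subset: Optional[np.ndarray] = None) -> np.ndarray:
        if subset is None:
            subset = np.arange(self.n_particles)
        return dipole_moment(self, subset)


def net_charge(system: ParticleSystem) -> float:
    """Total charge Σ q_i (e)."""
    return float(np.sum(system.charges))


def dipole_moment(system: ParticleSystem, subset: Sequence[int]) -> np.ndarray:
    """Dipole moment Σ q_i r_i (e·Å) of a particle subset.

    Origin-dependent when the subset carries net charge; the caller owns
    the choice of origin in that case.
    """
    idx = np.asarray(subset, dtype=np.int64).ravel()
    if idx.size == 0:
        raise ValueError("dipole_moment of an empty subset is undefined")
    return np.asarray(
        np.sum(system.charges[idx, None] * system.positions[idx], axis=0)
    )


# ----------------------------------------------------------------------
# Composition arithmetic


@dataclass(frozen=True)
class ResidueTemplateTable:
    """Per-residue atom counts and formal charges for composition accounting.

    ``atoms``/``formal_charge`` map residue names (``DA``, ``DC``, ``DG``,
    ``DT``, ``HOH``, ``NA``, ``CL``) to atom counts (hydrogens included) and
    integer formal charges. 5′-terminal nucleotides lack the phosphate group
    (``five_prime_atom_delta`` atoms, ``five_prime_charge_delta`` charge);
    3′-terminal nucleotides gain the 3′ hydroxyl proton.
    """

    atoms: Mapping[str, int]
    formal_charge: Mapping[str, int]
    five_prime_atom_delta: int = -2
    five_prime_charge_delta: int = 1
    three_prime_atom_delta: int = 1
    three_prime_charge_delta: int = 0

    def __post_init__(self):
        for name, count in self.atoms.items():
            if int(count) <= 0:
                raise ValueError(f"template {name}: atom count must be positive")


_LETTER_TO_RESIDUE = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


def load_nucleic_templates() -> ResidueTemplateTable:
    """Load the bundled nucleic-acid/solvent residue template table."""
    text = resources.files("zdsum").joinpath("data/residue_templates.json").read_text()
    raw = json.loads(text)
    return ResidueTemplateTable(
        atoms={k: int(v["atoms"]) for k, v in raw["residues"].items()},
        formal_charge={k: int(v["charge"]) for k, v in raw["residues"].items()},
        five_prime_atom_delta=int(raw["terminal"]["five_prime"]["atoms"]),
        five_prime_charge_delta=int(raw["terminal"]["five_prime"]["charge"]),
        three_prime_atom_delta=int(raw["terminal"]["three_prime"]["atoms"]),
        three_prime_charge_delta=int(raw["terminal"]["three_prime"]["charge"]),
    )


def _strand_atoms(strand: str, templates: ResidueTemplateTable) -> int:
    if not strand:
        return 0
    total = 0
    for letter in strand:
        try:
            total += templates.atoms[_LETTER_TO_RESIDUE[letter.upper()]]
        except KeyError as exc:
            raise KeyError(f"unknown nucleotide letter {letter!r}") from exc
    total += templates.five_prime_atom_delta + templates.three_prime_atom_delta
    return total


def strand_formal_charge(strand: str, templates: ResidueTemplateTable) -> int:
    """Formal charge of one strand (each phosphate −1, 5′ terminus lacks one)."""
    if not strand:
        return 0
    q = sum(templates.formal_charge[_LETTER_TO_RESIDUE[c.upper()]] for c in strand)
    return q + templates.five_prime_charge_delta + templates.three_prime_charge_delta


def composition_count(
    strands: Sequence[str],
    n_waters: int,
    n_cations: int,
    n_anions: int,
    templates: Optional[ResidueTemplateTable] = None,
) -> int:
    """Total atom count of a DNA-plus-solvent box.

    Sums per-residue template atoms over every strand (with 5′/3′ terminal
    adjustments applied per strand), plus 3 atoms per water and 1 per
    monatomic ion.
    """
    if min(n_waters, n_cations, n_anions) < 0:
        raise ValueError("counts must be non-negative")
    if templates is None:
        templates = load_nucleic_templates()
    dna = sum(_strand_atoms(s, templates) for s in strands)
    return dna + templates.atoms["HOH"] * n_waters + n_cations + n_anions


def nucleotide_count(strands: Sequence[str]) -> int:
    """Total number of nucleotide residues across all strands."""
    for s in strands:
        bad = set(s.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"unknown nucleotide letters {sorted(bad)}")
    return sum(len(s) for s in strands)


def neutralizing_cation_count(dna_formal_charge: int, n_anions: int) -> int:
    """Monovalent cations needed to neutralize a polyanion plus added anions."""
    if dna_formal_charge > 0:
        raise ValueError("expected a polyanion (non-positive formal charge)")
    n = abs(int(dna_formal_charge)) + int(n_anions)
    if n < 0:
        raise ValueError("negative cation count")
    return n


# ----------------------------------------------------------------------


def merge_systems(a: ParticleSystem, b: ParticleSystem) -> ParticleSystem:
    """Concatenate two systems, offsetting molecule/residue ids and indices.

    The box is taken from ``a`` (both must agree when both periodic).
    """
    if a.periodic and b.periodic and not np.allclose(a.box, b.box):
        raise ValueError("cannot merge systems with different boxes")
    off = a.n_particles
    mol_off = int(a.molecule_id.max()) + 1 if a.n_particles else 0
    res_off = int(a.residue_id.max()) + 1 if a.n_particles else 0
    groups = {k: v.copy() for k, v in a.group_labels.items()}
    for k, v in b.group_labels.items():
        groups[k] = np.concatenate([groups.get(k, np.empty(0, np.int64)), v + off])
    pairs = np.vstack([a.exclusions, b.exclusions + off]) if (a.exclusions.size or b.exclusions.size) else np.empty((0, 2), np.int64)
    scaled = np.vstack([a.scaled_pairs, b.scaled_pairs + off]) if (a.scaled_pairs.size or b.scaled_pairs.size) else np.empty((0, 2), np.int64)
    bonded: Dict[str, list] = {}
    for key in set(a.bonded_terms) | set(b.bonded_terms):
        terms = list(a.bonded_terms.get(key, []))
        for term in b.bonded_terms.get(key, []):
            n_idx = len(term) - 2  # trailing entries are force constant + equilibrium
            terms.append(tuple(int(t) + off for t in term[:n_idx]) + tuple(term[n_idx:]))
        bonded[key] = terms
    return ParticleSystem(
        positions=np.vstack([a.positions, b.positions]),
        charges=np.concatenate([a.charges, b.charges]),
        box=None if a.box is None else a.box.copy(),
        molecule_id=np.concatenate([a.molecule_id, b.molecule_id + mol_off]),
        residue_id=np.concatenate([a.residue_id, b.residue_id + res_off]),
        group_labels=groups,
        exclusions=pairs,
        scaled_pairs=scaled,
        scale14=a.scale14,
        masses=np.concatenate([a.masses, b.masses]),
        names=(list(a.names or ["X"] * a.n_particles) + list(b.names or ["X"] * b.n_particles)),
        bonded_terms=bonded,
    )
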