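"""Cutoff-based electrostatic energy/force evaluators.

Implements the zero-dipole (ZD) method and its comparison schemes — the
zero-charge Wolf method, the shifted-force method, and the residue-based
bare-Coulomb truncation (RESA) — with a common report structure:

* total energy E^x (kcal/mol),
* a per-atom decomposition E_i^x with the pair energy e_ij split half to
  atom i and half to atom j, so that Σ_i E_i^x == E^x exactly,
* pair/self/exclusion component subtotals.

Exclusion policy for the smooth kernels (ZD/Wolf/shifted-force): excluded
1–2/1–3 pairs inside the cutoff contribute q_i q_j (u(r) − 1/r) — the bare
Coulomb part is removed while the neutrality-completion terms are retained,
mirroring the reciprocal-space retention under Ewald exclusions. Scaled
1–4 pairs scale only the bare 1/r part. RESA, being a bare-Coulomb
truncation, simply skips excluded pairs and scales 1–4 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .kernels import get_kernel
from .neighbors import minimum_image_displacements, pairs_within
from .system import ParticleSystem
from .units import COULOMB

__all__ = [
    "ElectrostaticsConfig",
    "EnergyReport",
    "zd_energy",
    "wolf_energy",
    "shifted_force_energy",
    "resa_energy",
    "evaluate",
    "forces",
]

_METHODS = ("zd", "wolf", "shifted_force", "resa", "ewald")


@dataclass(frozen=True)
class ElectrostaticsConfig:
    """Method choice and parameters for an electrostatics evaluation.

    ``alpha`` is the erfc damping factor (Å⁻¹, ≥0; 0 means undamped).
    ``cutoff_mode`` is atom-based for the smooth kernels (the RESA method
    forces residue-based). ``ewald_accuracy`` is forwarded to the Ewald
    reference when ``method == "ewald"``.
    """

    method: str = "zd"
    r_c: float = 12.0
    alpha: float = 0.0
    cutoff_mode: str = "atom_based"
    coulomb_constant: float = COULOMB
    ewald_accuracy: float = 1e-8

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {_METHODS}")
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.method == "resa" and self.cutoff_mode != "residue_based":
            object.__setattr__(self, "cutoff_mode", "residue_based")

    def label(self) -> str:
        return f"{self.method}(r_c={self.r_c:g}, alpha={self.alpha:g})"


@dataclass
class EnergyReport:
    """Total electrostatic energy with per-atom decomposition and bookkeeping."""

    total: float
    per_atom: np.ndarray
    components: Dict[str, float] = field(default_factory=dict)
    config: Optional[ElectrostaticsConfig] = None

    def __post_init__(self):
        self.per_atom = np.asarray(self.per_atom, float)
        if self.per_atom.size:
            rel = abs(self.per_atom.sum() - self.total) / max(abs(self.total), 1e-30)
            if rel > 1e-9:
                raise ValueError(
                    f"per-atom decomposition does not sum to total (rel err {rel:.2e})"
                )


def _check_cutoff(system: ParticleSystem, r_c: float) -> None:
    if system.periodic and r_c > min(system.box) / 2 + 1e-9:
        raise ValueError(
            f"r_c={r_c} exceeds half the shortest box edge "
            f"({min(system.box) / 2:.3f} Å): ambiguous minimum images"
        )


def _exclusion_maps(system: ParticleSystem):
    n = system.n_particles
    excl = set(map(tuple, system.exclusions))
    scaled = set(map(tuple, system.scaled_pairs))
    return excl, scaled


def _pairwise_energy(
    system: ParticleSystem, config: ElectrostaticsConfig, want_forces: bool = False
):
    """Shared evaluator for the atom-based smooth kernels."""
    _check_cutoff(system, config.r_c)
    kernel = get_kernel(config.method)
    k_c = config.coulomb_constant
    n = system.n_particles
    per_atom = np.zeros(n)
    force = np.zeros((n, 3)) if want_forces else None
    comp = {"pair_sum": 0.0, "self_term": 0.0, "exclusion_correction": 0.0}

    self_coeff = kernel.self_coefficient(config.alpha, config.r_c)
    self_terms = k_c * self_coeff * system.charges**2
    per_atom += self_terms
    comp["self_term"] = float(self_terms.sum())

    i_idx, j_idx, r = pairs_within(system, config.r_c)
    if i_idx.size:
        qq = system.charges[i_idx] * system.charges[j_idx]
        u = kernel.u(r, config.alpha, config.r_c)
        excl, scaled = _exclusion_maps(system)
        # bare-Coulomb removal factor per pair: 1 for 1-2/1-3, (1-s) for 1-4
        bare_removed = np.zeros(r.shape)
        if excl or scaled:
            keys = list(zip(i_idx.tolist(), j_idx.tolist()))
            for m, key in enumerate(keys):
                if key in excl:
                    bare_removed[m] = 1.0
                elif key in scaled:
                    bare_removed[m] = 1.0 - system.scale14
        e_pair = k_c * qq * (u - bare_removed / r)
        np.add.at(per_atom, i_idx, 0.5 * e_pair)
        np.add.at(per_atom, j_idx, 0.5 * e_pair)
        plain = bare_removed == 0.0
        comp["pair_sum"] = float((k_c * qq * u)[plain].sum())
        comp["exclusion_correction"] = float(e_pair.sum() - comp["pair_sum"])
        if want_forces:
            du = kernel.du(r, config.alpha, config.r_c) + bare_removed / r**2
            disp = system.positions[i_idx] - system.positions[j_idx]
            if system.periodic:
                disp -= np.round(disp / system.box) * system.box
            fmag = -k_c * qq * du / r  # along r_i - r_j
            fvec = fmag[:, None] * disp
            np.add.at(force, i_idx, fvec)
            np.add.at(force, j_idx, -fvec)
    total = float(per_atom.sum())
    report = EnergyReport(total=total, per_atom=per_atom, components=comp, config=config)
    return (report, force) if want_forces else report


def zd_energy(system: ParticleSystem, config: ElectrostaticsConfig) -> EnergyReport:
    """Zero-dipole summation energy (smooth kernel + ZD self term)."""
    if config.method != "zd":
        raise ValueError("config.method must be 'zd'")
    return _pairwise_energy(system, config)


def wolf_energy(system: ParticleSystem, config: ElectrostaticsConfig) -> EnergyReport:
    """Zero-charge (Wolf) energy: potential-shifted erfc kernel."""
    if config.method != "wolf":
        raise ValueError("config.method must be 'wolf'")
    return _pairwise_energy(system, config)


def shifted_force_energy(
    system: ParticleSystem, config: ElectrostaticsConfig
) -> EnergyReport:
    """Shifted-force energy: undamped force-shifted Coulomb kernel."""
    if config.method != "shifted_force":
        raise ValueError("config.method must be 'shifted_force'")
    return _pairwise_energy(system, config)


def _resa_weights(system: ParticleSystem, r_c: float):
    """Residue-visibility pair weights of the residue-based cutoff.

    Returns (dist, w) full matrices: w_ij = ½([res(j) visible from i] +
    [res(i) visible from j]), where a residue is visible from atom i when
    at least one of its atoms lies inside the cutoff sphere of i.
    """
    disp = minimum_image_displacements(system.positions, system.box)
    dist = np.linalg.norm(disp, axis=-1)
    within = dist < r_c
    res_ids, res_inverse = np.unique(system.residue_id, return_inverse=True)
    n_res = res_ids.size
    # visible[i, R]: any atom of residue R within r_c of atom i
    visible = np.zeros((system.n_particles, n_res), dtype=bool)
    for r_index in range(n_res):
        cols = res_inverse == r_index
        visible[:, r_index] = within[:, cols].any(axis=1)
    vis = visible[:, res_inverse].astype(float)  # [i, j] = res(j) seen from i
    w = 0.5 * (vis + vis.T)
    np.fill_diagonal(w, 0.0)
    return dist, w, disp


def resa_energy(system: ParticleSystem, config: ElectrostaticsConfig) -> EnergyReport:
    """Residue-based bare-Coulomb truncation (RESA).

    All interactions with a residue are counted when at least one of its
    atoms lies inside the cutoff sphere centered on the probing atom; the
    asymmetric double sum is halved, so one-sided pairs enter at half
    weight.
    """
    if config.method != "resa":
        raise ValueError("config.method must be 'resa'")
    if system.residue_id is None:
        raise ValueError("resa requires residue assignments")
    _check_cutoff(system, config.r_c)
    report, _ = _resa_eval(system, config, want_forces=False)
    return report


def _resa_eval(system, config, want_forces):
    k_c = config.coulomb_constant
    n = system.n_particles
    dist, w, disp = _resa_weights(system, config.r_c)
    excl, scaled = _exclusion_maps(system)
    scale = np.ones((n, n))
    for i, j in excl:
        scale[i, j] = scale[j, i] = 0.0
    for i, j in scaled:
        scale[i, j] = scale[j, i] = system.scale14
    qq = np.outer(system.charges, system.charges)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = np.where(dist > 0, 1.0 / dist, 0.0)
    e_mat = k_c * qq * w * scale * inv_r  # ordered-pair halves included twice
    per_atom = 0.5 * e_mat.sum(axis=1)
    total = float(per_atom.sum())
    force = None
    if want_forces:
        fmag = k_c * qq * w * scale * inv_r**3  # -d/dr(1/r) => +1/r² along r̂
        np.fill_diagonal(fmag, 0.0)
        force = np.einsum("ij,ijk->ik", fmag, disp)
    report = EnergyReport(
        total=total,
        per_atom=per_atom,
        components={"pair_sum": total, "self_term": 0.0, "exclusion_correction": 0.0},
        config=config,
    )
    return report, force


def evaluate(system: ParticleSystem, config: ElectrostaticsConfig) -> EnergyReport:
    """Dispatch on ``config.method`` (including the Ewald reference)."""
    if config.method == "ewald":
        from .ewald import EwaldParams, ewald_energy

        return ewald_energy(
            system, EwaldParams(target_relative_accuracy=config.ewald_accuracy)
        )
    return {
        "zd": zd_energy,
        "wolf": wolf_energy,
        "shifted_force": shifted_force_energy,
        "resa": resa_energy,
    }[config.method](system, config)


def forces(system: ParticleSystem, config: ElectrostaticsConfig) -> np.ndarray:
    """Analytic forces (kcal/mol/Å) of the configured method."""
    if config.method == "ewald":
        from .ewald import EwaldParams, ewald_forces

        return ewald_forces(
            system, EwaldParams(target_relative_accuracy=config.ewald_accuracy)
        )
    if config.method == "resa":
        _, force = _resa_eval(system, config, want_forces=True)
        return force
    _, force = _pairwise_energy(system, config, want_forces=True)
    return force


def energy_and_forces(system: ParticleSystem, config: ElectrostaticsConfig):
    """(EnergyReport, forces) in one pass — used by the MD engine."""
    if config.method == "ewald":
        from .ewald import EwaldParams, ewald_energy_and_forces

        return ewald_energy_and_forces(
            system, EwaldParams(target_relative_accuracy=config.ewald_accuracy)
        )
    if config.method == "resa":
        return _resa_eval(system, config, want_forces=True)
    return _pairwise_energy(system, config, want_forces=True)
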