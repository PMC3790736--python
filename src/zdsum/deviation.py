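"""Accuracy metrics of cutoff electrostatics against the Ewald reference.

Implements the ensemble-averaged relative energy deviation

    dev = ⟨ |E^x − E^Ewald| / |E^Ewald| ⟩_snapshots   (percent),

its partition into per-group (per-molecule, per-nucleotide, …) mean
contributions |Σ_{i∈g}(E_i^x − E_i^Ewald)| / |E^Ewald|, and a sweep driver
producing a tidy (method, r_c, α, mean, sd) table over snapshot ensembles.

A signed variant is kept alongside the magnitudes so the conservation law —
signed group contributions sum to the signed total deviation, frame by
frame, exactly — is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .electrostatics import ElectrostaticsConfig, evaluate
from .ewald import EwaldParams, ewald_energy
from .system import ParticleSystem

__all__ = ["SnapshotSet", "DeviationReport", "relative_deviation", "partition_deviation", "sweep"]


@dataclass
class SnapshotSet:
    """Coordinate frames sharing one topology."""

    topology: ParticleSystem
    frames: np.ndarray  # (n_frames, n, 3)
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            self.topology.n_particles,
            3,
        ):
            raise ValueError("frames must be (n_frames, n_particles, 3)")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def systems(self):
        for f in self.frames:
            yield self.topology.with_positions(f)


@dataclass
class DeviationReport:
    """Per-frame relative deviations (percent) with summary statistics."""

    per_frame: np.ndarray  # |dev| percent per frame
    signed_per_frame: np.ndarray
    partition: Optional[pd.DataFrame] = None
    signed_partition: Optional[np.ndarray] = None  # (n_groups, n_frames)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_frame))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_frame, ddof=0))


def relative_deviation(
    test_energies: Sequence[float], ref_energies: Sequence[float]
) -> DeviationReport:
    """Average relative deviation of test vs reference totals (percent)."""
    test = np.asarray(test_energies, float)
    ref = np.asarray(ref_energies, float)
    if test.shape != ref.shape or test.ndim != 1 or test.size == 0:
        raise ValueError("need equal-length, non-empty energy lists")
    if np.any(ref == 0):
        raise ValueError("zero reference energy")
    signed = 100.0 * (test - ref) / np.abs(ref)
    return DeviationReport(per_frame=np.abs(signed), signed_per_frame=signed)


def partition_deviation(
    per_atom_test: np.ndarray,
    per_atom_ref: np.ndarray,
    ref_totals: Sequence[float],
    partition: Dict[str, np.ndarray],
) -> DeviationReport:
    """Per-group mean contributions to the energy deviation (percent).

    ``per_atom_test``/``per_atom_ref`` are (n_frames, n_atoms); the
    partition must cover all atoms exactly once.
    """
    test = np.atleast_2d(np.asarray(per_atom_test, float))
    ref = np.atleast_2d(np.asarray(per_atom_ref, float))
    ref_totals = np.asarray(ref_totals, float)
    if test.shape != ref.shape or test.shape[0] != ref_totals.size:
        raise ValueError("shape mismatch between per-atom arrays and totals")
    n_atoms = test.shape[1]
    cover = np.concatenate([np.asarray(ix, np.int64) for ix in partition.values()])
    if len(np.unique(cover)) != cover.size:
        raise ValueError("partition groups overlap")
    if not np.array_equal(np.sort(cover), np.arange(n_atoms)):
        raise ValueError("partition does not cover all atoms")
    if np.any(ref_totals == 0):
        raise ValueError("zero reference energy")

    delta = test - ref  # (frames, atoms)
    denom = np.abs(ref_totals)[:, None]
    signed_total = 100.0 * delta.sum(axis=1) / denom.ravel()
    rows = []
    signed_groups = []
    for name, idx in partition.items():
        g_signed = 100.0 * delta[:, np.asarray(idx, np.int64)].sum(axis=1) / denom.ravel()
        signed_groups.append(g_signed)
        rows.append(
            {
                "group": name,
                "n_atoms": int(len(idx)),
                "mean_abs_pct": float(np.mean(np.abs(g_signed))),
                "sd_pct": float(np.std(np.abs(g_signed), ddof=0)),
                "mean_signed_pct": float(np.mean(g_signed)),
            }
        )
    return DeviationReport(
        per_frame=np.abs(signed_total),
        signed_per_frame=signed_total,
        partition=pd.DataFrame(rows),
        signed_partition=np.asarray(signed_groups),
    )


def sweep(
    configs: Sequence[ElectrostaticsConfig],
    snapshots: SnapshotSet,
    reference: Optional[EwaldParams] = None,
) -> pd.DataFrame:
    """Mean/sd relative deviation for each config over a snapshot ensemble."""
    if not configs:
        raise ValueError("need at least one config")
    reference = reference or EwaldParams()
    ref_totals = [ewald_energy(s, reference).total for s in snapshots.systems()]
    rows = []
    for cfg in configs:
        test_totals = [evaluate(s, cfg).total for s in snapshots.systems()]
        rep = relative_deviation(test_totals, ref_totals)
        rows.append(
            {
                "method": cfg.method,
                "r_c": cfg.r_c,
                "alpha": cfg.alpha,
                "mean_dev_pct": rep.mean,
                "sd_pct": rep.sd,
                "n_frames": len(snapshots),
            }
        )
    return pd.DataFrame(rows)
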