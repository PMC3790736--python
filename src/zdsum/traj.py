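"""Trajectory superposition, rmsd/rmsf, and cross-correlation analysis.

The fluctuation metrics follow the standard residue-level conventions:

* rmsf of group m:  sqrt( (1/N_m) Σ_{i∈m} ⟨ |r_i − ⟨r_i⟩|² ⟩ ), i.e. the
  time variance of each atom about its window-mean position, averaged over
  the group's atoms, then rooted;
* the dynamic cross-correlation matrix (DCCM)
  C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), with Δr_i the displacement
  of group i's representative position from its window mean — positive for
  in-phase, negative for out-of-phase motion.

Δr_i uses the group geometric center per frame by default (the common DCCM
convention for residue-level matrices); a per-atom-averaged alternative is
available via ``mode="atom_mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .system import ParticleSystem

__all__ = [
    "Trajectory",
    "FluctuationResult",
    "superpose",
    "rmsd_trace",
    "rmsf",
    "cross_correlation",
    "method_agreement",
]


@dataclass
class Trajectory:
    """Ordered coordinate frames with times (ps), tied to one topology."""

    frames: np.ndarray  # (n_frames, n, 3)
    times_ps: np.ndarray
    topology: Optional[ParticleSystem] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, float)
        self.times_ps = np.asarray(self.times_ps, float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n, 3)")
        if self.times_ps.shape != (self.frames.shape[0],):
            raise ValueError("one time per frame required")
        if self.times_ps.size > 1 and np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def window(self, start_frac: float = 0.3, end_frac: float = 1.0) -> np.ndarray:
        """Frame indices of a fractional time window (default: final 70%)."""
        lo = self.times_ps[0] + start_frac * (self.times_ps[-1] - self.times_ps[0])
        hi = self.times_ps[0] + end_frac * (self.times_ps[-1] - self.times_ps[0])
        idx = np.flatnonzero((self.times_ps >= lo - 1e-12) & (self.times_ps <= hi + 1e-12))
        if idx.size == 0:
            raise ValueError("empty analysis window")
        return idx


@dataclass
class FluctuationResult:
    """Per-group rmsf and group×group cross-correlation with metadata."""

    rmsf: Dict[str, float] = field(default_factory=dict)
    correlation: Optional[np.ndarray] = None
    group_order: List[str] = field(default_factory=list)
    valid: Optional[np.ndarray] = None  # False where variance vanished
    window_frames: Optional[np.ndarray] = None
    superposition_set: Optional[np.ndarray] = None


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation (no reflection) of mobile onto reference."""
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    h = (mobile - mu_m).T @ (reference - mu_r)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear or coincident) superposition set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    shift = mu_r - rot @ mu_m
    return rot, shift


def superpose(
    frame: np.ndarray, reference: np.ndarray, atom_set: Sequence[int]
) -> Tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``frame`` onto ``reference``.

    The fit uses ``atom_set`` (≥3 non-collinear atoms); the returned frame
    is the whole coordinate set transformed, together with the post-fit
    rmsd over the fitting atoms.
    """
    frame = np.asarray(frame, float)
    reference = np.asarray(reference, float)
    idx = np.asarray(atom_set, np.int64)
    if idx.size < 3:
        raise ValueError("need at least 3 atoms to superpose")
    rot, shift = _kabsch(frame[idx], reference[idx])
    moved = frame @ rot.T + shift
    delta = moved[idx] - reference[idx]
    rmsd = float(np.sqrt(np.mean(np.sum(delta**2, axis=1))))
    return moved, rmsd


def rmsd_trace(
    traj: Trajectory, reference: np.ndarray, atom_set: Sequence[int]
) -> np.ndarray:
    """Per-frame rmsd (Å) over ``atom_set`` after superposition."""
    return np.asarray(
        [superpose(f, reference, atom_set)[1] for f in traj.frames]
    )


def _superposed_frames(
    traj: Trajectory, idx: np.ndarray, superposition_set: Optional[Sequence[int]],
    reference: Optional[np.ndarray],
) -> np.ndarray:
    frames = traj.frames[idx]
    if superposition_set is None:
        return frames
    ref = traj.frames[0] if reference is None else np.asarray(reference, float)
    return np.asarray([superpose(f, ref, superposition_set)[0] for f in frames])


def rmsf(
    traj: Trajectory,
    groups: Dict[str, Sequence[int]],
    window: Tuple[float, float] = (0.3, 1.0),
    superposition_set: Optional[Sequence[int]] = None,
    reference: Optional[np.ndarray] = None,
) -> FluctuationResult:
    """Per-group root-mean-square fluctuation (Å) over a time window.

    Frames are optionally superposed onto ``reference`` (default: first
    frame) over ``superposition_set`` before the fluctuations are taken.
    """
    if not groups:
        raise ValueError("no groups given")
    idx = traj.window(*window)
    frames = _superposed_frames(traj, idx, superposition_set, reference)
    mean_pos = frames.mean(axis=0)
    msd_atom = np.mean(np.sum((frames - mean_pos) ** 2, axis=2), axis=0)  # per atom
    out: Dict[str, float] = {}
    for name, atoms in groups.items():
        atoms = np.asarray(atoms, np.int64)
        if atoms.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = float(np.sqrt(np.mean(msd_atom[atoms])))
    return FluctuationResult(
        rmsf=out,
        group_order=list(groups),
        window_frames=idx,
        superposition_set=None if superposition_set is None else np.asarray(superposition_set),
    )


def cross_correlation(
    traj: Trajectory,
    groups: Dict[str, Sequence[int]],
    window: Tuple[float, float] = (0.3, 1.0),
    superposition_set: Optional[Sequence[int]] = None,
    reference: Optional[np.ndarray] = None,
    mode: str = "center",
) -> FluctuationResult:
    """Dynamic cross-correlation matrix between group displacements.

    ``mode="center"`` correlates group geometric centers; ``"atom_mean"``
    averages the per-atom displacement vectors instead. Zero-variance
    groups are flagged in ``valid`` and their entries set to NaN rather
    than propagated.
    """
    if mode not in ("center", "atom_mean"):
        raise ValueError("mode must be 'center' or 'atom_mean'")
    idx = traj.window(*window)
    if idx.size < 2:
        raise ValueError("need at least 2 frames for correlations")
    frames = _superposed_frames(traj, idx, superposition_set, reference)
    names = list(groups)
    reps = []
    atom_var = []
    for name in names:
        atoms = np.asarray(groups[name], np.int64)
        if atoms.size == 0:
            raise ValueError(f"group {name!r} is empty")
        sub = frames[:, atoms, :]
        reps.append(sub.mean(axis=1))  # group geometric center per frame
        d_atoms = sub - sub.mean(axis=0)
        atom_var.append(float(np.mean(np.sum(d_atoms**2, axis=2))))
    reps = np.stack(reps, axis=1)  # (frames, groups, 3)
    delta = reps - reps.mean(axis=0)
    cov = np.einsum("fgd,fhd->gh", delta, delta) / delta.shape[0]
    # center mode normalizes by the center variance; atom_mean by the mean
    # per-atom variance (the covariance of averaged displacements is the
    # center covariance in both conventions)
    var = np.diag(cov).copy() if mode == "center" else np.asarray(atom_var)
    valid = var > 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(var, var))
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan
    np.fill_diagonal(corr, np.where(valid, 1.0, np.nan))
    result = rmsf(traj, groups, window, superposition_set, reference)
    result.correlation = corr
    result.group_order = names
    result.valid = valid
    return result


def method_agreement(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Pearson correlation between two equal-length fluctuation profiles."""
    a = np.asarray(profile_a, float).ravel()
    b = np.asarray(profile_b, float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("profiles must be equal-length with >= 3 entries")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance profile")
    return float(stats.pearsonr(a, b).statistic)
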