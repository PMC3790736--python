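# Methods

## The problem

Long-range electrostatics dominates the energetics of charged biomolecular
systems. Double-stranded DNA is the hard case: a polyanion with one
phosphate per non-terminal nucleotide, stabilized in solution by counterion
condensation and dielectric screening. A bare truncation of the Coulomb sum
at a cutoff r_c injects large artificial forces at the cutoff sphere and is
known to deform duplex DNA within picoseconds, while lattice-sum (Ewald)
methods are accurate but impose artificial periodicity and a reciprocal-space
cost. Cutoff-based "non-Ewald" schemes repair truncation by building charge
(and dipole) neutrality into the interaction sphere of every atom.

This package implements the zero-dipole summation (ZD) scheme together with
everything needed to evaluate it the way such methods are evaluated in the
literature: a plain-Ewald reference, the competing cutoff schemes, energy
deviation statistics with per-molecule/per-residue partitions, a small MD
engine, and rmsd/rmsf/cross-correlation trajectory analysis — all exercised
on synthetic charged systems, including a coarse DNA-like duplex with
neutralizing counterions.

## Electrostatic models

All evaluators share one contract: total energy in kcal/mol (Coulomb
constant 332.06371 kcal·Å/(mol·e²), the AMBER convention), a per-atom
decomposition E_i with each pair energy split half/half so Σᵢ E_i equals
the total exactly, and component bookkeeping (pair, self, exclusion terms).

**Zero-dipole (ZD).** The damped kernel erfc(αr)/r is completed with a
quadratic and a constant term,

    u(r) = erfc(αr)/r + A r² + B,
    A = [erfc(αr_c)/r_c³ + (2α/√π)e^(−α²r_c²)/r_c²]/2,
    B = −erfc(αr_c)/r_c − A r_c²,

which is the unique quadratic completion with u(r_c) = 0 and u′(r_c) = 0
(smooth truncation: both the potential and the force vanish at the cutoff).
The self-energy coefficient is B/2 − α/√π per unit Σq². Two exact
consequences are used as tests: for a neutral charge set with zero dipole
moment lying entirely inside r_c, the α = 0 scheme reproduces the direct
Coulomb sum to machine precision; for a neutral set with dipole moment D the
residual is exactly −k_C·A·|D|², i.e. −k_C|D|²/(2r_c³) at α = 0. At α = 0
the kernel reduces to 1/r + r²/(2r_c³) − 3/(2r_c).

**Zero-charge (Wolf).** Constant completion only: erfc(αr)/r − erfc(αr_c)/r_c
with self coefficient −erfc(αr_c)/(2r_c) − α/√π. The potential vanishes at
r_c but the force does not.

**Shifted force.** The undamped force-shifted Coulomb kernel
1/r − 1/r_c + (r − r_c)/r_c²; both value and derivative vanish at r_c. The
self term uses the damped-shifted-force convention −1/(2r_c) per unit Σq²
(not exercised by any oracle here; documented as a convention choice).

**RESA (residue-based bare truncation).** The straight Coulomb sum over a
residue-based neighborhood: all interactions of atom i with residue R are
counted if at least one atom of R lies inside the cutoff sphere of i. The
asymmetric double sum is halved, so a pair seen from only one side enters
at half weight. Its forces are discontinuous whenever a residue crosses a
cutoff sphere — this non-smoothness is inherent to the method and is
precisely what the stability comparison probes.

**Bonded exclusions.** For the smooth kernels, an excluded 1–2/1–3 pair
inside r_c contributes q_iq_j(u(r) − 1/r): the bare Coulomb part is removed
but the neutrality-completion terms are retained, mirroring how
reciprocal-space contributions of excluded pairs survive under Ewald.
Scaled 1–4 pairs scale the bare part only. RESA, having no completion,
simply omits excluded pairs.

**Ewald reference.** Plain Ewald with conducting (tinfoil) boundaries:
real-space erfc sum over periodic images within a real-space cutoff,
half-space reciprocal sum, −α/√π Σq² self term, and erf-kernel exclusion
corrections. Auto-tuning from a target relative accuracy ε sets
α = √(−ln ε)/r_cut and the per-axis reciprocal bound k_max =
⌈αL√(−ln ε)/π⌉; r_cut defaults to half the shortest box edge. The per-atom
reciprocal attribution goes through each particle's structure-factor
contribution q_i Re[e^{ik·r_i}S(k)*], which sums to |S(k)|² identically.
The Ewald sum qualifies itself as the reference by invariance: energies at
different splitting parameters agree to ≤1e−6 and k_max doubling changes a
converged energy by ≤1e−8 (both asserted on a rock-salt lattice, whose
Madelung constant is reproduced to 1e−7). No PME/mesh is provided — plain
Ewald is adequate at the ≤10⁴-particle scale used here.

## Deviation metrics

The accuracy of a cutoff method x is the ensemble average over snapshots of
|E^x − E^Ewald|/|E^Ewald| (reported in percent, with the standard deviation
across snapshots as the error bar). Per-group contributions are
|Σ_{i∈g}(E_i^x − E_i^Ewald)|/|E^Ewald| per frame, averaged; a signed variant
is kept so that the signed group contributions sum to the signed total
deviation exactly, frame by frame — the conservation property inherited
from the per-atom halving convention. The magnitude-then-average order was
chosen to match one-sided error bars; the signed bookkeeping preserves the
alternative reading.

## Synthetic systems

No external data is used; seeded generators supply every test class
(identical spec + seed ⇒ bit-identical system):

* **rock-salt lattice** — alternating ±1 charges, the Madelung oracle;
* **random electrolyte** — ±1 pairs placed uniformly with a hard minimum
  separation (rejection sampling);
* **water-like lattice** — rigid-geometry 3-site molecules with TIP3P-style
  charges (O −0.834 e, H +0.417 e, r_OH 0.9572 Å, 104.52°) at random
  orientations, flexible harmonic bonds/angle for dynamics, intramolecular
  pairs excluded;
* **coarse duplex** — two antiparallel helical strands of −1 "phosphate"
  beads (B-DNA-like rise 3.4 Å, 10 beads/turn, radius 9 Å, strands offset
  by half a turn), +1 counterions placed with a 2 Å exclusion radius.
  The bonded model is a light elastic network: nearest- and
  next-nearest-neighbor springs along each strand (stacking stiffness),
  cross-strand springs to the opposed bead and its diagonal neighbors
  (pairing), all at the generated native distances. Beads are heavy
  (95 amu, phosphate-like), ions sodium-like.
* **solvated duplex** — the coarse duplex plus randomly placed 3-site
  waters at a hard-core separation, emulating an explicit-solvent
  environment at desk scale.

What the toys do *not* emulate: dielectric screening at water density
(solvation shells are sparse), atomistic DNA chemistry (base pairing is a
spring, not hydrogen bonds), and sizes beyond ~10³ particles. Passing the
trend tests therefore demonstrates the *ordering* of method errors under
controlled conditions; the published benchmark percentages belong to a
27,958-atom solvated system over nanosecond trajectories and are not
reproducible from printed information at desk scale.

## MD engine

Velocity-Verlet integration; Maxwell–Boltzmann initial velocities at the
target temperature (seeded, center-of-mass motion removed); Berendsen
velocity rescaling (λ clamped to [0.5, 1.5]) for NVT; no barostat, no
constraints (stiff harmonic bonds stand in). Positions are never wrapped —
periodicity enters only through minimum-image forces — so trajectories are
analysis-ready without unwrapping. Units: Å, fs, kcal/mol, amu; the
force-to-acceleration conversion is 1 kcal/(mol·Å·amu) =
4.184×10⁻⁴ Å/fs². Lennard-Jones terms (energy-shifted at the cutoff,
Lorentz–Berthelot combination, name-keyed defaults) keep opposite charges
from collapsing.

Energy conservation is itself a method property: NVE with the smooth ZD
kernel drifts ≤1e−4 (relative) over 10⁴ steps at 0.5 fs on the electrolyte,
while RESA's membership discontinuities pump energy continuously.

## The stability comparison protocol

Mirroring the equilibrate-with-the-reference-then-produce design used for
the real DNA system:

1. the seeded duplex is relaxed by 32 ps of Ewald-force NVT dynamics
   (2 fs steps, τ = 200 fs, 300 K);
2. the rmsd reference is the ensemble-mean structure of the equilibration's
   second half (frames superposed on the final one) — the relaxed duplex is
   longer than the built helix because bead–bead self-repulsion stretches
   it, so the built geometry is *not* the equilibrium structure and would
   measure relaxation rather than method fidelity;
3. production runs (32 ps NVT) start from the same relaxed state with the
   same velocity seeds for every method; three seeds each;
4. final-window (last ~30%) mean backbone rmsd against the reference is the
   deformation measure; per-bead rmsf profiles (superposed on the bead set,
   final 70% window) averaged over seeds give the fluctuation comparison.

The deformation contrast is probed at r_c = 8 Å — the same cutoff-to-box
ratio (~0.2) as the published deformation run (18 Å in an ~85 Å cell) —
where residue-based truncation loses the long-range self-repulsion that
holds the polyelectrolyte extended (the electrostatic-stiffening effect)
and its force noise heats local modes; the smooth-kernel run tracks the
Ewald-force run. Reference-level agreement (rmsd within 2×, rmsf Pearson)
is evaluated at the production cutoff 12 Å.

## Numerical choices

* Minimum image everywhere; evaluators reject r_c > min(box)/2 for
  periodic systems (open clusters allow any r_c).
* Pair enumeration: an O(n²) distance matrix is the default at desk scale;
  a cell-list search with an identical-pair-set contract (tested) engages
  for periodic systems above ~2000 particles.
* Per-atom decompositions use strict half/half splitting for every pairwise
  term, making all partition sums exact rather than approximate.
* The deviation of Eq.-style metrics requires nonzero reference energies;
  zero-variance groups in cross-correlation matrices are flagged invalid
  (NaN entries) rather than propagated.
* Cross-correlation Δr_i defaults to the group geometric-center
  displacement (the usual residue-level DCCM convention); a per-atom-
  normalized variant is available (`mode="atom_mean"`).
* The analysis window defaults to the final 70% of a trajectory.
* Snapshot ensembles for deviation statistics are generated by Ewald-force
  NVT dynamics sampled every 100 steps (0.2 ps) after an equilibration
  stretch — decorrelated, physically plausible configurations, 50 frames by
  default.

## Problem sizes

All tests and the acceptance script run on: 64-ion rock-salt cells,
25–200-pair electrolytes, the 44-particle coarse duplex, and a 344-particle
solvated duplex (100 waters) in a 40 Å box with 50 snapshots. These sizes
give stable orderings of method errors while keeping every experiment a
desk-scale computation.

## Known limitations

* Plain Ewald is O(N²)–O(N^1.5); it is a reference oracle, not a
  production engine.
* The Berendsen thermostat does not sample the canonical ensemble; it is
  used for relaxation and temperature control of demonstrations only.
* The shifted-force self-energy constant is a convention; total energies of
  that method carry it, pair forces do not.
* The 1–4 exclusion treatment of the ZD family (scale the bare part,
  retain the completion) is one defensible reading of how bonded
  modifications should interact with neutrality completion; alternatives
  exist and would shift total energies of bonded systems slightly.
* RESA deformation at toy scale is a small-margin effect: the coarse
  duplex lacks the dense solvent whose truncation artifacts destroy real
  DNA, so the contrast rests on electrostatic stiffening and force noise
  rather than on solvation-shell artifacts.
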