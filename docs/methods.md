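# Methods

`mdpost` re-implements, as a tested library, the post-simulation analysis
battery commonly applied to molecular-dynamics studies of small GTPase
systems (Ras and its regulator/effector complexes): conformational
statistics, two-variable free-energy landscapes with basin clustering,
end-point MM/PBSA binding energetics, and correlation-based allosteric
network analysis. Because microsecond explicit-solvent MD is not
reproducible at desk scale, every stage is validated against synthetic
inputs whose statistical structure is known exactly.

## Trajectory model and geometric primitives

Coordinates are Cartesian Å, frames 0-based, residues 1-based (PDB
convention). All distance and persistence thresholds are inclusive (≤ / ≥),
which makes boundary cases such as a 75.0% contact fraction or a 4.50 Å
separation well defined.

**Superposition.** Least-squares rigid fit by the Kabsch SVD construction,
constrained to a proper rotation (det = +1). The default reference is the
first frame, matching the common practice of aligning to the initial
(crystal) structure; RMSD is reported over the fitted selection after the
fit. A selection with fewer than 3 atoms or collinear geometry is rejected
— the rotation would not be unique.

**RMSF.** Per-atom root-mean-square fluctuation about the time-mean
position, computed on an already-aligned trajectory. Since no single
convention exists for the RMSF reference, the pipeline aligns iteratively
to the running mean structure (two passes, `align_to_mean`), which is the
fixed point of the mean-structure definition for well-behaved data.

**SASA.** Shrake–Rupley with a deterministic golden-spiral quadrature
(default 960 points, probe 1.4 Å) — no RNG, so results are bit-reproducible.
An isolated atom is exact by construction; the quadrature error for
occluded atoms at 960 points is below 1% on the two-sphere benchmark with
a closed-form cap area. Because the point directions are fixed in space,
SASA is exactly translation-invariant but only approximately
rotation-invariant (discretisation-level differences, tested at 0.01
kcal/mol through the nonpolar term).

**Contact persistence.** The fraction of frames in which a residue pair's
minimum heavy-atom distance is ≤ the cutoff. Salt-bridge mode restricts the
atoms to the charged side-chain groups (Asp/Glu carboxylate O, Lys NZ, Arg
guanidinium N, His ring N, phosphotyrosine phosphate O) with a 4.0 Å
default cutoff; the criterion is a package choice since no single
literature definition exists.

**t-test.** Welch's unequal-variance statistic with Welch–Satterthwaite
degrees of freedom. Frames are treated as independent observations, as is
conventional in MD analyses; serially correlated data overstate
significance, so p-values on raw frame series should be read as
descriptive, not inferential.

## Free-energy landscapes and clustering

The 2D potential of mean force over collective variables (d1, d2) is

    G(b) = -k_B T ln(n_b / n_max),   k_B = 0.0019872 kcal/(mol K), T = 300 K,

referenced to the most occupied bin; empty bins are undefined (NaN), never
zero. The default grid is 50×50 bins over the observed range padded 5%.
Basins are 4-connected components of bins with G ≤ a depth cutoff (default
1.0 kcal/mol), labelled by ascending minimum G; the cutoff is explicit
config because basin boundaries are an analysis choice, not a property of
the data.

Conformational clustering is agglomerative average linkage on the pairwise
RMSD matrix of frames previously superposed on a common reference (no
per-pair refit), cut at a requested cluster count. Representatives are
medoids — the frame minimising summed RMSD to its cluster mates — with ties
broken toward the lowest frame index for determinism. The merge order is
tested against a brute-force reference implementation on small frame sets.

## MM/PBSA energetics

Single-trajectory protocol: receptor and ligand conformations are cut from
the complex frames, so the internal (bond/angle/torsion) difference is
identically zero and

    dG_binding = dE_vdW + dE_ele + dE_PB + dE_nonpolar   (−T dS omitted).

* Electrostatics: Coulomb sum with k_c = 332.0636 kcal·Å/(mol·e²), no
  distance cutoff (cutoffs are an MD-engine concern, not an analysis one).
* van der Waals: 12-6 Lennard-Jones, Lorentz–Berthelot combining.
* Nonpolar solvation: γ·SASA + b with γ = 0.00542 kcal/(mol·Å²) and
  b = 0.92 kcal/mol. Note that the constant b enters once per subsystem,
  leaving an irreducible −b offset in the binding difference even for a
  fully separated pair; this is a property of the model, not a defect.
* Polar solvation: finite-difference Poisson(-Boltzmann) solver below.

Per-residue decomposition attributes each receptor–ligand MM pair term half
to each atom's owning residue; the polar term as ½·q_i·Δφ_RF(x_i) between
the complex and the isolated subsystem; and the nonpolar term through
per-atom SASA differences, with the ownerless −b offset spread uniformly
over residues so that residue sums reproduce the totals exactly (verified
to 1e−6 kcal/mol).

### The PB solver

The linearized Poisson equation (optionally Debye-screened, off by default)
is discretized on a regular grid with a 7-point stencil: ε_in = 1 inside
the union of atom spheres at their PB radii, ε_out = 80 outside, no Stern
layer, no reentrant molecular surface — deliberate simplifications relative
to production PB codes, chosen because they are exactly testable against
the Born ion. Face dielectrics use the fractional edge coverage of the
sphere union (per-atom maximum, exact for a single sphere) combined
harmonically; charges are spread trilinearly; boundary values are
Debye–Hückel monopoles. The solvation energy is

    dE_PB = ½ Σ q_i [φ_solv(x_i) − φ_ref(x_i)],

with the reference solve on the identical grid at uniform ε_in, so the grid
self-energy of the spread charges cancels exactly. The solver is
diagonal-preconditioned conjugate gradient (rtol 1e−8, cap 20,000
iterations; non-convergence raises with the residual). On the Born ion
(q = 1 e, R = 2 Å) the error decreases monotonically through spacings
1.0 / 0.5 / 0.25 Å: 3.0% → 0.6% → 0.1% against −81.98 kcal/mol.

The grid is anchored to the solute bounding box (default spacing 0.5 Å,
padding 8 Å), so whole-complex translations reproduce energies exactly;
arbitrary rotations move the dielectric boundary relative to the grid axes
and reproduce only to the discretisation level. Energetics defaults to
every 10th frame.

## Correlation network analysis

**DCCM.** C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩) over node atoms of a
superposed trajectory; an immobile atom has no defined correlation and is
reported by name. The display mask hides |C| < 0.3 (strict, so 0.3 itself
survives).

**Network.** Nodes are residues (Cα); an edge joins non-sequence-adjacent
residues whose minimum heavy-atom distance stays ≤ 4.5 Å in ≥ 75% of
frames — residue-level minimum distance is used because Cα–Cα pairs almost
never approach 4.5 Å. Edge weight is d_ij = −ln|C_ij| (natural log; the
magnitude is floored at 1e−6). The absolute value keeps anti-correlated
pairs informative, since a literal −log of a negative correlation would be
undefined. Optimal paths are invariant to the log base; the suboptimal
tolerance is not, so the natural-log convention is pinned.

**Communities.** Girvan–Newman divisive clustering with edge betweenness
computed on d_ij as lengths and ties broken lexicographically; among the
divisive sequence of partitions the one maximising weighted modularity is
returned. Modularity needs an affinity rather than a distance, and
exp(−d_ij) = |C_ij| is the natural inverse of the weight convention, so
|C_ij| is the modularity weight. Intercommunity connectivity is the summed
betweenness of edges joining each community pair.

**Paths.** All-pairs shortest distances by Floyd–Warshall; suboptimal
simple paths within a tolerance δ (default 20 weight units — the tolerance
is dimensionless in the −ln|C| metric) are enumerated by depth-first search
pruned with the exact distance-to-sink bound, which makes the enumeration
provably complete; it is tested against exhaustive simple-path enumeration
on random graphs.

## Synthetic data: what it emulates, and what it does not

* *Correlated Gaussian trajectories*: zero-mean displacements about a
  reference with a prescribed atom–atom covariance applied identically to
  x/y/z, drawn through a symmetric eigenfactorisation. Ground truth is the
  normalised covariance; sample DCCMs converge at the 3/√n rate.
* *Multi-basin CV series*: Gaussian mixtures with prescribed occupancies
  and recorded per-frame membership.
* *Contact schedules*: a pair sits at the contact distance in exactly
  round-half-up(fraction·n) frames — integer counts, zero sampling error —
  enabling boundary tests of the 75%/4.5 Å rule. Each residue may appear
  in only one scheduled pair; shared residues raise an infeasibility error.
* *Toy complexes*: protein-like parameter magnitudes (|q| ≤ 1 e, σ ≈ 3.4 Å,
  ε ≈ 0.1 kcal/mol, PB radius 1.9 Å) keep LJ/PB numerics well conditioned.

These generators reproduce the *statistical* structure the analyses assume
— Gaussian fluctuations, exact contact fractions, mixture occupancies —
and none of the physics of real proteins: no solvent, no force-field
realism, no conformational kinetics, no periodic boundary effects. Passing
tests therefore demonstrate that the estimators and thresholds behave
correctly on data satisfying their own assumptions, not that any particular
biological conclusion is reproduced.

## Numerical choices and degenerate inputs

* Thresholds inclusive throughout; half-up rounding for scheduled contact
  counts; medoid and Girvan–Newman ties broken deterministically.
* Angles at coincident points are flagged NaN per frame, never dropped
  silently.
* Single-frame RMSF, zero-variance correlations, both-constant t-test
  samples, non-PSD covariances, overlapping atoms in pair energies, and
  sources/sinks in different components all raise typed errors.
* One global pipeline seed fans out to per-stage seeds by fixed offsets, so
  toggling one stage never changes another stage's randomness.

## Problem sizes

The default validation battery uses 1,000-frame contact schedules,
50,000-frame Gaussian fixtures for correlation recovery, 100,000-sample
mixtures for occupancy checks, toy complexes of ≤ 10 atoms for energetics,
and Born-ion grids down to 0.25 Å spacing — sizes at which every oracle is
exact or has a computable sampling bound, and the whole suite runs in well
under a minute on one core.

## Known limitations

* The PB dielectric boundary is the union of atom spheres; production
  MM/PBSA codes use molecular (reentrant) surfaces and typically ε_in = 1–4
  with ion screening. Absolute binding energies from real systems will not
  match production pipelines; differences and trends on fixed geometry are
  meaningful.
* Entropy (−TΔS) is not estimated at all.
* No periodic-boundary imaging: inputs must be whole, unwrapped molecules.
* Frame autocorrelation is ignored by the t-test and by std estimates.
* DCCM on short trajectories mixes convergence error with true correlation;
  the 3/√n bound applies to the Gaussian fixtures, not to arbitrary data.
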