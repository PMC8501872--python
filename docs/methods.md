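# Methods

`pathsage` reimplements, at desk scale, the computational machinery used to
map a large conformational transition of a membrane protein: optimize a
transition pathway with the mean-force string method, measure the free
energy along it with umbrella sampling, and characterize the structures
along the way (substates, rigid domains, domain rotations, contacts, lipid
and ion observables).  The all-atom molecular dynamics engine of such
studies is replaced by an overdamped Langevin sampler on analytic
collective-variable (CV) landscapes, and real trajectories are replaced by
synthetic structures with planted ground truth, so that every stage of the
pipeline can be validated against known answers.

## Toy sampling backend

**Model.** A `CVSystem` is an energy surface V(z) (units of kT) with an
analytic gradient over a low-dimensional CV space.  Sampling uses the
Euler–Maruyama discretization of overdamped Langevin dynamics,

    z ← z − (Δt/γ) ∇[V + U](z) + √(2 kT Δt / γ) ξ,

with harmonic restraints U(z) = (κ/2)|z − c|² whose center may move
linearly in time (targeted-dynamics driving).  Reduced units: kT = 1,
γ = 1 by default.

**Parameters that matter.**

- `dt` — must satisfy (λ_max + κ)·Δt ≲ 1 for non-oscillatory integration,
  where λ_max is the largest Hessian eigenvalue (≈ 4×10³ along the
  Mueller–Brown transition path, hence the 10⁻⁴–10⁻⁵ defaults there).
- `kappa` — restrained sampling estimates the mean force as κ(z − ⟨θ⟩).
  This equals the gradient of the *Moreau-envelope-smoothed* landscape: the
  systematic error relative to ∇V scales as H·|∇V|/κ locally and the
  integrated profile error as |∇V|²/2κ.  Mean-force restraints must
  therefore be stiff relative to both the local curvature and the
  tolerated energy error.
- `burn_in_fraction` — leading fraction of each run discarded (default
  10%), covering restraint-center relaxation.

Each chain owns an explicitly seeded generator; identical parameters give
bitwise-identical streams regardless of how many chains run in the same
batch call.

**Initial paths.** `tmd_path` drives a restrained chain from start to
target and resamples the trace at equal arc length.  At finite temperature
the raw trace's accumulated arc length is dominated by thermal jitter, so
the trace is boxcar-smoothed (window ≈ schedule/2K steps) before
resampling; without this the images bunch wherever the chain lingered and
the initial string can even fold back on itself.  The driving restraint
must dominate the steepest wells (κ_TMD = 2000 by default for
Mueller–Brown; softer driving lets the chain stick in deep minima while
the center moves on, again bunching the images).

## Mean-force string method

A path is discretized as K images z₁…z_K.  Per iteration: (1) estimate
the mean force at every image from restrained sampling (one chain per
image, vectorized); (2) move each image downhill, z ← z − h·∇A(z), with a
per-image displacement cap (trust-region style, default 0.01–0.02 CV
units) so steep-wall images cannot overshoot while soft-direction images
keep making progress; (3) optionally smooth with a discrete Laplacian;
(4) redistribute the images at equal arc length along the piecewise-linear
path.  Convergence is monitored as RMS image displacement per iteration
normalized by path length; endpoints are pinned by default.

Two stiffness conditions proved essential in practice and set the
defaults used for the Mueller–Brown benchmark (κ = 5000, h = 2×10⁻⁴,
cap 0.01, 2000 samples/image, ≤300 iterations):

- κ must exceed λ_max ≈ 4×10³.  At softer κ the mean force is the
  gradient of a substantially Moreau-smoothed surface whose minimum
  free-energy path (MFEP) genuinely differs — the string then converges,
  stably and reproducibly, to a *direct* channel that crosses the ridge
  away from the saddle.
- h·λ_max < 1 for non-oscillatory relaxation; larger steps fold the
  string (neighboring images cross) under sampling noise.

With these settings a 32-image string between the two deep Mueller–Brown
minima lands within ~0.02 CV units (mean) of a brute-force MFEP oracle
(steepest descent from the grid-located saddles) in ~150 iterations.

Reparametrization is piecewise-linear: redistributed points lie exactly on
the previous polyline at equal arc spacing measured along it.  (Chords of
the new polyline therefore cut corners at second order; cubic
reparametrization is deliberately not used — monotone, no overshoot.)

## Umbrella sampling and the PMF estimator

One window per image with isotropic bias (κ/2)|θ − z_k|², window k seeded
`seed + k`.  Window free energies f_k solve the standard binless
self-consistent (pooled-likelihood) equations; the solver runs a few
direct sweeps and then Newton–Raphson on the convex stationarity
conditions (gauge f₁ = 0), certifying convergence by the direct-iteration
residual.  Workspaces drop to float32 when the pooled matrix is large; the
tolerance is then floored at the float32 self-consistency resolution,
orders of magnitude below the statistical error of the f_k.

The profile along the path progress coordinate s (orthogonal projection
onto the string polyline, ties toward the lower segment) is accumulated in
bins only at this final step.  Two departures from the textbook "reweight
to the unbiased ensemble" recipe are deliberate:

1. **Tube confinement.**  In more than one CV dimension the unbiased
   marginal over s integrates over the transverse direction, which the
   windows never sample beyond the tube width √(kT/(κ+V″⊥)); the naive
   unbiased weights grow as exp(+κy²/2kT) with transverse offset y and the
   estimator's variance diverges (observed as ±1.5 kT bin-to-bin noise).
   `wham_pmf` therefore reports the free energy of the *tube-confined*
   ensemble: each sample weight carries the factor exp(−κy²/2kT), which
   cancels the blow-up exactly.  For stiff tubes (κ ≫ V″⊥) the confined
   profile equals the potential along the path up to an s-independent
   constant — the same object the thermodynamic-integration cross-check
   measures.  For a 1D identity CV the factor is unity on the path's span.
2. **Endpoint exclusion.**  Samples beyond the path ends have no
   orthogonal projection; clamping them to s ∈ {0, 1} pools a half-space
   of weight into the terminal bins (≈1 kT artifacts that corrupt the
   min-anchoring).  They are excluded instead.

Empty bins are reported as missing (NaN), never interpolated; profiles are
anchored at min = 0.

**TI cross-check.** `ti_pmf` integrates supplied mean-force vectors along
the path (trapezoid).  The agreement benchmark on the Mueller–Brown string
uses Simpson integration with additional midpoint mean forces and the
stiff-spring conditions derived above: umbrella κ = 2×10⁴ ≫ λ_max, 107
windows (≈1.8σ spacing) at kT = 4 (window width ∝ √kT, so fewer windows
cover the path at fixed κ), 4×10⁵ steps per window, and TI mean forces at
κ = 4×10⁵ (integrated Moreau error < 0.05 kT).  The dominant residual is
the random walk of f_k stitching errors along the 107 windows
(≈0.1–0.2 kT for these run lengths), which is what the 0.3 kT acceptance
margin absorbs.

## Structural analyses

- **Superposition** is least-squares rigid fitting with a proper rotation
  enforced (no reflections); **dRMS** is the RMS difference of all
  intramolecular pair distances of the selected atoms — rigid-transform
  invariant by construction, so no superposition is involved.
- **Fixed-radius substate clustering**: sequential seeding in path order
  (join the nearest centroid if closer than the radius, else found a new
  cluster) followed by medoid refinement until stable.  On a path whose
  metastable segments are separated by more than the radius this yields
  contiguous clusters.
- **Motion tree**: average-linkage agglomerative clustering of the
  Cα difference distance matrix D_ij = |d_ij(A) − d_ij(B)|; node height =
  mean inter-cluster |Δd| (monotone toward the root).  Rigid domains are
  read off by cutting at a height threshold (default 2 Å) and folding
  clusters below `min_size` (default 30) into their nearest large cluster.
  A final membership sweep reassigns each residue to the domain with the
  smallest mean difference-distance: a single atom pair whose mutual
  distance is accidentally conserved across the conformations would
  otherwise seed a spurious cross-domain merge at near-zero height (such
  pairs are common — any atom moving perpendicular to the line connecting
  it to a partner keeps that one distance).
- **Domain rotation**: superpose on the reference domain, fit the residual
  transform of the mobile domain (A → B direction), and decompose it as a
  screw motion.  Convention: rotation-vector axis with angle in [0, 180);
  the translation along the axis is reported signed.  Fixing the axis sign
  by the screw translation instead was rejected: for pure domain rotations
  the translation along the axis is ≈ 0, so under noise that convention
  flips the reported axis at random.  Axes are flagged undefined below
  0.1°.  Identifiability: the axis direction is determined only to about
  (noise-induced rotation)/(planted angle), so sub-degree planted angles
  cannot pin the axis regardless of estimator.
- **Lipid density maps**: frames rigid-aligned to frame 0 on a protein
  selection; lipid positions split into leaflets by z (per-frame median by
  default) and binned in xy, counts normalized per frame.
- **Ion occupancy**: per frame, the number of ion atoms within a cutoff
  (default 4 Å) of any binding-site atom.
- **Representative frame**: average-linkage clustering of the pairwise
  superposed-RMSD matrix, cut at the largest merge-height gap, medoid of
  the largest cluster.

Atom bookkeeping: fixed-column PDB via biotite; highest-occupancy altloc
retained; hydrogens dropped by default, HETATM kept; atoms matched across
structures by (chain, residue id, atom name) with unmatched atoms an
error.  Selections use a small boolean grammar
(`chain A and resid 124-235 and name CA`; EBNF in the `structure` module
docstring).  Coordinates are stored float32 (PDB precision is 10⁻³ Å), so
"exact" invariances hold to ~10⁻⁷ relative through the containers and to
machine precision on float64 coordinate arrays.

## Synthetic data: what it does and does not emulate

The generators plant precisely the structure each analysis looks for:
rigid-body domain motions on self-avoiding Cα traces (3.8 Å spacing) with
Gaussian coordinate noise; trajectories jittering around well-separated
anchor conformations; membrane snapshots with lipid phosphorus atoms in an
annulus, two leaflets at z = ±18 Å, and a truncated-Gaussian hotspot; ion
frames with exact planted site occupancies and decoys.  Planted-motion
fixtures place the rotation axis well away from the structure: residues
near the axis barely move and their domain membership is genuinely
undetermined.  For the rigid-domain fixtures, 17° about an axis ~55 Å away
yields the target mean inter-domain |Δd| ≈ 5 Å.

None of this is physically realistic — no side chains, no excluded-volume
membrane, no solvent, no correlated backbone motion.  Passing closure
tests therefore demonstrates that the *estimators* recover planted
geometric/statistical structure at realistic noise levels, not that the
pipeline's conclusions transfer to any particular real protein.

## Problem sizes

The benchmark suite uses: 32-image strings (2000 samples/image, ≤300
iterations), 27-window double-well umbrellas (4×10⁴ steps), 107-window
Mueller–Brown umbrellas (4×10⁵ steps, thinned 10×), 64-frame/5-substate
paths, 80–120-residue domain fixtures for motion trees, 800-residue
domains for the 100-draw rotation-recovery benchmark, and 2000-lipid,
20-frame membranes.  These sizes put every statistical check comfortably
inside its tolerance on a single CPU in minutes.

## Known limitations

- The string method finds a *local* MFEP; multiple transition channels
  are resolved only by trying different initial paths.
- The PMF is one-dimensional along the path; transverse structure beyond
  the tube width is invisible by design.
- The WHAM–TI agreement degrades for soft restraints (Moreau smoothing)
  and for long window chains (stitching random walk); both effects are
  quantified above rather than removed.
- Automatic domain-boundary detection is out of scope: domain rotations
  are computed for user-specified selections.
- Trajectory input is multi-model PDB only.
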