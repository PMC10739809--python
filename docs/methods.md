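# Methods

This note documents the models implemented in `flexsemble`, their
assumptions, the defaults that matter, and the numerical choices made where
the design was genuinely open.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Fragment recombination

The target object is the solution ensemble of a three-domain protein whose
two fragment pools (mobile = outer domain 1 + shared middle domain;
static = shared middle domain + outer domain 2) are sampled independently,
e.g. by MD.  The combination step assumes that

* the shared domain is internally rigid enough that superposing the two
  fragments at its Cα atoms defines a common frame (the fit RMSD is
  reported per pair and is the continuity bound for the stitched chain);
* interactions between the two outer domains can, to first order, be
  reduced to excluded volume: pairs are rejected only for steric overlap,
  not re-weighted by an interaction energy.

**Clash definition.**  A clash is a heavy-atom cross pair at distance
< 0.20 nm.  The literature workflow this mirrors counted "atom-pair
clashes" without publishing the criterion; 0.20 nm corresponds to severe
van-der-Waals overlap (sum of radii ≈ 0.3–0.4 nm), i.e. contacts that
side-chain repacking cannot plausibly relieve are *not* what is counted —
only genuine core overlap is.  The cutoff is configurable
(`AssemblyConfig.clash_cutoff`).  Counting uses KD-trees; a query radius of
`nextafter(cutoff, 0)` makes the closed-ball KD-tree count exactly equal to
the strict-inequality brute force, which the tests verify pair-for-pair.

**Threshold semantics.**  A pair passes iff its clash count is strictly
below the threshold (default 100).  The source workflow's prose is
ambiguous ("did not exceed" vs "fewer than"); the strict reading is adopted
because it reproduces the published 275/125 partition of 400 pairs.

**Junction.**  The stitched conformer takes residues `< j` from the mobile
fragment and `≥ j` from the static one, with `j` defaulting to the first
residue of the shared domain's second half — deep inside the superposed
rigid region, so the seam inherits the fit quality.  The seam C–N distance
is reported (canonically 0.133 nm).  This geometric stitching replaces the
original spatial-restraint homology modelling; no side-chain rebuilding or
relaxation is attempted.

## SAXS forward model

Scattering is computed from atomic (or bead) positions only:

* `saxs_debye` — the exact spherical average
  `I(q) = Σ_ab g_a g_b sinc(q r_ab)`; the reference implementation and the
  oracle for everything else.
* `saxs_qvector` — the production route for large systems: an explicit
  average over unit directions û, `I(q) = ⟨|Σ_a g_a exp(i q û·r_a)|²⟩`,
  with 2000 directions per |q| (the convention of explicit-solvent SAXS
  codes).  Directions come from a deterministic spherical Fibonacci
  lattice rather than a random set: reproducibility at equal accuracy.
  The acceptance suite requires ≤ 1% relative deviation from the Debye sum
  for q ≤ 3 nm⁻¹ on a 500-bead fixture.

**Contrast.**  Vacuum amplitudes are Cromer–Mann 4-Gaussian form factors
(f(0) = Z within 0.5%).  Excluded volume uses the Gaussian dummy-atom
model, `g_a(q) = f_a(q) − ρ_s V_a exp(−q² V_a^{2/3} π/(4π)^{2/3})`, with
Fraser-type displaced volumes and ρ_s = 334 e·nm⁻³ (the experimental bulk
water density).  This implicit-solvent model replaces explicit-water
envelope scattering, which needs MD water and is out of scope here.

**Hydration layer.**  The ordered water shell raises the apparent Rg; it
is represented by a fixed additive offset δRg = 0.076 nm applied to
model radii (`apply_hydration_offset`) — the same device the source
workflow used to compare bare models with experiment — not by modelling
shell density.

**Guinier analysis.**  `ln I` vs `q²` is fitted iteratively: fit, compute
Rg, truncate to `q·Rg ≤ 1.3`, refit until the window is stable (≥ 5
points).  Caveats established numerically in the tests: on an ideal
Guinier curve the fit is exact to 1e-6; on a solid sphere the *window
itself* biases Rg by ≈ +1.8% at `q·Rg = 1.3` and the bias scales with the
squared window, so checks that compare against geometric radii fit at 0.8.
On elongated particles the bias has the opposite sign and similar size.

**Discrete-cloud limit.**  A bead cloud of n scatterers has an incoherent
floor: `I/n² = F(q)(1−1/n) + 1/n` for the continuum form factor F.  Near a
form-factor zero the relative deviation of any finite cloud therefore
diverges; the sphere acceptance check subtracts the floor and compares up
to qR = 4.0 (intensity down ~2.5 decades), verifying the first-minimum
*position* separately.

## Ensemble analytics

* **PCA** (`EnsemblePCA`): members are superposed on the fit selection to
  the running mean conformation, two passes (the fitting reference is a
  convention; two passes make the mean self-consistent without iterating
  to convergence), then the covariance of the analysis-selection
  coordinates is diagonalized with 1/M normalization so training
  projection variances equal the eigenvalues exactly.
* **Clustering** (`GromosClustering`): greedy neighbor counting — the
  member with the most RMSD-neighbors within the cutoff becomes a
  centroid, it and its neighbors are removed, repeat.  Deterministic (ties
  → lowest member index); clusters reported in population order.  The
  RMSD cutoff is system-dependent and exposed (default 0.3 nm; the
  acceptance workflow on the synthetic world uses 0.05 nm because rigid
  bead domains fluctuate far less than real proteins).
* **Rotation dihedral**: the Cα dihedral of four marker residues (two per
  domain, ends of central strands) monitors the relative domain rotation;
  circular histograms use 5° bins and peaks are strict circular local
  maxima ordered by height.
* **Free-energy surfaces**: `F = −kT ln(ρ/ρ_max)` on a 2D histogram
  (default kT = 2.478 kJ/mol, 298 K).  Empty bins are masked, not
  pseudo-counted — unexplored regions stay visibly unexplored, and
  `F_i − F_j = −kT ln(n_i/n_j)` holds exactly on occupied bins.
* **Minimum free-energy path**: defined as the minimax path (minimizing
  the maximum F) on the 8-connected occupied-bin graph, computed by a
  Dijkstra variant with max-cost composition.  The published figures show
  such a pathway without defining it; minimax is the standard
  discrete-landscape choice and its barrier is the quantity of interest.
* **Density maps**: mobile-domain COM histograms (0.2 nm voxels) after
  superposition on the static core, normalized to total mass 1, with
  isolevels reported at 1/10 and 1/1000 of the maximum (the conventional
  opaque/transparent rendering pair).

All analytics are invariant under a global rigid transform applied
uniformly to the ensemble (property-tested).

## The synthetic world

`SyntheticEnsembleSpec` defines a stated toy world, not a tuning surface:

* Domains are rigid serpentine bead chains on a 0.38 nm lattice (N/CA/C
  pseudo-backbone per residue placed on the Cα polyline, so seam bonds and
  Cα analytics behave like a real chain); bead counts 100/100/250 mirror
  the N-SH2 / C-SH2 / PTP proportions.
* Heterogeneity is planted: domain A rotates about hinge axes through its
  linker pivot (von Mises angles, default κ = 100 ≈ 5.7° width — small
  interdomain fluctuations around a preferred pose); domain C rotates
  about the B–C linker axis so that a planted marker dihedral takes values
  drawn from a von Mises mixture at −100°/−30° (weights 0.6/0.4,
  κ = 33 ≈ 10° width), the bimodal rotation seen in the real system.
* Domain A's rest direction points toward domain C's −30° orbit position,
  tilted away by 18°.  With this one geometric choice the default
  400-pair grid shows the qualitative mix of the real workflow
  (clash-free ≈ 40%, passing ≈ 68%, discarded ≈ 33%); no test asserts
  these fractions, only exact agreement with the brute-force ground truth.
  If `target_clash_fraction` is set, the tilt is chosen from a fixed grid
  to approach the target — a generator feature, not a fit.
* Ground truth records everything recoverable downstream: domain atom
  indices, per-member COMs and radii of gyration, hinge-mode linearized
  eigenvalues, per-member dihedral values, and the brute-force O(N²)
  per-pair clash matrix (computed only for grids ≤ 500 pairs; larger pools
  are meant for clustering-stage tests where the matrix is unused).

What a green test on this world establishes: the pipeline recovers planted
collective modes, mixtures, barriers and clash counts *exactly or within
stated statistical tolerances*.  What it does not establish: force-field
realism, linker energetics, side-chain packing, or hydration physics —
real-data behavior is covered only by the accession checks in
`flexsemble.validation`, which require manually downloaded inputs.

## Degenerate inputs and tie-breaks

Altloc resolution keeps the highest occupancy, ties to 'A'.  Dihedrals at
exactly ±180° report +180°; collinear triplets are errors, not NaNs.
Superposition rejects < 3 or collinear fit points and never returns a
reflection.  Guinier fits fail loudly on non-negative slopes.  Clustering
ties resolve to the lowest member index.  An empty assembled ensemble
(threshold 0) is a warning plus a truncated report, not a crash.

## Known limitations

* The stitched conformers are not relaxed; clashes below threshold remain.
* The implicit-solvent SAXS model plus fixed hydration offset is a
  deliberate simplification; absolute intensities are arbitrary units.
* GROMOS clustering is O(M²) in members; fine for ≤ a few thousand
  conformers, not for full MD trajectories.
* The q-vector route converges to the Debye sum as the direction count
  grows; at 2000 directions the residual error on compact particles is
  ≲ 0.1% for q ≤ 3 nm⁻¹ but grows with qR beyond that range.
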