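# Methods

This note records the models, conventions and design choices behind
`confcube`, in the spirit of a methods appendix: what each stage computes,
which knobs matter, and what the synthetic tests do and do not demonstrate.

## Units and containers

Coordinates are held in nanometres internally (the convention of the MD
engines whose output this pipeline targets); PDB serialization converts to
angstroms at the boundary and is limited by the fixed-width `%8.3f` field to
[−999.999, 9999.999] Å — out-of-range coordinates are rejected, never
clamped, and round-trips are accurate to the format's 10⁻³ Å resolution.
SASA and residue distances are *reported* in Å-based units, matching how
such quantities are usually tabulated; everything else stays in nm. A
trajectory is a coordinate stack over a fixed topology; per-residue
(φ, ψ) metadata may ride along for bead models (see below) and travels
through PDB round-trips in a plain-text `.phipsi.tsv` sidecar, since PDB has
no dihedral field.

## Superposition and RMSD

RMSD is mass-unweighted over all selected atoms and always follows an
optimal least-squares rigid superposition: the Kabsch algorithm via SVD of
the 3×3 cross-correlation matrix, with the determinant correction that
restricts the solution to proper rotations. The all-against-all matrix over
`F` frames uses a batched formulation (per-pair RMSD from singular values
only, no explicit rotation), processed in row blocks to bound memory at
O(block · F · 9) — the full matrix is O(F²). `superpose` (which must return
a rotation) rejects selections of fewer than three atoms or collinear
geometry, where the rotation is not unique; the RMSD *value* remains
well-defined for collinear inputs and `rmsd` therefore accepts them.
Self-distances are exactly zero in the tuple cube (the diagonal is set, the
trace formula alone carries ~10⁻⁸ nm of float cancellation noise).

## Fraction of native contacts (Φ)

No single convention exists for FNC, so the package uses a standard hard
cutoff definition, fully configurable: native contacts are pairs of CA/bead
atoms within 0.8 nm in the replica's *own first frame*, from residues at
least 4 apart in sequence (cross-chain pairs always qualify); a contact
counts as formed in a later frame when its distance is within 1.2× the
cutoff. Φ of the reference frame is exactly 1, and Φ is invariant under
rigid motions because only internal distances enter. Φ over an empty
contact set is an error, never silently 0.

## Other per-frame metrics

* **Radius of gyration** — mass-weighted RMS distance from the centre of
  mass (equal masses assumed when the topology carries none).
* **SASA** — Shrake–Rupley with 960 sphere points and a 0.14 nm probe by
  default, per-element van der Waals radii (C 1.70, N 1.55, O 1.52, S/P
  1.80, H 1.20 Å; overridable). Exactly coincident equal-radius atoms are
  collapsed to one sphere before evaluation because the surface-point
  inclusion test is strict on the boundary. 960 points put the single-atom
  sphere within 1 % of 4π(r+p)²; doubling the points moves a 10-atom toy by
  < 0.5 %.
* **Helix content** — percentage of residues whose (φ, ψ) fall in
  φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] *and* belong to a run of at least 4
  consecutive such residues. Dihedrals come from planted per-residue
  metadata (bead models) or from backbone N/CA/C atoms when present. This
  is a deliberate dihedral-window approximation, not a hydrogen-bond (DSSP)
  assignment; absolute percentages are method-dependent and comparisons
  should stay within one method.
* **Residue distances** — CA-to-CA by default (closest-heavy-atom mode
  available), reported in Å.
* **LOWESS** — locally weighted linear regression with default
  `frac = 0.1`, used for presentation and for the replica-stability screen
  only; smoothed series never feed the quantitative thermodynamics.

## Replica screening and the tuple cube

A replica is kept when its (optionally LOWESS-smoothed) RMSD-vs-initial
series varies by at most a tolerance (default 0.05 nm, roughly the noise
floor of an equilibrated RMSD trace) over the final window (default 10 ns);
shorter trajectories are rejected per-replica with a recorded reason. The
ensemble's representative replica is the one whose final-frame RMSD is
closest to the mean of all final-frame RMSDs, ties to the lowest index.

The tuple cube enumerates *ordered* pairs, diagonal included: exactly F²
entries (at the published scale of 4863 pooled frames, 23,648,769 tuples).
This follows the squared-total counting convention even though (X, Y) and
(Y, X) carry the same RMSD with swapped Φ; a frame stride/offset can
subsample per replica *before* squaring. Entry order, and hence everything
downstream, is deterministic given manifest order. Counts are conserved
exactly: clusters partition the cube, and the package treats any count
mismatch as a bug, not a rounding issue.

## Clustering and k selection

K-means is Lloyd's algorithm, implemented in-package so that the
per-iteration objective is exposed (tests assert monotone descent at every
iteration) and so the stopping rule (centroid displacement below `tol`) and
the empty-cluster policy (re-seed at the point farthest from its assigned
centroid) are explicit. Initialization draws centroids uniformly from the
data points; `n_restarts` (default 10) independent initializations are run
and the lowest-inertia solution kept; an optional `kmeans++` (D²-sampling)
initialization exists for hard cases with many unbalanced, tightly
separated clusters, where uniform seeding rarely covers every cluster
(the 16-cell synthetic recovery below is such a case). Results are
deterministic given the mandatory seed. sklearn's KMeans is used in the
test suite as an independent cross-check of the attained inertia, never as
the implementation.

Axes are clustered raw by default (RMSD in nm against two unitless Φ axes);
a z-score `standardize` mode is available and is used where the Φ axes must
carry equal weight. Clusters are always renumbered in descending size
order, so cluster 1 is the most populated.

The elbow method computes the explained-variance fraction
`1 − inertia_k / inertia₁` per k (best of the restarts) and selects the k
where the curve bends most sharply — the largest second difference of the
inertia curve, which is the point where the marginal gain drops. A flat or
degenerate curve returns the smallest k with a warning flag rather than
inventing structure.

## Free energies and representatives

With cluster counts as occupancies, `ΔG°(i,j) = −RT ln(P_i/P_j)` with
R = 8.314 J mol⁻¹ K⁻¹. The table is antisymmetric and path-additive to
10⁻⁹ J/mol by construction, and zero populations raise an explicit
infinite-ΔG error. The table also flags whether the largest |ΔG°| sits
below a thermal-noise threshold; the conventional 2.47 kJ/mol figure is the
default while RT at the 310 K simulation temperature (2.577 kJ/mol) is
reported alongside, since the two differ. Reproduction of published
population-derived tables is checked to ±0.2 J/mol, absorbing rounding of
R and T in printed values (two published pairs differ from exact
recomputation by 0.1 J/mol).

Interpreting tuple counts as equilibrium occupancies assumes the pooled
replicas sampled the accessible conformational space exhaustively — a
strong assumption that holds for the synthetic generator by construction
and must be argued separately for real ensembles.

Each cluster's representative is found by fitting a Gaussian KDE (Scott
bandwidth) to the cluster's tuples, evaluating it *on the tuples
themselves* (no continuous optimizer), taking the density argmax (ties to
the lowest index; degenerate clouds fall back to the point nearest the
cluster mean) and returning the tuple minimizing squared distance to that
mode. A tuple references two frames; the row frame (frame X) is reported as
the associated conformation, configurable to frame Y.

## Synthetic generator

The generator emulates the branching-replica study design, not physics: no
force field, no integrator, no field dynamics.

* **Protein** — a coarse bead chain, one CA-labelled bead per residue,
  arranged as a four-helix bundle (default 33 beads per helix on idealized
  CA-helix geometry — 0.23 nm radius, 0.15 nm rise, 100°/residue — joined
  by 5-bead loops; 147 beads total). Helical residues carry planted
  (φ, ψ) = (−57°, −47°), loops an extended pair, so helix content is
  exercisable on a bead model.
* **Basins** — built from the reference by splitting the bundle into two
  two-helix sub-domains and displacing the second (translation plus
  rotation; defaults 0.8/1.6/2.4/3.2 nm for four basins) with a growing
  unfolded tail (0/15/30/45 % of the sub-domain laid on an extended line
  with extended dihedrals). Default basin weights (0.38, 0.24, 0.19, 0.19)
  mirror the published cluster-size fractions. FNC and residue distances
  discriminate the basins monotonically in the displacement.
* **Replicas** — each replica samples `reference + jitter` before the
  switch frame and `basin + jitter` (default jitter 0.02 nm per coordinate)
  from it onward, with the basin drawn once per replica (no
  back-transitions, matching a stability-screened ensemble). Total frames
  are exactly `n_replicas × frames_per_replica`; the generator never pads
  toward a foreign total (34 × 143 = 4862, not 4863 — per-replica frame
  counts are free parameters). Bitwise reproducible from the seed.
* **Bilayer** — two leaflets of phosphate-marker particles at mean
  z = ±separation/2 with Gaussian z-noise; leaflet membership is recorded
  at generation and assigned by z-sign relative to the frame-0 centre of
  mass when read from file, then held fixed (intact-leaflet assumption).
  Thickness is the z-separation of leaflet centres of mass (membrane
  normal = z, the applied-field axis), and ΔV = E·d assumes a homogeneous
  dielectric — both stated limitations of the estimate, surfaced in the
  report rather than modelled.

What passing tests on this generator show: the pipeline's bookkeeping,
metrics, clustering and thermodynamics are correct on data whose truth is
known. What they do not show: anything about force-field accuracy,
equilibration, back-transitions between states, or pore formation in real
membranes — real trajectories have correlated, anisotropic fluctuations
and gradual transitions that the isotropic-jitter model deliberately omits.

## Synthetic free-energy recovery

With k planted basins, tuples fall into (basin_X, basin_Y) cells whose
counts are products `n_i · n_j` of the per-basin replica counts, so raw
tuple-count ratios recover `ln(n_i/n_j)` only between cells sharing one
index. The recovery analysis therefore clusters the cube with k = 16 cells
(standardized axes, kmeans++ seeding, 30 restarts), maps clusters to cells
by majority vote, and compares ΔG° between cells sharing the Y basin
against `−RT ln(p_i/p_j)`, within 3× the multinomial sampling error of the
replica draw (variance `(1−p_i)/(N p_i) + (1−p_j)/(N p_j) + 2/N` on the
log-ratio). The default problem size — 200 replicas × 2 frames, cube built
on final frames only (offset 1, stride 2; 40,000 tuples) — keeps the
analysis comfortably within a single-CPU test run while leaving the
multinomial error (≈ 0.4–0.8 kJ/mol observed) well-resolved against the
planted ΔG° of 0–1.8 kJ/mol.

## Numerical conventions

* Stochastic stages take explicit seeds everywhere; provenance headers on
  every artifact name the package version, config hash and seed, and
  deterministic stages are bitwise-reproducible under rerun.
* Ties break to the lowest index throughout (representative replica, KDE
  mode, argmin/argmax), making every selection deterministic.
* Degenerate inputs have defined behaviour: empty contact set → error;
  empty leaflet → error; flat elbow curve → smallest k + flag; all-equal
  KDE cluster → that point; k exceeding the point count → error.
* The pipeline CLI exits 0 on success, 2 on validation failure (before
  compute), 3 on stage failure (partial artifacts retained).
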