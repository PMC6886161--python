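# Methods

## Contact-to-distance model

Hi-C counts are converted to target distances on C1 (pairs with nonzero
contact) by δ = β(1/c)^α. α (default 1/3) controls how steeply distance
grows as contacts fall; 1/3 corresponds to the volume-filling intuition
that contact frequency scales inversely with enclosed volume. β (default 1)
is a pure unit choice: the reconstruction's length scale is arbitrary, which
is why truth-recovery comparisons allow a fitted global scale. δ is stored
only where defined; a boolean C1 mask carries definedness, and no sentinel
values ever enter the distance matrix.

For the `eq4` objectives every C2 (zero-contact) pair needs a reference
distance R. The shortest-path scheme computes all-pairs shortest paths over
the C1 graph (edge weight δ) once per matrix — R is a property of the data,
not of any candidate structure — via `scipy.sparse.csgraph`. A disconnected
contact graph is an error rather than a silent patch, because R is undefined
across components; `largest_connected_component` is provided for callers
who want to pre-filter. The max scheme uses the single largest δ over C1.
On C1 pairs the shortest path may undercut the direct edge (the triangle
route can be shorter); only C2 entries are consumed by the objective.

## Objectives and optimizer

All sums run over unordered pairs i<j; summing ordered pairs would only
double every term (and halve the effective γ in eq3). The eq3 regularizer
−γΣd² is unbounded below if any bead has no C1 edge (nothing counteracts
its outward drift), so such inputs are rejected with a pointer to the
connected-component helper. The eq2/eq4 C1 terms normalize by δ², eq3 by δ.

Minimization is quasi-Newton (L-BFGS-B) on the 3n coordinates with exact
analytic gradients; defaults: 3000 iterations, gradient tolerance 1e-7,
5 restarts. Restart 0 uses a classical-MDS (Torgerson) embedding of the
target-distance matrix completed by graph shortest paths — the standard
warm start for metric stress MDS, and the reason noiseless inputs are
recovered to machine precision; the remaining restarts draw coordinates
uniformly from a cube with side equal to the mean δ, from a PRNG seeded by
the run seed, so the whole procedure is deterministic given the seed. If
two beads in an active pair coincide exactly (gradient singularity), a
symmetric jitter of 1e-9× the init scale is applied and logged. The best
final objective across restarts wins; restarts that go non-finite are
discarded with a log message.

`ChromatinMDS` wraps this as a scikit-learn estimator (`fit`,
`fit_transform`, `embedding_`, `stress_`, `get_params`/`set_params`) so it
composes with sklearn tooling; `reconstruct()` is the function interface
over the same code path.

### What reconstruction cannot determine

Pairwise distances are invariant under rigid motions *and reflection*, so
the inferred structure's chirality is unobservable. Truth-recovery scoring
(`recovery_rmsd`) therefore takes the better of the structure and its
mirror image, each superposed by a proper-rotation Kabsch fit with a free
global scale. Structure-vs-structure comparisons (`kabsch_superpose`,
`pairwise_structure_rmsd`) never allow reflections and, by default, no
scale either: two reconstructions of the same matrix share a unit, and
silently rescaling would hide genuine disagreement.

## Superposition

Kabsch via SVD of the 3×3 covariance; the smallest singular value's sign is
flipped when needed so the rotation is always proper. The optional scale
(similarity/umeyama fit) is intended for comparisons against ground truth
whose unit is arbitrary. Collinear point sets are solved (the in-line
rotation component is undetermined but irrelevant to RMSD) and flagged.

## Structural metrics

**Radius of gyration.** R_g = sqrt(Σ mᵢ‖xᵢ−R_C‖²/M) with M = Σ mᵢ by
default. The mass schemes are: unit mass; 1 + TSS count; 2 if any of
TSS/H3K4me3/polII present else 1; and 1 + TSS + H3K4me3 + polII counts.
The phrase "mass normalized by TAD length" admits two readings; the
default keeps the physically standard M = Σ mᵢ and a `length_normalized`
flag divides M by the bead count n instead (equivalent to multiplying R_g
by √n). Length is measured in beads, not base pairs, so the variant is
resolution-independent.

**Folding degree.** The bead chain (a path graph) is lifted through three
line-graph iterations; L3 of a path on n nodes is a path on n−3 nodes, one
per dihedral angle between consecutive bead planes. The statistic is
Σ exp(λ) over the eigenvalues of S = A(L3) + diag(φ), divided by the node
count (the raw sum is available via `normalized=False`). The exact matrix
composition — adjacency plus dihedral diagonal, angles in radians, mean
rather than raw sum — is this package's concrete reading of the
Estrada-index construction; both conventions are exposed so either can be
used downstream. Dihedrals are unsigned angles in [0, π] between plane
normals (chirality is discarded: the diagonal needs a magnitude), and an
exactly collinear bead triple (cross-product norm ≤ 1e-12) is a hard error
naming the bead, not a silent zero.

**Exponent parameter.** For each genomic separation s the mean contact
over all |i−j| = s pairs is computed with zeros included — a zero count is
data, not missingness — then separations whose mean is exactly 0 are
dropped and γ is the negative slope of the log10–log10 least-squares fit.
All usable separations enter by default; `max_s` truncates the range.
Fewer than 3 usable separations is an error.

## TAD-level analyses

Peak-type features are counted by the midpoint rule (a peak spanning two
beads or TADs is counted exactly once, in the bin holding its midpoint);
signal-type features are averaged on log2 scale with non-positive values
excluded under a counted warning. Both are divided by TAD length in base
pairs. Pearson correlations between metrics and features report raw
two-sided p-values (t-distribution, n−2 df).

Chromatin-state fold enrichment of state s in TAD t is (fraction of t's bp
covered by s) / (fraction of all segmented bp covered by s), so 1 means
the TAD matches the genome-wide composition. TAD–TAD affinity is the
absolute Pearson correlation between fold-enrichment profiles; clustering
is normalized-Laplacian spectral embedding plus seeded k-means with 10
restarts (scikit-learn's `SpectralClustering` on the precomputed
affinity), default 20 clusters.

Observed/expected inter-TAD contacts use E_ij = R_i·R_j·N_inter. Each
inter-TAD contact is credited to **both** of its TADs, so Σ R_i = 2 (this
is asserted). The convention is chosen because it makes the degenerate
two-TAD case give O/E exactly 1; a sum-to-1 per-read convention would give
4 there, which has no natural reading.

ICE balancing iteratively divides rows and columns by their marginals
until the coefficient of variation of nonzero-row marginals falls below
`tol` (default 1e-5, max 200 iterations), then rescales so the mean
nonzero-row marginal is 1. All-zero rows are left untouched and excluded
from the convergence check; non-convergence is logged, never raised.

## Synthetic data

The generators define the conditions under which the package's guarantees
are tested:

* **Structures**: helices (bead k at (r cos kθ, r sin kθ, k·pitch),
  defaults r = 1, θ = π/4, pitch = 0.3) and unit-step random walks with
  collinear triples resampled away.
* **Contacts**: c = (β/d)^(1/α), the exact inverse of the conversion, so
  structure → contacts → target distances is an identity when noiseless.
  Noise is multiplicative lognormal (Hi-C counts are positive and
  heteroscedastic) and dropout zeroes whole pairs symmetrically, creating
  the C2 sets the eq3/eq4 objectives need. A seed is mandatory for any
  stochastic setting.
* **Power-law matrices** plant an exact decay exponent for the 2D metric.
* **Feature tracks**: Poisson peak counts per bead (defaults: 1 TSS and
  0.5 H3K4me3/polII peaks per 40 kb bead — the order of magnitude of
  mammalian gene/peak density at that resolution) placed uniformly within
  their bead; lognormal per-bead signal values for bedGraph-type tracks.
* **State profiles**: block-specific mean enrichment vectors plus Gaussian
  noise (sd 0.05), with true labels returned for ARI scoring. Block means
  are rejection-sampled so no two exceed |Pearson r| = 0.4: with 20 blocks
  in a 14-state space, unconstrained means can collide in correlation
  space, which would make the planted partition unidentifiable *by
  construction* under the absolute-correlation affinity — the cap keeps
  the fixture a well-posed recovery problem rather than easing the
  clustering itself.

What passing on these fixtures does **not** show: real Hi-C matrices carry
distance-dependent coverage biases, structural variation between cells,
and unmappable regions, none of which the generators emulate; the noiseless
recovery results are a correctness statement about the optimizer and the
conversion, not an accuracy claim for real data.

## Problem sizes and numerical choices

Test and acceptance workloads use n = 50 beads for noiseless recovery,
n = 40 with 20% dropout for the C2-behavior comparison, n = 5 for
finite-difference gradient checks (central differences, step 1e-6,
tolerance 1e-5 relative), chains up to n = 12 against the
characteristic-polynomial eigen oracle, n = 60 matrices for exponent
recovery (±0.05 under 5% lognormal noise), and T = 200 TADs for the
k = 20 clustering. These sizes exercise every code path while keeping the
full suite in the tens of seconds.

Tolerances elsewhere: contact-matrix symmetry 1e-9 absolute (reader repair
threshold 1e-6 relative, larger asymmetries are errors naming the worst
cell); rotation orthogonality 1e-9; collinearity 1e-12.

## Known limitations

- One chromosome (or TAD) at a time; no genome-wide multi-chromosome
  matrices, no .cool/.hic binary readers.
- No polymer physics: the generators have no excluded volume or loop
  extrusion, and the MDS model itself imposes no chain connectivity prior.
- The Estrada-matrix composition is one defensible reading of the
  construction (see above); absolute folding-degree values should not be
  compared across tools, only within one convention.
- Local minimization with restarts does not guarantee the global optimum
  for noisy matrices; determinism is per-seed, not per-machine across
  BLAS implementations.
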