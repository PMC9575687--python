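# Methods

## The problem and the model

A molecular machine in thermal equilibrium is imaged as a large ensemble of
noisy 2D projections, each a snapshot of an unknown conformational state
seen from a known viewing direction.  Images are grouped by projection
direction (PD): all images of one PD share (approximately) one orientation,
so the only systematic variation within the group is conformational.  With
n independent quasi-continuous motions (conformational motions, CMs), the
images of one PD lie on an n-dimensional manifold in pixel space whose
Laplace–Beltrami eigenfunctions, on a rectangular state-space domain with
Neumann boundaries, are products of interval cosines cos(kπx).

A diffusion map of the PD's pairwise image distances approximates these
eigenfunctions.  Pairs of eigenvectors therefore trace Lissajous curves;
for each CM exactly one 2D eigenvector subspace carries the clean
first-vs-second eigenfunction pair {cos(πx), cos(2πx)}, whose locus is a
parabola (the Chebyshev identity cos 2t = 2cos²t − 1).  The method this
package implements recovers, per PD, those CM subspaces; repairs
PD-dependent mixing of eigenfunctions across eigenvectors by planar
(Givens) rotations; converts each subspace into an ordered set of
equal-area conformational bins; and intersects the per-image bin indices
across CMs and PDs into an n-D occupancy map, converted to a relative
free-energy landscape by Boltzmann statistics ΔG = −k_BT ln(n/n_max).

## Synthetic ground truth

The generator replaces an atomic model with parametric pseudo-atom toys:

* `two_arm_v` — a V-shaped static frame with genuine z-extent (tripod core)
  and two thick four-rod arm bundles.  Arm 1 (length 12 units) swings about
  the frame plane normal; arm 2 (length 11) rotates about a tilted axis
  (0.35, 0, 0.937) so that its displacement has both in-plane and
  out-of-plane components from every viewing direction.  Most of the
  machine's mass is in the arms, so the conformational signal dominates the
  clean-ensemble variance, and the two arc lengths differ enough to keep
  the two eigenfunction families spectrally non-degenerate.  Hinge ranges
  default to [0°, 40°].
* `mouth_wings` — concerted per-atom translation fields (non-rigid motion):
  a mouth whose lips open with per-atom directions and magnitudes, and
  wings flapping out of plane.  It checks that the spectral geometry does
  not depend on motions being rigid rotations.

States are an equispaced M-point grid per motion (default M = 20, M^n
states).  Images are rendered analytically: an isotropic 3D Gaussian blob
(σ = 1.5 px) projects to an isotropic 2D Gaussian, so projections are
splatted directly from rotated atom positions; a voxel route
(`render_density` + `project`) exists and agrees to interpolation error.
Frames are P = 64 pixels, pixel size 1 unit.

Realism tiers: I clean/τ=1; II adds τ noisy copies per state at a stated
SNR; III adds a CTF with per-image uniform defocus in 0.5–2.5 µm (300 kV,
Cs 2.7 mm, amplitude contrast 0.1, no envelope); IV adds a non-uniform
occupancy (default: bimodal wells along CM_1 at the quarter points,
a single central well along CM_2, on a 0.05 baseline; copies are assigned
by largest-remainder rounding of the weights at the τ·M^n image budget).
SNR is var(clean ensemble pixels)/var(noise) with one noise variance per
PD per regime; all randomness flows from a master seed with per-image
seeds recorded in the metadata.

What the generator does *not* emulate: orientation misassignment inside a
PD (images of one PD share one exact orientation unless jittered),
structural noise/ice, per-particle envelopes, and model error in the CTF.
Passing tests therefore demonstrate the algorithmic chain under known
orientations, not robustness to alignment error.

## Embedding

Distances are Euclidean between pixel vectors.  For noisy ensembles two
standard pre-conditioners are applied before the distance computation:

* a Gaussian low-pass matched to the blob width (σ = 1.5 px) — the signal
  is band-limited, the noise is not;
* ensemble-variance weighting: pixels whose ensemble variance does not
  exceed the noise floor (median over pixels) carry no conformational
  signal and are down-weighted by their excess variance.  Under per-image
  CTFs the same weighting is applied per Fourier coefficient (a
  Wiener-type relevance weighting), combined with the double-filter
  distance ‖CTF_j∘I_i − CTF_i∘I_j‖, which expands into three Gram products
  and costs the same as plain distances.

The kernel bandwidth ε is set where the kernel sum S(ε) = Σ exp(−D²/2ε)
reaches 0.3·N (mean effective-neighbor fraction 0.3).  This lands on the
transition region of the log–log kernel-sum curve and, unlike a
maximum-slope rule, is insensitive to the constant noise floor that
offsets all squared distances in noisy ensembles.

The diffusion map uses density normalization (α = 1, the Laplace–Beltrami
limit), then Markov normalization; eigenvectors of the symmetric conjugate
are re-weighted, unit-normalized, and sign-fixed by requiring a
nonnegative third moment.  Dense eigendecomposition below N = 1200,
Lanczos with a fixed start vector above (deterministic).  A PCA route is
kept for cross-checks.  The discrete eigenvectors sample cos(kπx) at the
*midpoints* of the M state cells — the standard second-order behavior of
the discrete Neumann Laplacian — so oracle correlations are computed on
the midpoint grid.

## CM determination and realignment

All 2D subspaces {Ψ_i × Ψ_j}, i < j, are fitted; CMs are accepted
greedily by descending parabola fit R² subject to two harmonic-exclusion
rules: (1) index-disjointness with already-accepted CMs; (2) a functional
dependence test — one minus the correlation ratio of the candidate's
opening column against the accepted CM's ordering column, estimated from
adjacent pairs with duplicate-state clusters detected by sorted-value gaps
and scrambled before pairing.  Harmonics (e.g. the cos(3πx)/cos(6πx)
pair) are smooth functions of an accepted coordinate and score near 0;
genuinely new coordinates score near 1 (threshold 0.5).  Rule (2) is
needed because higher-order harmonics can be index-disjoint.

R² is the ordinary functional coefficient of determination of
y = ax² + bx + c.  In general-conic mode (CTF data, where trajectory ends
curl inward) the fitted coefficients come from the algebraic least-squares
implicit conic (smallest singular vector, unit coefficient norm), but the
reported score remains the functional R²: a Sampson/algebraic residual
score proved non-discriminative as a gate (amorphous blobs fit implicit
conics well).

Misalignment repair searches one plane per CM pair — the cross pair of
eigenvector indices closest in spectral order, where near-degeneracy
drives mixing (an `all_cross` mode searches all four).  For each candidate
angle on a 1° grid in [−90°, 90°), the affected CM subspaces are rotated
and their 2D histograms (40×40 bins, bounding box frozen at θ = 0)
counted; the angle minimizing the summed number of occupied bins is the
counter-rotation (aligned parabolas are thin, mixtures smear).  An
operator that worsens any CM fit by more than 0.01 in R² is reverted.

Detection runs at a permissive threshold (0.2) so that mixed subspaces can
be found and repaired; the acceptance gate (0.7) applies to the
post-realignment fits.

## Partitioning

Each CM eigenvector is rescaled to [−1, 1] and arccos-mapped, which
linearizes the traversal rate.  The rescaling uses the 5% quantile range
by default (0 for noiseless data): minmax rescaling of noisy extremes
stretches the range and compresses the end states.  Points clamped to the
frame by the quantile are excluded from the outline (they rejoin at
assignment).  The cloud is outlined by an alpha shape — Delaunay triangles
kept below a circumradius threshold, with the largest alpha giving one
simple hole-free polygon covering ≥ 99% of points found by binary search;
for sparse near-1D clouds, whose triangle unions only connect after
filling the concavities, a union of point discs is used instead, and the
convex hull is the last resort.  The polygon is closed and simplified
(fractions 0.04/0.01 of the bounding-box diagonal) to remove noise
scallops.

An absolute-value fit y = a|x − h| + k locates the cloud's symmetry axis
and vertex.  The ray anchor is placed on the axis, on the side where the
polygon is star-shaped around it (probed at the vertex: the open alcove
for thick bands, the apex side for filled sparse clouds), offset by 10% of
the cloud height and doubled until (a) the polygon's angular span from the
anchor stays below 93% of a full turn and (b) rays to (almost all)
boundary vertices cross the boundary exactly twice, with small secondary
clips tolerated.  The angular window is the complement of the largest
angular gap of the densified boundary.  Equal-area cuts are found by
bisection to 0.1% of total area; points are assigned by polygon
membership (boundary ties to the lower bin, strays to the nearest bin).
Bin averages of the raw images form the 2D movie; an SVD filter keeps the
top-k singular triplets of the frame matrix.

## Compilation

In synthetic runs CM identity and sense per PD are set by the maximal
|Spearman correlation| of bin index against each true state coordinate
(`ground_truth` mode); for real data a reference-PD occupancy-profile
correlation is provided instead of the out-of-scope optical-flow/belief
propagation machinery.  A PD whose top two correlations differ by less
than 0.05 is flagged ambiguous — such subspaces are irreparable mixtures
of two motions — and is excluded from occupancy compilation (its images
remain available for per-state export).  Gated, sense-corrected bin
indices are intersected into the n-D occupancy map; ΔG = −kT ln(n/n_max)
with empty cells masked and kT = 1.  Per-state stacks are exported as MRCS
plus STAR alignment tables for external reconstruction; a Fourier shell
correlation utility (0.143 criterion, linear interpolation between unit
shells) compares map pairs.

## Problem sizes and determinism

The recovery study runs at M = 20, τ = 10, SNR 0.1, 8 Fibonacci-hemisphere
PDs (4000 images per PD) and completes in a few minutes on one CPU; the
non-uniform-occupancy study uses three informative PDs at τ = 5, SNR 0.5
with CTF.  The test suite runs the recovery study once at a fixed seed;
the acceptance script re-runs it at the caller's seed.  All stochastic
steps are seeded (including the Lanczos start vector), so repeated runs
are bit-identical.

## Known limitations

* Assignment accuracy saturates at roughly ±1 bin per motion at SNR 0.1,
  τ = 10 (per-image embedding coordinate noise); jointly about 60% of
  images land within the 8-neighborhood of their true two-motion cell,
  and boundary states are systematically compressed inward — the same
  boundary degradation appears in the corner cells of the occupancy map.
* PDs viewing nearly along a motion's displacement see a weak, sometimes
  irreparably mixed geometry; the R² gate and the ambiguity flag exclude
  them, so the occupancy map is built from the informative subset of PDs.
* The equal-area premise (area along the trajectory proportional to state
  coverage) is exact for uniform rates; strong PD foreshortening bends it,
  which is visible as occupancy warp from oblique views.
* The histogram angle search assumes the mixing is confined to the
  searched planes; steric-coupling scenarios needing many operators are
  out of scope.
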