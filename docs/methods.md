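# Methods

## Model and estimators

A membrane sheet is an observation window `W = [x0,x1] × [y0,y1]` (nm) of
area `A`, carrying one or two point populations of immunogold coordinates.
The univariate second-order statistic is the K-function estimator

    K(r) = A n⁻² Σ_{i≠j} w_ij 1(‖x_i − x_j‖ ≤ r),

evaluated on a 1-nm grid, default 1–240 nm, with the variance-stabilized
form `L(r) − r = √(K(r)/π) − r` (0 under CSR, positive for clustering).
Note the `n⁻²` normalization, which this package keeps deliberately (it is
the convention of the immunogold EM literature); the textbook unbiased
normalization is `1/(n(n−1))`, so under CSR the expectation of this
estimator is `((n−1)/n)·πr²` rather than `πr²`, and the mean of `L(r) − r`
under CSR carries a small negative offset (≈ −0.2 nm averaged over
r = 10–110 nm at n = 170). Tests assert against the estimator's exact
expectation.

Edge effects are corrected with Ripley's isotropic correction: `w_ij` is the
reciprocal of the fraction of the perimeter of the circle centred at `x_i`
with radius `d_ij` that lies inside `W`, computed in closed form for
rectangles (per-edge arc deficits `2·arccos(e/d)` with adjacent-corner
overlaps `arccos(e1/d)+arccos(e2/d)−π/2` removed when `e1²+e2² < d²`).
Coincident particles (`d = 0`) are legal and carry weight 1. A toroidal
alternative (wraparound distances, unit weights) is provided and is the
right choice where exact label-swap or particle-average symmetries are
required; under isotropic correction those symmetries hold only
approximately (≤ 1% relative on interior-dominated patterns).

The bivariate (cross) statistics for big (`n_b`) and small (`n_s`) gold are

    K_bs(r) = A (n_b n_s)⁻¹ Σ_{i∈b} Σ_{j∈s} w_ij 1(d_ij ≤ r),
    K_sb    = roles (and weight centres) swapped,
    K_biv   = (n_b + n_s)⁻¹ (n_b K_sb + n_s K_bs),
    L_biv(r) − r = √(K_biv/π) − r.

With toroidal weights `K_bs ≡ K_sb` exactly, and `K_biv` is invariant to
swapping the species labels.

## Monte Carlo envelopes and standardization

Clustering significance is referred to pointwise Monte Carlo envelopes:

* univariate null: CSR — the image's own `n` redrawn uniformly in its
  window; envelope = pointwise 99th percentile of `L(r) − r` across
  simulations (default 1000, minimum 100 enforced).
* bivariate null: spatial independence — by default random toroidal shifts
  of the small population (uniform shift vector with wraparound, big
  fixed), which preserves each species' internal clustering and destroys
  only the cross-correlation; CSR resampling of both populations is
  available as an option. Envelope = pointwise 95th percentile.

Percentiles use linear interpolation between order statistics; every
envelope records its simulation count, null model and seed. The observed
curve is divided by the envelope pointwise, so 1.0 is the significance
boundary at every r. Where the envelope drops below a floor of 10⁻³ nm
(which happens as r → 0, where the null statistic collapses to −r plus a
vanishing spread), the standardized value is flagged undefined (NaN) rather
than divided, and summaries exclude those points; the Lmax search therefore
starts at 10 nm by default.

Summaries:

* **Lmax** — maximum of the standardized univariate curve over
  [10, 240] nm; ties broken toward smaller r (first attainment);
  significant iff strictly > 1.
* **LBI** — trapezoidal integral of the standardized bivariate curve on the
  1-nm grid over the fixed range [10, 110] nm, endpoints included, chosen so
  the unit boundary curve integrates to exactly 100; significant iff > 100.
  Negative standardized values (segregation) integrate as-is and lower LBI.
  Undefined grid points inside the range are an error, never interpolated.

Studies analyze each sheet independently — its own envelope matched to its
`n` and window — and pool Lmax or LBI as mean ± SD (sample SD, ddof = 1; a
single sheet reports SD 0 with a warning).

### Calibration of the significance calls

The pointwise envelope construction calibrates the *per-radius* test: the
measured exceedance of the estimated 99% envelope at a fixed r under CSR is
~1%. Lmax, however, maximizes over ~230 grid radii, so the *per-image*
probability that a CSR sheet is called significant is much higher — measured
at ~0.30–0.40 at n = 170, n_sim = 1000. This multiplicity inflation is
intrinsic to pointwise envelopes (it is the standard motivation for global
rank envelopes, which are out of scope here); Lmax should therefore be read
as a graded summary of clustering strength across sheets, not as a
single-sheet 1% test. LBI, being an integral rather than a maximum,
calibrates close to its nominal level: ~5% of independent two-species
sheets exceed 100.

## Oligomer classification

Local curves `K_i(r) = A (n−1)⁻¹ Σ_{j≠i} w_ij 1(d_ij ≤ r)` (note the
particle-average identity: with toroidal weights, mean_i K_i equals the
global estimator times `n/(n−1)` because the global uses `n⁻²`) diagnose
each particle's clustering scale. The partition itself is single-linkage:
an edge joins particles within a link radius, connected components are
oligomers, and fractions are reported per particle (share of labels in
components of size 1 / 2 / ≥3).

The link radius can be supplied, or chosen from the data as the radius of
the standardized global peak clamped to [10, 50] nm, with a 30 nm fallback
for non-significant patterns (roughly primary antibody + gold conjugate
reach on both partners). For mixtures with intra-cluster spacing `s` and
per-particle labelling jitter SD `σ`, the balanced choice is
`s + √2·σ` (one SD of the relative displacement beyond the spacing): smaller
radii split true dimers, larger radii coalesce unrelated clusters. At the
default simulation conditions (spacing 12 nm, jitter 3 nm, 170
particles/μm²) that balance point is ≈ 17 nm, where the *replicate-averaged*
per-class fractions are recovered within ±0.06 over 20 seeds. Per-sheet
worst-case recovery within ±0.1 is **not** achievable at this density with
single-linkage (chance coalescence alone affects ~15% of particles at
r ≈ 17 nm), which is why recovery is stated, tested and should be reported
on pooled fractions — matching the mean ± SD pooling used everywhere else.

## Synthetic generators

All generators take a seed (NumPy `SeedSequence` spawning for per-image
streams), emit exactly the requested counts inside the window, and return
truth metadata (cluster ids, linked pairs) for recovery tests. Defaults
emulate realistic immunogold labelling: 1000×1000 nm sheets, ~170
particles/μm².

* CSR: uniform points.
* Oligomer mixture: anchors uniform; members on a randomly rotated regular
  polygon of side `spacing` (dimer = segment, trimer = equilateral
  triangle, …) plus isotropic Gaussian jitter; anchors resampled when a
  member would leave the window (bounded retries).
* Thomas process: uniform parents, Poisson(`mean_offspring`) offspring,
  Gaussian(`sigma`) displacement, wrapped toroidally to keep counts.
* Two species: `independent` (two CSR draws), `linked` (a chosen fraction
  of small particles placed at `link_distance` from distinct big partners,
  orientation re-drawn if the position would leave the window; remainder
  CSR), `segregated` (disjoint half-windows).

What the generators do **not** model: gold-particle steric exclusion,
labelling efficiency < 1, antibody-linkage geometry beyond isotropic
jitter, membrane curvature, pixel quantization, or image segmentation
errors. Passing recovery tests therefore demonstrates correctness of the
estimators and the classification logic under the stated point-process
assumptions, not robustness to those experimental artifacts.

## Proximity-set computations

Prey identity is the identifier string, trimmed and upper-cased; no
orthology mapping. SAINT filtering keeps prey with SS ≥ threshold
(inclusive boundary; defaults 0.7 for BioID-style lists, 0.9 conventional
for FLAG-MS). Overlap between sets is asymmetric —
`100·|a∩b|/|a|`, "the share of a's prey found in b" — and undefined for an
empty reference set. Venn partitions enumerate all 3 (two-set) or 7
(three-set) exclusive regions, which always sum to the union. Fold changes
are plain ratios over a positive control value, with an `n-fold` label
rounded to the nearest integer.

## Numerical and interface choices

* Grid: strictly increasing, unit spacing, float nm; pair distances are
  binned by `searchsorted(..., side="left")` so a pair at exactly r is
  included at r.
* Windows default to the axis-aligned bounding box when a table supplies no
  bounds — supply the true sheet window whenever known.
* Species mapping on read: the label with the larger numeric prefix
  ("6nm" > "2nm") is the big population; lexicographic fallback.
* Determinism: every stochastic operation takes a seed or Generator;
  studies spawn per-image child streams, so results are independent of
  image order only in the sense that each image's analysis is reproducible
  under the same position in the list. CLI runs without a seed generate,
  log and manifest one.
* Degenerate inputs: n < 2 (univariate), an empty species (bivariate) and
  n_sim < 100 raise typed errors; zero-distance pairs are accepted.

## Problem sizes in the test suite

Unit and property tests run envelopes at 100–200 simulations and patterns
of 20–200 points, calibration smoke tests at 10–25 seeded replicates, and
the acceptance checks at the full 500–1000 simulations with n = 170 —
sizes chosen so the whole suite completes in about a minute while the
Monte Carlo assertions retain comfortable margins.

## Known limitations

* Pointwise (not global) envelopes: Lmax per-image significance is
  anti-conservative under the null (see calibration above).
* The `n⁻²` estimator's small negative CSR offset in `L(r) − r`.
* Single-linkage oligomer calling is density-limited: chance coalescence
  grows as `1 − exp(−λπr²)` and dominates per-sheet errors above ~150
  particles/μm².
* Isotropic correction assumes rectangular windows; irregular sheet
  outlines are not supported.
* 2-D analysis only; membrane topography is projected away.
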