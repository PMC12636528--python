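# Methods

This note documents the models implemented in `perchmatch`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make the pipeline
deterministic.

## Viewer model and pattern metrics

The observer is a violet-sensitive tetrachromatic bird (parameterized for
the laughing kookaburra, a widespread predator of the study species):
cone peak sensitivities LW 610, MW 545, SW 475, VS 415 nm with a double
cone at 560 nm, spatial acuity 41 cycles/degree, viewing distance 5 m,
Weber fraction 0.05 for both chromatic channels and luminance, and a
floor of 0.001 replacing non-positive cone catches. Cone-catch images are
taken as input; building spectral sensitivities from the λmax values is
out of scope — the generator plants catch values directly.

**Acuity correction.** One resolvable cycle (1/41°) at 5 m spans
s = 5000 mm · (π/180)/41 ≈ 2.128 mm at the object plane. Each channel is
blurred with an isotropic Gaussian of FWHM = s (σ = FWHM/2.3548),
reflective boundaries; the symmetric extension plus a normalized
symmetric kernel preserves channel means to machine precision. Kernels
below one pixel degrade to the identity with a warning, so coarse-scale
images pass through unchanged.

**RNL distances.** Chromatic distance uses the standard log-linear
receptor-noise form over the four single-cone channels with per-channel
noise e_i = w/√(abundance_i/max abundance); equal abundances are the
default because only the Weber fraction is known, and the abundance
weights are exposed on `ViewerModel`. Luminance distance is
|ln(a/b)|/w on the double cone, the usual convention for VS-bird models.
Distances are symmetric, non-negative, zero only for equal log-contrasts,
and invariant to common scaling of both stimuli.

**Segmentation.** Agglomerative two-stage merging: stage 1 merges
4-adjacent regions while the chromatic *and* luminance distances between
region means stay below the thresholds θ_color and θ_lum (default 3.0 JND
each; the thresholds are stated to exist in the field protocol without
printed values, so they are configurable); stage 2 merges
indistinguishable cluster means regardless of adjacency so that disjoint
patches of one color share a cluster. Merge order is lowest combined
distance first (combined = max of the threshold-scaled distances), ties
broken by lowest label; together with the raster-order relabeling this
makes the segmentation fully deterministic. Patch counts use
4-connectivity (8-connectivity is available on `cluster_stats`).

**Edge intensity.** Per pixel, the maximal chromatic and luminance RNL
contrast toward the neighbors along the four directions (horizontal,
vertical, two diagonals — both neighbors per axis, which makes the metric
invariant under 90° rotations), averaged over ROI pixels with at least
one in-ROI neighbor, computed on the filtered, unsegmented image.

**Secondary statistics.** The analysis uses twelve descriptors spanning
three families: color adjacency (Shannon diversity of cluster area
proportions, its evenness, Shannon diversity of off-diagonal boundary
transitions, horizontal:vertical transition ratio), visual contrast
(area-weighted mean pairwise chromatic/luminance contrast and their CVs),
and boundary strength (the same contrasts weighted by shared boundary
length). The exact twelve used in the original field protocol are defined
in supplementary material that is not redistributable, so this set is a
documented stand-in with the same family structure and count; it is the
single place where the package substitutes its own definitions, and the
set is isolated behind `secondary_stats` so it can be replaced. Edge
cases are pinned: a single-cluster ROI yields zero diversities, contrasts
and CVs, evenness 1 and transition ratio 1; a zero vertical-transition
count makes the ratio equal the horizontal count.

## Component spaces

Cluster (number of clusters, total patch count, largest-cluster area in
mm²), edge (chromatic, luminance edge intensity) and visual model — PC1–3
of the twelve secondary statistics. The PCA is fitted on lizard and
background rows jointly: lizard-background distances only make sense in a
shared space. Variables are centered and scaled (sample SD); loadings get
a deterministic sign (largest-magnitude entry positive). Component
support uses a permutation test: each column independently permuted
(default 999 times), observed eigenvalues compared with the null 95th
percentiles. The permutation operates on column-sorted values with
per-column spawned seed streams, which makes the null exactly invariant
to input row order without changing its distribution. Three components
are always retained for the pipeline, with support flags reported, so the
downstream geometry is stable even when synthetic data support fewer.

Distances and hulls are computed on z-scored coordinates by default: the
cluster variables mix counts and mm² areas of incommensurate magnitude,
and standardization makes the three spaces comparable. `raw` mode is
provided for sensitivity analysis since the original protocol does not
state its convention.

## Matching and diversity statistics

The optimal background is the argmin of the Euclidean distance to the
lizard, ties broken by lowest background id and flagged. The proportion
test across clades is the Pearson k-sample chi-square on the 2×k table
without continuity correction (df = k−1).

All responses — d(L,P); d(P,O*) on the subset of lizards not already on
the optimal background; log10 hull measure — share one factorial
machinery: Gaussian GLM of sex + habitat + clade + SVL + sex×habitat +
sex×clade. Interactions are tested first by sequential (Type I) deviance
tests; if at least one is significant at α = 0.05, non-significant
interactions are dropped and all terms are tested by Type III sums of
squares under sum-to-zero contrasts (required for interpretable Type III
marginal tests); otherwise interactions are dropped and main effects are
tested by Type II. Type I rows report the deviance drop with an F-based
p-value under the estimated dispersion; Type II/III rows report
SS/dispersion as a chi-square statistic. Default response transforms:
log10 for edge and visual distances, none for cluster d(L,P), square root
for cluster d(P,O*), log10 for all hull measures. Degenerate hulls
(fewer than d+1 points or affinely dependent, e.g. coplanar 3D points)
have measure 0, are excluded from the log-scale GLM, and their count is
reported. Estimated marginal means average model predictions over the
levels of the non-target factors with SVL at its mean; pairwise contrasts
within a conditioning factor are Holm-adjusted (a conservative default
since the original protocol reports adjusted contrasts without naming a
method).

## Range-wide comparisons

The full lizards × backgrounds matrix includes each lizard's own
backgrounds (the crossing is complete by design: 52 × 309 = 16,068
distances per space at the default design). Per-lizard per-location means
(±SE; 52 × 7 = 364 points) form 3D points (one mean per space) compared
between groups with two-sample Hotelling's T²,
T² = (n₁n₂/(n₁+n₂))·Δx̄ᵀS⁻¹Δx̄, reported in its large-sample chi-square
form (df = p) for the heat maps, with the exact-F version carried
alongside. Pairwise tests over clades, habitats and locations are
Bonferroni-adjusted by default; groups smaller than p+2 are flagged
untestable rather than silently dropped. The within-vs-outside summary
flags locations whose lizards are closer to backgrounds elsewhere than to
their own — the signature of a locally mismatched background pool.

## Synthetic-data generator

The generator emulates the survey design: 52 lizards over 7 named
locations (8+8 in clade A, 6 in B, 8+9+8 in C, 5 in D, matching the field
tally), one clade and one habitat class per location, snout–vent length
uniform on 70–120 mm, 6 backgrounds per lizard of which one is the perch,
and 3 background images removed as corrupted — never a perch, and never
the last alternative of a microhabitat.

Metrics are drawn hierarchically from normals floored at family minima
(cluster counts ≥ 1, areas > 0): species mean → random location offset
(shared by a location's lizards and backgrounds, which is what produces
location-level clustering in the range-wide stage) → lizard vector →
background vectors centered on their lizard. The per-microhabitat
background *spread* is the single planted-effect dial: its log responds
linearly to standardized SVL and to factor-selector offsets (e.g.
`{"sex": "M", "clade": "D"}`), so a planted group contrast moves d(L,P),
d(P,O*) and hull diversity together with a common sign. A
`mismatched_location` option shifts one location's backgrounds away from
its lizards by a fixed number of species SDs to plant the
outside-closer-than-within signature. Perch rules: `random` (default),
`optimal` (the perch is a near-copy of the lizard's pattern, hence the
distance minimizer in every space), `kth_closest`.

Defaults (means/SDs per metric, location scatter 0.6 SD, lizard scatter
0.5 SD, unit background spread) are plausible magnitudes for the metric
families, chosen once as the study conditions; the field protocol
publishes no metric distributions, so they are placeholders rather than
estimates. What the generator does **not** emulate: metrics are drawn
directly rather than extracted from rendered images (the image chain is
validated separately on planted-pattern scenes), metrics are continuous
(no count integrality), independent across families given the hierarchy,
and corruption is uniformly random. Passing tests therefore demonstrate
that the *pipeline* is correct and calibrated — not that real lizards
behave like the generator.

The planted-pattern scene generator is the image-side counterpart:
non-overlapping rectangular patches with exact areas and ≥1 px separation
on a uniform background, with the label map, per-color patch counts,
areas and catch values recorded as ground truth.

## Numerical choices and problem sizes

- Segmentation thresholds 3.0/3.0 JND; merge order and tie-breaks fixed
  as above; all randomness flows through explicit integer seeds
  (`numpy.random.default_rng`), and the run manifest records config and
  seeds so outputs are byte-reproducible.
- PCA permutation default 999; permutation counts below 99 warn.
- Calibration checks use 100 replicates at n = 200 (GLM terms, pairwise
  Hotelling) and 40 replicates × 199 permutations (PCA support);
  effect-recovery checks use one synthetic study of 500 lizards per
  planted effect. These sizes give stable nominal-rate estimates while
  keeping the full suite fast.
- Monte-Carlo hull validation uses membership sampling in the bounding
  box (10⁶ samples at 1% tolerance on random 6-point sets).

## Known limitations

- The twelve secondary statistics are a documented stand-in (above).
- The pixel-level agglomerative segmentation is quadratic-ish in ROI
  size; it is intended for desk-scale ROIs (≲ 10⁴ pixels), not full-frame
  field photographs.
- Type III tests rely on sum-to-zero contrasts and balanced-enough cells;
  empty factor cells are flagged, not imputed.
- The chi-square form of Hotelling's T² is anticonservative for small
  groups; the exact-F p-value is reported alongside and should be
  preferred when group sizes are near p+2.
- Hulls and distances share one standardization; analyses on raw
  coordinates are available but not the tested default.
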