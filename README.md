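# perchmatch

Viewer-corrected pattern metrics and background-matching statistics for
camouflage field studies of patterned animals.

## The problem

Field studies of background matching ask whether cryptic animals occupy
the backgrounds that best resemble their own color pattern, how much the
available backgrounds vary within a microhabitat, and whether the degree
of matching differs across a species' range. `perchmatch` implements that
entire analysis chain for a survey design in which each animal (here, a
semi-arboreal agamid lizard) is photographed together with its occupied
background ("perch") and several alternative backgrounds nearby, across
multiple locations spanning genetic clades and habitat types, all scored
through the visual system of an avian predator.

The pipeline has five stages:

1. **Pattern metrics** (`perchmatch.visionmetrics`). Cone-catch images
   (5 channels: LW, MW, SW, VS, double cone) are floored, blurred to the
   predator's acuity at the viewing distance (Gaussian with object-plane
   FWHM = d·(π/180)/acuity; 41 cpd at 5 m ⇒ ≈ 2.13 mm), segmented into
   color clusters by receptor-noise-limited (RNL) agglomerative merging,
   and summarized as cluster statistics, local edge intensity, and twelve
   secondary color-pattern statistics (color adjacency, visual contrast,
   boundary strength). Chromatic distance follows the log-linear
   receptor-noise model, ΔS² = Σ_{i<j} (Πe/e_i e_j)²(Δf_i−Δf_j)² / Σ_i (Πe/e_i)²
   (JND units), luminance distance is |ln(a/b)|/w on the double cone.
2. **Component spaces** (`perchmatch.spaces`). Each ROI becomes three
   vectors: cluster (3D), edge intensity (2D), and visual model — the
   first three principal components of the twelve secondary statistics,
   with permutation-based component support.
3. **Matching** (`perchmatch.matching`). Euclidean distances d(L,P) and
   d(L,O) within each microhabitat, the optimal (closest) background,
   Pearson proportion tests of optimal-background use by clade, and
   factorial Gaussian GLMs (sex, habitat, clade, SVL, sex×habitat,
   sex×clade) with the Type I → Type II/III sums-of-squares decision rule
   and estimated-marginal-mean contrasts.
4. **Diversity** (`perchmatch.diversity`). Convex-hull volume/area of each
   microhabitat's background options as a background-diversity measure,
   with the same GLM machinery.
5. **Range-wide** (`perchmatch.rangewide`). The full lizards × backgrounds
   distance matrix per space, per-location mean points, and pairwise
   Hotelling's T² comparisons (large-sample chi-square form) between
   clades, habitats and locations, plus within- vs outside-location
   matching summaries.

Because the field data themselves are not redistributable, the package
ships a first-class synthetic-study generator
(`perchmatch.synthgen`) that emulates the survey design — 52 lizards,
7 locations, 4 clades, 2 habitat classes, 6 backgrounds per lizard with 3
lost to file corruption — with controllable planted group effects, so
every statistical stage can be exercised and validated end to end.

## Worked example

```python
from perchmatch.pipeline_io import RunConfig, run_pipeline

cfg = RunConfig(seed=1, n_perm=499, outdir="out")
bundle = run_pipeline(cfg, write=False)

ds = bundle["dataset"]
print(f"lizards: {ds.n_lizards}, usable backgrounds: {ds.n_usable_backgrounds}")

oc = bundle["optimal_calls"]["cluster"]
print(f"on optimal background (cluster space): {oc['on_optimal'].sum()}/{len(oc)}")

print(bundle["proportion_tests"][["space", "chi2", "df", "p"]].to_string(index=False))
```

prints

```
lizards: 52, usable backgrounds: 309
on optimal background (cluster space): 11/52
  space     chi2  df        p
cluster 1.077664   3 0.782469
   edge 1.247262   3 0.741693
 visual 1.319205   3 0.724578
```

With the default (effect-free) generator, 11 of 52 synthetic lizards sit
on their best-matching background in cluster space — close to the 1-in-6
chance expectation for six interchangeable options — and the chi-square
proportion tests (df = 3, one per component space) find no clade
differences, as they should under the null. The matching GLM term tables,
hull-diversity GLMs, Hotelling heat maps and within/outside summaries are
in the same bundle (and are written as TSV files when `write=True`).

The same pipeline is scriptable from the shell:

```sh
perchmatch all --seed 1 --outdir out        # every stage, all TSV outputs
perchmatch simulate --seed 1 --outdir out   # just the synthetic metric table
perchmatch metrics image_dir/ --outdir out  # metric rows from cone-catch TIFFs
```

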