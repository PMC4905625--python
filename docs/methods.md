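# Methods

## Scope and model

`tuberhist` re-implements, as a tested pipeline, a quantitative
histopathology workflow for epilepsy-surgery tissue from Tuberous
Sclerosis Complex (TSC): semi-automated quantification of DAB
immunohistochemistry on slide scans, a deterministic classifier that
assigns each cortical tuber one of three histological types (A/B/C), Ward
clustering of the marker features that originally revealed those types,
and the supporting statistics battery. Because no slide archive ships with
the package, a synthetic-data module generates slide phantoms and cohort
feature tables with exact ground truth; every downstream stage is
validated against that truth.

## Image quantification

All measurements assume 8-bit RGB slide scans at a known resolution
(default 0.64 µm/pixel, the resolution of the original scans).

**Tissue segmentation.** A pixel is tissue when its luminance (mean of the
three channels) falls below a background cutoff (default 240); the mask is
morphologically closed (3×3) and components under 64 px are discarded as
debris. Tissue area in mm² is the pixel count times `res² × 10⁻⁶`. The
original analysis used a proprietary "smart segmentation" tool; this
luminance rule is the package's own re-specification and recovers phantom
tissue masks to < 2 % symmetric difference.

**DAB positivity.** The chromogen (3,3′-diaminobenzidine) absorbs strongly
in the blue channel, while the hematoxylin counterstain is blue-dominant.
A pixel is positive iff it lies in tissue, its blue value is at or below
the marker's brightness threshold, and red > blue. The red > blue guard is
this package's replacement for the original (unavailable) colour
segmentation recipe; thresholds below the cutoff select *dark* pixels, the
natural reading for a dark chromogen. Positivity is monotone in the
threshold by construction.

**Counting and densities.** Counted markers use the published per-stain
blue thresholds (NeuN 120; CD3, SMI32, Olig2 100; CD34 150) and pixel-area
gates (NeuN 120–2500; CD3 20–155; Olig2 20–155 surgical / 5–120 autopsy;
CD34 100–unbounded; SMI32 750–5000). Components are 8-connected (the
connectivity was not specified originally; 8-connectivity is the common
choice for blob counting). Density is count per mm² of segmented tissue.
Giant cells (vimentin) carry no published gate; they share SMI32's
large-cell gate (750–5000 px), both being large-soma populations. A
field-based protocol (10 fields of 1.081 mm²) is provided for manual
giant-cell counts.

**Area and optical density.** Area markers (pS6, GFAP, Cr3/43) report the
positive-area percentage of tissue with no size gate. Per-pixel optical
density is `−log10((L + 1)/256)` with `L` the luminance; the reference 256
with a +1 offset avoids log(0) and makes a blank (255) pixel exactly OD 0.
Whether the original software measured OD on luminance or a single channel
is unknown; luminance is used. Blank-slide background correction is not
modelled. The overall myelin content is the exact product
`OMC = MBP area % × mean OD`; this identity holds for every emitted
result. Zero tissue area makes fractions and densities *undefined* (NaN
plus a warning), never silently 0.

## Classification

With `g` the giant-cell density (vimentin, /mm²), `d` the
dysmorphic-neuron density (SMI32, /mm²) and `c` the H&E calcification
score:

* type C iff `c` (calcification is the unique discriminator named for the
  calcifying pattern; it takes precedence),
* else type B iff `g > 10` or `d > 3`,
* else type A (so A requires both `g ≤ 10` and `d ≤ 3`).

The published low/high criteria each use "or", which does not partition
mixed inputs (one density high, one low); resolving "B if either exceeds"
makes the rule total and exclusive and treats B as the higher-grade
pattern. The boundary is inclusive for A. Perituberal cortex is defined by
`g = d = 0` and no calcification. Calcification enters as an eye-scored
binary input, as in the original workflow — it is not detected from
images.

## Clustering

The pattern-discovery step clusters three features (pS6 area %, SMI32
density, vimentin density). Because these distributions are left-skewed,
each value is transformed to `ln(x + ε)` with `ε = 10⁻³` (zero densities
occur in perituberal samples; the offset keeps them finite while
preserving rank order). Columns are then z-standardized — without this, a
count-scale column would dominate squared Euclidean distances over a
percentage-scale one — and agglomerated by Ward's minimum-variance method.
The cluster count `k` is a parameter (default 3); an automatic selector is
reported separately: it cuts the dendrogram at the largest *relative* gap
between consecutive merge heights (equivalently the largest gap on log
heights), for cuts giving 2..10 clusters, smaller k on ties. The relative
gap was chosen over the absolute gap after benchmarking both on planted
Gaussian clusters: the absolute gap is scale-dependent and collapses to
k = 2 on unbalanced three-cluster data (correct in only 55–99 % of runs
depending on geometry), while the relative gap is invariant to the
height scale (so it agrees whether heights are Euclidean or squared
Euclidean) and recovered the planted count in 87–100 % of runs without
losing accuracy on true two-cluster data.

Per-feature one-way ANOVA across cluster labels reports F, (between,
within) degrees of freedom and the F-distribution p-value; groups need at
least two members.

A caveat of z-standardization: a clustered column carrying *no*
between-group signal is rescaled up to unit variance and acts as pure
noise of the same magnitude as the signal columns, which can break exact
recovery even of widely separated clusters. This is inherent to mixing
measurement scales and is documented rather than patched.

## Statistics battery

* **Kruskal–Wallis** on mid-ranks with tie correction (`H = 0`, `p = 1`
  when all observations are identical and the tie-correction denominator
  vanishes); df = groups − 1; chi-square approximation for p.
* **Pairwise post hoc**: Dunn's z statistics on the joint ranking with tie
  correction; the original report says only "pairwise comparison", so both
  the unadjusted and Bonferroni-adjusted p are reported.
* **Kendall tau-b** with tie handling and the asymptotic normal p.
  **Partial Kendall correlation**
  `τ_xy·z = (τ_xy − τ_xz τ_zy) / √((1 − τ_xz²)(1 − τ_zy²))`; its p-value
  applies the plain-tau normal approximation to the partial coefficient —
  an approximation, flagged as such in the docstring.
* **Chi-square**: Pearson X² without continuity correction (the original
  reports a plain chi-squared test); zero marginals are rejected.
* **Inter-rater kappa**: Cohen's kappa for two raters, Fleiss' kappa for
  more. Interpretation bands are lower-inclusive: < 0.2 poor, 0.2–<0.4
  fair, 0.4–<0.6 moderate, 0.6–<0.8 good, 0.8–1.0 very good. If every
  rater assigns one identical category throughout, expected agreement is 1
  and kappa is undefined; observed agreement is perfect, so 1.0 is
  returned with a `degenerate` flag.
* **BCa bootstrap** (default B = 1000, level 0.95): bias correction z₀
  from the fraction of resample statistics below the observed value (ties
  counted half), clipped to (1/(B+1), B/(B+1)); acceleration from
  jackknife skewness; degenerate resample distributions collapse to a
  point interval with a warning. Deterministic under a seed.

## Synthetic data

**Slide phantoms** emulate the appearance a DAB/hematoxylin slide presents
to the measurement code — not photorealistic histology. Tissue is a
centred rectangle covering the requested fraction of the frame, painted a
pale, slightly basophilic base (blue ≥ red, luminance ≈ 223) on a
background of 250, with blue-dominant nuclei sprinkled at ~150/mm².
Discrete positive objects are random connected blobs of exactly the
requested pixel area, grown by stochastic frontier expansion and placed by
rejection sampling with a one-pixel guard band, so no two blobs touch even
diagonally — connected-component counting on the truth is therefore an
exact oracle. Object pixels are brown: blue = chromogen darkness (default
60), red/green offset above it. Diffuse positive stain selects random
tissue pixels to hit the requested area fraction exactly (to one pixel)
and paints them at the luminance matching the requested mean OD.
Calcifications are dense blue-purple blobs recorded in truth and never
image-detected. Stored truth (masks, counts, area fractions, mean ODs
recomputed from the rendered image) is exact by construction, and
rendering is bitwise deterministic in (spec, seed).

What phantoms do *not* model: staining batch effects, stain co-expression,
out-of-focus regions, tissue folds, pyramidal formats. Passing recovery
tests therefore demonstrates correctness of the measurement logic, not
robustness to real-slide artefacts.

**Cohorts.** Feature tables are drawn per group (A, B, C, perituberal,
control) from (median, low, high) triples. The marker rows use the
study's published per-group medians and ranges. Left-skewed features
(pS6, SMI32, vimentin — the trio the original analysis log-transformed)
are drawn log-normally with the configured median and σ chosen so the
2.5–97.5 percentile span matches high/low; other features are symmetric
normal draws clipped to [low, high]. Group-defining constraints are
enforced per draw: type A keeps vimentin ≤ 10 and SMI32 ≤ 3 /mm², type B
exceeds at least one, type C always calcifies (prevalence elsewhere 0 —
calcification is definitional for the pattern), perituberal and control
samples have no giant cells or dysmorphic neurons. SMI32 and vimentin
group levels are not tabulated in the source; the defaults (A: vim 3
(0.5–9), smi 0.8 (0.1–2.5); B: vim 18 (11–40), smi 6 (3.3–15); C: vim 60
(25–140), smi 18 (6–45)) were fixed once, a priori, to respect the
classifier cutoffs and to give the clearly separated patterns that the
reported near-perfect inter-rater agreement (κ = 0.973) implies. Clinical
covariates (age at surgery per group, epilepsy duration ≤ age, AED count,
FCD-like MRI flag, Engel score) are plausibility-level synthetic values.

Because the cohort generator draws OMC on the table's printed scale but
the image-derived OD is bounded by `−log10(1/256) ≈ 2.4`, cohort records
derive `MBP mean OD = OMC / MBP %` so the OMC identity holds exactly; the
unit mismatch reflects the original software's different OD scale and is
not reconciled.

## Problem sizes and numerical choices

Validation runs use phantom sides of 96–256 px, cohorts of 7/13/8 tuber
samples (the study's group sizes) plus 7 perituberal and 10 controls, 100
replicate cohorts for cluster-count recovery, 200 phantoms for
counter-oracle equivalence, 5000 null simulations for Kruskal–Wallis
calibration and 500 replicates (B = 1000) for bootstrap coverage — sizes
at which every oracle is exact or the Monte Carlo error is well below the
asserted tolerance. Bisection for the classifier boundary runs to 10⁻⁶ on
[0, 100]. Ties in agglomeration are broken by cluster index (scipy's
deterministic rule). All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give identical outputs,
including bitwise-identical phantom bitmaps and pipeline CSV/JSON
artifacts.

## Known limitations

* The positivity rule and tissue segmentation replace proprietary tools;
  absolute agreement with the original software is unverifiable, only the
  published thresholds, gates and derived statistics are.
* Under the committed cohort parameters the three tuber groups overlap in
  the clustered feature space: a forced three-cluster Ward cut reaches
  mean adjusted Rand index ≈ 0.74 against truth, and the automatic
  largest-gap cut finds exactly three clusters in about 81 % of replicate
  cohorts — replicates without clean three-cluster structure are a real
  feature of small-cohort clustering, not a selector defect.
* Partial Kendall p-values are approximate (see above).
* The cohort generator draws features independently within group; real
  marker correlations (e.g. pS6 with SMI32) are not modelled.
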