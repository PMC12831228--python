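# Methods

This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not emulate.

## Lifespan analysis

Cohorts record one row per animal: day of death or censoring and an
event flag. Lifespans are whole days (worm assays are scored daily);
same-day events are pooled into a single risk-set update. The log-rank
statistic accumulates observed-minus-expected deaths in the treated
cohort with the hypergeometric variance at each distinct event day and
refers (ΣO−ΣE)²/ΣV to χ²(1). Animals censored on day *t* count as at
risk at *t*. Per-replicate p-values are combined with Fisher's method
(−2Σln p ~ χ²(2k)); this assumes replicate independence, which holds
for distinct biological runs. A p of exactly 0 is rejected rather than
silently floored; callers may pass an explicit floor (default exposed:
1e-300).

"Mean lifespan" excludes censored animals (escapers and bagged worms
are conventionally dropped from means); percent extension is
100·(treated−control)/control on the pooled observed lifespans. Both a
pooled and a per-replicate-mean extension are computed; pooled is the
default because it weights animals equally when replicate sizes differ.

## Statistical primitives

* Welch's t-test (scipy) with explicit degenerate conventions: both
  variances zero and equal means → p = 1; unequal means → p = 0.
* One-way ANOVA with Tukey's HSD (statsmodels) for multi-group designs.
* Two-way group × bin ANOVA with Type II sums of squares
  (statsmodels); per-bin group comparisons (Welch for two groups,
  one-way ANOVA otherwise) are Bonferroni-corrected by the number of
  bins and flagged at α = 0.05. Type II is used because per-cell
  imaging designs are unbalanced by nature (7–15 cells per replicate).
  With a single bin the correction factor is 1, so the procedure
  reduces to the one-way comparison.
* Rank-sum test: below m+n ≤ 20 (configurable) the exact permutation
  distribution of the rank-sum statistic is enumerated over midranks,
  which remains exact under ties; above it, the normal approximation
  with tie correction. The exact limit is an enumeration-cost bound
  (C(20,10) ≈ 1.8×10⁵ combinations).
* Benjamini–Hochberg step-up for FDR (statsmodels), chosen as the field
  default where no procedure is named.

## ChIP-seq profiling

Coverage is held per base (float per chromosome); bedGraph I/O is
run-length compressed and exact. Coordinates are 0-based half-open; the
TSS of a minus-strand gene is the annotation end.

Depth scaling divides each track by its genome-wide **median** depth
(background scaling). The mean was considered and rejected: when
enrichment is confined to a minority of the genome in one condition,
mean scaling deflates every unenriched base of that track by the
enrichment mass, which a replicate test then detects as a systematic
genome-wide shift; the median is insensitive to minority enrichment.
Mean scaling remains available (`CoverageTrack.scaled(stat="mean")`).

The mark/H3 ratio uses a pseudocount ε = 0.5 on the denominator to keep
uncovered bases finite at the ~1 background level of scaled tracks.
Ratios, matrices and differential calls are invariant to multiplying
any input track by a positive constant (up to ε effects).

TSS matrices span ±1 kb in 50 bp bins (40 bins), reversed for
minus-strand genes so bin 0 is biological upstream; genes whose window
leaves the chromosome are dropped with a count. Metaprofile comparison
reports bin-wise mean curves, per-gene window means, group medians, and
an unpaired two-sample rank-sum test on the per-gene means; a paired
signed-rank option exists for matched gene universes (the unpaired form
is the default because gene universes may differ between matrices).

Differential sites are fixed 200 bp tiling windows (the genome is
covered exactly once; a short terminal window is kept). With ≥2
replicates per condition each window's per-replicate mean ratios are
compared by Welch's t-test; with one track per condition the
background-scaled window sums are rounded and compared with the exact
conditional binomial test (the Poisson-ratio test conditional on the
total). BH correction runs over all windows. A window is called at
p < 0.01 and q < 0.05 **and** |log2 ratio| ≥ 0.5. The effect-size floor
is deliberate: an FDR threshold admits false discoveries at its stated
rate by construction, so a minimum fold change — standard practice in
differential-binding analysis, and symmetric with the RNA filter's fold
change > 1.5 — is required for a site call; set `min_log2fc=0` to
disable.

## Integration funnel

Windows map to genes by ≥1 bp overlap with the gene body or the 1 kb
strand-aware upstream promoter interval (intervaltree); a multi-gene
window goes to all overlapping genes by default (a nearest-TSS mode
exists). The both-mark set is the exact intersection of me2-up and
me3-up genes, with all Venn regions reported. The RNA filter is strict:
fc > 1.5, p < 0.01, q < 0.05 (a gene at exactly 1.5 is excluded).

Promoters are upstream intergenic spans bounded by the nearest
annotated neighbor (any strand) or the chromosome edge; genes with
span > 1 kb are retained and the TSS-proximal 1 kb is scanned,
reverse-complemented for minus-strand genes. The scan covers the
proximal 1 kb rather than the full span, matching the eligibility rule;
full-span scanning would only add distal hits.

PWM scanning scores log2(p/background) on both strands; counts are
accepted and normalized with a small pseudo-probability (1e-6 floor) so
log-odds stay finite. The default threshold is 80% of the maximum
attainable score; "presence" is ≥1 hit per promoter, and the presence
count is the funnel's final number. **No published SKN-1 matrix ships
with the package** — the consensus used in examples and synthetic
scenarios (`GCATTTATCATG`) is an illustrative stand-in; real scans must
supply the user's matrix (`Pwm.read_tsv`, 4-row A/C/G/T).

## Radial profiling

Normalized radius r = d(pixel, center)/d(center, boundary along the
pixel's ray) maps any cell star-shaped about its nuclear center onto
r ∈ [0, 1] regardless of size or elongation; the boundary intersection
is computed exactly on the ROI polygon (vectorized segment
intersection), not on a rasterized mask, avoiding staircase bias. An
absolute mode bins by physical distance in μm via the scale-bar
calibration instead; both modes are provided because either convention
is defensible and they answer slightly different questions (shape-
normalized localization vs physical distance).

Pixels are binned into 20 equal-width r bins; empty bins are reported
as missing (NaN), never zero. Boundary pixels whose rasterized center
falls marginally outside the polygon are clipped to r = 1 and counted
(`n_clipped`), so the intensity-conservation identity
Σ(bin mean × bin count) = Σ in-ROI intensity holds exactly. No
background is subtracted by default (`background_percentile` opts in).

The nuclear center is the intensity-weighted centroid of the
Otsu-thresholded (within-ROI) nuclear channel; a centroid outside the
ROI (e.g. a bimodal mask) is an error, not a silent result. Group
curves average cells within each biological replicate first and report
mean ± s.e.m. over replicate means; per-bin comparisons use the cell as
the observational unit nested in replicate, via the two-way ANOVA +
Bonferroni primitive.

Profiles are exactly invariant under 90° rotation (up to float
summation order) and stable under integer upscaling to within
discretization tolerance (~5% at 2–3×).

## Synthetic data

Generators are pure functions of (spec, seed); child streams derive
from `SeedSequence(seed, spawn_key=(stream,))` with one fixed stream
number per generator. Every generator emits machine-readable truth.

* **Lifespans** follow a Gompertz law (shape 0.001, giving CV ≈ 0.20 —
  realistic worm mortality curvature; mean solved to 20 d for
  controls). A planted extension multiplies the treated time scale, so
  the mean shifts by exactly the planted percent before day-rounding;
  5% of animals are censored uniformly before their death day. Not
  emulated: plate effects, day-1 mortality excess, interval censoring.
* **Coverage** is per-base Poisson (30× default) for H3 and marks, with
  mark rate multiplied by the enrichment factor over TSS ± 1 kb of a
  planted gene subset in the treated condition, so the H3-normalized
  ratio carries the factor by construction. Genes sit on a 200 bp grid
  so planted regions align exactly with differential windows (a
  partially overlapping window has no well-defined truth label). Not
  emulated: mappability, GC bias, fragment-length smoothing,
  nucleosome positioning.
* **Counts** are negative binomial (mean 100, dispersion 0.1, 6 vs 6
  samples); the built-in DE table is a Welch test on log2(count+1)
  with BH. At the default planted fold change of 4 per-gene power is
  ~97–99%, so exact funnel recovery over a 10-seed batch occasionally
  misses one gene at the strict p < 0.01 cut — a property of the
  stated conditions, not of the implementation.
* **Promoters** are i.i.d. background (64% AT) with the consensus
  planted once per chosen promoter at a recorded position and strand;
  background is scrubbed of chance exact consensus occurrences so the
  planted subset is exact truth. At the 95%-confidence PWM and 80%
  threshold only perfect matches score above threshold.
* **Images** are 160×160 px with an elliptical 72-vertex ROI, a
  Gaussian nuclear blob, and an absent/uniform/nuclear/ring signal
  pattern under Poisson + Gaussian read noise (ring SNR ≈ 8 at
  defaults). Not emulated: PSF blur, z-structure, uneven illumination,
  touching cells.

Passing tests on these data show the algorithms recover planted
structure under idealized noise; they do not validate robustness to the
unmodeled artifacts above.

## Pipeline

One flat config (YAML or dict) selects stages and parameters; unknown
keys are fatal. All randomness derives from the config seed; two runs
of one config are digest-identical, and the manifest records version,
parameters and SHA-256 of every output.

## Problem sizes

Default study-scale conditions used throughout tests and the acceptance
script: 3 replicates × 90 worms (100 planted + 500 null simulations);
100 kb genome = 500 windows, 25 genes, 3 enriched, 3+3 replicates at
30×, 10 seeds; 36 promoters with 18 planted; 20 cells per planted ring
radius. These sizes make every recovery measurable while keeping a full
run around a minute on one CPU.

## Known limitations

* The differential-site caller is a fixed-window scan, not a peak
  caller; window boundaries straddling true enrichment edges dilute
  signal (the synthetic generator aligns regions to the grid; real data
  would not).
* The pooled (1-replicate) differential mode treats rounded scaled
  ratio sums as counts; it is a pragmatic fallback, not a replacement
  for replicates.
* Radial normalization assumes the ROI is star-shaped about the nuclear
  center; deeply concave outlines can yield r > 1 pixels (clipped and
  counted).
* The two-way ANOVA treats cells as exchangeable within groups apart
  from the replicate nesting used for s.e.m.; a mixed model is out of
  scope.
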