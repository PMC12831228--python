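# wormepi

A Python toolkit for the quantitative analyses behind *C. elegans*
transgenerational-longevity studies: replicate-combined lifespan
statistics, total-H3-normalized H3K79 ChIP-seq profiling with
differential-site calling, a ChIP × RNA × promoter-motif candidate-gene
funnel, and center-to-periphery radial fluorescence profiling of single
cells (e.g. −2 oocytes). A seeded synthetic-data layer generates inputs
with known ground truth for every stage, so the whole pipeline is
testable without any sequencing or imaging download.

It is written for researchers who run worm lifespan assays, histone-mark
ChIP-seq, and germline immunostaining, and want the figure-legend
statistics reproduced as auditable code.

## The statistics at the core

**Lifespan.** Each biological replicate pairs a treated and a control
cohort (~90 worms each). Per replicate, survival curves are compared
with the log-rank test: over distinct event days *t*,
χ² = (Σ(O₁ₜ − E₁ₜ))² / ΣVₜ with hypergeometric variance Vₜ, df = 1.
Replicate p-values p₁…p_k are combined with Fisher's method,
−2Σln pᵢ ~ χ²(2k). The headline summary is the percent mean-lifespan
extension, 100·(mean treated − mean control)/mean control, on
observed-event lifespans (censored escapers excluded). Kaplan–Meier
curves use the product-limit estimator.

**ChIP profiles.** Mark coverage (H3K79me2/me3) is depth-scaled to a
common background level, divided per base by total-H3 coverage plus a
pseudocount ε = 0.5, binned into ±1 kb windows around each TSS (40 × 50
bp bins, strand-oriented), and compared between conditions with a
rank-sum test on per-gene window means. Differential sites are fixed
200 bp tiling windows tested per window (Welch t on replicate means, or
an exact conditional binomial test on pooled counts when each condition
has one track), BH-corrected, and called at p < 0.01, FDR < 0.05 with a
|log2 ratio| ≥ 0.5 effect-size floor.

**Integration funnel.** Significant windows map to every gene whose
body or 1 kb upstream promoter they overlap; genes carrying both marks
are intersected with genes passing the RNA filter (fold change > 1.5,
p < 0.01, FDR < 0.05, all strict). Candidate promoters (upstream
intergenic span > 1 kb; proximal 1 kb scanned) are searched on both
strands with a log-odds position weight matrix at 80% of the maximum
attainable score.

**Radial profiling.** The nuclear center is the intensity-weighted
centroid of the Otsu-thresholded nuclear channel inside the cell
outline. Every ROI pixel gets a normalized radius
r = d(pixel, center) / d(center, boundary along the same ray), computed
by exact ray–polygon intersection, and intensities are averaged in 20
equal-width r bins. Curves aggregate cell → replicate → group
(mean ± s.e.m. over replicate means), are expressed relative to a
negative control, and compared per bin with a two-way ANOVA plus
Bonferroni correction.

## Worked example

```bash
python examples/lifespan_analysis.py
```

```
planted extension: +35%
estimated extension: +31.7%
per-replicate log-rank p: ['8.64e-19', '4.28e-28', '1.36e-19']
Fisher combined: chi2 = 296.1, df = 6, p = 5.6e-61
```

Three simulated replicates (90 treated + 90 control worms each, planted
+35% Gompertz time-scale shift) each give an individually decisive
log-rank test; Fisher's combination over the three replicates has
df = 6, and the pooled estimate (+31.7% here) scatters around the
planted +35% with a standard error of about two percentage points.

The other examples cover the remaining layers and print the planted
truth next to what the pipeline recovered:

```bash
python examples/chip_metaprofile.py     # 3x enrichment -> 3.00x recovered, 30/30 windows
python examples/candidate_funnel.py    # both-mark ∩ upregulated -> exact candidate set
python examples/radial_profiling.py    # ring at r=0.5 -> relative curve peaks at 0.475-0.525
python examples/pipeline_run.py        # config-driven run with a digest manifest
```

A thin CLI wraps the same functions:
`wormepi simulate|survival|chip|integrate|radial|run|report`
(see `wormepi --help`).

## Layout

```
src/wormepi/
  stats.py        statistical primitives (Welch, ANOVA+Tukey,
                  two-way ANOVA+Bonferroni, rank-sum, Fisher, BH, blot ratios)
  survival.py     cohorts, Kaplan-Meier, log-rank, combined lifespan tests
  chipseq.py      coverage tracks, H3 normalization, TSS matrices,
                  differential windows
  integration.py  site->gene mapping, mark intersection, DE filter,
                  promoters, PWM scanning
  radial.py       ROIs, nucleus detection, radial profiles, group statistics
  synthetic.py    seeded generators with ground truth for every stage
  pipeline.py     config-driven reproducible runs
  cli.py          thin click CLI
```

See `docs/methods.md` for the models, parameter choices and known
limitations.
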