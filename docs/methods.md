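# Methods

## Phenotypes and the continuous clock

Bedtime and sleep-onset time (SOT) are clock times represented as
decimal hours on a continuous scale with domain **[12, 36)**: times
after midnight exceed 24 (04:30 ↦ 28.5).  Parsing maps any `hh:mm` with
hour < 12 forward by 24 — defensible for adolescent bedtimes, none of
which fall between noon and 20:00 — and formatting rounds to the
nearest minute.  The scale makes every downstream statistic (means,
regression coefficients, differences) ordinary arithmetic with no
wraparound case analysis.

Nine measures: bedtime, sleep-onset latency (SOL, minutes) and SOT, by
self-report (SR), actigraphy (ACT) and polysomnography (PSG).  The SR
habitual bedtime is the school-week weighted average
(5·weekday + 2·weekend)/7; the weighting applies to bedtime only — the
questionnaire has a single SOL item, so SR SOL enters unweighted.
SOT ≡ bedtime + SOL/60 exactly, per method.  The loader accepts raw
fields (deriving the nine measures) or precomputed measures (re-checking
the SOT identity to within one minute and failing on violation).  SOL
values outside the plausibility window [0, 600) minutes are *warned
about*, not rejected: the loader's hard errors are reserved for
structural problems (missing columns, unparseable clock strings), and
linear-model simulations at realistic noise can legitimately produce
small negative latencies (below).

Covariates: age (years), sex (male = 1), race (minority indicator — the
cohort description reports a single minority percentage, so a binary
coding is used and is configurable), BMI percentile (0–100, continuous),
and sequencing batch (categorical; one-hot with the first sorted batch
as reference).

## Site filtering

A site×sample cell is **available** iff coverage (methylated +
unmethylated reads) ≥ `min_coverage` (default 10).  A site is
**retained** iff available in ≥ `min_sample_fraction` (default 0.5) of
*all* samples — exactly-at-threshold is retained; only strictly-below is
excluded.  This two-stage reading (cell availability first, then a
site-level fraction over all samples) is the standard RRBS
operationalization of the coverage/availability exclusion rule; whether
the 50 % rule should count samples before or after the 10× rule is
ambiguous in prose, and the two-stage form is used and documented here.
Unavailable cells at retained sites are masked; each site's regression
is complete-case (masked samples dropped from that site's fit only).
Imputation is deliberately avoided — it would inject model assumptions
the analysis never states.  Filtering is idempotent and monotone in
both thresholds.

## Per-site association

For measure *y* and site *i*: OLS of `y_s` on
`[1, m_is, age, male, minority, bmi_pct, batch one-hot]`, with `m_is`
the methylation proportion in [0, 1].  Because the regressor is a
proportion, the coefficient is directly "phenotype units per 100 %
methylation change": minutes for SOL, hours for bedtime/SOT (fitted on
decimal hours).  Inference: two-sided t-test with residual degrees of
freedom.  A fit requires at least one residual degree of freedom beyond
the parameter count and non-zero methylation variance; otherwise the
(site, measure) pair is skipped with a logged reason, and the skip log
accounts for every missing record.  Rank-deficient designs drop aliased
covariate columns (never the methylation column) with a warning.  The
solver is numpy `lstsq` plus an explicit (XᵀX)⁻¹ for the coefficient
SE; a unit test cross-checks β, SE and p against `statsmodels.OLS`.

FDR: Benjamini–Hochberg step-up q-values (via
`statsmodels.stats.multitest`), applied **within each measure** across
its estimable sites — significance is reported measure by measure, so a
per-measure FDR matches the reporting unit; a pooled variant would mix
error budgets across phenotypes.  Significance threshold q < 0.05.

One consequence worth knowing: under a global null, BH at α makes at
least one rejection with probability exactly α per measure (Simes'
identity), so across nine measures a run with *zero* significant sites
anywhere has probability well below (1−α)... a "clean" null run is the
norm but not a near-certainty.  The test suite measures this honestly.

## Annotation

Gene models are one interval per gene id (no transcript structure),
1-based inclusive internally, BED6 on disk (0-based half-open,
converted at the boundary).  Borders extend 1500 bp upstream and 500 bp
downstream; **strand-aware by default** (upstream = 5′ of the gene),
with an unstranded mode (`stranded=False` / `--unstranded`) that applies
−1500/+500 in genomic coordinates.  Site-in-interval queries use an
interval tree; a brute-force O(S·G) scan serves as the test oracle.  A
site may map to several genes and all mappings are kept; per-gene zone
is `intragenic` (inside the body) or `upstream`/`downstream` by flank.
Sites on chromosomes without gene models become intergenic with a
warning, not an error.  Enrichment counts a multi-gene site **once**
per group, avoiding double-counting in the hypergeometric universe.

## Enrichment

Per measure, with nominal hits defined as sites at p < 0.05 among
annotated (non-intergenic) analyzable sites:

- **Hypergeometric (site level):** N = annotated analyzable sites,
  K = nominal hits, n = sites in the GWAS-informed gene group,
  k = observed hits in the group; p = P(X ≥ k) (scipy `hypergeom.sf`).
- **Permutation (gene level, default):** 1000 null replicates each draw
  a random gene subset of the same *gene count* from the annotated gene
  universe and recount hit sites within the drawn genes;
  p = (1 + #{null ≥ observed}) / (n_perm + 1).  Resampling genes rather
  than sites preserves intra-gene site clustering under the null; the
  permuted unit is a genuinely open choice, so a site-level null
  (`null_unit="site"`) is provided behind a flag.  The add-one
  correction keeps p ≥ 1/(n_perm+1); given a seed the p-value is
  bit-reproducible.

Both p-values are discrete (the overlap k has finite support) and
conservative in the usual tail-probability sense: at small counts the
null distribution of the p-value has sizable atoms and is only
approximately uniform.  This matters when testing uniformity of
enrichment p-values at desk scale.

**GO over-representation** is gene-level: universe = annotated genes
with ≥ 1 analyzable site; "significant" = genes containing ≥ 1 q < 0.05
site (gene-wide, not restricted to GWAS-informed genes — a deliberate
resolution of an underspecified choice); per term a one-sided
hypergeometric over genes, BH within each ontology.  The gene→term map
is a user-supplied TSV taken as given — no ontology download, no
graph/ancestor propagation, no coverage- or length-bias correction.

Not implemented, deliberately: genomic-inflation correction, cell-type
deconvolution, surrogate variables, mixed or robust models — the
analysis this pipeline implements uses none of them.

## The synthetic-data generator

What it emulates:

- **Cohort** (defaults = the study's summary statistics, n = 263):
  bedtimes as truncated normals on the continuous clock (SR 23:40 ± 1:30;
  ACT 23:59 ± 1:20; PSG 22:00 ± 0:12 within the in-lab 21:00–23:06
  window); SOLs as moment-matched truncated lognormals (SR 24.1 ± 19.6,
  ACT 7.5 ± 8.5, PSG 25.7 ± 21.45 min) — lognormal because latencies
  are positive and right-skewed, with wide [0, 600) plausibility bounds
  (the printed min–max are sample extremes, not truncation points, and
  truncating at them would visibly shift the mean).  Methods within a
  construct share a latent correlation, default 0.5 ("moderate"): the
  source reports no numeric cross-method correlations, so this stays
  configurable and uncalibrated.  Covariates: age 17.3 ± 2.1 (13–23),
  55.9 % male, 23.2 % minority, BMI percentile 64.5 ± 29.0 (0.7–99.8),
  4 batches (batch count unstated anywhere; 4 is a typical sequencing
  batch granularity at this cohort size).
- **Genome:** non-overlapping stranded genes (2–10 kb) on 5 Mb
  chromosomes, extended intervals kept ≥ 1 kb apart so the generator's
  intragenic/intergenic bookkeeping is exact; per-gene CpG counts
  1 + Poisson(mean−1), positions uniform over the extended interval;
  intergenic sites uniform over the complement.  Configs whose genes
  cannot fit the chromosome are rejected.
- **Counts:** coverage ~ negative binomial (mean 30, dispersion 3 —
  over-dispersed, so a realistic share of cells falls below 10×);
  missing calls as zero-coverage cells (5 % at random, plus 5 % of
  sites "high-missing" at rate 0.7 to exercise the 50 % availability
  rule); methylation proportion π_is ~ Beta(2, 2) per cell; methylated
  reads ~ Binomial(coverage, π).
- **Planted effects:** methylation is drawn first; the designated
  phenotype is then regenerated as
  `mean + Σ effect·(level − mean level) + covariate terms + N(0, SD)`,
  using the **observed** level at the planted site (the latent π only
  where coverage is zero — and those subjects are complete-case-dropped
  from that site's fit anyway).  Using the observed level keeps the
  per-site OLS estimand exactly the planted effect; constructing the
  phenotype from the latent proportion would attenuate recovery by the
  binomial measurement-error factor (~0.86 at 30× coverage).  Planting
  targets bedtime or SOL; SOT is always recomputed as bedtime + SOL/60
  so the construction identity survives planting.  Planted sites are
  the gene's first intragenic CpG and are excluded from the
  high-missing designation — a planted effect must remain analyzable to
  be ground truth.  Covariate terms default to a mild age slope (0.3
  measure-SD per age-SD) and a 0.2-SD male shift, so covariate
  adjustment is exercised.  The regeneration is exactly linear and
  unclipped: at realistic SOL noise (SD 21.45 min) occasional negative
  simulated latencies result and are retained — clipping would bend the
  conditional mean and bias effect recovery.

What it does **not** emulate — and hence what passing tests do not show
about real data: read-level artifacts (bisulfite conversion error,
mapping bias, M-bias), spatial correlation of methylation along the
genome, site-to-site heterogeneity in methylation shape, cell-type
composition, batch effects on methylation itself (batch affects nothing
in simulation; it is adjusted for regardless), non-linear or interactive
phenotype dependence, and informative missingness (cells go missing at
random, not by sequence context).

Determinism: one root seed; each stage draws from its own tagged
`numpy` Generator (`default_rng([tag, seed])`), so identical configs
reproduce byte-identical outputs, including file serializations.
Truncation is by rejection-resampling (out-of-bounds rows redrawn,
which for correlated draws replaces the offending entry with an
independent one — a negligible distortion at the configured tail
masses).

## Numerical and procedural choices

- Lognormal parameters by moment matching: σ² = ln(1 + (SD/mean)²),
  μ = ln(mean) − σ²/2; SD = 0 degenerates to the constant mean.
- Top tables sort by q with deterministic (chrom, pos) tie-breaks.
- Pipeline outputs use a fixed `%.10g` float format so reruns are
  byte-identical; every summary number is recomputable from stage TSVs.
- Coverage-file percentages are recomputed from counts; a mismatch
  beyond 0.05 percentage points logs a warning and the counts win.
- Permutation seeds in the pipeline derive from the root seed per
  measure and stay below 2³¹.
- Stage failures abort with the stage named; earlier artifacts are kept.

## Problem sizes in the test and acceptance runs

Statistical checks keep the study's subject count (n = 263) and scale
the genome: ~2050 sites for type-I calibration, 200 replicates for
planted-effect recovery (the recovery property is stated over ≥ 200
replicates), 1000-site/200-gene universes for permutation–hypergeometric
agreement, and ~325–400-site genomes across 100 seeds for the
end-to-end null and planted runs.  End-to-end statistical tests drive
the in-memory stage functions (generator → filter → EWAS → annotate →
summarize → enrich); the file/CLI layer is exercised separately at
small scale.

## Known limitations

- Tail-probability enrichment p-values are discrete and conservative at
  small counts; uniformity under the null is only asymptotic in the
  hit counts.
- Per-measure BH implies ~α probability of ≥ 1 false significant site
  per measure under a global null; across nine measures, occasional
  isolated significant sites in null runs are expected behaviour, not a
  defect.
- Complete-case per-site fits assume availability is non-informative;
  the generator satisfies this by construction, real RRBS may not.
- The binary race covariate and fixed one-hot batch coding are
  conventions chosen where the analysis description is silent; both are
  isolated in `build_design` and easy to swap.
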