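# Methods

This note records the statistical model behind `matriscore`, the conventions
and tunable parameters, what the synthetic cohorts do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Selection pipeline

### Deep-event counting and top-fraction selection

GISTIC-thresholded calls are integers in {−2, −1, 0, +1, +2}. Only the extreme
codes are counted as events: −2 (deep deletion) and +2 (amplification); shallow
±1 calls contribute to neither count. Per direction, the shortlist takes the
top `top_fraction` of the gene universe by event count with **ceiling**
rounding — `k = ⌈0.05 × 1027⌉ = 52` genes per direction on a full matrisome
list — because floor rounding would give 51 and not match the intended
per-direction size. Two further conventions:

* **Ties at the selection boundary are all included.** Bars of equal height
  have no defined order, so any subset choice would be arbitrary and
  order-dependent; including the whole tie block makes the selection
  deterministic and permutation-invariant (the shortlist may then exceed `k`).
* **Genes with zero events are never selected**, even when `k` would reach
  them: selection is among altered genes. `top_fraction(..., of_altered=True)`
  instead computes `k` from the number of altered genes, for the reading where
  the per-cancer 5% refers to that cancer's altered genes only.

### Differential expression and concordance

Expression is analysed on a log2(TPM+1)-like scale throughout, so a fold
change of 2 is `|log2FC| ≥ 1` computed as a difference of group means. The
default two-group statistic is Welch's *t* (unequal variances — the
conservative default when group spreads differ); `test="wilcoxon"` switches to
Mann–Whitney. Direction calls use **raw** p-values at `alpha` (the screen's
convention); a Benjamini–Hochberg FDR column is emitted alongside for
transparency but never drives calls. When both groups have zero variance the
test is undefined and `p = 1` (equal means) or `p = 0` (unequal) by convention.

The concordance filter keeps amplified genes called *up* and deleted genes
called *down*; genes missing from the DEG table are dropped with a warning
rather than raising, since per-cancer expression panels can be smaller than
the copy-number universe.

### Percentile survival screen

`assign_groups(values, high_cut=0.75, low_cut=0.25)` labels samples strictly
above the 75th empirical percentile *high* and strictly below the 25th *low*;
the middle half is excluded. This is the custom-cutoff convention of
percentile-based survival portals ("cutoff-high 75 / cutoff-low 25"); the
alternative reading (top 75% of samples = high) is one flag away since both
cutoffs are parameters. Ties exactly at a boundary go to *excluded* —
deterministic and order-independent. With `high_cut == low_cut` the split is
two-way with no exclusion and ties at the cut go low. Quantiles use NumPy's
default linear interpolation.

The two-sample log-rank statistic is the standard `(O − E)² / V` over pooled
event times with the hypergeometric variance for ties (computed via
`lifelines.statistics.logrank_test`, cross-checked in the test suite against an
explicit risk-set enumeration). When neither group has any events the test is
undefined and `(0, 1)` is returned with a warning. Hazard ratios come from a
Cox proportional-hazards partial-likelihood fit with the **Efron** tie
approximation (more accurate than Breslow under heavy ties) via
`lifelines.CoxPHFitter`; non-convergence or separation yields a flagged
not-evaluable record, never an exception. Subgroup ("multivariate") analyses
fit the same univariate model separately within each race or gender level —
one HR per level, not a simultaneous multivariable adjustment — and levels
with fewer than 2 events in either expression group are reported
not-evaluable. Significance of a cancer in the screens uses the log-rank p.

### Breadth, scoring and the final intersection

A gene's breadth is `100·k/n` rounded to two decimals, with `n` the configured
number of cancers analysed (default denominator 30). Expression breadth counts
cancers with a concordant significant call; survival breadth counts cancers
where the log-rank screen rejects. Each breadth is converted to a 1-based
**competition rank** (top gene = 1; tied values share the minimal position of
their block; the next distinct value resumes at its actual position), and the
two ranks are summed. Ranking is done separately for up- and downregulated
genes. A gene present in only one breadth table has no defined position in the
other ranking and is dropped with a log message rather than given a penalty
score. Output ties are broken alphabetically so tables are deterministic.

The final list intersects the pan-cancer scored shortlist with the
individual-cancer hits: genes shortlisted, concordant and survival-significant
in at least `min_cancers_individual = 2` separate cancers.

### Validation battery

* **Correlation**: Spearman rank correlation of each candidate with the anchor
  gene across tumour samples; constant vectors are reported not-evaluable.
* **Stage trend**: one-way ANOVA of expression across pathological stages,
  sub-stages collapsed to their parent (IIIa → III); needs ≥2 groups with ≥2
  samples.
* **Co-occurrence**: 2×2 joint alteration table; odds ratio with the
  Haldane–Anscombe +0.5 correction applied when any cell is zero, keeping the
  log2 OR finite; two-sided Fisher exact p by the point-probability method
  (every table with the observed margins whose probability does not exceed the
  observed table's). "Altered" defaults to deep (±2) calls; `mode="any"`
  widens to any non-zero call.
* **Hub ranking**: node degree within the candidate-induced subgraph, ranked
  descending with alphabetical tie-break, thresholded at `min_hub_degree = 1`.
* The four criterion sets are intersected exactly, with a per-gene audit table
  of pass flags so near-misses are visible.

## Synthetic cohorts

`simulate_cohort(SimConfig)` generates, per cancer: a GISTIC matrix over
tumour samples, tumour and normal expression, clinical records and a shared
interaction edge list, all deterministically from one seed.

* **Copy number**: each gene acquires +2 with `amp_prob` and −2 with
  `del_prob` per sample (drivers elevated within their active cancers,
  background genes at `background_alteration_prob` split evenly between
  directions). Cells left neutral may carry ±1 shallow calls at
  `shallow_alteration_prob = 0.05`, so deep-only counting is non-trivially
  exercised. Co-occurring pairs draw their amplification events from the
  unique 2×2 joint distribution with the configured marginals and odds ratio
  (the Plackett construction: the admissible root of the quadratic in the
  joint-positive cell).
* **Expression** is generated directly on the log2(TPM+1)-like scale with
  additive effects — per-gene baseline ~ U(3, 8), Gaussian noise
  (`noise_sd = 0.5`), plus for active drivers the shift, the per-call
  copy-number coupling and a linear stage trend — floored at 0 (the floor
  essentially never binds at these baselines). Additive generation keeps the
  coupling and shift interpretable in log2 units, matching how fold changes
  are computed downstream.
* **Survival**: exponential event times with hazard
  `baseline_hazard · exp(Σ_d γ_d z_d)`, `z_d` the within-cancer z-score of
  driver d's tumour expression; `baseline_hazard = 1/1000` per day gives a
  ~690-day median survival. Censoring is independent uniform over a study
  window solved numerically so that the expected censored fraction under the
  baseline hazard equals `censoring_rate` (default 0.3).
* **Stages** I–IV are drawn with probabilities (0.30, 0.30, 0.25, 0.15), race
  and gender from fixed categorical distributions including an explicit `NA`
  missing token.
* **Edges**: a confidence-0.95 clique over the driver genes plus random
  background edges with U(0, 1) confidences, so hub recovery has a known
  answer and the 0.4 confidence floor removes real edges.

Default cohort dimensions (5 cancers, 100 tumour + 40 normal samples, 200
genes) are the problem sizes used by the end-to-end recovery analyses.

What the simulator does **not** emulate: copy-number segment structure (calls
are independent across genes), tumour purity, batch effects, library-size or
count-level noise (expression is Gaussian on the log scale), correlated
co-expression modules beyond the planted effects, and non-proportional
hazards. Passing tests therefore demonstrate that the pipeline's logic and
statistics behave as specified under the assumed generative model — not that
the model captures every property of real TCGA data.

## Calibration and recovery experiments

* **Null calibration**: with all effects zero, the tumour-vs-normal screen,
  the 75/25 log-rank screen, the stage ANOVA and the Fisher co-occurrence test
  must each reject at a rate inside the 99% binomial band around α = 0.05 over
  500 tests. Gene-level survival and stage tests within one cohort share that
  cohort's clinical table and are therefore positively correlated; the
  calibration pools 50 independent replicate cohorts of 10 genes each so the
  binomial band applies to the pooled rate. The expression screen uses a
  single 500-gene cohort since per-gene noise is independent there. Fisher
  calibration uses 500 independent pairs at n = 500 samples with marginals
  0.3 (the exact test is conservative; large cells keep it near nominal).
* **Parameter recovery**: a planted log-HR of 0.7 (n = 500, 100 replicates)
  is recovered by the Cox fit within ±0.15 mean bias; a planted odds ratio of
  4 at n = 10⁴ is recovered within ±0.3 on the log2 scale (20 seeds).
* **Driver recovery**: one planted pan-cancer driver (amplification 0.3,
  +1.5 log2 shift, γ = 0.7, active in 3 of 5 cancers) must be the unique
  output of the full pipeline in ≥90% of 50 seeded runs, and the all-null
  configuration must produce a non-empty final list in ≤10% of runs.

## File dialects and degenerate inputs

Matrices use the Xena `genomicMatrix` TSV dialect (header
`sample<TAB>id1<TAB>...`, one gene per row). Missing matrix cells are
**rejected, not imputed** — the error message says so — since silent
imputation would change event counts. Duplicate gene or sample identifiers and
ragged rows are format errors naming the offender. Gene lists are plain text,
one symbol per line (dependency-free and diff-able; no spreadsheet import),
duplicates dropped keeping the first with a warning. Edge lists auto-detect
the STRING 0–1000 integer scale (any score > 1 rescales the whole file by
1000); self-loops are removed and reciprocal duplicates collapsed keeping the
highest confidence. Clinical tables use the explicit token `NA` for missing
stage/race/gender so subgroup filters are testable; values outside the closed
vocabularies are rejected.

## Known limitations

* The pipeline screens marginal associations; no multiple-testing correction
  is applied to the direction calls (by design), so per-stage false-positive
  rates are α, controlled only by the conjunction of filters.
* Subgroup hazard ratios are per-level univariate fits and must not be read as
  covariate-adjusted effects.
* The "multivariate" survival surface fits one binary expression covariate;
  continuous-covariate Cox is available but the pipeline does not use it.
* `cross_cancer_overlap` and the four-criteria intersection are exact set
  operations: they inherit whatever miscalls upstream screens make.
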