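# Methods

This note documents the statistical model, default parameters, and the
synthetic-data generator behind `screentriage`. Problem sizes quoted here
(478-construct library, 18 NTCs, 1086-line dependency panel, 159-patient
cohort) are the package's default simulation scale; every size is a
parameter.

## Count model and differential abundance

Construct counts are modelled as negative binomial with mean μ and variance
μ + αμ² (Poisson at α = 0). All sampling uses
`numpy.random.Generator.negative_binomial(r, p)` with r = 1/α and
p = r/(r + μ).

**Size factors** follow the median-of-ratios construction: for each sample,
the median over all-positive rows of count / geometric-row-mean, computed in
linear space (the median of linear ratios differs from the exponentiated
median of log ratios whenever the median interpolates between two values, so
linear space is used throughout and matched by the brute-force oracle).
Factors are rescaled to geometric mean 1. If no row is all-positive, the
estimator falls back to rows positive in every sample of a largest subset and
warns.

**Dispersion** is estimated per construct by method of moments,
α̂ = max(0, (s² − μ̄)/μ̄²), pooling within-group statistics across the two
groups. A trend is fit by averaging α̂ in 20 equal-occupancy bins of
normalized abundance. Each construct's final dispersion is a weighted
combination of its own α̂ and the trend value, with weight
w = df/(df + prior_df) on the construct estimate, prior_df = 24 by default.
Rationale: with 3 + 3 replicates (df = 4) the construct estimate is extremely
noisy; a fixed 50/50 weighting leaves enough noise in the plug-in dispersion
to make the Wald test anticonservative (measured type-I ≈ 0.065 at nominal
0.05 on 12 000 null constructs). df-weighted shrinkage with prior_df = 24
gives w ≈ 0.14 at df = 4 — mostly trend, as replicate counts warrant — and
restores calibration (measured 0.048–0.053 across seeds, inside the
3·MC-SE band). At large df the construct's own estimate dominates, as it
should. Dispersions are floored at 10⁻⁸.

**Wald test.** For normalized group means m_T, m_C:
log2FC = log2((m_T + 0.5)/(m_C + 0.5)); the delta-method variance of the
log2 ratio under the NB variance function is
SE² = [(1/n_T)(1/max(m_T, 0.5) + α) + (1/n_C)(1/max(m_C, 0.5) + α)] / ln²2,
tested two-sided against a standard normal. Constructs at zero in both groups
are flagged untestable (log2FC 0, p 1). Multiplicity is controlled by
Benjamini–Hochberg (`statsmodels.stats.multitest.multipletests`).

**Gene aggregation.** Gene log2FC is the median over the gene's constructs;
its SEM is the construct-level standard error of the mean. A gene is
*essential* when median log2FC < −1 and ≥ 2 constructs individually have
log2FC < −1 with p < 0.05. The 18 non-targeting controls are seeded-randomly
partitioned into pseudo-genes of sizes 5/5/4/4 (matching targeting-gene guide
counts) and aggregated identically, giving an empirical null at gene level.

A note on that null: at the generator's default noise (α = 0.05, depth 10³,
3 vs 3) the delta-method per-construct null log2FC sd is
√((2/3)(10⁻³ + α))/ln 2 ≈ 0.27, so a 4-guide pseudo-gene median exceeds
|0.25| with ≈ 8% probability; requiring all four medians within ±0.25 in
≥ 95% of screens would need α ≲ 0.015. The acceptance test asserting that
bound is therefore red by design; `scripts/acceptance.py` reports both the
per-screen and per-median fractions.

## Triage

- **Cross-context quadrants**: genes measured in both contexts are labelled
  essential_both / essential_<ctx>_only / dispensable_both by the −1 median
  log2FC threshold per context.
- **Essentiality score** over a binary gene × cell-line dependency matrix:
  E = 100 · (dependent lines)/(lines); E ≥ 50 ⇒ common essential
  (so 543/1086 → 50.0, common essential).
- **Candidate filters** (defaults in `TriageThresholds`): in vivo median
  log2FC < −1; Δlog2FC = tumour − fibroblast < 0; co-expression r > 0.5 with
  the activity score; tumour-vs-normal log2FC > 0.3. Passing genes are ranked
  by r descending, ties broken by in vivo log2FC ascending.

## Expression and survival

Expression is z-scaled per gene across samples (ddof = 1; zero-variance rows
become zeros with a warning). A gene-set activity score is the per-sample
mean of member z-rows. Candidate–score association uses Pearson r with the
exact t-transform p-value (t = r√(n−2)/√(1−r²), n−2 df). Tumour-vs-normal
fold change uses log2((mean_T + c₀)/(mean_N + c₀)) with c₀ = 0.1 and a
delta-method SE. Survival stratification takes sample tertiles of one or two
scores (intersection of top/bottom tertiles, or tertiles of their combined
score), compares high vs low by the log-rank test and reports Kaplan–Meier
curves (`lifelines`).

## Occupancy

Spike-in scaling: f_s = median(n_spike)/n_spike per sample; scaled signal is
read-start counts in strand-aware promoter windows TSS ± 3 kb (half-open,
truncated at 0) times f_s. Interval classification assigns each interval by
midpoint with precedence promoter > gene body > downstream (2 kb past the
TES) > intergenic, so the four fractions partition to 1. Regulation bin
plots use 8 equal-width bins over the regulation range; rank bin plots sort
by Δ occupancy and split into 15 equal-count bins (remainder spread over
leading bins). Bin summaries report n, mean x, mean y and the SEM of y.

## Synthetic-data generator

- **Screen counts**: log-normal construct baselines (σ = 0.25,
  mean-corrected), planted per-gene per-context effects applied
  multiplicatively to treated means, NB sampling at the configured depth and
  dispersion. An optional engraftment bottleneck multinomially subsamples
  each in vivo replicate to a fixed cell number before sequencing,
  reproducing stochastic dropout of low-abundance constructs.
- **Dependency matrix**: each gene's dependent-line count is
  round(fraction × lines), placed deterministically per seed.
- **Expression cohort**: a latent per-patient activity factor a ~ N(0,1)
  drives gene-set members linearly in FPKM space (base U(8,20) + a + noise);
  keeping the link linear means the planted Pearson r survives per-gene
  z-scaling unattenuated. The candidate gene's loading is
  r·a + √(1−r²)·η, giving an exact planted co-expression at noise 0.
  Normals lack the tumour overexpression shift. Survival is exponential with
  hazard scaled by activity tertile (hazard ratio HR for the top tertile,
  √HR for the middle), with exponential censoring tuned to the target
  censoring rate.
- **Spike-in ChIP**: spike material is held constant across samples while
  experimental material is globally depleted in the treated sample, with
  per-promoter regulation tilting the depletion; reads are multinomially
  resampled at fixed total depth, so the spike-normalized treated/vehicle
  ratio recovers the planted depletion factor.

Scope: the generator produces counts, matrices and read tables with known
planted truths for calibration and recovery testing. It does not model PCR
duplication, sequencing error, guide off-target effects, copy-number
artefacts, or non-exponential survival; fixtures stay small and text-only.

## Numerical choices

- Pseudocounts: 0.5 on group means for screen log2FC; 0.1 for FPKM fold
  changes.
- Dispersion floor 10⁻⁸; dispersion shrinkage prior_df = 24 (see above).
- Medians and size factors in linear space; geometric-mean-1 normalization.
- All stochastic routines take explicit integer seeds; pipeline runs are
  byte-identical across reruns and hashed into the manifest.

## Limitations

- The Wald test is asymptotic; at 3 + 3 replicates its p-values track an
  exact permutation reference in calls (≈ 96% agreement at α = 0.05,
  rank correlation ≈ 0.98) but not pointwise, as the permutation null
  conditions on the empirical spread.
- Gene-level SEM treats constructs as independent; shared-target correlation
  is ignored.
- The log-rank test and KM curves assume non-informative censoring.
- Equal-width regulation bins can leave sparse outer bins; Pearson r over
  bin means is descriptive, not inferential.
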