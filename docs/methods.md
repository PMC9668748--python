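# Methods

## The question and the statistic

In neurotypical cortex, pairs of cortical areas are distinguished by
thousands of differentially expressed genes, and a substantial fraction of
these differences follow the anterior-posterior (A-P) axis. The analyses in
this package quantify *attenuation of transcriptomic regional identity*
(ARI): whether the number of genes separating two regions is reduced in
cases (e.g., ASD, dup15q) relative to controls.

The elementary statistic is a paired regional DE count. For a region pair
(r_a, r_b) and one diagnosis group, each subject possessing both regions
contributes one within-subject difference per gene,
d_gs = x_g(s, r_b) − x_g(s, r_a), on regressed log2 expression. Genes are
tested with the two-sided paired Wilcoxon signed-rank test across subjects
and counted at Benjamini-Hochberg FDR q < 0.05. The ARI statistic for a
pair is n_de(case) − n_de(control).

Because the signed-rank test's granularity depends strongly on the number
of paired subjects (with n subjects the smallest attainable p is 2/2^n, so
a group of 7 subjects can be structurally unable to clear a BH threshold
that a group of 10 clears easily), raw DE counts are not comparable across
groups or pairs. Two complementary inference routes address this:

1. **Subject-label permutation** (per pair). Diagnosis labels are
   reshuffled uniformly over the subjects possessing both regions,
   preserving group sizes; both counts are recomputed under identical tie
   and FDR rules for each of B permutations. The two-tailed p-value is
   (1 + #{|Δ_perm| ≥ |Δ_true|}) / (B + 1). A pair is *attenuated* when
   p < 0.05 and the case count is lower, *over-patterned* when p < 0.05
   and the case count is higher, otherwise *not significant*. An
   exhaustive mode enumerates every equal-size assignment and reports the
   exact tail fraction; it is used when the assignment space is small.
2. **Age-matched bootstrap** (across pairs). Each group is first reduced
   to k = 10 subjects closest in age to the group's median age for that
   pair (ties broken by subject id), equalising the design across pairs.
   Subjects are then resampled with replacement B times and the DE count
   recorded per draw; the control and case count distributions are
   compared with a two-sided Mann-Whitney U test, BH-corrected across the
   pairs tested. A pair is attenuated when q < 0.05 and the median case
   count is below the median control count. A subject drawn twice
   contributes its difference vector twice; the resulting exact ties are
   handled by the enumeration null below.

## Signed-rank null distributions

Zero differences are dropped before ranking (classical Wilcoxon); a gene
with no nonzero differences gets p = 1. The null of W+ (sum of positive
ranks over n nonzero pairs) is computed by, per gene:

* **exact dynamic programming** when the nonzero |d| are untied and
  n ≤ 25 (one distribution per n, cached);
* **exact enumeration of all 2^n sign assignments** applied to the
  observed midranks when ties are present and n ≤ 14 — the regime
  bootstrap duplication creates; doubled midranks are exact integers, so
  the enumeration is float-exact;
* **normal approximation** with continuity correction and the standard
  tie correction of the variance otherwise.

Two-sided p-values are min(1, 2·min(P(W ≤ w), P(W ≥ w))). The permutation
and bootstrap loops use the same vectorised engine, so null and observed
statistics share identical tie rules by construction. The engine is
cross-checked in the test suite against `scipy.stats.wilcoxon` (exact and
approximate modes), a brute-force sign-assignment enumerator, and
`statsmodels` BH.

## ARI gene extraction

For each pair the permutation test classifies as attenuated, genes DE in
the true control group are filtered by *occurrence*: the number of
permutations (same stream, same seed) in which the gene was DE in the
pseudo-control group. Genes DE in ≥ 95% of permutations are
labelling-insensitive — their regional difference survives diagnosis
mixing and thus carries no attenuation signal — and are dropped (strict
"< 95%" retention). Each retained gene is assigned to the region with
higher control expression (sign of the median within-subject difference;
mean fallback on an exact zero; excluded with a warning if both vanish).

Retained genes are pooled across attenuated pairs (union without
duplicates) and split by the sign of the Spearman correlation between the
gene's control median expression across all regions and the A-P rank:
positive (rises posteriorly in controls) → ARI-downregulated, negative →
ARI-upregulated, zero → unassigned and logged. The all-region correlation
also resolves genes retained with contradictory per-pair directions.

## Effect-size slope

To compare regional against whole-cortex case-control effect sizes, both
log2 fold-change vectors are estimated with error, and the OLS slope
depends on which vector is labelled the response — it is attenuated toward
zero by the predictor's error variance. The package therefore fits total
least squares (orthogonal, equivalently principal-components) regression:
both vectors are centred on shared genes and the slope S is the component
ratio of the leading eigenvector of the 2×2 covariance matrix, making
axis swap return exactly 1/S. Inference against S = 1 uses a gene-level
bootstrap (genes are the observations of this regression): percentile 95%
CI and p = 2·min(tail fractions), floored at 2/(n_boot + 1). A vertical
principal axis or isotropic cloud is reported as a degenerate condition,
never as a number. Fold changes are computed on regressed data by
subject-first averaging (each subject's in-scope samples are averaged
before group means), so subjects with more regions do not dominate.

## Preprocessing

Counts → CPM (column sums as library sizes) → feature filter: keep genes
with CPM > 0.1 (strict) in at least ⌈0.30 · n_samples⌉ samples and
effective length ≥ 15 bp → log2(CPM + 0.5). The prior keeps zeros finite
at −1 and the filter is idempotent. More elaborate GC/length and
depth-variance adjustments are deliberately omitted: every downstream
statistic is rank-based on regressed values, and those offsets do not
change signed ranks of within-subject differences.

Sample QC groups samples by sequencing batch × cortical lobe (lobe alone
when batch is absent; groups under 5 samples are skipped with a warning)
and flags a sample only when **both** criteria hold: |z| > 3 on at least
one of the top min(10, rank) principal components of the gene-centred
matrix, and standardised connectivity z < −2, where connectivity is the
row sum of the signed adjacency ((1 + bicor)/2)^2 over the biweight
midcorrelation (c = 9) of sample columns. Connectivity is standardised by
the within-group mean/SD; if the SD is zero (all samples identical) the
score is undefined and nothing is flagged. Samples with zero MAD
(constant expression) have undefined correlations; they are marked
`degenerate` for manual review, never silently dropped.

Covariate regression fits, per gene, a linear mixed model with a subject
random intercept, fixed effects for diagnosis and region, and fixed
effects for every remaining metadata column (age, sex, batch, any extra
technical covariates; categorical columns are dummy-coded, constant
columns skipped with a log notice). REML estimates are obtained with
statsmodels MixedLM; the regressed value is the observation minus the
summed nuisance contributions, leaving subject, diagnosis, region, and
residual untouched. Non-convergent genes fall back to OLS and are
recorded in the output provenance. A singular design is refused with the
collinear columns named. Note that subject-level covariates are partially
confounded with subject intercepts; with few subjects their estimated
effects absorb some intercept variance, which bounds how exactly a
no-nuisance dataset is reproduced (tested with an explicit tolerance).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, on log2 scale:

    x_gsr = b_g + u_s + slope_g · rank(r) · (λ if case else 1)
            + Σ_c β_gc z_cs + ε,    ε ~ N(0, noise_sd)

* b_g ~ N(mean_log_expr, gene_mean_sd): per-gene baseline abundance.
  Default spread 2.0 log2 units — real expression levels span orders of
  magnitude, and this is what makes samples strongly mutually correlated,
  so connectivity-based QC behaves as it does on real data. Baselines
  cancel in every within-gene contrast.
* u_s ~ N(0, subject_sd): subject random intercept (default 0.3 log2).
* A fraction `gradient_fraction` of genes carry an A-P gradient with
  per-rank-step slope sign·(gradient_min_slope + |N(0, sd)|); the default
  min of 0 reduces to a plain Gaussian slope. The default sd of 0.05
  log2/rank-step gives ~0.5 log2 across the full 11-region axis.
* λ ∈ [0, 1] multiplies gradient slopes in cases only: 1 is the null,
  0 erases gradients entirely. Attenuation is multiplicative on the
  gradient term — cases keep their subject and noise structure.
* Region ranks default to an A-P ordering of 11 Brodmann-area groupings
  (BA9 … BA17); missingness is independent Bernoulli per
  (subject, region), and a realisation leaving any region with fewer than
  two subjects in a group is rejected as infeasible.
* Optional negative-binomial count emission: expected counts proportional
  to 2^x rescaled to a library size (default 3×10^7), gamma-Poisson with
  dispersion 10 (variance μ + μ²/10, a typical bulk RNA-seq gene-level
  value); −∞ expression is the structural-zero sentinel.
* Default cohort size, 54 controls / 49 cases with ~35% regional
  missingness, mirrors a large multi-region post-mortem cohort.

Everything is a pure function of the config (identical seed ⇒
bit-identical output). The generator does **not** model structured
missingness, batch-specific depth artifacts, GC content, isoforms, or
cell-type composition; passing tests demonstrate correctness of the
statistics under the assumed additive log-scale model, not robustness to
those real-data complications.

## Benchmark conditions and their rationale

* *Calibration*: λ = 1 cohorts (200 genes, 12+12 subjects, 10% regional
  missingness, B = 500, 100 replicates); the rejection rate at 0.05 on the
  max-span pair must fall within the binomial 95% band [0.01, 0.11].
  Subjects are exchangeable at λ = 1, so the permutation test is exact up
  to Monte-Carlo error.
* *Power*: λ = 0.3, gradient fraction 0.3, 15 subjects/group, B = 500,
  50 replicates. The gradient scale (sd 0.05/rank-step, noise 0.25) is
  chosen so that control effects at the full axis span clear the BH
  threshold while the 0.3-scaled case effects mostly do not — the regime
  the statistic is designed for.
* *Recovery*: λ = 0 with a 3-region geometry, gradient fraction 0.5, and
  slopes bounded away from zero (|slope| ≥ 0.35/rank step). The small
  geometry is deliberate: unioning BH discoveries across P pairs
  accumulates roughly P·α·(1−f) spurious genes, an analytic property of
  FDR unioning rather than of the extraction filter, and a 55-pair union
  would be dominated by it at desk scale. Three pairs isolate what the
  benchmark is meant to measure — that the occurrence filter and grouping
  recover planted gradient genes with their planted orientations.
* The end-to-end demo (4 regions, 60-80 genes, B = 100-200) exists to
  verify orchestration and bit-identical reruns, not statistical
  performance; its sizes are chosen for fast iteration.

## Numerical and design notes

* BH rejection counting uses the sorted-p shortcut
  max{k: p_(k) < α·k/m} (strict, matching q < α), verified equivalent to
  the full step-up on random inputs.
* Permutation p-values use the add-one estimator and can never be 0;
  exhaustive enumeration reports the exact tail fraction instead.
* Per-pair bootstrap streams are spawned from a master seed keyed by the
  pair label (CRC32), so adding or removing pairs never perturbs the
  streams of others; pipeline stages derive their seeds from the master
  seed keyed by stage name, with the same property.
* The permutation cache stores the per-gene paired-difference matrix once
  per pair — valid because relabeling never changes the subject pairing —
  and can be disabled to verify equivalence against direct recomputation.
* The up/down grouping via the sign of the all-region Spearman correlation
  is an operationalisation choice; a principal-component summary across
  regions would be a natural alternative and could disagree for
  non-monotone profiles, which the rank correlation leaves unassigned.
* The Mann-Whitney p-values comparing two B-sized Monte-Carlo
  distributions are resolution-limited in B; B is recorded in the output.

## Known limitations

* DE counting is unadjusted (no covariate-aware or moderated test); the
  design assumes nuisance structure was removed upstream by the mixed
  model.
* FDR correction is applied per region pair, not pooled across pairs.
* With fewer than ~8 paired subjects the signed-rank granularity makes DE
  counts structurally small; the permutation route remains valid but the
  counts themselves are not interpretable as effect sizes.
* The bootstrap route requires k = 10 paired subjects per group per pair
  and refuses otherwise.
* TLS slope consistency assumes comparable error variances on both effect
  vectors; with grossly unequal variances the orthogonal fit is biased
  (Deming regression with a variance ratio would be required).
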