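# Methods notes

## Model and procedure

The pipeline treats CD8+ T-cell infiltration as a latent per-tumor
quantity observed through a small metagene: the geometric mean of the
log2(normalized count + 1) expression values of the member genes. The
geometric mean is taken of the log2 values themselves, not of linear-scale
counts; consequently a single member with log2 value 0 zeroes the sample's
score. This is deliberate — the score lives on the same log2 scale as the
matrix — but it means near-zero member expression dominates; users scoring
sparse data should check member detection rates first.

All stratification is rank-based and balanced rather than
quantile-threshold-based: within a context (a tumor group, or a biopsy
timing stratum), samples are sorted by score with ties broken by sample
id, and cut into blocks whose sizes differ by at most one, extras assigned
to the lowest strata first. This keeps tertiles/quartiles nearly equal
even under heavy ties and makes every split reproducible; 48 samples
always give quartiles of 12.

Gene ranking runs two deliberately different statistics in parallel. The
LFC method contrasts the high and low score tertiles (lfc = mean(high) −
mean(low), so negative values mark CD8-Low overexpression) and draws
p-values from a moderated t statistic; ranking itself uses the fold
change, not the t statistic, whose only role is to produce p/q values.
The SC method correlates each gene with the score over all samples,
tertiles ignored. Percentile ranks are assigned by position: the gene at
position i of G (position 1 = most CD8-Low-associated, ties broken by
smaller q then gene id; genes with undefined statistics forced to the
bottom) gets pr = 100(G − i + 1)/G, a bijection onto (0, 100].

### Moderated t

The moderated t shrinks per-gene pooled variances s²_g (d = n₁ + n₂ − 2
degrees of freedom) toward a scaled-inverse-chi-square prior (d₀, s₀²)
fitted across genes by method of moments: marginally s²_g ~ s₀² F(d, d₀),
so matching the first two moments of the observed variances gives d₀ =
(4r − 2c)/(r − c) with r = m₂/m₁², c = (d + 2)/d, and s₀² = m₁(d₀ − 2)/d₀;
when the observed dispersion is no larger than chi-square sampling
dispersion (r ≤ c) the prior is infinite and all genes share the common
variance. The posterior variance (d₀s₀² + ds²_g)/(d₀ + d) enters the t
denominator with d₀ + d degrees of freedom. With d₀ = 0 the statistic
reduces exactly to the ordinary pooled-variance t (asserted against a
plain-t oracle); against the limma reference implementation on random
data, fold changes agree to machine precision and p-values to within a
few percent on the log scale — the residual difference comes from limma's
maximum-likelihood-flavored F-fit of (d₀, s₀²) versus our pure moment
match. Genes with zero within-tertile variance still get finite p because
s₀² > 0. No precision weights or covariates are used.

### Recurrence statistics

The exact binomial probability uses the *point* mass P(X = k), not the
tail P(X ≥ k): p_bonf = min(1, G·C(T,k)·f^k(1−f)^(T−k)), evaluated in log
space (gammaln), with the Bonferroni factor equal to the universe size G.
Both choices follow from reproducing the published k = 5..12 probability
table exactly; a `tail=True` option exposes the upper-tail alternative.
The pairwise overlap test places each pair's top sets in a 2×2 table over
the constant G-gene universe and applies the Yates-corrected chi-square;
Benjamini–Hochberg runs across all T(T−1)/2 pairs. BH is used wherever
the procedure is stated only as "FDR-corrected".

MPR selection is inclusive at its bounds (≥ 75, ≤ 0.1) and requires both
methods simultaneously; it is monotone — raising any percentile rank never
deselects a gene. EBP selection requires k ≥ min_k (default 5, matched to
the 23-group setting); at other group counts T, min_k scales
proportionally and rounds (floored at 2), e.g. min_k = 2 at T = 10. An
optional p_bonf ceiling can be conjoined for significance-based selection.

### Mutual exclusivity

Binarization happens *after* subsetting to the CD8-Low tertile: per gene
and group, the mean over that group's CD8-Low samples is the threshold,
strictly-above maps to 1 (values equal to the mean map to 0, a
deterministic tie rule consistent with "below mean = 0"), and groups are
concatenated. This makes the binary matrix invariant to per-group affine
rescaling. Fisher's exact test uses the uncorrected table for the
two-sided p (minimum-likelihood convention: sum of hypergeometric
probabilities ≤ the observed table's, verified against exhaustive
enumeration for every table with n ≤ 24); the Haldane–Anscombe +0.5 enters
only the log2 OR point estimate and only when a cell is zero, keeping the
test exact while bounding the estimate. Genes with degenerate margins
(all-0/all-1) are excluded from the q computation and flagged.

Clustering is complete-linkage agglomeration on 1 − Spearman ρ between
gene rows (expression vectors, or rows of the log2-OR matrix with NaN
treated as 0 = no association); rows are sorted by gene id first so
results are order-independent. C1/C2 are the two-cluster cut labeled by
descending size (ties by smallest member id). Synexpression groups are the
maximal dendrogram subtrees whose *mean* pairwise ρ clears the threshold
(default 0.15), scanned root to leaves with descent stopping at the first
qualifying subtree; singletons are never reported. Mean aggregation and
the stop-at-first-hit scan are design choices where the published
procedure is silent; note that with the mean rule a subtree that unions
two strong blocks can itself qualify at a low threshold, so the cutoff
controls cluster granularity directly. Published OR/q cutoffs appear in
the literature in both comparison directions; the thresholding operation
therefore parameterizes both the values and their directions, defaulting
to log2 OR < −1, q < 1e-30 (strict mutual exclusion).

### Outcome association

Responders are CR/PR (the standard RECIST responder definition); SD/PD
are pooled as non-responders and NE is excluded. Quartiles are formed within pre-
and on-treatment strata independently, then pooled for the Fisher tests
(Q1 vs Q4, Q1 vs Q2+Q3, two-sided). Survival uses the product-limit
estimator and the standard unweighted k-group log-rank statistic
(lifelines); the group construction is caller-supplied, with Q1 vs pooled
Q2–Q4 as the CLI default and `--per-quartile` for the 4-group test.

## Synthetic data: what it emulates and what it does not

Each sample s in group t draws a latent infiltration factor z_s ~
N(μ_t, 1) with group means μ_t ~ N(0, 1) drawn once per cohort — the
cross-group mean variation forces all downstream statistics to operate
within groups. Gene expression is baseline α = 5 (log2 units) plus
N(0, σ²) noise with σ = 1, clipped at 0 to respect the log2(x+1) floor
(clipping rather than truncated resampling: simple and monotone).
Signature genes add +β·z (β = 1); culprit genes add −γ·z (γ = 1) in a
configurable subset of groups (default 8 of 10) and are pure noise
elsewhere; the two program gene sets (20 + 20) add δ = 1.5 in the cold
(lower z-tertile) samples assigned to program A (probability π = 0.5) or
B — programs are coupled to cold samples so planted program genes are also
recovered as culprits, nesting the mutual-exclusivity analysis inside the
CD8-Low phenotype exactly as the pipeline expects. Defaults (10 groups ×
120 samples, 2,000 genes, 50 culprits) are the desk-scale study
conditions used throughout the tests; they keep every stage's signal
comfortably detectable at σ = 1 while a full run stays under a second.

The treatment generator reuses the single-group expression model; a
sample's response probability is logistic(a − b·score_z) with a =
logit ≈ 0.25 baseline and score_z the standardized metagene score, so
positive b concentrates responders in low-score quartiles; responders
split CR:PR = 1:2 and non-responders SD:PD = 1:2 deterministically.
Survival is exponential with hazard λ₀·exp(θ·score_z), λ₀ = ln2/600 per
day (median ~600 days), under independent exponential censoring at half
that rate (~30–40% censoring); times are rounded to 0.1 day. Timing
(pre/on) and cohort labels are assigned round-robin on different strides
so they are not confounded.

Not emulated: negative-binomial count noise, library-size and batch
effects, gene–gene correlation beyond the planted structure, dropout, or
missing clinical fields. Passing recovery tests therefore shows the
statistics find the planted structure under Gaussian log-scale noise —
not that they are robust to real RNA-seq artifacts; on real data the
within-group normalization and rank-based statistics carry that burden.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give byte-identical cohorts and clinical tables.
- Spearman correlations are computed as Pearson on mid-ranks (tie
  corrected), vectorized across genes, and cross-checked against
  scipy.stats.spearmanr; constant genes get ρ = 0, p = 1 and a flag that
  forces them to the rank bottom. A constant signature score within a
  group is an error, not a silent zero.
- Validation is fail-fast with named exceptions (duplicate ids,
  unannotated samples, non-numeric cells, malformed GMT lines); nothing is
  coerced.
- Probabilities that could underflow (EBP, Fisher enumeration) are
  computed in log space or via scipy's stable routines.
- p-value ties in rank ordering are broken by q then gene id; every sort
  in the package is stable and keyed, so outputs are deterministic across
  runs and platforms.

## Known limitations

- The moderated-t prior fit is a moment match, not limma's F-likelihood
  fit; p-values differ from limma by a few percent in the tails (fold
  changes are identical).
- The EBP model assumes top-percentile membership is independent across
  groups with constant probability f; correlated groups (shared biology)
  make it anti-conservative as a literal null probability — it is used as
  a ranking/selection statistic, not a calibrated test.
- The exact Fisher route enumerates per pair; all-pairs matrices beyond a
  few hundred genes become slow (O(n² ) exact tests). Identical tables are
  cached within a call.
- No covariate adjustment anywhere (survival, differential expression);
  the non-cancer-specimen culling criterion for real compendia is the
  caller's responsibility.
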