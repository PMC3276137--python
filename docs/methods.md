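# Methods notes

## Data model and preparation

Genotypes are minor-allele counts for biallelic SNPs. Inbred accessions are
coded haploid-style (ploidy 1, calls 0/1); diploid 0/1/2 coding is supported
but heterozygotes are not expected in the motivating panels. Readers enforce
minor-allele orientation per SNP at load time, so MAF is always the mean
call over ploidy and all downstream burden statistics are invariant to the
original allele coding (the regression slope may flip sign; the LR does
not). Multi-allelic VCF records are rejected per site and reported, never
silently dropped. Fragment membership comes only from the annotation table;
positional overlap is never used.

Phenotype preparation is impute-then-normalize and fully deterministic.
The imputation is a k-nearest-trait scheme (default k = 3): each trait is
standardized over its observed entries, a missing cell is predicted from the
sample's k most correlated observed traits (absolute Pearson correlation
over complete pairs) as a signed |r|-weighted mean of their standardized
values, then mapped back to the target trait's scale. This is a
deterministic stand-in for clustering-style phenotype imputation and is
flagged as such in the run log; it presumes the traits are substantially
intercorrelated, which holds for the flowering-time-style trait families the
pipeline targets. Normalization is the rank-based inverse-normal transform
with Blom offset 3/8 and midranks for ties, so every tested trait is
marginally Gaussian and the Gaussian LR machinery applies.

## Function prediction

PolyPhen categories (benign / possibly damaging / probably damaging) and
SIFT categories (tolerant / intolerant) are inputs; the package never runs
the predictors. Possibly or probably damaging and intolerant calls are
functional, benign and tolerant are not, and nonsense changes are functional
regardless of predictor. SNPs without a prediction are counted as
non-functional and tallied as unscored.

The MAF -> proportion-functional relation is estimated on 20 bins of width
2.5% over (0, 0.5], left-open right-closed (a boundary MAF belongs to the
lower bin). Three candidate regressions are fitted: power (OLS of ln
proportion on ln p), logarithmic and linear. R² is computed on the original
proportion scale for all three — squared correlation of fitted vs observed —
so the models are directly comparable; whether a transformed-scale R² was
intended elsewhere is not decidable, and the original-scale choice is the
documented default. Zero-proportion bins are dropped from the log-space
power fit rather than offset by a pseudo-count, avoiding an arbitrary
constant; a configurable pseudo-proportion exists for users who prefer
offsets. The bin representative is the midpoint by default (mean MAF of the
bin's SNPs is selectable).

MAF units in the fit default to **percent**: the reference coefficients
(PolyPhen a = 0.3562, b = −1.4162; SIFT a = 0.4346, b = −1.4863) only yield
proportions ≤ 1 over the observed MAF range when p is expressed in percent.
The weight used by the function-aided sum test is the *unclipped* a·p^b — it
is a relative weight, not a probability — while a clipped min(1, ·)
companion is reported for display.

Panels too small to populate three usable bins (the fit precondition) fall
back to the reference PolyPhen coefficients, logged with r_squared = NaN:
the MAF–functionality relation is a population-scale regularity, not a
per-panel quantity.

S weights default to the per-category means of predictor delta scores
(0.6772 benign-or-synonymous, 1.7051 possibly damaging, 2.4277 probably
damaging); per-SNP delta scores are selectable. Synonymous or unscored SNPs
inside a fragment take the benign-or-synonymous weight.

## Kinship and the mixed model

Kinship is estimated as allele-sharing similarity
S_ik = 1 − mean_j |x_ij − x_kj| / ploidy (exact-match proportion for integer
calls; missing calls mean-imputed for this computation only), rescaled
against the mean off-diagonal similarity so an average-related pair has
kinship 0 and clipped below at 0, with unit diagonal. The estimator is
pluggable; any n×n PSD matrix can be supplied. Non-PSD inputs are projected
by eigenvalue clipping and the clip is logged.

The mixed model y = Xβ + u + e with Var(u) = 2K σ²_g is fitted by REML.
After the spectral decomposition 2K = U D Uᵀ the covariance is diagonal in
the rotated basis, so the problem reduces to a one-dimensional profile
optimization over γ = σ²_g/σ²_e (bounded Brent on log γ ∈ [−12, 12],
tolerance 1e−8), with an explicit γ = 0 boundary check. β̂ is GLS at the
optimum and û = 2K σ̂²_g V̂⁻¹ (y − Xβ̂). The profile solution is verified in
the test suite against a dense two-parameter Nelder–Mead REML oracle.

Model selection crosses the candidate covariate sets (intercept-only,
genotype PCs with k ∈ {1, 2, 3} by default, optional file-supplied Q or
nMDS coordinates) with {with K, without K} and minimizes BIC =
−2 lnL_ML + q ln n, where q counts fixed effects plus estimated variance
parameters. BIC uses the **ML** log-likelihood, not REML, so models with
different fixed-effect counts are comparable; REML estimates are what the
fit reports for the variance components. Ties break toward fewer
parameters. The exact composition of the model grid is configuration, not
fixed behavior, and each run logs its own grid.

GRAMMAR: marker tests never refit the mixed model. The adjusted phenotype
y_adj = y − Xβ̂ − û is computed once per trait and all single-SNP and
fragment tests regress against it. Permutations likewise permute y_adj
(consistent with the GRAMMAR approximation; permuting raw phenotypes would
re-entangle structure).

Genomic control: λ = median(LR)/0.4549 over the single-SNP scan. The
default mode divides by max(λ, 1) — deflation only — because dividing by
λ < 1 would anti-conservatively inflate statistics; symmetric adjustment and
off are flags.

## Test statistics and thresholds

All tests share LR = n·ln(RSS₀/RSS₁) with RSS₀ from the intercept-only
fit. For single-regressor tests the closed form uses the centered
cross-products; multivariate designs are reduced to a maximal linearly
independent column set greedily in input order (first kept, relative
tolerance 1e−8) and projected through a QR basis, with df = retained
columns. A numerically perfect alternative fit (RSS₁ below 1e−12·RSS₀) is
capped and logged rather than returning an infinite statistic. Designs with
≥ n − 2 retained columns are rejected as saturated.

Rare means 0 < MAF < 0.05 strictly; the boundary SNP is common; monomorphic
SNPs are excluded everywhere. p_j in the weighted-sum denominator is the
sample MAF with no pseudo-count, so a single carrier contributes weight
1/√(n·(1/n)(1−1/n)). Any collapsing test requires m ≥ 3 rare variants; the
fragment is otherwise skipped with the reason recorded, and dispatch falls
back to the multivariate common-variant test when commons exist.

Finite-sample behavior worth knowing: the n·ln(RSS₀/RSS₁) statistic is
mildly liberal against its asymptotic χ²_df reference at n ≈ 100, visibly
so for multi-df designs (df ≈ 10 gives empirical size ≈ 0.07 at nominal
0.05). This is precisely why fragment-level significance in the pipeline is
permutation-based; the acceptance suite checks asymptotic calibration for
the 1-df collapsing tests and exact permutation calibration for the
multi-df tests.

Permutation thresholds are experiment-wise per (trait, method): each of
n_perm (default 1000) seeded permutations of y_adj records the maximum LR
across all fragments of that method's battery, and LR99 is the empirical
99th percentile (linear/type-7 interpolation) of the maxima. The scope is
configurable to per-fragment. Per-unit permutation p-values are the
fraction of maxima at or above the observed LR. Designs are orthonormalized
once, so observed and permuted statistics share one code path and the
battery is O(n·df) per permutation.

## Filtering and gene network

Routes partition the tested (trait, fragment) cells: a priori confirmation
(candidate-listed gene, p ≤ 0.001 in *every* applicable method — permutation
p when available, else asymptotic, with the source recorded), top-30 triage
on the LR/LR99 scale (ties: LR descending, then unit id — the deterministic
stand-in for an unstated tie rule), the ≥ 3 predicted-functional-SNP rule,
and rejection. Cross-method consistency reports the Venn cells of the three
collapsing tests over a shared unit universe.

Network interrogation scores a gene by the summed LLS of its edges into the
seed set (max-edge scoring is a flag); the sum matches the additive
Bayesian-integration semantics of LLS networks. The seed set's coherence is
a leave-one-out ROC AUC: each seed scored against the remaining seeds,
every non-seed network gene scored against the full seed set (negatives are
all non-seeds, not a sample — deterministic), AUC by the midrank
Mann–Whitney statistic. Pruning removes the minimal-LOO-score seed
(lexicographic tie-break) until AUC ≥ 0.95 or a 3-seed floor errors out;
the audit trail records every removal with the recomputed AUC. Note the
stopping rule means a final isolated seed can survive if the AUC crosses
the target before its removal; a stricter target removes it. Retrieval
ranks non-seed genes by seed score (zero scores excluded, ties by id) and
returns at most top-200.

## Synthetic data

The generators emulate the statistical regularities the pipeline assumes:

- **MAF spectrum:** each SNP draws a target MAF from a mixture — rare with
  probability 0.5 on (1/n, 0.05), common uniform on [0.05, 0.5) — and is
  realized as an *exact* minor-allele count (clamped to the rare/common side
  of its mixture component), so the realized rare fraction tracks the ~50%
  the pipeline is designed around instead of drifting with binomial noise.
- **Structure:** carriers are drawn with per-subpopulation weights
  exp(N(0, divergence²)); divergence 0 gives a panmictic panel.
- **Function:** a SNP is functional with probability min(1, a·(100p)^b)
  using the reference curve; functional SNPs are nonsynonymous
  (probably/possibly damaging, 5% nonsense), non-functional SNPs distribute
  over benign/synonymous/intronic/intergenic; SIFT agrees with PolyPhen 90%
  of the time; delta scores scatter around the category S means.
- **Phenotypes:** subpopulation mean shifts + a polygenic term with
  covariance 2K σ²_g (h² = 0.3 by default) + a shared factor inducing
  trait correlation (~0.5) + i.i.d. noise. Planted causal fragments add a
  rare-variant burden scaled to explain 20% of trait variance by default —
  the single-major-locus regime typified by FRI in Arabidopsis flowering
  time — with per-SNP effects either uniform or proportional to S_j·p^F_j.
- **Network:** a planted seed clique with high LLS (U(1.5, 3)) over an
  Erdős–Rényi noise background with low LLS (U(0.1, 0.5)); optional
  appended isolated "seeds" give pruning something to remove.

What the generators deliberately do **not** emulate: within-fragment
linkage disequilibrium and haplotype structure (columns are exchangeable
given frequency), sequencing/calling error, selection-driven site-frequency
shapes, ascertainment of fragments, or trait non-Gaussianity beyond what
the rank transform removes. Passing tests therefore demonstrate the
statistical machinery — calibration, weighting, thresholds, routing — not
robustness to LD confounding or data-quality pathologies in real
resequencing panels.

Every generator is a pure function of its spec (mandatory seed); truth
records list causal fragments, SNPs and effects so recovery checks never
reverse-engineer the generator.

## Problem sizes in the test suite

Simulation-based checks run at deliberately modest sizes chosen to make the
suite quick to run repeatedly during development: null-calibration at 1500
replicates (99% binomial CI half-width ≈ 0.015 around α = 0.05),
permutation calibration at 40 runs × 200 permutations, REML recovery at
n = 300 × 30 replicates, power ordering at 150 paired replicates with a
one-sided sign test, end-to-end recovery at 10 pipeline replicates, and the
demo/battery panels at 96 samples × 30–60 fragments with 150–200
permutations. The assertions use tolerance bands matched to these replicate
counts.

## Known limitations

- The GRAMMAR approximation tests markers against residuals rather than
  refitting the mixed model per marker; its small power cost is the price
  of the permutation budget, as usual.
- The multi-df asymptotic p-values are liberal at panel-scale n (see
  above); rely on permutation significance for fragments.
- The kinship estimator is a simple allele-sharing rescaling; panels with
  strong inbreeding-depth gradients may prefer a supplied kinship.
- Phenotype imputation assumes correlated traits; with near-orthogonal
  traits it degrades toward column means (and says so in the log).
- The network AUC treats all non-seeds as negatives; in a real functional
  network some "negatives" are undiscovered positives, which biases AUC
  downward — harmless for pruning, but not an unbiased retrieval estimate.
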