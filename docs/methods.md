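# Methods

## Model and estimators

All association fits are additive Cox proportional-hazards models: the hazard
of individual i is h0(t)·exp(β·g_i + x_iᵀγ) with dosage g ∈ {0,1,2}. The scan
fits one SNP at a time (the field's standard mass-univariable analysis), with
optional covariate adjustment and stratified baselines. The Wald statistic
β̂/σ̂ is referred to the standard normal; "selected" means the two-sided p is
below the rule's α, optionally capped at the top k ranks. Ranks are assigned
by ascending p with ties broken by SNP id, so results are independent of file
order. Before any resampling the panel is recoded (g → 2−g) so every naive
estimate is non-negative; by the reparameterisation symmetry of the partial
likelihood this is a sign flip, not a refit.

### Genome-wide bootstrap

Each of B replicates draws n individuals with replacement (within-sample) and
keeps the never-drawn individuals (out-of-sample, ~e⁻¹·n of them). The full
scan and the same selection rule are rerun on the within-sample data; the
replicate's own k-th-ranked SNP is paired with the original k-th rank — by
rank, never by identity, which is precisely what lets the estimator absorb
ranking competition among SNPs. For original rank k the bias estimate is the
average over the B(k) ≤ B usable replicates (those selecting ≥ k SNPs with a
convergent out-of-sample fit) of

  (β̂_Di(k) − β̂*_Ei(k)) · √(2p_i(1−p_i)) / √(2p_k(1−p_k)),

subtracted from β̂_N(k) and truncated at 0. Both MAFs are measured in the
original data: selection bias in a logHR scales as the inverse genotypic
standard deviation √(2p(1−p)), so the factor converts a bias measured on the
replicate-selected SNP to the scale of the originally selected one.

The within- and out-of-sample estimates are negatively correlated because the
total sample is fixed. The adjustment β̂*_E = β̂_E − r·(β̂_D − β̂_N,selected)
uses, by default, the empirical ratio r = cov(β̂_D, β̂_E)/var(β̂_D) computed
across the replicates at each rank. This plug-in is well defined at any B ≥ 2,
vanishes when the two fits are uncorrelated, and makes the whole correction
exactly recomputable from the persisted replicate records (the property the
oracle tests assert to 1e-12). A variant that rescales the empirical rank
correlation by each replicate's model-based standard errors is available as
`adjust="hybrid"`; `adjust="none"` disables the adjustment.

Replicate-level orientation: within each replicate the selected, ranked SNPs
are oriented so the within-sample estimate is positive (the out-of-sample and
original-scan values are flipped coherently). The original-sample recoding
alone cannot do this — a replicate can select a null SNP in the direction
opposite its original orientation, and without re-orientation such replicates
would cancel rather than contribute the selection-bias signal that the
concordant/discordant decomposition diagnostic (Δ_C, Δ_C*) measures.

### Comparators

The single-SNP bootstrap applies the same resampling to one SNP: only the
replicates in which that SNP itself is significant contribute
(β̂_D − β̂*_E) differences (MAF factor ≈ 1, computed as within-replicate vs
original frequency). It corrects threshold bias only; with low power both
within- and out-of-sample estimates of a selected SNP are inflated, so the
difference understates the bias — visible in the studies as residual upward
bias for low-power SNPs.

The conditional-likelihood compromise estimator conditions the normal
approximation β̂ ~ N(β, σ̂²) on its own selection event |β̂/σ̂| > c and averages
the conditional MLE with the mean of the normalised conditional likelihood.
Numerics: both are evaluated on [β̂ − 8σ̂, β̂ + 8σ̂]; the MCL mean by
trapezoidal integration on 4,001 points, the CMLE by bounded scalar
maximisation (tolerance 1e-8). An independent 10⁴-point grid implementation
agrees to 1e-4.

### Power and selection bias

power = Φ(|β|·√(D·2p(1−p)) − z_{1−α/2}) with Hardy–Weinberg genotypic
variance 2p(1−p); required events invert this in closed form with an exact
minimality fix-up. The expected selection bias is the mean of the positively
oriented two-sided truncated normal minus |β|; it is non-negative, grows with
stricter α and lower MAF, and vanishes as power → 1. At n = 2,000 the
empirical detection frequency of the simulator matches this approximation
within Monte-Carlo error; at a few hundred events the approximation is
optimistic by a few percentage points (it uses the null variance of β̂).

## Numerical core

Per-SNP fits use a Newton solver for the Breslow partial likelihood,
vectorised across SNPs. Because dosages take only three values, the risk-set
sums S0, S1, S2 at every event time are affine in (e^β, e^2β) with
β-independent count coefficients, precomputed once per dataset; an iteration
costs O(D·m). Safeguards: step clipping at |Δβ| ≤ 2, step halving on
likelihood decrease (30 halvings max), 50 iterations, |β| > 15 flagged as
monotone likelihood (non-convergent, excluded from selection), constant
dosages flagged degenerate. Bootstrap rescans run the same solver warm-started
at the original estimates in single precision (estimates to ~1e-5, which only
replicate-level averages consume); original-sample fits are double precision.
A conventional dense Newton handles covariate-adjusted fits and Efron ties.
Cross-checks: brute-force maximisation of the Breslow likelihood (1e-6),
lifelines on tie-free and Efron fixtures, stratified fits against lifelines.

Missing dosages are handled by per-SNP complete-case analysis, and MAFs are
computed over non-missing entries; risk scores report a per-individual count
of missing scored SNPs rather than imputing.

## Synthetic data

Event times follow the inverse-cumulative-hazard construction: U ~ U(0,1),
h* = −log(U)/exp(η) with η clipped to ±35, and T = min{t: H0(t) ≥ h*} by
right-continuous step inversion (ties to the earlier step); h* beyond the
last step ⇒ administrative censoring at the stratum's last follow-up time.
Baselines are Nelson–Aalen step functions estimated per stratum (lifelines)
or parametric exponentials for closed-form checks — with an exponential
baseline and η = 0 the generated times are exactly Exponential(λ).

Genotypes are drawn Binomial(2, p) per SNP, independent across gene blocks;
optional within-block LD comes from a per-individual, per-haplotype latent
uniform shared across the block (mixture weight ρ), preserving marginal MAFs.
The two-donor expansion enlarges an existing panel: gene blocks are split
greedily into two SNP-balanced sets, each new individual copies one set from
each of two donors drawn with replacement, and covariates follow the second
donor. Block haplotype patterns are preserved exactly; per-SNP MAFs drift
only by donor-resampling noise (SD ≈ 0.4 pp at a 4× expansion).

What the generator does not emulate: realistic recombination/coalescent LD,
population structure, genotyping error, informative censoring or mid-study
dropout. Passing tests therefore demonstrate the estimator's behaviour under
threshold/ranking selection with clean genotypes, not robustness to those
artefacts.

## Study profiles and scales

The application-scale profile mirrors the motivating candidate-gene design:
1,213 analysed SNPs in 201 gene blocks, n = 5,444, 15 common true positives
carrying the published generating MAFs/logHRs plus four low-frequency
(2–5% MAF) background positives whose values are representative choices (the
originals were not published), covariates sex (−0.59), treatment (−1.48),
cohort (0.73), and entry-year strata.

The default evaluation runs a reduced profile chosen as this package's
desk-scale design: 300 SNPs in 100 blocks, n = 2,000, three entry-year strata
with exponential baselines (rates 0.020/0.028/0.038 per year, administrative
censoring at 18 years; ≈1,180 events per dataset), the same three covariates,
eight common true SNPs whose generating logHRs (0.17–0.37) were set via the
analytic power formula to span detection power ≈0.95 down to ≈0.1 at the
5×10⁻⁵ threshold, and two low-frequency background SNPs excluded from the
MAF ≥ 5% analysis panel. Because generation is multivariable but analysis is
univariable, bias is measured against the mean fitted marginal logHR over all
replicates, not the generating value. The study harness runs 200 replicates
with B = 50 bootstrap replicates at 5×10⁻⁵ (parameter recovery), and a
60-replicate companion at α = 0.01 with B = 25, where false positives are
frequent enough to populate MAF bins (at 5×10⁻⁵ a 300-SNP panel yields only
a handful of false positives in 200 replicates). B = 50 is half the
application default B = 100: the studies summarise mean bias across many
selections, where the extra bootstrap precision is immaterial.

## Reproducibility

Every stochastic component takes an explicit seed. Bootstrap replicate i is
seeded seed+i, so any single replicate is reproducible in isolation; study
replicates derive child seeds from a SeedSequence, so a study is a pure
function of (spec, seed, n_replicates). Replicate records (within/out
estimates, variances, MAFs, the original estimate of each replicate-selected
SNP) are retained and exported, making every corrected estimate recomputable
after the fact. CLI runs write a manifest (config echo, versions, seed,
warning counts) beside their outputs.

## Known limitations

- The GW estimator overcorrects high-power true positives (conservative on
  average above ~65–70% power); this is inherent to rank matching, not a bug.
- Eq-level variance adjustment uses cross-replicate empirical moments; at
  B(k) < 2 the adjustment is dropped (ratio 0).
- Time-dependent covariates, repeated measures, family data and bias-reduced
  confidence intervals are out of scope; point estimates only.
- The analytic power formula ignores covariate-induced variance inflation and
  is calibrated for the univariable scan.
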