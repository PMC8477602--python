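# Methods

## The question and the quantities

Populations under divergent selection accumulate differentiation both at the
loci responding to selection and in the phenotypes those loci build. The
package quantifies both with proportion-of-variance statistics and models
their relationship across a heterogeneous collection of studies.

**F_ST** is computed from per-population allele frequencies as
Σⱼ(pⱼ − p̄)²Nⱼ / (p̄(1 − p̄)ΣⱼNⱼ), with p̄ the census-weighted pooled
frequency (weighting matches the census terms elsewhere in the formula; an
unweighted pooled mean is a defensible alternative the code does not offer).
A monomorphic locus (p̄ ∈ {0, 1}, a 0/0 form) returns 0 — no differentiation
is expressible — and multilocus aggregation averages per-locus values over
polymorphic loci only, so fixed loci neither inflate nor deflate divergence.
Marker classes (microsatellite, AFLP, SNP, QTL-linked, microhaplotype,
sliding window) are metadata covariates, not distinct estimators; no
sample-size-corrected (Weir–Cockerham-style) estimator is provided, because
the database records extracted values rather than recomputing them.

**P_ST** is 1 − SSW/SST over individuals grouped by population — the R² of a
one-way fixed-effects decomposition. It deliberately does not adjust for
heritability or the between/within additive proportion (the c/h² scaling
used in some Q_ST comparisons): those corrections require quantities most
field studies cannot supply, and the database treats common-garden rearing
as a covariate instead. Three derived estimators recover the same number
from what papers actually print:

* from a model **R²** whose only predictor is population (identity);
* from an **F ratio**: with vₜ = fₜ·dfₙᵤₘ/df_den per model term,
  P_ST = v_pop / (1 + v_pop + Σ_Z v_Z). The population term itself appears
  in the denominator; dropping it (as a naive reading of the usual
  formula sheet suggests) would break the identity P_ST = R² in the
  covariate-free case, since R² = v/(1 + v) for a one-way model.
* from **means and SDs**: B/(B + W) with B = Σⱼ(x̄ⱼ − x̄)²Nⱼ. Two weighting
  conventions are offered for W: `printed_n` (W = Σ sⱼ²Nⱼ, matching how such
  formulas are usually printed) and `sum_of_squares` (W = Σ sⱼ²(Nⱼ−1)),
  which reconstructs the raw-data definition exactly when sⱼ are sample
  standard deviations. The between fraction is always returned; the
  within fraction would be 1 − P_ST.

A one-way ANOVA F test on (k−1, N−k) degrees of freedom screens comparisons
for P_ST indistinguishable from zero (threshold p < 0.05).

**Bounded logit.** All proportion-of-variance statistics are modeled on
ln(x/(1−x)) after clamping into [0.005, 0.995]. The floor keeps zeros (e.g.
a neutral F_ST reported as 0) finite; it is applied symmetrically and to all
three statistic kinds, since the logit is undefined at both ends for any of
them, and every clamped value is flagged in the output. The natural log is
used throughout. On this scale the statistic V_b/(V_b+V_w) becomes
ln(V_b/V_w), so doubling the between-population variance component adds
exactly ln 2 wherever no clamping occurs — the property that makes slopes
comparable across very different baseline levels of differentiation.

## The database layer

One `StudyRecord` is a single extracted observation (paper × unordered
population pair × phenotype × method). Invariants (proportions in [0, 1],
non-neutral locus count ≤ total, distinct populations) are enforced at
construction; file ingest reports violations with row numbers and can run
strictly (reject the file) or leniently (drop and log). Neutral F_ST and
mean sample size may be missing; rows missing a model's variables are
dropped per-model, not globally.

For the global analysis, records are averaged into one row per (paper,
population pair, method, software group) on the untransformed scale and then
logit-transformed — averaging before transformation follows how such
databases are usually assembled, and the alternative (average the logits) is
a one-line change kept out of scope. A comparison replicated with distinct
methods keeps one datapoint per method. The within-study table skips
averaging entirely: its unit is the paper × phenotype × method combination
across population pairs.

## The models

All fits are Gaussian identity-link OLS ("general linear models"), with the
log-likelihood evaluated at the ML variance estimate so likelihood-ratio
χ² and AIC are well defined; AIC counts that variance as a parameter
(AIC = 2(k+1) − 2ℓ). R² is 1 − SSE/SST about the response mean, also in the
no-intercept within-study parameterisation.

**Type II likelihood-ratio tests** respect marginality: term T is tested by
comparing the model containing every term that does not contain T, with and
without T; df is the number of design columns removed, p from the upper χ²
tail. Tiny negative χ² (< 10⁻¹⁰, pure rounding on null terms) is clamped to
zero; anything larger fails the test suite.

**Relative likelihood** compares the two non-nested single-predictor
baselines as exp((AIC_a − AIC_b)/2) — the evidence for model B relative to
model A — computed on the rows where both predictors are observed (the only
footing on which the AICs are comparable); at equal parameter counts it
reduces to exp(ℓ_b − ℓ_a).

**The proportion model** adds logit(N_nn/N_total) and its interaction with
logit(nnF_ST); if the interaction's type II test exceeds α = 0.05 the model
is refit without it and both R² values are reported. A proportion of exactly
0 is clamped to the floor and flagged.

**Methodological models** are fit one factor at a time (common-garden flag,
marker, method, software group) to avoid overfitting a ~31-paper database:
factor intercepts, a logit(nnF_ST) slope, factor-specific slopes
(interaction), and the shared proportion effect, each type II tested.
Microhaplotype and sliding-window records fold into the SNP marker level
(both are SNP-based assays; the mapping is an argument), giving the marker
factor four levels. Reference coding is alphabetical and immaterial to the
tests. Levels observed fewer than twice are flagged, not dropped.

**The within-study model** is one joint fit over all winnowed combinations
(≥ 5 population-pair datapoints each): combination-specific intercepts and
logit(nnF_ST) slopes plus a single shared proportion slope — one error
variance, not per-combination fits, because several combinations are too
small to estimate their own. Slope t tests use the joint residual df. The
slope distribution is summarised by the unweighted mean and SD/√n of the
per-combination estimates. Per-combination R² is 1 − SSE_c/SST_c about the
combination's own response mean; because the shared proportion slope can work
against an individual combination, a few negative values are expected and
are reported as-is. A combination with no variation in logit(nnF_ST), or a
proportion column aliased with the intercepts, is reported as an error
naming the combination.

## The generators

**Metapopulations.** Population allele frequencies follow the
Balding–Nichols beta model around a uniform ancestral frequency; non-neutral
loci are simulated with a higher divergence parameter as a proxy for
directional selection rather than via explicit selection dynamics — the
statistical structure the congruence models assume is divergence level, not
its mechanism. The `divergence_f` parameter targets the expected *realized*
single-locus statistic: the raw beta parameter would undershoot it (the
pooled sample mean absorbs 1/k of the between-population variance — half of
it for pairwise comparisons — and the per-locus ratio adds Jensen
curvature), so the beta parameter is calibrated internally by root-finding
on a common-random-numbers Monte Carlo estimate of the expectation
(deterministic, cached per configuration). Diploid genotypes are
Binomial(2, pⱼ); the phenotype is an effect-weighted genotype sum over a
causal set (the flagged non-neutral loci, or — for null constructions — a
disjoint neutral set) plus Gaussian environmental noise with variance
V_g,within(1 − h²)/h², so the within-population heritability matches the
configured h². Per-pair truth (P_ST, neutral F_ST, nnF_ST) is computed by
the package's own statistics on the drawn frequencies and phenotypes.
Defaults — 2 populations × 30 individuals, 500 neutral and 20 non-neutral
loci, divergence 0.05 (neutral) and 0.2 (non-neutral), h² = 0.5 — reflect
the sample sizes and differentiation levels typical of the field studies the
database emulates. Not modeled: dominance, epistasis, linkage, plasticity
beyond iid noise, and selection dynamics; passing tests therefore say the
statistics and models behave correctly for additive architectures, not that
real systems satisfy those assumptions.

**Databases.** Per paper, a marker, method, software group, common-garden
flag, total locus count, and sample size are drawn once; per comparison,
logit(nnF_ST) ~ N(−2, 1.5²) with logit(neutral F_ST) offset one unit below
it plus N(0, 0.5²) noise (the two F_ST kinds are strongly coupled in real
extractions), and a per-paper logit-normal proportion of non-neutral loci
with within-paper jitter (so the proportion is not confounded with paper
identity in within-study fits). Then logit(P_ST) = β₀ + β_F·logit(nnF_ST) +
β_L·logit(prop) + factor shifts + N(0, σ²), inverse-logited into (0, 1).
Defaults — 31 papers × 3 comparisons, β_F = 0.43, β_L = −0.3, σ = 1.1 —
emulate a database of ~90 comparisons in which the congruence slope is
moderate and the single-predictor fit explains roughly a fifth to a quarter
of the variance. The proportion entering the predictor is the realized
count ratio after rounding, so generator parameters are recoverable from the
emitted records alone; recovery within 2·SE at 200 comparisons is an
acceptance property. Inverse-logit keeps values strictly inside (0, 1), so
floor clamping distorts recovery only for draws beyond |logit| ≈ 5.3, which
are vanishingly rare at these settings.

## Numerical and design choices

* Rank deficiency is detected before fitting (matrix rank vs column count)
  and reported with the aliased columns; statsmodels' silent pseudo-inverse
  fallback is never relied on.
* Unordered population pairs are canonicalized lexicographically; all
  statistics are symmetric in the pair.
* Report JSON is written with sorted keys and no timestamps, so a rerun at
  the same seed is byte-identical.
* Test problem sizes (500-dataset oracle sweeps, 200-replicate power checks,
  200-comparison recovery) were chosen as the smallest sizes at which the
  Monte-Carlo error is comfortably inside the asserted tolerances.

## Known limitations

* The F-ratio route assumes the published model's F ratios are mutually
  consistent (same error term); hierarchical or mixed-model F ratios will
  not reproduce a meaningful R².
* Per-comparison averaging treats all contributing records equally; no
  precision weighting (the records rarely carry usable standard errors).
* The within-study summary treats combination slopes as exchangeable; no
  shrinkage or meta-analytic weighting is applied.
* Statistics are not adjusted for sampling error in allele frequencies; at
  very small census sizes the realized F_ST of genotyped individuals will
  scatter around the drawn-frequency truth.
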