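# Methods

## The statistical problem

Given per-patient germline genotype dosages (0/1/2 copies of the alternate
allele, with unknowns), a clinical table (cancer code, covariates, follow-up
time, event indicator), and per-variant annotation (population allele
frequency, CADD deleteriousness, nearest gene), the pipeline asks: which
variants are associated with survival after adjusting for the clinical
covariates that already predict outcome, how consistent are those effects
across cancers, and do they add predictive value to the clinical model?

## Synthetic cohorts with planted truth

Real cohorts of this kind are access-controlled, so the generator in
`germscan.synthetic` produces all input layers with recorded ground truth
(`EffectPlan`, serialized as `truth.json`). What it emulates, and what it
deliberately does not:

- **Genotypes** are Hardy–Weinberg draws at each variant's annotated
  population AF, independent across variants and of the clinical covariates.
  Real cohorts have linkage disequilibrium, population structure, and
  genotype–covariate correlation (ancestry); none is modelled, except that
  duplicated genotype columns can be planted to exercise linkage pruning.
  Consequently, passing tests show the estimators are correct under the
  model's own assumptions, not that they are robust to confounding.
- **Outcomes** follow a Weibull proportional-hazards model. With baseline
  shape *k* and scale *λ*, event times are `λ·(−ln U / exp(η))^{1/k}` with
  linear predictor η = Σ β_cov·covariate + Σ β_var·dosage, which makes every
  planted log hazard ratio exact under PH. Defaults: shape 1 (exponential —
  the least structured choice), scale 365 (a one-year median-scale time
  unit). Censoring is independent uniform "administrative" censoring whose
  horizon is calibrated by bisection so the expected censored fraction
  equals the requested rate (default 0.3, a typical observational-cohort
  figure); real censoring is neither uniform nor independent of calendar
  effects.
- **Call sets**: each of the three sources (normal exome, tumor exome,
  tumor RNA) equals the true genotypes except that each entry is flipped,
  independently per source with probability `discordance_rate` (default
  0.02), to one of the other two genotype classes uniformly. Depths are
  Poisson with per-source means 60/80/30 — ballpark exome/RNA coverage, with
  RNA lowest so that depth masking is exercised mainly where it would be in
  real data. No allele-specific error structure, tumor purity, or somatic
  contamination is modelled.
- **Expression** is standard normal per gene with planted carrier shifts in
  SD units; **driver mutations** are Bernoulli with the planted odds-ratio
  multiplication for risk-allele carriers.
- All randomness flows from one master seed through named child streams
  (`child_rng(seed, name)`), so adding a generator never perturbs another's
  draws and identical configs are byte-reproducible.

## Merge and QC

Calls under `min_depth` (default 10) reads become unknown; merging takes the
first known call in the order normal exome → tumor exome → tumor RNA. A
patient is concordant for a variant only when all three sources agree on a
known genotype — a patient with any unknown source counts as *not*
concordant, the conservative reading of a denominator defined as "all
patients". The three discovery filters are population AF strictly > 0.05,
carrier count (merged dosage ≥ 1) ≥ 15 within the cancer, and per-cancer
concordance strictly > 90%. Both strictness choices and the carrier reading
of "found in" are configurable (`QcThresholds`).

## Survival kernel

`cox_fit` maximizes the Cox partial likelihood by Newton–Raphson with step
halving; tie handling is Efron (Breslow available). With no tied event
times — the generator's continuous times — a vectorized cumulative-sum path
is used (Efron and Breslow coincide there), which keeps genome-scale scans
at well under a millisecond per fit. Convergence requires max |score| <
1e-9; fits with |β| > 50 are flagged as separation and excluded from their
BH family rather than assigned p = 1, keeping the family calibrated (skips
are logged). Wald p-values are reported, matching the convention of the
standard survival packages. The fitter is cross-checked against lifelines
(coefficients and SEs) and its score test against the log-rank statistic in
the suite.

Covariate selection fits the Lasso-Cox path (scikit-survival, 100
log-spaced penalties) and picks the penalty minimizing 5-fold
cross-validated partial-likelihood deviance, computed with this package's
held-out Breslow partial likelihood. Minimum-deviance (no 1-SE rule) is the
least arbitrary rule when the source protocol is silent. An empty selection
is valid.

Genotype coding is additive dosage by default (a dominant/carrier option
exists): carrying two copies plausibly acts more strongly than one, and the
additive score nests the carrier contrast.

Power uses the Schoenfeld events formula with variance inflation,
`power = Φ(|ln HR|·√(D·p(1−p)(1−R²)) − z_{1−α/2})` with D expected events
and p the exposed fraction, at the scan-wide two-sided level α = 0.10 /
(number of variants tested in the cancer). The formula is validated against
simulated rejection rates, not against any particular R implementation,
since published analyses rarely state which variant of the formula they
used. R² defaults to 0 because genotypes are simulated independent of the
covariates.

## Discovery

Per-cancer scans fit one Cox model per QC-passing variant (cancer's selected
covariates + dosage), BH-adjust within the cancer, and call hits at
FDR < 0.10. Recurrence filters the *full* per-cancer results for variants
with p < 0.05 in one shared hazard-ratio direction in ≥ 7 cancers (≥ 5 in
the CADD-restricted version). Group scans pool pre-specified cancer groups
with membership dummies (reference = lexicographically first member, a pure
reparametrization) and per-cancer interaction columns `cancer × covariate`
that are zero outside the cancer; only variants with ≥ 15 pooled carriers
are tested, and a variant hit in overlapping groups is reported from the
largest group. Dummy coefficients are nuisance terms, never reported as
hits. The CADD-restricted analyses re-run the same machinery on the
CADD > 25 subset, with BH families being those subsets.

## Characterization

The direction-concordance index for a variant significant (p < 0.05) in ≥ 3
cancers is `max(n_poor, n_favorable)/(n_poor + n_favorable)`; its expected
value under the observed overall direction imbalance is the same ratio over
all qualifying associations pooled. The comparison of per-variant indices to
that scalar is a one-sample Wilcoxon signed-rank test of the differences: a
two-sample rank-sum against a single constant is degenerate, and the
signed-rank test is the standard one-sample location analogue.

Hazard-ratio consistency uses all within-variant unordered pairs of HRs
(ordered by cancer code), Spearman-correlated; the partial version
rank-transforms HR₁, HR₂ and the variant's AF and computes the first-order
partial correlation r₁₂·₃ = (r₁₂ − r₁₃r₂₃)/√((1−r₁₃²)(1−r₂₃²)).

Linked variants (pairwise genotype r² > 0.8 — no published threshold
exists, 0.8 is the conventional "high LD" cut) are collapsed transitively to
the first variant by genomic position before the GWAS-style statistics.
Minor-allele status uses population AF (< 0.5); the enrichment test is a
one-sided Fisher exact test of minor × poor-direction.

The pair-independence test builds, per pair of poor-direction variants,
three groups — double reference homozygotes, heterozygous for exactly one,
heterozygous for both — excluding alternate-allele homozygotes (their
stronger effect would confound the contrast) and unknown calls; two
covariate-adjusted Cox fits give HR(2 vs 1) and HR(3 vs 1), and a one-sided
paired signed-rank test asks whether carrying both variants is worse than
carrying one. Pairs with an empty group are skipped and logged.

Driver association tests risk-allele carriage × mutation per (variant,
driver with ≥ 5 mutated patients) by one-sided Fisher with BH over all
tested pairs, then a global one-sided Fisher of prognostic-vs-other variants
× associated-vs-not.

Region classification is an interval lookup against a transcript model
(BED12 accepted): upstream/downstream windows are strand-aware 1 kb,
positions inside a transcript are exonic / 5′ or 3′ UTR (CDS boundaries,
strand-aware) / intronic, and a position may collect multiple labels from
different transcripts; anything matching no transcript is intergenic.

## Predictive value and eQTL triage

The time-dependent AUC is the cumulative/dynamic IPCW estimator: cases are
events by *t*, controls are patients at risk beyond *t*, cases weighted by
1/Ĝ(T⁻) with Ĝ the Kaplan–Meier estimate of the censoring distribution
(the controls' common weight cancels); marker ties count one half. Under no
censoring this reduces exactly to concordant-pair counting, which the tests
assert at 1e-12, and it agrees with scikit-survival's estimator under
censoring. ΔAUC compares the linear predictors of the clinical-only and
clinical+variant Cox models, both fit and evaluated in-sample (matching the
source protocol; a cross-validated variant would be the natural extension
but is out of scope), on the grid of unique observed event times between
the 10th and 90th percentiles of event times. Grid points with no cases or
no controls are skipped and flagged. The improvement test is a one-sided
rank-sum across grid points — rank-sum rather than the (arguably more
appropriate) paired signed-rank is a faithful-reproduction choice and is
documented as such.

The eQTL triage requires, at p < 0.10 each (a deliberately relaxed,
hypothesis-generating cut since two tests must agree), a carrier/non-carrier
expression rank-sum difference and a covariate-adjusted Cox association of
the gene's z-scored expression (per-SD hazard ratio; the z-scoring makes the
scale interpretable when the source scale is unstated), with the sign chain
self-consistent: sign(variant log HR) = direction(expression shift) ×
sign(expression log HR). Note the triage cannot distinguish mediation from
confounding: a true eQTL shift on a prognostic variant makes expression a
proxy for carrier status, so its marginal survival association is genuinely
non-null even when the gene itself is inert.

## Numerical and design choices

- BH adjustment is the standard step-up (statsmodels); it is monotone in the
  sorted order but *not* idempotent (no step-up adjustment is), so the suite
  asserts monotonicity and the brute-force `min_{j≥i}(m·p₍ⱼ₎/j)` oracle.
- Patients with an unknown genotype at the tested variant are dropped from
  that variant's fit only; covariates constant within the fitted subset are
  dropped from that fit.
- Every output TSV carries the config hash and master seed in `#` header
  lines; reruns with identical config and seed are byte-identical, and any
  stage can be rerun in isolation from serialized upstream outputs.
- Problem sizes in the shipped demo and tests (3–5 cancers × 200–300
  patients, 40–500 variants, 25–100 replicates) are chosen as the smallest
  cohorts at which the planted effects are comfortably detectable and null
  calibration is measurable; the same code paths scale to cohort sizes in
  the hundreds of thousands of variants.

## Known limitations

Independence of genotypes from covariates and across variants (no ancestry
confounding, no LD); no treatment covariates; no time-varying effects,
stratified baselines, or frailty; in-sample AUC evaluation is optimistic for
weak effects (the null-variant ΔAUC is centred near zero but slightly
positive); the region classifier is a simplified transcript-interval lookup,
not a full annotation engine; the recurrence analyses inherit the source
protocol's caveat that no unbiased chance model exists for them.
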