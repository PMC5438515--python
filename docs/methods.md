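# Methods

## Scope and data flow

`survscan` performs single-variant association scans of time-to-event
outcomes.  Per variant the pipeline is: read genotype evidence → convert to
an additive dosage → align complete cases with the phenotype table → compute
allele-frequency/imputation QC → build the design matrix → fit the chosen
survival model → per-coefficient and overall tests → one output row per
coefficient.  The genotype file is streamed, so memory scales with the
subject count only; any contiguous partition of the line range reproduces
the single-run output exactly, which is the contract that makes cluster
batching safe.

## Input handling

**GEN dialect.**  Five leading columns (snp id, rs id, base-pair position,
allele A, allele B) followed by one probability triple per subject.  The
chromosome is not a column; it is taken from the `-chr` flag.  `-lstart` and
`-lstop` are 0-based *inclusive* line indices (the upstream convention is
ambiguous between 0/1-based and inclusive/exclusive; we fix one convention
and test it).  The optional `-sp`/`-ep` base-pair window is 1-based inclusive
and applied after line selection.

**Probability triples.**  Triples are validated per subject: a NaN or
negative entry, or a sum below 0.9, marks the subject missing at that SNP
(imputation tools emit a probability shortfall when imputation is
uncertain).  All other triples are renormalised to sum to one — including
sums above 1.1 — which keeps every dosage inside [0, 2] without discarding
whole variants.

**VCF.**  Genotype evidence is taken with priority GP > DS > GT.  GP triples
map directly (ALT is allele B); DS produces a dosage-only record for which
the triple-based *info* measure is reported as `NA`; GT hard calls embed as
degenerate 0/1 triples.  Multi-allelic sites are skipped with a warning
because the dosage model is biallelic.

**Sample file.**  Whitespace-delimited with a header row; an Oxford
type-code second row (all tokens in {0, D, C, B, P}) is auto-detected and
skipped so both SNPTEST-style and plain tabular files parse.  The literal
`NA` is the only missing-value token.  Covariates must be numeric
(continuous or 0/1); a non-numeric column is rejected with an instruction to
recode categorical factors as binary indicators.

## Dosage, allele orientation and QC

The dosage is `S_i = p_i1 + 2 p_i2` against allele B.  If the allele-B
frequency among the *analysed* subjects (after listwise deletion) exceeds
0.5, the vector is flipped (`S' = 2 − S`) and the allele labels swapped, so
the reported effect allele is always the empirical minor allele; an exact
tie at 0.5 is not flipped.  Orientation is decided on the analysed subset so
the frequencies, the flip and the regression all refer to the same subjects.
EAF is reported as the major-allele frequency (`1 − MAF`), with both allele
labels present in the output so no information is lost.

The IMPUTE *info* measure uses `e_i = p_i1 + 2p_i2`, `f_i = p_i1 + 4p_i2`,
`θ = Σe_i/2N`:

    info = 1 − Σ(f_i − e_i²) / (2N θ(1−θ)),

defined as 1 when θ ∈ {0, 1} and when every triple is degenerate.  It is not
clamped below zero — negative values are a useful diagnostic.  The measure
is invariant under allele flips.

## Survival models

**Cox proportional hazards.**  Breslow approximation for tied event times:

    ℓ(β) = Σ_k [ s_k'β − d_k log Σ_{j∈R(t_k)} exp(x_j'β) ],

summed over distinct event times with d_k events, covariate sum s_k, risk
set R(t_k).  Breslow ties keep the objective simple, are standard in
GWAS-scale tools, and have well-defined reference implementations for
validation.  Newton–Raphson starts at β = 0 with up to 10 step-halvings per
iteration; the evaluation sorts subjects by time and uses suffix sums, O(n p²)
per iteration.  Standard errors come from the inverse observed information.

**Weibull regression.**  Proportional-hazards parameterisation
`h(t|x) = γ t^(γ−1) exp(α + x'β)` with log likelihood

    ℓ = Σ_i [ d_i(log γ + (γ−1)log t_i + α + x_i'β) − t_i^γ exp(α + x_i'β) ],

maximised over the unconstrained `(α, log γ, β)` with analytic gradient and
Hessian.  Starting values: `α` from the exponential maximum-likelihood rate
(events / total time), `log γ = 0`, `β = 0`.  Zero survival times are
shifted to half the smallest positive time (with a warning) since `log t`
enters the likelihood; the Cox fit is unaffected by such ties at zero.  An
optional fixed-shape mode pins `log γ` (0 gives the exponential sub-model),
used mainly for closed-form validation.

**Convergence.**  Both fits stop when the maximum absolute score drops below
1e−6 or the relative change in the objective falls below 1e−8, with a cap of
25 iterations.  A step whose apparent deterioration is within 1e−10·(|ℓ|+1)
is accepted: near the optimum the true improvement underflows double
rounding (at |ℓ| ≈ 5×10³ the representable resolution is ≈ 1e−12·|ℓ|), and
treating that as a failed step would misreport converged fits.
Non-convergence and singular information are reported per SNP as NA rows
with a reason code, never silently accepted, and never abort the scan.

**Tests.**  Cox coefficient rows carry two-sided Wald tests
(`z = β̂/SE`) and 95% hazard-ratio intervals `exp(β̂ ± 1.959964·SE)`;
intervals are reported for the Cox model only.  Weibull coefficient rows
carry Rao score tests: the design column under test is removed, the
restricted model refitted, and the full-model score U and observed
information I evaluated at that point; the statistic is `U_T' S⁻¹ U_T` with
S the Schur complement of the nuisance block (the efficient information),
χ² with df = number of tested columns, reported as a signed z when df = 1.
The Weibull intercept and shape rows carry Wald tests (for the shape, of
`log γ = 0`, i.e. against the exponential sub-model) — score tests are not
meaningful association tests for these parameters — with the shape SE
mapped from the log scale by the delta method.  The overall model is
summarised by the likelihood-ratio statistic `2(ℓ_full − ℓ_null)` clamped at
zero, df = number of regression coefficients (the Weibull α and γ appear in
both models and are excluded), against the covariate-free null fitted to the
same complete-case data.

## Synthetic data generator

The generator emulates a pharmacogenetic GWAS simulation design at reduced
scale.  What it reproduces:

* biallelic SNP genotypes, Binomial(2, freq) per subject, frequency drawn
  per SNP from a configurable range (default 0.05–0.5), the causal SNP
  pinned at MAF 0.3;
* optional imputation uncertainty: each one-hot triple is mixed with a
  random triple at weight `imputation_noise` and renormalised;
* an exactly balanced 1:1 binary treatment via random permutation — the
  design intends even division between arms, and exact balance also makes
  the assignment deterministic given the seed;
* survival from a Weibull baseline (default shape = scale = 1, i.e. unit
  exponential) under either the proportional-hazards model, by inverse
  transform `T = scale·(−log U / exp(η))^{1/shape}` with
  `η = β_snp·S + β_trt·Z + β_int·S·Z`, or the accelerated-failure-time model
  `log T = log scale − η + G/shape` (G standard minimum-Gumbel); for the
  Weibull family the two coincide when `β_aft = β_ph/shape`;
* random censoring: C ~ Uniform(0, c_max) with c_max solved by Brent's
  method so the expected censored fraction on the realised event-time sample
  matches the target (default 20%).

Default effect size: hazard ratio 2 per minor allele (`β_snp = log 2`),
chosen so the causal SNP is genome-wide significant (p < 5×10⁻⁸) at
n = 1000 — the reference study conditions report only that qualitative
outcome, not its effect sizes.

What it does **not** reproduce: linkage disequilibrium (SNPs are
independent; haplotype-resampling realism is irrelevant to validating a
per-SNP engine), chromosome-scale variant counts, population structure,
informative censoring, and covariate-dependent missingness.  Passing tests
on these data therefore validate the estimator, its inference and the file
plumbing — not robustness to LD, confounding or non-random censoring.

## Numerical and design notes

* Monomorphic dosage (in the analysed subjects), zero events, zero complete
  cases, non-convergence and singular information each produce a single
  per-SNP NA row with a reason code in the final `note` column, keeping the
  output schema machine-readable.
* MAF filtering (e.g. dropping MAF < 0.01) is deliberately *not* applied by
  the scan; it is a downstream results-processing step, so the scan reports
  every variant with its MAF and lets the analyst filter.
* Output floats carry 6 significant digits; p-values are scientific
  notation; `hazard_ratio = exp(coef)` holds in every coefficient row.
* Interactions are requested by the added `-int=` flag (comma-separated
  subset of `-cov=`), the smallest extension consistent with the flag
  grammar; only requested products are fitted, not all pairs.
* Calibration: at n = 1000 the per-SNP tests hold their nominal 0.05 level
  closely; at n = 200 both Weibull tests (Wald and score alike, and
  identically in independent reference implementations) run slightly above
  nominal — ordinary finite-sample behaviour of Weibull maximum-likelihood
  inference, quantified by the type-I-error rates the acceptance script
  computes.
* Problem sizes in the test-suite and acceptance script (25–200 SNPs,
  n = 150–2000, 2000 calibration replicates) are chosen as the smallest
  sizes at which the asymptotic properties under test are expected to hold.

## Known limitations

Efron/exact tie handling, stratified/frailty Cox, time-varying covariates,
competing risks and robust variances are out of scope.  BGEN and indexed
random access (tabix/bgenix) are not supported; GEN input is consumed as a
(possibly compressed) text stream.  Hard-call thresholds and
Hardy–Weinberg tests are not provided; the dosage model is the intended way
to carry imputation uncertainty into the regression.
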