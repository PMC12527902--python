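# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `dcemcda`, and what the synthetic-data tests do and do
not establish about real survey data.

## Attribute schema and coding

The packaged schema holds seven attributes with three levels each:
disease severity, unmet needs, drug efficacy, improvement in
health-related quality of life (HRQoL), drug safety, quality of drug
evidence, and annual treatment cost per patient reimbursed by basic
medical insurance. Levels are ordered worst-to-best and the worst level
(ordinal 0) is the dummy-coding reference, so a profile encodes to 12
indicators plus the continuous cost entry — 13 design columns. Cost is
measured in units of 10,000 RMB/year with levels 50 / 20 / 8
(500,000 / 200,000 / 80,000 RMB); this is the only unit convention under
which the coefficient, WTP and relative-importance scales are mutually
consistent. Effects coding is available as an option but is never the
default. Main effects only; no interaction terms are modelled.

## Experimental design

Design quality is the D-error `det(I)^(-1/K)` of the multinomial-logit
information matrix `I = Σ_sets Σ_j P_j (x_j − x̄)(x_j − x̄)'`, computed
under a prior coefficient vector. The default prior is zero
(utility-neutral: every alternative equally likely); nonzero priors are
accepted. Singularity is detected on the eigenvalues (smallest ≤ 1e-10 ×
largest reads as singular) rather than the raw determinant, so
rank-deficient designs report a D-error of +∞ instead of a spuriously
large float.

The search is coordinate exchange: starting from a random paired design,
every (set, alternative, attribute) position is revisited and the level
that lowers the D-error is kept; passes repeat to convergence and the
best of `n_restarts` random starts wins. Accepted steps never increase
the D-error. Identification requires at least K sets for paired tasks,
enforced up front. Candidate swaps that would make a set's two profiles
identical are skipped; sets where one profile dominates the other on
every attribute are logged as warnings but not forbidden.

The default 30-set design is split into three blocks of ten by a greedy
swap heuristic that balances attribute-level frequencies across blocks
(the blocking objective is a design choice; any equal split is
structurally valid). Each questionnaire is a block plus one duplicated
task inserted at a seeded position at least two tasks after its
original, giving 11 tasks; the opt-out is appended to every task at
questionnaire assembly and never enters the design optimization.

## Synthetic respondents

The generator exists because the underlying survey data are not publicly
deposited; it emulates the statistical structure the analysis assumes.

* Coefficient means default to the published all-respondents mixed-logit
  estimates (packaged in `dcemcda.reference`); between-respondent SDs
  default to half the absolute means, a moderate heterogeneity level
  chosen once for realism.
* The opt-out ASC (default 2.454) attaches to the opt-out utility, the
  stated definition in the source analysis. Because the sign/attachment
  convention cannot be settled externally, `asc_on_opt_out=False`
  attaches it to the drug alternatives instead.
* Choices are sampled from the MNL probabilities of each respondent's
  own drawn coefficients; attentive respondents answer the repeated task
  identically with probability 1 − `lapse` (default 0).
* A `careless_fraction` (default 15/84) of respondents choose uniformly
  at random, produce random SMART blocks, and draw completion times
  below the 8-minute validity threshold, so the default 84-respondent
  run yields exactly 69 valid questionnaires. Completion times are
  lognormal, median 12 min (attentive, truncated above 8) and 5 min
  (careless, truncated below 8), σ = 0.25 — invented defaults, stated
  here.
* SMART scores are each respondent's own part-worth ranges scaled so the
  top attribute reads 100, plus N(0, 8) rating noise clipped to [0, 100];
  ranks are the descending score order. This makes DCE-derived and SMART
  weights correlated but not identical, mirroring the empirical finding
  that the two methods disagree in ordering; the noise SD is a knob.

What the generator does **not** model: item nonresponse, attribute
non-attendance, learning or fatigue effects, correlated random
coefficients, or systematic subgroup differences (the demographic
`group` label alternates deterministically and carries no preference
shift by default). Passing tests therefore show the pipeline is correct
under the assumed data-generating process, not that real respondents
behave this way.

## Validity screening

A questionnaire is valid iff completion time ≥ 8.0 minutes (compared
inclusively, sub-minute precision preserved) AND (the repeated task got
the identical answer OR the SMART ranks are weakly concordant with the
SMART scores). Concordance means no strictly higher score carries a
strictly worse rank; ties impose no constraint. The identical-answer
reading of the consistency test is the strict interpretation; a
rank-correlation-threshold variant of the SMART rule can be configured.
Verdicts depend only on the individual record, so filtering is
idempotent and order-independent.

## Estimation

Estimation rows are 3 per scored task (drug 1, drug 2, opt-out with a
zero design vector); the consistency repeat is excluded by default, so
69 respondents contribute 69 × 10 × 3 = 2,070 rows. The panel must be
regular (equal tasks per respondent, equal alternatives per task);
results are invariant to row order because tensors are sorted
internally.

**Conditional logit.** Analytic gradient, BFGS followed by Newton
polishing with the exact Hessian; convergence is declared on the
gradient norm (∞-norm < 1e-7·(1+|ll|)). SEs come from the inverse
observed information. Non-convergence is flagged on the result, never
raised, so pipelines can log and continue.

**Mixed logit.** Default specification: the 12 categorical dummies
random (independent normals), cost and ASC fixed — 26 parameters
(14 means + 12 SDs). This parameter count, together with
N = alternatives × scored tasks × respondents, exactly reproduces the
published AIC/BIC from the published log-likelihoods
(2k = AIC + 2·ll ≈ 52 and k·ln N = BIC + 2·ll give N = 2070/1110/960 in
the three respondent groups), which both fixes the default `ModelSpec`
and confirms that the repeated task was excluded from estimation. The
simulated likelihood averages the product of a respondent's task
probabilities over R scrambled-Halton normal draws (default R = 500,
burn-in 100, one long stream partitioned across respondents; draw count
and seed recorded in every result). Optimization is L-BFGS-B with the
analytic gradient, started from the conditional-logit fit with SDs at
0.1; a negative SD is observationally equivalent to its absolute value,
so reported SDs are sign-normalized. SEs come from a central-difference
Hessian of the analytic gradient (relative step 1e-5); a singular
Hessian yields absent SEs, not fabricated ones. Conventional
Hessian-based SEs only — no robust/clustered variants.

AIC = 2k − 2ll and BIC = k·ln(N) − 2ll are recomputed and asserted on
every reported result.

## Weights

* **Relative importance**: categorical range = max − min over {0} ∪
  {level coefficients} — the reference contributes 0, so an attribute
  whose best level is a middle level (e.g. evidence, where the moderate
  level outweighs the high one) or whose levels are all negative still
  spans its full range. The cost range is |β_cost| × 42 (the 10,000-RMB
  level span). The formula source states only "βmax − βmin" for the
  continuous attribute; the span-scaled reading is the interpretation
  implemented here, validated by exact reproduction of all 21 published
  weight cells within rounding of the 3-decimal printed coefficients.
  Weights are scale-invariant and sum to 1 by construction.
* **WTP**: −β/β_cost per non-reference level, with a delta-method SE when
  a coefficient covariance is available. A cost coefficient below 1e-8 in
  magnitude raises rather than divides. Unit coherence: recomputing with
  cost in RMB rescales WTP by exactly 1e4.
* **SMART**: per-respondent score normalization then averaging;
  all-zero score vectors are excluded from the score average and logged.
  Orderings are reported both by mean score and by mean rank because the
  two genuinely differ; no reconciliation is attempted.
* **Concordance**: Spearman and Kendall correlations of the DCE and
  SMART rankings plus top-3 overlap.

No aggregate MCDA value score for a specific drug is computed — the
pipeline stops at criterion weights. No sensitivity analysis and no
delta-method intervals for RI.

## Problem sizes and reproducibility

The test suite exercises parameter recovery at 500 simulated respondents
with 500 Halton draws (all 26 parameters recovered within 3 estimated
SEs in the packaged seed), conditional-logit recovery at 1,000
respondents, and Monte-Carlo checks at 20,000–50,000 draws; pipeline
tests use smaller designs (15 sets, ~24 respondents) chosen to keep the
default run quick while still exercising every stage. All randomness
flows through explicit integer seeds: a pipeline config's master seed
derives per-stage seeds deterministically, and regenerating any dataset
or design with its recorded seed is bit-identical.

## Known limitations

* Independent normal mixing only — no correlated coefficients,
  lognormal mixing, or WTP-space estimation.
* The design stage offers no Bayesian (distributional-prior) efficiency
  and no interaction-capable designs.
* Published coefficients are printed to three decimals, so quantities
  recomputed from them (RI, WTP) inherit rounding error of up to ~1.3%
  relative on near-zero coefficients.
* Simulated-likelihood results depend (weakly) on the draw count; the
  suite checks < 0.1% movement between 500 and 1,000 draws on a
  50-respondent fixture.
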