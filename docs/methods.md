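# Methods

This note documents the statistical procedures `nhqi` implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## 1. Quality indicators and restriction

A QI is defined entirely as data: declarative numerator, denominator and
exclusion predicates over named assessment items, plus a covariate list and
a stratifier name (`definitions.py`). Evaluation is three-valued: a rule
whose items are missing is *undecided*. Policy:

- New admissions are excluded unconditionally (restriction), before any
  QI-specific exclusion rule; exclusion rules short-circuit in order, and an
  undecided exclusion rule does **not** exclude.
- An undecided denominator or numerator rule removes the record from the
  denominator. Outcome items are never imputed — fabricating outcomes would
  contaminate the rates that everything downstream consumes. Mean-based
  single imputation (`impute_item_means`) applies to covariates only.
- Change-scope QIs pair quarter *t* (baseline) with quarter *t+1* (outcome)
  for the same resident; residents without a follow-up assessment drop from
  the denominator, and the event is attributed to the outcome-quarter
  facility. Covariates and the stratifier are taken from the *baseline*
  quarter: risk adjustment should condition on status before the outcome
  window, not on values contemporaneous with (and possibly consequent to)
  the outcome.
- Facility-quarters below a configurable minimum denominator (default 5)
  are flagged `low_denominator` but still scored; small denominators make
  rates unstable but no principled cutoff exists.

## 2. The adjustment model

All adjustment quantities are estimated once from a **standard population**
and then frozen into a serializable artifact (`StandardModel`): the
stratifier's p20/p80 thresholds, per-stratum logistic coefficients, the
denominator-share weights w_s, the anchor rates P_s and P_std, and the
covariate means used to fill missing covariates at scoring time. Scoring
any panel against the artifact is then deterministic; the standard
population affects all facilities equally.

Numerical and procedural choices:

- **Quantiles** use linear interpolation between order statistics.  Stratum
  assignment: value < p20 → low, value > p80 → high, ties and the closed
  interval [p20, p80] → middle.  A missing stratifier maps to the middle
  (least extreme) stratum and is counted in `n_stratifier_imputed`.
- **Stratum logits** are maximum-likelihood fits (`statsmodels` Logit).
  Non-convergence, divergence (|coefficient| ≥ 30) or separation triggers a
  ridge-penalized refit (penalty 1e-4 on slopes, intercept free), then an
  intercept-only model; the path taken is recorded in `fit_status` so a
  frozen artifact is always reproducible and finite.  A stratum whose
  outcome is constant in the standard population stores the
  boundary-corrected rate (k+½)/(n+1) as intercept and anchor.
- **Log-odds adjustment**: A = expit(logit O′ − logit E + logit P) realizes
  the observed-versus-expected comparison as a log-odds difference anchored
  at the standard rate, so O = E ⇒ A = P exactly.  O ∈ {0, 1} is corrected
  to O′ = (n+½)/(d+1); the correction is applied identically in the gen-2
  and gen-3 paths so the comparison between generations is fair.  Because
  the correction depends on d, scores at the boundary are not exactly
  invariant to replicating residents; interior scores are.
- **Direct standardization**: gen3 = Σ w̃_s A_s with w̃ the standard weights
  renormalized over the facility's non-empty strata.  Substituting P_s for
  an empty stratum instead would shrink every incomplete facility toward
  the standard mean by a case-mix-dependent amount; renormalization keeps
  the composite an average of the facility's own adjusted strata.  The
  number of empty strata is reported per score.
- **Which covariates at scoring time**: missing covariates are filled with
  the *standard population's* means stored in the artifact, keeping the
  frozen artifact self-contained and all facilities treated identically.

### Why the standard population must be external

Fitting the adjustment regressions on the very sample being profiled lets
the case-mix slopes absorb whatever part of the quality variation is
collinear with case mix (facilities with sicker residents and genuinely
worse care donate their quality signal to the covariate coefficients).  The
expected rates then over-adjust, and the adjusted score tracks only the
part of quality orthogonal to case mix.  `nhqi` therefore treats the
standard population as a separate, broadly representative reference panel —
the configuration the evaluation suite uses — and this is the configuration
under which third-generation scores demonstrably out-rank raw rates in the
presence of confounding (section 4).

## 3. Reliability and validity evaluation

- **Reliability**: Pearson autocorrelation of facility scores across
  consecutive quarters, pairwise-complete, requiring ≥ 3 facilities; zero
  variance in either quarter leaves the coefficient undefined with a
  recorded reason.
- **Element imputation**: chained linear regressions with hot-deck
  replacement.  Cells start at column means; then, for 5 cycles in fixed
  left-to-right column order, each incomplete column is regressed (OLS) on
  all others, missing cells are predicted, and each prediction is replaced
  by the nearest observed value of that column (ties go to the
  first-occurring donor).  The procedure is deterministic and every imputed
  cell is an observed value of its own column.
- **Components**: PCA on standardized columns (the elements are
  heterogeneous in scale, so the correlation matrix is the right metric);
  the first 10 preventive and 10 responsive component scores are exactly
  uncorrelated within each set by construction.
- **Validity models**: unweighted OLS of a QI's facility scores (most
  recent quarter, gen-3) on the 10 preventive components (Model 1), the 10
  responsive components (Model 2), and all 20 (Model 3); R_m is the
  positive root of R².  Classification uses R1 and R3 with the Level I rule
  applied first — R1 ≥ 0.45 or R3 > 0.55 → Level I; else
  R1 ∈ [0.30, 0.45) or R3 ∈ (0.40, 0.55] → Level II; else Level III.  R2 is
  reported but does not enter classification.  Classification is monotone
  in both correlations.

## 4. The synthetic world

No public deposit of real resident-assessment panels exists, so the
generator (`simulate.py`) provides the test bed, with ground truth:

- Each facility carries a quality effect u_f ~ N(0, quality_sd²) on the
  logit scale (higher = more adverse outcomes) and a case-mix shift whose
  correlation with u_f is the `confounding` parameter.
- Residents have a latent frailty = facility shift + within-facility N(0,1)
  deviation.  Case-mix covariates load (0.7) on frailty; the stratifier
  loads (0.8) on the *within-facility* deviation.  Confounding therefore
  enters raw rates through the covariate channel — the facility-mean
  component the adjustment is supposed to remove — while the stratifier
  captures within-facility risk heterogeneity, keeping every facility's
  stratum composition near the standard 20/60/20.  (Shifting the stratifier
  across facilities instead makes stratum cells tiny for extreme-case-mix
  facilities, and the directly standardized composite degenerates into
  boundary-correction noise; that regime is representable by lowering
  `stratifier_loading` and raising `case_mix_shift_sd`, but it is not the
  default world.)
- The cross-sectional outcome is Bernoulli with
  logit p = α + β·x + u_f, α calibrated by root-finding on the realized
  linear predictors so the marginal rate matches `base_rate` exactly in
  expectation.  Change-type outcomes (pain level 0–2, ADL 0–4) follow
  two-state-style quarterly Markov transitions whose deterioration rates
  load on u_f; restraint use is a near-immutable resident trait whose
  stability is controlled by `restraint_flip_rate`.
- Validation elements: 61 preventive columns load negatively and 92
  responsive columns positively on standardized quality (prevention tracks
  good care; responsive activity tracks the problem rates it reacts to),
  plus unit noise and missingness.
- Identical seeds reproduce identical output bit-for-bit.

Defaults (chosen once): 209 facilities × 30 residents × 3 quarters,
base rate 0.25, item missingness 0.08, new-admission rate 0.10,
quality_sd 0.5, confounding 0.5, case-mix shift SD 1.0 (half the frailty
variance between facilities — a cross-sector reference world pooling
custodial, post-acute and continuing-care populations whose resident mixes
differ grossly).

What a green simulation test does **not** establish: the generator's
covariates are exactly the outcome model's covariates (no model
misspecification), items are Gaussian rather than MDS-coded ordinals,
residents neither die nor discharge, and facility effects are
unidimensional.  Real panels violate all four.

## 5. Measured properties and limitations

With the standard model fitted on a large external reference panel and
facility scores averaged over three quarters, third-generation scores
rank-correlate with true facility quality better than raw rates in ≥ 95%
of replicates when case mix is confounded with quality (r = 0.7), and the
gen-2/gen-3 quarter-to-quarter autocorrelations agree to well under 0.1 on
the default world — both recomputed by the test suite.

Two honest caveats, both verified by the suite rather than assumed away:

1. **Direct standardization carries a small variance premium.**  The
   composite multiplies fixed weights into noisy stratum rates; its
   sampling variance exceeds the raw rate's unless every facility's stratum
   shares equal the standard weights.  In the unconfounded null world this
   appears as a ~0.001 deficit in rank correlation with truth — practically
   nil, but statistically resolvable over 200 paired replicates, so "the
   two are indistinguishable" is not exactly true in the strict
   paired-CI sense.
2. **Endogenous adjustment.**  When the standard population *is* the
   profiled sample, the adjustment strips real quality signal (section 2)
   and gen-3 can rank *worse* than raw under positive confounding.  Users
   should fit artifacts on an external reference panel.

Out of scope by design: the full 79-indicator operational library (the
schema supports user-defined definitions instead), multilevel/shrinkage
scoring, facility flagging thresholds (none are established for
third-generation scores), and rare-outcome small-denominator stabilization
beyond flagging.
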