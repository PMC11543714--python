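# Methods

## The measurement model

`truthmpt` implements the two-high-threshold (2HT) variant of the
three-sources source-monitoring model as a multinomial processing tree
(MPT). Responses in the memory test (*true*, *false*, *unchecked*,
*new*) are modelled per item condition (old with "true" feedback, old
with "false" feedback, old unchecked, new) as sums of branch
probabilities, each branch a product of latent Bernoulli probabilities:

- `D_true, D_false, D_unchecked` — item memory: recognizing an old claim
  as old; `D_new` — detecting a new claim as new (2HT architecture).
- `d_true, d_false, d_unchecked` — feedback (source) memory conditional
  on recognition.
- `b` — guessing "old" for an unrecognized item; `a_fb`, `a_true` —
  guessing that feedback was present, and that it was "true", after
  genuine recognition without source memory; `g_fb`, `g_true` — the same
  two guesses following a mere "old" guess.

Guessing parameters are shared across item conditions within a group (the
respondent cannot condition guessing on a source they do not remember)
but differ between groups, because the base-rate manipulation is expected
to shift guessing. The two-group model concatenates two independent
parameter sets, suffixed `_HTB` / `_HFB`; cross-group equalities are
expressed through `ConstraintSet`, which also carries fixed-value
constraints (used by the bias tests).

### Identifiability

The base model equates `D_new = D_unchecked`. Without that constraint
the single-group model has 12 parameters against 12 free category
proportions; its Jacobian is generically full rank (we verified the rank
symbolically), so the model is locally identifiable in the strict sense,
but it is saturated (df 0) and numerically fragile: the smallest singular
value of the probability Jacobian drops by one to two orders of magnitude
relative to the constrained model, i.e. near-flat likelihood directions.
`check_identifiability` therefore reports both the numerical Jacobian
rank (maximized over random interior points) and the minimum singular
value as a practical-identifiability diagnostic. With the constraint the
two-group model has 22 free parameters, 24 free category proportions, and
goodness-of-fit df 2.

## Estimation

Fitting maximizes the multinomial log-likelihood kernel `Σ n log p` on
frequencies aggregated over participants (the standard workflow for this
model family; participant-level heterogeneity is out of scope). The
optimizer is the classic MPT expectation-maximization scheme: the E-step
allocates each observed category count to the branches ending in that
category proportionally to their current probabilities; the M-step sets
each free parameter to its expected success ratio, with tied parameters
pooled across their equality class and fixed parameters folded into
branch constants. EM increases the likelihood monotonically and respects
the unit interval natively. Convergence is declared when the relative
log-likelihood change falls below 1e-10 (at most 10,000 iterations); the
winner over 20 random interior starts plus one moment-style heuristic
start (derived from observed response rates) is then polished by
L-BFGS-B with analytic gradients, bounded to [1e-6, 1−1e-6]. Estimates
within 1e-4 of a bound are flagged `boundary`. When near-tied optima
(within 1e-4 in log-likelihood) disagree by more than .01 in any
parameter, the fit is flagged as a flat-likelihood symptom
(`starts_agree = False`). For routine simulation studies 2 random starts
suffice (the likelihood is well behaved at this design size) and keep
500-replicate studies in tens of seconds; the default of 20 starts is
used for one-shot data analyses.

Goodness of fit is `G² = 2 Σ n ln(n/ê)` with `0·ln 0 ≡ 0`, referred to
χ² with df = free category proportions − free parameters. Standard
errors come from the expected Fisher information
`I = Σ_cells (N_tree/p) (∂p)(∂p)ᵀ` at the estimates; confidence
intervals are Wald, truncated to [0, 1]. A singular information matrix
yields flagged NaN intervals rather than an exception. Wald rather than
profile intervals are the default; published intervals from other
software may differ slightly near boundaries.

## Inference

Nested models are compared by `ΔG² = G²_restricted − G²_general` on df
equal to the number of independent constraints added; each restricted
model is refit from scratch with the full multistart protocol (never
warm-started only), which in practice prevents spurious negative ΔG².
Values in (−1e-4, 0) are clamped to zero; anything more negative raises.

The preregistered restriction ladder tests, in order: (i) item memory
equal across groups (3 df), (ii) `D_true = D_false` within groups (2 df),
(iii) `d_true = d_false` within groups (2 df) — the test that separates
the Cartesian account from the Spinozan and expectation-violation
accounts —, (iv) `b` equal across groups (1 df), (v) `a_fb = g_fb` and
`a_true = g_true` within groups (4 df), (vi) `a_fb` and `g_fb` equal
across groups (2 df). A restriction is adopted iff p ≥ α (default .05)
and later steps are tested against the retained model, so the printed dfs
(3, 2, 2, 1, 4, 2) hold whenever earlier overlapping restrictions were
rejected. No multiple-testing correction is applied across steps — a
deliberate mirror of the preregistered plan. The guessing-bias tests fix
`a_true` or `g_true` at .50 (an interior null, so the central χ²₁
reference applies) and report the direction of the unconstrained
estimate.

## Power analysis

The noncentrality of a restriction test is computed by the
expected-frequency method: generate the exact expected counts under the
alternative's parameter values, fit the restricted model to these
noise-free data, and take the resulting G². This is exact for the G²
statistic, reuses the estimation machinery unchanged, and scales linearly
in total N, so `λ(N) = N·λ(1)`. Power is
`P(χ²_df(λ) > χ²_df,1−α)`; `power_at(0, df, α)` returns α exactly.
`min_sample_size` inverts the power curve by integer bisection, holding
the two-group allocation at the design ratio. Power for goodness of fit
(as opposed to parameter restrictions) is out of scope.

## Synthetic data

The simulator emulates the two-group base-rate design: per group,
participants × items row totals (defaults 103/105 participants;
36 majority-feedback, 12 minority-feedback, 12 unchecked old items and
30 new items each) with multinomial counts drawn from the tree
probabilities. Trial-level records, when requested, are sampled per
participant and aggregate exactly to the returned table. Participants
are homogeneous by default — precisely the assumption of aggregated
fitting — with an optional logit-normal per-participant jitter to probe
robustness; real data additionally contain item effects, sequential
dependencies, and attention lapses that the generator does not emulate,
so passing recovery tests validate the estimation machinery, not the
model's adequacy for any particular dataset.

The three theoretical accounts are encoded as ordinal patterns on the
feedback-memory parameters, with magnitudes as configuration (the source
study does not publish generating values): Cartesian
`d_true = d_false = .60`; Spinozan `d_true = 0` with `d_false = .60`
(and untagged unchecked claims, `d_unchecked = 0`, exposed as a knob);
expectation-violation `d` lower by Δ = .15 for each group's majority
(expected) feedback. Remaining base levels — `D = .55`,
`d_unchecked = .30`, `b = .27`, `a_fb = .66`, `g_fb = .77`,
`a_true = g_true = .70` (majority-"true" group) / `.30`
(majority-"false" group) — sit near the magnitudes observed in this
paradigm, so recovery studies run under realistic cell probabilities.

## Validation choices and problem sizes

- Parameter recovery at the design size uses 500 replicates in the test
  suite (300 in `scripts/acceptance.py`), 2 random starts plus the
  heuristic start per fit; observed |bias| < .01 and 95% CI coverage
  within [.93, .97] for all 22 parameters.
- Error-rate studies of the feedback-memory test use 400 replicates
  (tests) / 300 (script). The power scenario places the effect in the
  Spinozan direction at interior levels, `d_true = d_false − .15 = .45`:
  this matches the study's planning target ("effect of Δ = .15 between
  the feedback-memory parameters") while avoiding the boundary value
  `d_true = 0`, whose literal effect size would be .60, not .15.
- The published minimum sample size for that planning target cannot be
  recomputed because the pilot-study parameter values it assumed are not
  public; the power machinery is instead validated against closed forms
  (binomial KL noncentrality; `power(λ=0) = α`; the df-1, α = .05,
  1−β = .95 inversion at λ ≈ 12.995) and by simulation agreement.
- Degenerate inputs: zero observed cells contribute nothing to G²; a
  zero-total row for a model tree is an error; fitted probabilities are
  kept off zero by the parameter clamp, so G² stays finite.

## Known limitations

- No hierarchical/Bayesian MPT estimation, no latent-class
  heterogeneity, no information-criterion model weights, and no order or
  inequality constraints — equality and fixed-value constraints only.
- Wald intervals degrade near parameter boundaries (e.g. under the
  literal Spinozan regime `d_true = 0`); boundary flags mark the affected
  parameters.
- The `.eqn` reader accepts the classic dialect only (products of
  parameters and complements); constraints are not serialized.
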