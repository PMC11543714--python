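# truthmpt

Model-based measurement of memory for the *truth* and *falsity* of
information. People who see a claim labelled "true" or "false" may later
remember the claim itself, remember the veracity feedback, or merely guess
— and raw attribution scores hopelessly confound these processes.
`truthmpt` implements the standard psychometric solution: the
two-high-threshold variant of the three-sources **multinomial processing
tree (MPT) model**, which decomposes responses in a source-monitoring
memory test into item memory, feedback (source) memory, and several
guessing processes, together with everything needed to run, validate, and
plan such a study.

The package is aimed at memory researchers who want a scriptable,
reproducible Python pipeline for two-group veracity-feedback designs: the
high-"true" base-rate (HTB) and high-"false" base-rate (HFB) groups, each
with old items carrying majority/minority/no feedback plus new test items.

## The model

For each item condition (old "true", old "false", old "unchecked", new)
and each group, a processing tree maps latent events to one of the four
responses *true / false / unchecked / new*. For an old "true" claim:

- with probability `D_true` the claim is recognized as old; then
  - with `d_true` the "true" feedback is remembered → respond **true**;
  - with `1 − d_true` the response is guessed: with `a_fb` a feedback badge
    is guessed present, then "true" with `a_true` / "false" with
    `1 − a_true`; with `1 − a_fb` → **unchecked**;
- with `1 − D_true` recognition fails: the claim is called old with the
  guessing probability `b`; an "old" guess proceeds through the parallel
  guessing parameters `g_fb` and `g_true`; otherwise → **new**.

Parallel trees hold for "false" and unchecked claims (parameters
`D_false, d_false, D_unchecked, d_unchecked`) and for new claims
(detect-new probability `D_new`). The identifiable base model equates
`D_new = D_unchecked`, leaving 11 free parameters per group (22 in the
two-group model, df = 2 against the 24 free category proportions).

Fitting is maximum likelihood via the classic MPT
expectation-maximization scheme plus a bounded quasi-Newton polish;
goodness of fit is `G² = 2 Σ n ln(n/ê)`. Nested models are compared by
`ΔG²`, and a-priori power for parameter restrictions comes from the
expected-frequency noncentrality method with the noncentral chi-square
distribution.

## Worked example

Simulate the two-group design (n = 103/105; 36/12/12 old and 30 new items
per participant) under the *Cartesian* regime — truth and falsity tagged
equally well (`d_true = d_false = .60`) — and run the full preregistered
analysis:

```python
from truthmpt import (AccountSpec, RunConfig, account_parameters,
                      default_design, run_preregistered_pipeline, simulate)

design = default_design()                      # HTB n=103, HFB n=105
params = account_parameters(AccountSpec("cartesian"), design)
simulate(design, params, seed=42).to_csv("frequencies.csv")

run_preregistered_pipeline(
    RunConfig(frequency_csv="frequencies.csv", seed=0, starts=20, out_dir="out")
)
print(open("out/report.txt").read())
```

prints (abridged):

```
Base model: G2(2) = 2.18, p = 0.336

Memory parameters
       D_true  D_false  D_unchecked  d_true  d_false  d_unchecked
HTB      0.53     0.59         0.54    0.61     0.57         0.25
HFB      0.55     0.54         0.57    0.61     0.65         0.29

Restriction ladder
  D equal across groups: dG2(3) = 8.34, p = 0.039 -> rejected
  D_true = D_false within groups: dG2(2) = 9.55, p = 0.008 -> rejected
  d_true = d_false within groups: dG2(2) = 2.09, p = 0.351 -> adopted
  ...
  d_true = d_false retained: feedback memory does not differ between
  'true' and 'false' feedback (Cartesian pattern)

Guessing bias vs .50
  a_true_HTB: dG2(1) = 39.29, p = 0.000 (above .50)
  g_true_HFB: dG2(1) = 54.61, p = 0.000 (below .50)
```

The base model fits (G² small against χ²₂), the feedback-memory
restriction `d_true = d_false` is retained — the generating Cartesian
pattern — and the "true"-guessing parameters sit above .50 in the
majority-"true" group and below .50 in the majority-"false" group,
exactly the base-rate-induced guessing bias the design manipulates. The
CFIM block of the report shows why such raw attribution proportions must
not be read as memory: they shift with the guessing bias even when `d` is
constant.

The same steps are available from the shell:

```sh
truthmpt simulate --account cartesian --seed 42 --out freq.csv
truthmpt pipeline --frequencies freq.csv --seed 0 --out out/
truthmpt power my_power_config.yaml     # a-priori minimum sample size
```

## Model files

Models can be exchanged in the classic `.eqn` dialect used by the common
MPT tools: an optional first line with the number of branch lines, then
one branch per line — `tree category expression` — where the expression
is a `*`-separated product of parameter names and complements written
`(1-name)`; `#` starts a comment. Equality/fixed-value constraints are
not part of the format and are supplied programmatically
(`ConstraintSet`). `truthmpt write-model model.eqn` exports the built-in
two-group model.

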