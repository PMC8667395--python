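# Methods

## Model and decision rule

Each patient's toxicity outcome y at dose j is modelled in a
one-parameter exponential family f(y|d_j) = h(y) exp{η(θ_j) y − A(θ_j)}
with mean μ_j:

| endpoint | η(μ) | A(μ) | data |
|---|---|---|---|
| binary | log(μ/(1−μ)) | −log(1−μ) | DLT indicator in {0, 1} |
| quasi-binary | same, on the normalized score | same | grade score in {0, 0.5, 1.0, 1.5} |
| normal | μ/σ² | μ²/(2σ²) | continuous composite score |

All dose-transition decisions depend only on differences of η and A, so
h(y) is declared but never evaluated. Decisions compare the cumulative
sample mean at the current dose against a boundary pair (λ_e, λ_d):
escalate iff μ̂ ≤ λ_e, de-escalate iff μ̂ ≥ λ_d, otherwise retain. The
comparisons are inclusive, making floating-point ties deterministic.

**Fixed (gBOIN) boundaries** minimize the equally-weighted probability of
an incorrect transition decision under the three point hypotheses
μ = φ₀, φ₁, φ₂; the optimum is λ_k = (A(φ_k) − A(φ₀))/(η(φ_k) − η(φ₀)).
`decision_error_rate` provides an independent brute-force check of this
optimality (exact enumeration for binary data, Gaussian sample-mean CDF
for normal) and the test suite verifies the closed form attains the grid
minimum at n ∈ {6, 12, 30}.

**Shrinkage (gBOINS) boundaries** replace φ₁, φ₂ at per-dose sample size
n by the uniformly-most-powerful-Bayesian-test alternatives φ₁*(n), φ₂*(n)
optimizing g_γ(μ, φ₀) = (log γ + n{A(μ)−A(φ₀)})/(η(μ)−η(φ₀)) under the
evidence schedule γ_k = exp(c_k n^{ε_k}). For the normal family
φ_k* = φ₀ ∓ σ√(2 log γ_k / n) in closed form; for the (quasi-)binomial
family the optimum is found numerically (1001-point grid seed followed by
bounded scalar minimization to 10⁻⁸; the objective is smooth and unimodal
on each side of φ₀ in all regimes exercised). Both boundaries then follow
from the fixed-boundary formula with φ_k* in place of φ_k, so
|λ(n) − φ₀| = O(√(log γ/n)) → 0 and the interval never stops containing
φ₀ — the long-term-memory coherence property (never escalate with
μ̂ > φ₀, never de-escalate with μ̂ < φ₀), which the tests verify
exhaustively over binary tallies up to n = 12 and by fuzzing continuous
data.

## Parameter conventions

| parameter | default | meaning |
|---|---|---|
| φ₀ | — | target mean toxicity (probability / ETS / score units) |
| φ₁, φ₂ | 0.6 φ₀, 1.4 φ₀ | fixed sub-therapeutic / overly-toxic alternatives |
| ε₁, ε₂ | 0.5 | schedule exponents (1 > ε₁ ≥ ε₂ > 0) |
| c₁, c₂ | preset | schedule constants, dimensionless |
| N₀ | 6 | per-dose lead-in under fixed boundaries |
| σ (plug-in) | 1.1 φ₀ | score SD used for normal-family boundaries |
| elimination | 0.95, n ≥ 3 | posterior overdose cutoff and minimum sample |
| cohort / n_max | 3 / 30 | enrollment granularity and patient budget |

The asymptotic theory wants 0 < c₁ < c₂; the tabulation constants in
common use take c₂ = c₁/3 instead, trading the symmetric-consistency
constraint for a safety asymmetry (γ₁ > γ₂: escalation demands more
evidence than de-escalation). `validate_schedule` therefore *warns* about
constraint violations but never blocks a run. Named presets:

- `table1` — boundary-tabulation constants: binary φ₀ = 0.2:
  c₁ = log 1.05; binary φ₀ = 0.3 and continuous: c₁ = log 1.1; always
  c₂ = c₁/3.
- `sim-quasibinary` — c₁ = log 1.2, c₂ = log 1.2 / 3.
- `sim-continuous` — c₁ = log 1.1, c₂ = log 1.1 / 3.
- `sim-binary` — c₁ = c₂ = log 1.05 / 3 (φ₀ = 0.2) or log 1.1 / 3 (0.3).

Sources describing these studies print the (c₁, c₂) pairs inconsistently
(both orderings appear); this package standardizes on the ordering above
because it matches the safety rationale and reproduces both the published
boundary tables and the published operating characteristics, which the
reversed ordering does not.

**Quasi-binary normalization.** A quasi-Bernoulli likelihood requires
outcomes in [0, 1], while ETS scores reach 1.5. The boundary, posterior
and optimization machinery therefore operates on score / max-weight with
the target normalized identically; the API surface (targets, boundaries,
observed means) stays on the raw score scale. Without this normalization
the simulated operating characteristics are 5–10 points away from the
published values; with it the fixed-design results match them within
Monte-Carlo error.

**Normal-family σ.** Boundaries use the plug-in σ = 1.1 φ₀ by default so
in-trial decisions equal the pre-tabulated boundaries; `sample`
(divisor-n sample SD, falling back to the plug-in when n < 2 or the SD is
0) and `posterior_mean` (inverse-gamma(α₀, β₀) prior, user-supplied
hyperparameters — no canonical defaults exist) policies are opt-in.

## Safety rule and its scope

A dose j (and every dose above it) is eliminated when
P(μ_j > φ₀ | data) > 0.95 with n_j ≥ 3, evaluated at the current dose
after each cohort; eliminating the lowest dose terminates the trial and
no MTD is selected. The posterior is beta-binomial with a uniform prior
(fractional pseudo-counts on the normalized score scale for quasi-binary
data) or, for normal data, a t distribution with n−1 degrees of freedom
centered at μ̂ whose scale is the divisor-n sample SD as conventionally
printed for this design; `t_scale="standard"` switches to the
noninformative-posterior scale s/√n. The printed scale does not contract
with n, making elimination deliberately conservative for continuous
endpoints.

`use_elimination` (default on) controls the rule. The published
operating-characteristics studies for the *adaptive* design are
reproduced with the rule off — the source introduces the rule for the
fixed design, and its adaptive-design selection percentages sum to 100%
(no terminated, unselected trials) — so `published_study_config` disables
it for gBOINS runs and enables it for the gBOIN comparator. For actual
trial conduct the rule should stay on regardless of design.

## MTD selection

Only admissible doses with at least one treated patient enter selection.
Observed means are monotonized by weighted isotonic regression (PAVA,
per-dose sample sizes as weights; `sklearn.isotonic` supplies the solver
and a quadratic-programming oracle cross-checks it in the tests). The
selected dose minimizes |μ̃ − φ₀|; ties entirely below the target go to
the highest tied dose, entirely above to the lowest, and an equidistant
straddle to the lower dose (a safety preference; the stated rules cover
only same-side ties). Terminated trials select no dose.

## Simulator

Scenario fixtures ship as plain CSV inside the package: two sets of
sixteen binary scenarios (targets 0.2 and 0.3), four binary sample-size
scenarios, and ten toxicity-grade scenarios with per-dose grade
probabilities; continuous scenarios are generated from the law
N(0.05 + 0.05x, (0.05x)²) over doses x = 1..6. Three printed
grade-probability columns sum to 1.06, 0.99 and 1.14 as published; the
loader renormalizes any column within 0.15 of unity and rejects anything
further off. The expected scores these profiles imply are recomputed
rather than transcribed, because the published expected-score rows for
grade scenarios 9 and 10 duplicate those of scenarios 7 and 8 and
contradict their own probability tables.

Study conditions (in `published_study_config`): quasi-binary — target ETS
0.47 (from the profile 49/18/23/10% over grades 0-1/2/3/4), 30 patients
in cohorts of 3 from the lowest dose; continuous — targets 0.20/0.25
(scenarios 7–10), 100 patients in cohorts of 1 (15 or 60 for the
small-sample scenarios 1–6); binary — 30 patients in cohorts of 3.
Normal outcomes are *not* truncated at zero: the published law is used
verbatim, and the decision machinery is location-scale coherent, so rare
negative scores are harmless.

Each replicate runs on an independent RNG substream spawned from the
master seed, so results are independent of execution order; boundary
pairs are memoized per sample size, which keeps a 4000-replicate study of
100-patient trials under ten seconds.

What the generator does *not* emulate: patient heterogeneity and
covariates, accrual timing and late-onset toxicities, inter-cycle
dependence, and misclassification of grades. Passing simulations
therefore validate the decision arithmetic and the design's comparative
behavior under clean sampling assumptions, not robustness to those
real-data features.

## Numerical choices

- Tabulated boundary values are rounded half-up to 2 decimals for display
  only; trial decisions always use full precision.
- The binomial φ* search runs on (10⁻⁶, φ₀ − 10⁻⁶) and
  (φ₀ + 10⁻⁶, 1 − 10⁻⁶); γ = 1 returns φ₀ exactly (boundary collapse).
- Selection ties use a 10⁻⁹ absolute tolerance, wide enough to absorb
  PAVA pooling round-off and far below any scientifically meaningful
  difference in toxicity means.
- Elimination with a beta posterior uses the regularized incomplete beta
  function directly; the t tail uses the Student-t CDF primitive. Both
  avoid distribution-object overhead in the simulation hot path.

## Known limitations

- The adaptive design's published operating characteristics embed a few
  study-specific conventions (see the safety-rule scope above); two
  grade-endpoint scenarios reproduce 2–3 percentage points below the
  published selection percentages even so, consistent with residual
  unstated details of the original study code.
- The quasi-binary family assumes a fixed, known grade-weight map;
  eliciting weights is out of scope.
- Sample-size re-estimation, phase I/II extensions and delayed-outcome
  handling are out of scope.
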