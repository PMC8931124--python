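# Methods

This note documents the modelling and numerical choices behind
`cancelnudge`: what is computed, under which assumptions, and which
design decisions were genuinely open.

## Decision model

Agents have time-separable CRRA utility `u(x) = x^α/α` with curvature
`α ∈ (0, 1]` (lower α = faster diminishing marginal utility; the
log-utility limit α = 0 is out of scope and rejected), a per-day
discount factor `δ ∈ (0, 1]`, and a present-bias multiplier `β > 0`
that applies to the delayed option **only when the earlier option is
immediate** (t = 0). For t > 0 the present-bias term is inactive — the
β-exponent is zero, not β itself (setting β = 0 would annihilate the
later term entirely; we read the "β = 0 for t > 0" convention as
"β plays no role", and implement that reading).

For a binary choice the agent takes the later amount iff its
discounted utility weakly exceeds the earlier one; **ties go to the
later option** throughout (the indifference condition is stated with a
weak inequality, and the tie rule is explicitly tested).

### Cancellation (partitioned framing)

A pair presented as `c + y₀` now vs `c + y_k` later is evaluated, by an
agent applying the cancellation heuristic, on the residuals
`(y₀, y_k)` alone. The patience threshold then drops from
`δ* = [(1/β)(x₀/x_k)^α]^{1/k}` to the same expression on the residual
ratio. Two readings of the cancelled threshold circulate — with and
without the `1/β` factor. We **retain β** in the cancelled threshold so
that cancellation changes only the amount ratio, never the present-bias
treatment; the inequality `δ*_c < δ*` is unaffected because β enters
both thresholds identically. When `y₀ = 0` the threshold is defined as
0 (the later residual is the only positive payoff).

### Loss domain

Losses are modelled through **residual kept wealth** against the task
endowment ($10 in the published materials), not through a loss-value
function: paying `x` at time t means keeping `E − x` from time t, so a
loss trial is a gain trial in which the *earlier* option carries the
larger payoff. Prospect-theoretic loss aversion and gain/loss curvature
asymmetry are deliberately out of scope.

Cancelling the common *loss* component leaves kept wealth unchanged
(you keep `E − x` either way), so the heuristic is applied to the
kept-wealth representation itself: the two kept amounts share a
seemingly identical component — the smaller of them — and cancelling it
leaves residuals `(x_later − x_earlier, 0)`. A deterministic agent then
never defers a loss under partitioning (the deferred residual is worth
zero), while under integrated presentation agents with β > 1 (a
front-loaded *reverse* bias, present in the population tails) do defer
losses occasionally. This reproduces both qualitative facts in the
published loss data: low but non-zero baseline rates of deferring
losses, and fewer such choices under cancellation.

### Choice noise

The deterministic rule is the model proper. As a clearly-labelled
extension, a Fechner (logistic) noise model is available: the later
option is chosen with probability `logistic(ΔU / τ)` with temperature
`τ ≥ 0`; τ = 0 recovers the deterministic rule and the probability is
exactly ½ at indifference. Replication scenarios default to τ = 0.5
utility units, chosen so that simulated choice rates on the published
stimuli are interior (baseline roughly 40–75% later on $1-difference
gain rows, a few percent deferring losses) rather than degenerate at 0
or 100% — the regime in which framing effects are visible in finite
samples. Noise draws are seeded everywhere.

## Synthetic populations

Agents are drawn independently per parameter from truncated normals at
the published structural-estimate descriptives — α: 0.8861 (SD
0.1255), β: 0.9977 (SD 0.1645), δ/day: 0.9988 (SD 0.0068) — truncated
to the model's admissible ranges (α, δ ∈ (0, 1]; β > 0).

The underlying location/scale are solved numerically so that the
**truncated** moments match the targets. Two of the targets are not
jointly achievable inside this family: a bounded unimodal distribution
with mean 0.9988 and support capped at 1 cannot have an SD of 0.0068
(the achievable supremum is ≈ 0.0012), and mean 0.8861 on (0, 1] caps
the SD at ≈ 0.113. (The published SDs describe *estimates*, which are
not range-restricted — estimated δ can exceed 1.) In those cases the
mean is matched exactly and the dispersion is set to the closest
achievable value; β's moments match exactly. Consequence: simulated
between-subject dispersion in δ is smaller than the published estimate
dispersion, which mainly matters for how much residual heterogeneity
the panel logit has to absorb.

What the generator does *not* emulate: decision-rule heterogeneity
beyond (α, β, δ, τ), order/learning effects across trials, inattention,
and the response inconsistency that produces negative estimated α in
real data (simulated noiseless allocations are always rationalizable).
Passing tests therefore certify the machinery and the model's internal
predictions, not behavioural realism beyond the model class.

Condition assignment in every simulated experiment is
**between-subjects** (a seeded random split), mirroring the designs
being replicated.

## Convex-time-budget estimation

The allocation rule maximizes
`(1/α)δ^t(n·a_t)^α + (1/α)β^I δ^{t+k}((50−n)·a_{t+k})^α` over
`n ∈ [0, 50]`; the interior first-order condition is solved in closed
form and computed in logs so that α → 1 degrades gracefully into the
linear-utility corner (ties at the corner go to the later date). The
allocation is continuous by default; nearest-token rounding is
available to mimic real responses.

Estimation fits the log-linearized FOC
`ln(c_t/c_{t+k}) = b₀·I + b₁·k + b₂·ln(a_{t+k}/a_t)` by least squares
on **interior** allocations only (corners do not satisfy the FOC; they
are counted and reported, not ε-imputed) and inverts
`α̂ = 1 + 1/b₂`, `δ̂ = exp(b₁/b₂)`, `β̂ = exp(b₀/b₂)`. Identification
requires ≥ 3 interior allocations spanning both immediacy values and
two delay lengths; anything less raises an error rather than returning
a silently under-identified fit. `α̂ < 0` (arising when `b₂ ∈ (−1, 0)`,
i.e. a price response too inelastic for any concave utility) is
reported and flagged, never clipped; a separate filter drops flagged
subjects before downstream regressions, replicating the
flag-then-exclude convention. Exact numeric parity with published
parameter means is *not* a target: the published estimator's variant
and corner treatment are not specified, while ours is exactly
identified and verified by noiseless parameter recovery (round-trip
relative error < 1e-5, typically ~1e-8). A censored-regression
treatment of corners is noted as future work.

## Statistical layer

All formulas follow the variants actually used in this literature:

- **Pearson χ² without continuity correction** for 2×2 tables (the
  corrected statistic does not reproduce the published values), with
  Cohen's `w = √(χ²/N)`.
- **Fisher exact**, two-sided: sum of hypergeometric point
  probabilities ≤ the observed one (with a 1e-9 relative tolerance for
  floating-point ties), margins fixed.
- **Mann–Whitney U** with mid-ranks and the tie-corrected normal
  approximation (the replication sample sizes are far beyond exact
  tables); a permutation-exact option exists for small samples and is
  what the enumeration oracles check.
- **Cohen's d** with the (n−1)-weighted pooled SD.
- **Power**: one-tailed df = 1 χ² sizing via the equivalent one-sided
  two-proportion z-test, `N = ⌈((z_{1−α}+z_{pow})/w)²⌉` — the only
  coherent reading of a one-tailed df = 1 specification; two-tailed χ²
  and two-sample t sizing by exact noncentral (χ², t) power iteration.
  Note the published pilot-based N of 147 is 149 by the noncentral-χ²
  iteration; the discrepancy is documented, not replicated.
- **Count reconstruction**: all 2×2 tables consistent with rounded
  printed percentages are enumerated; percentages alone can be
  ambiguous (147 respondents at 77.8%/52.0% admit two tables), so
  published Wilson 95% CIs can be supplied as an additional filter,
  which makes the field experiment's table unique.
- **No multiple-testing adjustment** anywhere: the replication mirrors
  the per-row unadjusted Fisher tests of the source tables.

### Random-intercept logit

`P(y_it = 1) = logistic(x_it'b + u_i)`, `u_i ~ N(0, σ_u²)`, fitted by
maximum likelihood with 21-node Gauss–Hermite quadrature (validated to
1e-6 against adaptive numeric integration on small panels). The
variance is parameterized as `lnsig2u` with a floor at −12 so the
zero-variance limit is well-behaved: on data without subject effects
the fit collapses onto a plain logit (coefficients agree to 1e-3 or
better). Standard errors are cluster-robust over subjects (sandwich
with numerically differentiated per-cluster scores). Average marginal
effects are the sample-average derivative of the predicted probability
at the subject-average intercept (u = 0); integrating over the
estimated intercept distribution is available behind a flag. Possible
separation is warned about via the plain-logit starting fit. The three
reported specifications are (1) condition only, (2) + immediacy and
the three preference parameters, (3) + condition × immediacy and
condition × curvature. A trial-subset selector (`all` vs only the
$1-difference rows) is exposed as configuration, since the published
regression's exact trial basis is ambiguous.

## Retirement-menu valuation

The menu gives an annual benefit per claiming age; no valuation model
is specified by the design, so the simulator's rule is an extension of
this package: an agent claiming at age `s` values the stream of annual
payments from `s` to a horizon age (default 85, configurable) with the
same β–δ CRRA machinery (payments j years out discounted by δ^{365j},
β on non-immediate payments), and picks the age with the highest value
(ties to the later age). In the cancellation frame the constant base
payment is cancelled across all options before valuation, so only the
supplements are compared — the predicted mental representation of the
partitioned menu. The horizon materially affects simulated ages
(longer horizons favour later claiming); the qualitative prediction —
cancellation weakly delays claiming — holds across horizons and is
what the tests assert. The published age-70 menu row is internally
inconsistent by $100 (base + supplement ≠ the baseline figure); the
fixtures reproduce the printed values verbatim.

## Sizes, tolerances, degenerate inputs

- Default scenario sizes follow the published samples (147/75/115/215);
  property tests use 120–300 agents, enough for every qualitative
  assertion to be stable at the fixed seeds.
- Threshold inequality: randomized sweep of 10⁴ valid parameter draws
  plus boundary cases; threshold–sensitivity identity checked against
  central finite differences at relative error < 1e-4.
- Corner classification tolerance in CTB data: 1e-6 tokens.
- Degenerate inputs fail loudly: zero-margin contingency tables,
  empty samples, under-identified allocation sets, losses exceeding
  the endowment, menus with no option past the horizon.
- Every stochastic path takes an explicit seed; identical seeds yield
  byte-identical trial tables and hash-stable scenario reports.

## Known limitations

- The deterministic model cannot produce interior choice proportions
  on stimuli where the whole population sits on one side of the
  threshold (true at the published preference moments for several
  rows); interior rates require the noise extension.
- δ's simulated dispersion is family-capped (see above), so the panel
  logit's δ regressor carries little variation — as in the source
  regressions, its coefficient is essentially unidentified (huge SEs).
- The CTB estimator is least-squares on interior allocations;
  subjects who corner nearly everywhere are dropped as
  under-identified rather than estimated by a censored model.
- Loss-domain behaviour beyond the kept-wealth CRRA account (loss
  aversion, sign-dependent curvature) is out of scope.
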