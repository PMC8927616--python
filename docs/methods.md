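# Methods

## Model

Two players repeat a Prisoner's Dilemma with stage payoffs R = 5 (mutual
cooperation), S = 0, T = 10, P = 1 (row player; the matrix is generalizable,
and every formula below depends on it only through the bilinear form
U(p₁, p₂) = a·p₁p₂ + b·p₁ + c·p₂ + d with a = R−S−T+P, b = S−P, c = T−P,
d = P; defaults give U = −4p₁p₂ − p₁ + 9p₂ + 1).

Each player i is a memory-one (Markov) strategy (αᵢ, γᵢ): cooperate with
probability γᵢ after the opponent cooperated, αᵢ after the opponent
defected. The coupled response dynamics have stationary cooperation
probabilities

    p₁ᶜ = (α₁ − α₂(α₁−γ₁)) / (1 − (α₁−γ₁)(α₂−γ₂)),   p₂ᶜ symmetric.

Profiles with (α₁−γ₁)(α₂−γ₂) = 1 (within 1e−12) are rejected as degenerate:
the denominator vanishes and no unique stationary state exists. We raise
rather than return a limit because the limit depends on the approach path.

## Nash curve

A symmetric totally mixed equilibrium requires both partial derivatives of
player 1's stationary payoff with respect to their own α and γ to vanish at
the symmetric point. Differentiating the composed payoff symbolically, both
first-order-condition numerators share the factor

    5α² + 9γ² − 14αγ + 14α − 10γ + 1,

so the equilibrium set is this conic's arc in the unit square, from
(0, 1/9) to (0, 1). The γ-quadratic 9γ² − (14α+10)γ + (5α²+14α+1) = 0 has
discriminant 16(α² − 14α + 4), which vanishes at α = 7 − 3√5 ≈ 0.29180 —
the largest tolerance to defection on the curve, below the known 0.3 bound.

A transcription of this conic without the 14α term circulates in print. It
is inconsistent: it admits unit-square solutions with α up to ≈ 0.5 and its
points fail the numeric first-order conditions. Both variants are exposed
(`variant="derived"` / `"printed"`); everything operative uses the derived
one, and the inconsistency itself is asserted in the tests.

The numeric oracle for all of this is `foc_residuals`: central-difference
partial derivatives (step 1e−6) of the stationary payoff, computed without
unit-interval validation so the stencil may step marginally outside the
square. On-curve points must have FOC magnitudes < 1e−5; the implicit
residual tolerance for "on the curve" is 1e−9.

## Quantal response equilibrium

The two coordinates of the strategy are treated as binary logit choices with
precision λ. The payoff of pinning player 1's α (or γ) to 0 or 1 is obtained
by substituting the pure value into the *asymmetric* stationary formulas
first and symmetrizing the remaining parameters afterwards
(asymmetric-substitution convention). The resulting four pairs (p₁, p₂) are
intentionally not symmetric, and the "α = 0" expressions still contain α;
symmetrizing before substitution collapses the family to a much poorer set
and is not used. A QRE is a fixed point of

    α = 1/(1 + exp(λ(U|α=0 − U|α=1))),   γ = 1/(1 + exp(λ(U|γ=0 − U|γ=1))),

computed with the exponent clamped to ±700, so the residual is finite for
any finite λ (tested at λ = 1e6).

Published closed forms exist for the four restricted payoffs. Two of them
(the γ-deviation cases) circulate with leading terms that contradict the
very probability formulas they substitute; the test suite uses closed forms
with the leading terms implied by those probabilities as the transcription
oracle and keeps the verbatim variants as a documented inconsistency.

### Solver

`solve_qre` minimizes the squared fixed-point residual
f(α, γ) = (α_resp − α)² + (γ_resp − γ)² over the unit square:

1. evaluate f on a deterministic restart lattice (default 21 × 21,
   vectorized);
2. run bounded L-BFGS-B from every 8-neighbour lattice local minimum plus
   the warm start, if any (screening the lattice rather than polishing all
   441 points finds the same basins for this smooth two-dimensional
   objective at a fraction of the cost);
3. merge refined minima closer than 0.02 and return the lowest; when
   several minima tie within 1e−8 of the best and a warm start exists, the
   one closest to the warm start wins, which makes the λ-sweep follow a
   continuous branch.

There is no randomness anywhere in the solver; the config seed is carried
only for provenance. `converged` means residual < 1e−10. The brute-force
check is a 401 × 401 grid argmin (agreement within one grid cell for
λ ∈ {0.5, 1, 2, 3}).

`count_local_minima` is the same lattice census at a caller-chosen
resolution (≥ 101): interior 8-neighbour lattice minima, refined and merged
at radius 0.02. The census is raw — no residual filter. Noteworthy landscape
facts it exposes: a shallow strict local minimum (depth ≈ 0.042) near
(0.27, 0.95) exists from λ ≈ 1 onward, a precursor of the high-cooperation
fixed-point branch, so the count is already 2 at λ = 2; from λ ≈ 4.5 the
high-cooperation branches become exact fixed points, and from λ = 7.08 a
defection-basin minimum exists as well.

### Landmarks

* **Intersection.** Along the continuation trace (λ from 0 at step 0.01,
  warm starts), the derived Nash implicit function first changes sign
  between λ = 5.64 and 5.65; bisection with warm-started re-solves (width
  1e−3, final linear interpolation) puts the crossing at λ ≈ 5.649,
  (α, γ) ≈ (0.2032, 0.4706). The branch hugs the curve well before the
  crossing — its geometric distance to the conic is below 0.005 from
  λ ≈ 5.0 — which is why visual readings of the crossing tend to round to
  λ ≈ 5.
* **Defection collapse.** The residual's global minimum never moves to
  (0, 0): exact high-cooperation fixed points persist at all large λ. What
  collapses is *search*: at λ = 7.08 (on the 0.01 grid) a local minimum is
  born near the defection corner, and from that λ on, bounded descent
  started at the λ = 0 equilibrium (0.5, 0.5) lands in it; its minimizer
  tends to (0, 0) as λ → ∞. `find_defection_onset` reports this capture
  onset. Membership in the defection basin is a radius-0.4 ball around
  (0, 0): the captured minimizer sits within 0.26 of the corner at birth
  and moves inward, while every other minimum stays beyond 0.55, so any
  radius in roughly (0.3, 0.55) gives the same onset (asserted in tests).
  The literal criterion "trace enters and stays in a delta-ball around
  (0, 0)" is also provided (`find_collapse_threshold`, default delta 0.05)
  and correctly reports no collapse for the global-minimum trace at
  moderate λ.
* **Small-rationality segment.** The traced polyline for λ up to the
  intersection, from (0.5, 0.5) to the crossing point. Classification of an
  estimated strategy is by nearest point on the polyline: "near" within
  0.05, otherwise "above"/"below" by γ relative to that nearest point.
  Labels are stable under 2× resampling of the segment (tested).

## Estimation from play logs

Logs are tidy tables (experiment_id, phase, group_id, round, pair_id,
player_id, choice) with exactly two records per pair and round and rounds
consecutive from 1 within an (experiment, phase). The estimator counts
transitions: the opponent's choice at t−1 conditions the focal player's
choice at t, counted only when the same two players were matched in both
rounds (the memory-one response is defined against a fixed opponent;
re-matched rounds contribute no transition). γ̂ and α̂ are pooled-count
ratios; a zero denominator yields a missing estimate, which downstream
classification skips with a count of skipped units. Group aggregation pools
counts across players — the joint maximum-likelihood estimate under a
shared strategy — never averages per-player ratios. First rounds carry no
transition but do count toward the raw cooperation rate.

## Synthetic experiments

`generate_experiment` emulates the two-phase design: 12 players for 11–22
rounds, then two groups of 6 for 15–20 rounds (round counts drawn uniformly
per experiment). Per phase, each player's (α, γ) is drawn from uniform
boxes — before: [0, 0.3] × [0, 0.4]; after: [0.2, 0.7] × [0.5, 1.0]. These
boxes are calibrated stand-ins, not measured values: real experiments
report only aggregate outcomes (cooperation near 22% before and 58% after
socialization), and the defaults bracket that pattern (≈ 18% / 64% pooled
over 14 synthetic experiments) as a soft check. Pairing defaults to
re-matching every round within the group (uniform random perfect matching);
fixed partners are available. Round-1 choices are Bernoulli(0.5) by default
(`initial_coop_prob`), since the memory-one rule only defines behavior
conditional on a previous round.

What the generator does *not* emulate: strategy drift within a phase,
memory beyond one round, any mechanism of socialization, individual
rationality parameters, or dropout. Passing recovery tests therefore shows
the estimator is consistent for data generated by the model, not that human
play follows it.

## Problem sizes and numerical choices

The landmark pipeline traces λ ∈ [0, 8] at step 0.01 (801 multistart
solves, ~15 s on one CPU) and sweeps the capture onset over λ ∈ [0, 10] at
step 0.01 (~5 s); the full λ ∈ [0, 200] grid of the solver config is
supported but unnecessary for any reported quantity, since all landmarks
lie below λ = 10 and the capture onset is stable thereafter. Estimator
recovery uses 100 pairs × 500 rounds (truth (0.3, 0.7), pooled estimates
within 0.02). Ties in the multistart are broken toward the warm start;
without a warm start, the lowest residual wins. CSV output carries 12
significant digits; JSON carries full double precision.

## Known limitations

* Only the symmetric QRE is computed; asymmetric fixed points (and
  heterogeneous rationality) are out of scope.
* The defection-collapse threshold is a property of descent from the
  uniform point, reported as such; a different start point family would
  give a different capture onset (the basin birth λ is the lower bound for
  all of them).
* With per-round rematching, only repeat-partner transitions inform the
  estimator (≈ 1/(n−1) of rounds in a group of n), so per-player estimates
  from a single short experiment are noisy; pooling across players or
  experiments is the intended use.
* The empirical 22%/58% cooperation rates cannot be recomputed without the
  original round-level data; the synthetic generator only brackets them.
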