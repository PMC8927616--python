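# qrepd

Quantal response and Nash equilibria for the iterated Prisoner's Dilemma in
memory-one (Markov) strategies.

## The problem

Laboratory iterated Prisoner's Dilemma experiments show cooperation rates far
above what classical equilibrium analysis predicts, especially after players
socialize. One way to model this is to describe each player not by a pure
action but by a memory-one strategy `(α, γ)`:

* `γ` — *mutual cooperation*: probability of cooperating after the opponent
  cooperated in the previous round;
* `α` — *tolerance to defection*: probability of cooperating after the
  opponent defected.

Two such strategies playing the stage game with payoff matrix

|            | C (opponent) | D (opponent) |
|------------|--------------|--------------|
| **C**      | 5, 5         | 0, 10        |
| **D**      | 10, 0        | 1, 1         |

induce a Markov chain whose stationary cooperation probabilities
`(p₁ᶜ, p₂ᶜ)` solve `pᵢᶜ = γᵢ p₋ᵢᶜ + αᵢ (1 − p₋ᵢᶜ)`, and player 1's stationary
payoff is the bilinear form `U(p₁ᶜ, p₂ᶜ) = −4 p₁ᶜ p₂ᶜ − p₁ᶜ + 9 p₂ᶜ + 1`.

This package computes, for that model:

1. **The symmetric totally mixed Nash curve** — interior `(α, γ)` where both
   first-order conditions `∂U₁/∂α₁ = ∂U₁/∂γ₁ = 0` hold at symmetric points.
   Deriving the conditions symbolically yields the conic
   `5α² + 9γ² − 14αγ + 14α − 10γ + 1 = 0`, an arc from `(0, 1/9)` to `(0, 1)`
   whose largest tolerance to defection is `7 − 3√5 ≈ 0.2918`. (A variant of
   this conic without the `14α` term circulates in print; it fails the
   first-order conditions and is kept only for a documented-inconsistency
   check.)
2. **The symmetric logit quantal response equilibrium (QRE)** — fixed points
   of `α = σ(λ(U|α=1 − U|α=0))`, `γ = σ(λ(U|γ=1 − U|γ=0))`, where the four
   restricted payoffs come from substituting pure values for player 1's
   coordinates into the asymmetric stationary formulas *before*
   symmetrizing, and `λ ≥ 0` is the rationality (logit precision). Fixed
   points are found by minimizing the squared fixed-point residual over the
   unit square with a deterministic multistart, and the QRE curve is traced
   in `λ` with warm-start continuation.
3. **Landmarks** — the first intersection of the traced QRE branch with the
   Nash curve, the rationality at which fixed-point search collapses into
   the defection basin anchored at `(0, 0)`, and the "small-rationality
   segment" of the QRE curve used to classify empirical strategies as
   high- or low-cooperation.
4. **Estimation** — transition-count (maximum-likelihood) estimates of
   `(α, γ)` and cooperation rates from round-by-round play logs, with
   pooled-count group aggregation, plus a synthetic generator of two-phase
   (before/after socialization) experiments for end-to-end testing.

## Worked example

```python
import numpy as np
from qrepd import (SolverConfig, trace_qre, find_nash_intersection,
                   find_defection_onset, max_tolerance, solve_qre)

print(round(max_tolerance(), 4))          # 0.2918  largest alpha on the Nash curve

sol = solve_qre(1.0)                      # QRE at rationality 1
print(round(sol.alpha, 3), round(sol.gamma, 3))   # 0.274 0.39

cfg = SolverConfig(lambda_grid=np.round(np.arange(0, 8.001, 0.01), 6))
trace = trace_qre(cfg)                    # ~15 s on one CPU
lam, a, g = find_nash_intersection(trace, cfg)
print(round(lam, 2), round(a, 3), round(g, 3))    # 5.65 0.203 0.471
print(find_defection_onset())             # 7.08
```

The trace starts at the uniform point `(0.5, 0.5)` (at `λ = 0` the logit
response is coin-flipping), bends toward the Nash curve, crosses it at
`(α, γ) ≈ (0.203, 0.471)` around `λ ≈ 5.6`, and from `λ = 7.08` onward
numerical fixed-point search started from the uniform point is captured by
the defection basin, whose minimizer tends to `(0, 0)` as `λ → ∞`.

A command-line interface mirrors the library:

```bash
qrepd nash --n 500 --out curve.csv
qrepd trace --lambda-max 8 --out trace.csv
qrepd landmarks --out landmarks.json
qrepd simulate --seed 5 --out log.csv
qrepd estimate --in log.csv --out estimates.json
qrepd classify --in estimates.json --out labels.json
```

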