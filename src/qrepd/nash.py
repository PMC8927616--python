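"""Symmetric totally mixed Nash equilibrium curve for the memory-one
Prisoner's Dilemma.

At a symmetric interior equilibrium (alpha, gamma), player 1 must be
indifferent in both coordinates of their strategy: the partial derivatives of
the stationary expected payoff with respect to player 1's own alpha and gamma
vanish at ``alpha1 = alpha2 = alpha``, ``gamma1 = gamma2 = gamma``.  Both
first-order conditions share a single polynomial factor, so the equilibrium
set is the conic arc

    5*alpha**2 + 9*gamma**2 - 14*alpha*gamma + 14*alpha - 10*gamma + 1 = 0

inside the unit square ("derived" variant).  A variant of this conic without
the ``14*alpha`` term circulates in the literature ("printed" variant); it is
inconsistent with the first-order conditions and with the known bound that
the tolerance to defection never exceeds 0.3 on the curve, but is kept here
for transparency and for the documented-inconsistency check in the tests.

The curve runs from (0, 1/9) to (0, 1); its largest alpha is the smaller
root of ``alpha**2 - 14*alpha + 4 = 0``, i.e. ``7 - 3*sqrt(5) ≈ 0.2918``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .game import profile_payoff  # noqa: F401  (re-exported oracle target)

__all__ = [
    "CurvePoint",
    "nash_implicit",
    "gamma_roots",
    "nash_points",
    "max_tolerance",
    "foc_residuals",
]

# coefficients of the gamma-quadratic  9 g^2 - (14 a + 10) g + (5 a^2 + 14 a + 1) = 0
_DERIVED_LINEAR_ALPHA = 14.0


@dataclass(frozen=True)
class CurvePoint:
    alpha: float
    gamma: float


def nash_implicit(alpha: float, gamma: float, variant: str = "derived") -> float:
    """Residual of the symmetric totally mixed equilibrium condition.

    ``variant='derived'`` (default) evaluates the conic obtained from the
    symmetric first-order conditions; ``variant='printed'`` evaluates the
    literature transcription that omits the alpha-linear term.
    """
    if not (0.0 <= alpha <= 1.0) or not (0.0 <= gamma <= 1.0):
        raise ValueError(f"inputs must lie in [0, 1], got ({alpha}, {gamma})")
    base = 5.0 * alpha * alpha + 9.0 * gamma * gamma - 14.0 * alpha * gamma - 10.0 * gamma + 1.0
    if variant == "derived":
        return base + _DERIVED_LINEAR_ALPHA * alpha
    if variant == "printed":
        return base
    raise ValueError(f"unknown variant {variant!r}")


def gamma_roots(alpha: float, variant: str = "derived") -> tuple[float, ...]:
    """Real roots in gamma of the curve's quadratic at a given alpha,
    ascending.  Empty tuple when the discriminant is negative."""
    lin = _DERIVED_LINEAR_ALPHA if variant == "derived" else 0.0
    a_coef = 9.0
    b_coef = -(14.0 * alpha + 10.0)
    c_coef = 5.0 * alpha * alpha + lin * alpha + 1.0
    disc = b_coef * b_coef - 4.0 * a_coef * c_coef
    if disc < 0.0:
        return ()
    s = math.sqrt(disc)
    lo = (-b_coef - s) / (2.0 * a_coef)
    hi = (-b_coef + s) / (2.0 * a_coef)
    return (lo,) if disc == 0.0 else (lo, hi)


def max_tolerance() -> float:
    """Largest tolerance-to-defection alpha attained on the derived curve.

    The gamma-quadratic's discriminant is ``16*(alpha**2 - 14*alpha + 4)``;
    its smaller root, ``7 - 3*sqrt(5)``, is the apex of the conic arc.
    """
    return 7.0 - 3.0 * math.sqrt(5.0)


def nash_points(n: int) -> list[CurvePoint]:
    """Sample ``n`` points along the derived equilibrium arc, ordered from
    (0, 1/9) along the lower branch to the apex and back along the upper
    branch to (0, 1)."""
    if n < 2:
        raise ValueError("n must be at least 2")
    amax = max_tolerance()
    pts: list[CurvePoint] = []
    for k in range(n):
        t = k / (n - 1)
        if t <= 0.5:
            alpha = 2.0 * t * amax
            branch = 0
        else:
            alpha = 2.0 * (1.0 - t) * amax
            branch = -1
        roots = gamma_roots(alpha)
        if not roots:
            # roundoff just past the apex: fall back to the double root
            alpha = amax
            roots = gamma_roots(alpha) or (_apex_gamma(amax),)
        pts.append(CurvePoint(alpha=alpha, gamma=roots[branch]))
    return pts


def _apex_gamma(amax: float) -> float:
    return (14.0 * amax + 10.0) / 18.0


def _symmetric_payoff_unchecked(a1: float, g1: float, a2: float, g2: float) -> float:
    """Stationary payoff of player 1 without [0,1] validation, so central
    differences can step marginally outside the square."""
    d1, d2 = a1 - g1, a2 - g2
    den = 1.0 - d1 * d2
    if abs(den) < 1e-12:
        raise ZeroDivisionError("degenerate profile in FOC evaluation")
    p1 = (a1 - a2 * d1) / den
    p2 = (a2 - a1 * d2) / den
    return -4.0 * p1 * p2 - p1 + 9.0 * p2 + 1.0


def foc_residuals(alpha: float, gamma: float, step: float = 1e-6) -> tuple[float, float]:
    """Numeric first-order conditions at a symmetric point.

    Central-difference partial derivatives of player 1's stationary payoff
    with respect to their own alpha and gamma, holding the opponent fixed at
    (alpha, gamma).  Both vanish (|.| < 1e-5) exactly on the derived curve;
    this is the independent oracle the curve is verified against.
    """
    if abs(abs(alpha - gamma) - 1.0) < 1e-9:
        raise ZeroDivisionError("degenerate profile near |alpha - gamma| = 1")
    du_da = (
        _symmetric_payoff_unchecked(alpha + step, gamma, alpha, gamma)
        - _symmetric_payoff_unchecked(alpha - step, gamma, alpha, gamma)
    ) / (2.0 * step)
    du_dg = (
        _symmetric_payoff_unchecked(alpha, gamma + step, alpha, gamma)
        - _symmetric_payoff_unchecked(alpha, gamma - step, alpha, gamma)
    ) / (2.0 * step)
    return du_da, du_dg
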