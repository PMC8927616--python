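"""Stage game and memory-one (Markov) strategy dynamics for the iterated
Prisoner's Dilemma.

A memory-one strategy is the pair (alpha, gamma):

* ``gamma`` -- *mutual cooperation*: the probability of cooperating when the
  opponent cooperated in the previous round.
* ``alpha`` -- *tolerance to defection*: the probability of cooperating when
  the opponent defected in the previous round.

Two such strategies playing each other form a Markov chain over the four
joint outcomes; its stationary distribution is summarised by the pair of
stationary cooperation probabilities ``(p1, p2)``, which are the unique
solution of the coupled linear responses

    p1 = gamma1 * p2 + alpha1 * (1 - p2)
    p2 = gamma2 * p1 + alpha2 * (1 - p1)

whenever ``(alpha1 - gamma1) * (alpha2 - gamma2) != 1``.  Expected per-round
payoffs are the bilinear form of the 2x2 stage-game matrix evaluated at those
stationary probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "PayoffMatrix",
    "MarkovStrategy",
    "StrategyProfile",
    "StationaryState",
    "DegenerateProfileError",
    "markov_response",
    "stationary_probabilities",
    "expected_payoff",
    "profile_payoff",
]

_DEGENERACY_TOL = 1e-12


class DegenerateProfileError(ValueError):
    """Raised when (alpha1-gamma1)(alpha2-gamma2) = 1 and no unique
    stationary state exists (e.g. two pure win-stay/lose-shift mirrors)."""


@dataclass(frozen=True)
class PayoffMatrix:
    """Row player's payoffs of the 2x2 stage game.

    Default values are the classic high-temptation Prisoner's Dilemma used
    throughout this package: R=5 (mutual cooperation), S=0 (sucker),
    T=10 (temptation), P=1 (mutual defection).
    """

    reward_cc: float = 5.0
    sucker_cd: float = 0.0
    temptation_dc: float = 10.0
    punishment_dd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("reward_cc", "sucker_cd", "temptation_dc", "punishment_dd"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"payoff {name!r} must be a finite real number, got {v!r}")

    # bilinear form U(p1, p2) = a*p1*p2 + b*p1 + c*p2 + d
    @property
    def bilinear(self) -> tuple[float, float, float, float]:
        R, S, T, P = self.reward_cc, self.sucker_cd, self.temptation_dc, self.punishment_dd
        return (R - S - T + P, S - P, T - P, P)

    def to_json(self) -> str:
        return json.dumps(
            {"CC": self.reward_cc, "CD": self.sucker_cd,
             "DC": self.temptation_dc, "DD": self.punishment_dd}
        )

    @classmethod
    def from_json(cls, s: str) -> "PayoffMatrix":
        d = json.loads(s)
        return cls(reward_cc=d["CC"], sucker_cd=d["CD"],
                   temptation_dc=d["DC"], punishment_dd=d["DD"])


@dataclass(frozen=True)
class MarkovStrategy:
    """Memory-one strategy (alpha, gamma), both probabilities in [0, 1]."""

    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class StrategyProfile:
    player1: MarkovStrategy
    player2: MarkovStrategy

    @property
    def degeneracy(self) -> float:
        """(alpha1-gamma1)(alpha2-gamma2); the stationary state is unique iff
        this product differs from 1."""
        d1 = self.player1.alpha - self.player1.gamma
        d2 = self.player2.alpha - self.player2.gamma
        return d1 * d2


@dataclass(frozen=True)
class StationaryState:
    p1: float
    p2: float


def markov_response(prev_opponent_cooperated: bool, strategy: MarkovStrategy, rng) -> str:
    """Draw one choice ('C' or 'D') from a memory-one strategy.

    Cooperates with probability ``gamma`` if the opponent cooperated last
    round, otherwise with probability ``alpha``.  ``rng`` is a
    ``numpy.random.Generator``.
    """
    p = strategy.gamma if prev_opponent_cooperated else strategy.alpha
    return "C" if rng.random() < p else "D"


def stationary_probabilities(profile: StrategyProfile) -> StationaryState:
    """Stationary cooperation probabilities of a pair of memory-one strategies.

    Solves the coupled linear response system in closed form:

        p1 = (alpha1 - alpha2*(alpha1-gamma1)) / (1 - (alpha1-gamma1)(alpha2-gamma2))

    and symmetrically for p2.

    Raises
    ------
    DegenerateProfileError
        if ``(alpha1-gamma1)(alpha2-gamma2)`` equals 1 (within 1e-12), in
        which case the chain has no unique stationary state.
    """
    a1, g1 = profile.player1.alpha, profile.player1.gamma
    a2, g2 = profile.player2.alpha, profile.player2.gamma
    d1, d2 = a1 - g1, a2 - g2
    den = 1.0 - d1 * d2
    if abs(den) < _DEGENERACY_TOL:
        raise DegenerateProfileError(
            f"profile with (a1-g1)(a2-g2) = {d1 * d2!r} has no unique stationary state"
        )
    p1 = (a1 - a2 * d1) / den
    p2 = (a2 - a1 * d2) / den
    return StationaryState(p1=p1, p2=p2)


def expected_payoff(p1: float, p2: float, payoffs: PayoffMatrix | None = None) -> float:
    """Expected per-round payoff of player 1 at cooperation probabilities
    (p1, p2).

    With the default matrix this is the bilinear form
    ``-4*p1*p2 - p1 + 9*p2 + 1``.
    """
    if not (0.0 <= p1 <= 1.0) or not (0.0 <= p2 <= 1.0):
        raise ValueError(f"probabilities must lie in [0, 1], got ({p1}, {p2})")
    if payoffs is None:
        payoffs = PayoffMatrix()
    a, b, c, d = payoffs.bilinear
    return a * p1 * p2 + b * p1 + c * p2 + d


def profile_payoff(profile: StrategyProfile, payoffs: PayoffMatrix | None = None) -> float:
    """Player 1's stationary expected payoff for a strategy profile."""
    st = stationary_probabilities(profile)
    # stationary probabilities can stray outside [0,1] only for degenerate-ish
    # profiles; clip the validation, not the value, by calling the bilinear
    # form directly.
    if payoffs is None:
        payoffs = PayoffMatrix()
    a, b, c, d = payoffs.bilinear
    return a * st.p1 * st.p2 + b * st.p1 + c * st.p2 + d
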