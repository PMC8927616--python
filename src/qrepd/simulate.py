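"""Synthetic play-log generator emulating a two-phase socialization
experiment.

The emulated design: 12 mutually unfamiliar players play the iterated
Prisoner's Dilemma together for 11-22 rounds ("before" phase); the group is
then split into two groups of 6 that socialize, and each new group plays
another 15-20 rounds ("after" phase).  Each player follows a fixed
memory-one strategy per phase; the phase-specific strategy distributions
are uniform boxes chosen so that pooled cooperation rates bracket the
low-before / high-after pattern seen in such experiments (roughly 22%
before and 58% after).  The socialization process itself is not modeled —
the phase shift is imposed through the strategy distributions.

Players respond to the last move they observed: with per-round rematching
(the default), the state carried into round t is the choice made against
them by their round t-1 opponent, whoever that was.  Transitions where the
partner changed are later dropped by the estimator, matching its
fixed-opponent convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimate import REQUIRED_COLUMNS
from .game import MarkovStrategy, markov_response

__all__ = ["ExperimentDesign", "simulate_pair", "generate_experiment"]


@dataclass
class ExperimentDesign:
    """Parameters of one synthetic experiment.

    Strategy boxes are (low, high) uniform ranges for alpha and gamma per
    phase.  ``pairing`` is ``"rematch_each_round"`` or ``"fixed"``.
    """

    n_players: int = 12
    rounds_before: tuple[int, int] = (11, 22)
    rounds_after: tuple[int, int] = (15, 20)
    n_groups_after: int = 2
    before_alpha: tuple[float, float] = (0.0, 0.3)
    before_gamma: tuple[float, float] = (0.0, 0.4)
    after_alpha: tuple[float, float] = (0.2, 0.7)
    after_gamma: tuple[float, float] = (0.5, 1.0)
    pairing: str = "rematch_each_round"
    initial_coop_prob: float = 0.5
    seed: int = 0
    experiment_id: str = "E1"

    def __post_init__(self) -> None:
        if self.n_players % 2:
            raise ValueError("n_players must be even")
        if self.n_players % self.n_groups_after:
            raise ValueError("after-phase groups must be of equal size")
        if (self.n_players // self.n_groups_after) % 2:
            raise ValueError("after-phase group size must be even")
        if self.pairing not in ("rematch_each_round", "fixed"):
            raise ValueError(f"unknown pairing scheme {self.pairing!r}")
        for lo, hi in (self.rounds_before, self.rounds_after):
            if not (1 <= lo <= hi):
                raise ValueError("round ranges must satisfy 1 <= low <= high")
        if not (0.0 <= self.initial_coop_prob <= 1.0):
            raise ValueError("initial_coop_prob must be a probability")


def _pair_label(experiment_id: str, phase: str, p: str, q: str) -> str:
    lo, hi = sorted((p, q))
    return f"{experiment_id}:{phase}:{lo}|{hi}"


def _simulate_group(
    players: list[str],
    strategies: dict[str, MarkovStrategy],
    rounds: int,
    pairing: str,
    initial_coop_prob: float,
    rng: np.random.Generator,
    experiment_id: str,
    phase: str,
    group_id: str,
) -> list[dict]:
    last_observed: dict[str, str | None] = {p: None for p in players}
    fixed_matching: list[tuple[str, str]] | None = None
    rows: list[dict] = []
    for t in range(1, rounds + 1):
        if pairing == "fixed" and fixed_matching is not None:
            matching = fixed_matching
        else:
            order = [players[i] for i in rng.permutation(len(players))]
            matching = [(order[k], order[k + 1]) for k in range(0, len(order), 2)]
            if pairing == "fixed":
                fixed_matching = matching
        # choices are drawn in stable player order for reproducibility
        choices: dict[str, str] = {}
        for p in players:
            if last_observed[p] is None:
                choices[p] = "C" if rng.random() < initial_coop_prob else "D"
            else:
                choices[p] = markov_response(
                    last_observed[p] == "C", strategies[p], rng
                )
        for p, q in matching:
            pid = _pair_label(experiment_id, phase, p, q)
            for focal, other in ((p, q), (q, p)):
                rows.append(
                    {
                        "experiment_id": experiment_id,
                        "phase": phase,
                        "group_id": group_id,
                        "round": t,
                        "pair_id": pid,
                        "player_id": focal,
                        "choice": choices[focal],
                    }
                )
            last_observed[p] = choices[q]
            last_observed[q] = choices[p]
    return rows


def simulate_pair(
    s1: MarkovStrategy,
    s2: MarkovStrategy,
    rounds: int,
    initial_coop_prob: float = 0.5,
    rng: np.random.Generator | None = None,
    experiment_id: str = "E1",
    phase: str = "before",
    group_id: str = "g1",
    player_ids: tuple[str, str] = ("P1", "P2"),
) -> pd.DataFrame:
    """Simulate one fixed pair for ``rounds`` rounds.

    Round 1 choices are independent Bernoulli(initial_coop_prob); later
    rounds follow each player's memory-one response to the opponent's
    previous choice.
    """
    if rounds < 1:
        raise ValueError("rounds must be at least 1")
    if rng is None:
        rng = np.random.default_rng()
    p1, p2 = player_ids
    rows = _simulate_group(
        [p1, p2],
        {p1: s1, p2: s2},
        rounds,
        "fixed",
        initial_coop_prob,
        rng,
        experiment_id,
        phase,
        group_id,
    )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def _draw_strategies(
    players: list[str],
    alpha_box: tuple[float, float],
    gamma_box: tuple[float, float],
    rng: np.random.Generator,
) -> dict[str, MarkovStrategy]:
    out = {}
    for p in players:
        out[p] = MarkovStrategy(
            alpha=float(rng.uniform(*alpha_box)),
            gamma=float(rng.uniform(*gamma_box)),
        )
    return out


def generate_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Generate the full two-phase play log of one synthetic experiment.

    Fully reproducible from ``design.seed``.  Strategies are redrawn per
    phase; after-phase groups are a random split of the players.
    """
    rng = np.random.default_rng(design.seed)
    players = [f"P{i + 1:02d}" for i in range(design.n_players)]

    rounds_before = int(rng.integers(design.rounds_before[0], design.rounds_before[1] + 1))
    rounds_after = int(rng.integers(design.rounds_after[0], design.rounds_after[1] + 1))

    strategies_before = _draw_strategies(
        players, design.before_alpha, design.before_gamma, rng
    )
    rows = _simulate_group(
        players,
        strategies_before,
        rounds_before,
        design.pairing,
        design.initial_coop_prob,
        rng,
        design.experiment_id,
        "before",
        "all",
    )

    strategies_after = _draw_strategies(
        players, design.after_alpha, design.after_gamma, rng
    )
    perm = [players[i] for i in rng.permutation(len(players))]
    size = design.n_players // design.n_groups_after
    for g in range(design.n_groups_after):
        members = sorted(perm[g * size : (g + 1) * size])
        rows += _simulate_group(
            members,
            strategies_after,
            rounds_after,
            design.pairing,
            design.initial_coop_prob,
            rng,
            design.experiment_id,
            "after",
            f"g{g + 1}",
        )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
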