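"""Estimation of memory-one strategies from round-by-round play logs.

A play log is a tidy table with one row per (player, round) choice:

    experiment_id, phase, group_id, round, pair_id, player_id, choice

``choice`` is exactly ``"C"`` or ``"D"``; ``phase`` is ``"before"`` or
``"after"`` (socialization); a ``pair_id`` names the two players matched in
a given round, so every (experiment, phase, pair, round) has exactly two
rows.

The estimator is the transition-count (maximum-likelihood) estimator of the
memory-one strategy: gamma_hat is the fraction of rounds in which the focal
player cooperated given that the opponent cooperated in the previous round,
alpha_hat likewise after an opponent defection.  A transition from round
t-1 to t is counted only when the same two players were matched in both
rounds — the memory-one response is defined against a fixed opponent — so
under per-round rematching, transitions with a fresh partner are dropped.
First rounds of a pairing carry no transition but do count toward the raw
cooperation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "MalformedLogError",
    "StrategyEstimate",
    "validate_play_log",
    "read_play_log",
    "write_play_log",
    "estimate_strategy",
    "aggregate_group",
    "cooperation_rate",
]

REQUIRED_COLUMNS = (
    "experiment_id",
    "phase",
    "group_id",
    "round",
    "pair_id",
    "player_id",
    "choice",
)


class MalformedLogError(ValueError):
    """The play log violates the schema (odd pair counts, round gaps, bad
    choice codes)."""


@dataclass(frozen=True)
class StrategyEstimate:
    """Transition counts and the implied (alpha_hat, gamma_hat).

    ``gamma_hat = n_coop_after_coop / n_opp_coop`` when the denominator is
    positive, otherwise ``None`` (and analogously for alpha_hat).
    """

    alpha_hat: float | None
    gamma_hat: float | None
    n_opp_coop: int
    n_opp_defect: int
    n_coop_after_coop: int
    n_coop_after_defect: int

    @classmethod
    def from_counts(
        cls, n_opp_coop: int, n_opp_defect: int,
        n_coop_after_coop: int, n_coop_after_defect: int,
    ) -> "StrategyEstimate":
        return cls(
            alpha_hat=n_coop_after_defect / n_opp_defect if n_opp_defect else None,
            gamma_hat=n_coop_after_coop / n_opp_coop if n_opp_coop else None,
            n_opp_coop=n_opp_coop,
            n_opp_defect=n_opp_defect,
            n_coop_after_coop=n_coop_after_coop,
            n_coop_after_defect=n_coop_after_defect,
        )


def validate_play_log(records: pd.DataFrame) -> None:
    """Raise :class:`MalformedLogError` on schema violations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise MalformedLogError(f"missing columns: {missing}")
    if records.empty:
        raise MalformedLogError("empty play log")
    bad = set(records["choice"].unique()) - {"C", "D"}
    if bad:
        raise MalformedLogError(f"choice values must be 'C' or 'D', found {sorted(bad)}")
    sizes = records.groupby(
        ["experiment_id", "phase", "pair_id", "round"], sort=False
    ).size()
    if (sizes != 2).any():
        offender = sizes[sizes != 2].index[0]
        raise MalformedLogError(
            f"pair/round {offender} has {sizes[sizes != 2].iloc[0]} records, expected 2"
        )
    for (exp, phase), grp in records.groupby(["experiment_id", "phase"], sort=False):
        rounds = sorted(grp["round"].unique())
        if rounds != list(range(1, len(rounds) + 1)):
            raise MalformedLogError(
                f"rounds of ({exp}, {phase}) are not consecutive from 1: {rounds[:5]}..."
            )


def read_play_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"choice": str, "phase": str})
    validate_play_log(df)
    return df


def write_play_log(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def _opponent_annotated(records: pd.DataFrame) -> pd.DataFrame:
    """Attach opponent_id and opponent_choice to every record."""
    key = ["experiment_id", "phase", "pair_id", "round"]
    opp = records[key + ["player_id", "choice"]].rename(
        columns={"player_id": "opponent_id", "choice": "opponent_choice"}
    )
    merged = records.merge(opp, on=key)
    merged = merged[merged["player_id"] != merged["opponent_id"]]
    if len(merged) != len(records):
        raise MalformedLogError("pairings with duplicated or missing partners")
    return merged


def estimate_strategy(
    records: pd.DataFrame, player_id: str | None = None
) -> StrategyEstimate:
    """Transition-count estimate of (alpha, gamma).

    ``records`` must contain complete pair rows (both players of every
    pairing), since the opponent's previous choice conditions each focal
    transition.  With ``player_id`` given, only that player's transitions
    are counted (individual estimate); otherwise transitions of all players
    are pooled (group estimate).
    """
    validate_play_log(records)
    ann = _opponent_annotated(records).sort_values(
        ["experiment_id", "phase", "player_id", "round"], kind="mergesort"
    )
    g = ann.groupby(["experiment_id", "phase", "player_id"], sort=False)
    prev_round = g["round"].shift(1)
    prev_opp = g["opponent_id"].shift(1)
    prev_opp_choice = g["opponent_choice"].shift(1)
    # a transition requires consecutive rounds with the same partner
    valid = (ann["round"] == prev_round + 1) & (ann["opponent_id"] == prev_opp)
    if player_id is not None:
        valid = valid & (ann["player_id"] == player_id)
    after_coop = valid & (prev_opp_choice == "C")
    after_defect = valid & (prev_opp_choice == "D")
    coop_now = ann["choice"] == "C"
    return StrategyEstimate.from_counts(
        n_opp_coop=int(after_coop.sum()),
        n_opp_defect=int(after_defect.sum()),
        n_coop_after_coop=int((after_coop & coop_now).sum()),
        n_coop_after_defect=int((after_defect & coop_now).sum()),
    )


def aggregate_group(records: pd.DataFrame) -> StrategyEstimate:
    """Group-level estimate pooling transition counts across all players.

    Identical to :func:`estimate_strategy` on the pooled records; kept as a
    named operation because pooled counts, not means of per-player ratios,
    are the intended aggregation (they are the joint maximum-likelihood
    estimate under a shared memory-one strategy).
    """
    return estimate_strategy(records)


def cooperation_rate(records: pd.DataFrame) -> float:
    """Fraction of all choices (every round, including firsts) that are
    cooperative."""
    if records.empty:
        raise MalformedLogError("empty play log")
    return float((records["choice"] == "C").mean())
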