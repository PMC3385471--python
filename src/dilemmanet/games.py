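"""Two-player social dilemmas: payoff structures and one-shot equilibria.

Two symmetric cooperate-or-defect games are supported. In both, mutual
cooperation pays ``R`` to each player, mutual defection pays ``P``, and a
defector exploiting a cooperator receives the temptation ``T`` while the
cooperator receives the sucker's payoff ``S``.

* Prisoner's dilemma: ``T > R > P > S``. Defection strictly dominates, so the
  one-shot Nash equilibrium has zero cooperation.
* Snowdrift game: ``T > R > S > P``. The best reply is to do the opposite of
  the opponent, giving an interior mixed equilibrium.

Payoffs are stored as floats so alternative parameterisations can be explored;
the default games use the classic integer tables (7/6/2/1 and 8/5/2/1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Tuple

import numpy as np

__all__ = [
    "Move",
    "Game",
    "ipd_default",
    "isd_default",
    "payoff",
    "single_shot_equilibrium",
]


class Move(IntEnum):
    """A single action in one round: defect (0) or cooperate (1)."""

    D = 0
    C = 1


@dataclass(frozen=True)
class Game:
    """A symmetric two-player dilemma defined by its four payoffs.

    Parameters
    ----------
    name:
        ``"ipd"`` (prisoner's dilemma) or ``"isd"`` (snowdrift).
    T, R, P, S:
        Temptation, reward, punishment and sucker payoffs.
    check_order:
        If True (default), the constructor enforces the payoff ordering that
        defines the declared game type. Disabling the check is intended for
        controlled experiments (e.g. selectively neutral payoff tables); the
        equilibrium computation still refuses mis-ordered payoffs.
    """

    name: str
    T: float
    R: float
    P: float
    S: float
    check_order: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.name not in ("ipd", "isd"):
            raise ValueError(f"unknown game name {self.name!r}; use 'ipd' or 'isd'")
        for label, v in (("T", self.T), ("R", self.R), ("P", self.P), ("S", self.S)):
            if not np.isfinite(v):
                raise ValueError(f"payoff {label} must be finite, got {v!r}")
        if self.check_order:
            self._validate_order()

    def _validate_order(self) -> None:
        if self.name == "ipd":
            if not (self.T > self.R > self.P > self.S):
                raise ValueError(
                    "prisoner's dilemma requires T > R > P > S, got "
                    f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
                )
        else:
            if not (self.T > self.R > self.S > self.P):
                raise ValueError(
                    "snowdrift game requires T > R > S > P, got "
                    f"T={self.T}, R={self.R}, S={self.S}, P={self.P}"
                )

    def payoff_matrix(self) -> np.ndarray:
        """2x2 matrix ``M[own_move, opp_move]`` of the focal player's payoff."""
        return np.array(
            [[self.P, self.T], [self.S, self.R]], dtype=np.float64
        )


def ipd_default() -> Game:
    """The default iterated prisoner's dilemma (T=7, R=6, P=2, S=1)."""
    return Game("ipd", T=7.0, R=6.0, P=2.0, S=1.0)


def isd_default() -> Game:
    """The default iterated snowdrift game (T=8, R=5, S=2, P=1)."""
    return Game("isd", T=8.0, R=5.0, P=1.0, S=2.0)


def payoff(game: Game, move_self: Move, move_opp: Move) -> Tuple[float, float]:
    """Payoffs ``(payoff_self, payoff_opp)`` for one round of *game*.

    (C,C) -> (R,R); (D,D) -> (P,P); (D,C) -> (T,S); (C,D) -> (S,T).
    """
    m = game.payoff_matrix()
    return float(m[int(move_self), int(move_opp)]), float(m[int(move_opp), int(move_self)])


def single_shot_equilibrium(game: Game) -> float:
    """Equilibrium cooperation frequency of the *one-shot* game.

    Zero for the prisoner's dilemma (defection dominates). For the snowdrift
    game, the mixed equilibrium ``x`` makes a player indifferent between C and
    D against an opponent cooperating with probability ``x``::

        x*R + (1-x)*S = x*T + (1-x)*P  =>  x = (S-P) / ((S-P) + (T-R))

    which is 0.25 for the default snowdrift payoffs.

    Raises
    ------
    ValueError
        If the payoffs violate the ordering required by the declared type
        (possible when the game was built with ``check_order=False``).
    """
    game._validate_order()
    if game.name == "ipd":
        return 0.0
    return (game.S - game.P) / ((game.S - game.P) + (game.T - game.R))
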