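"""Probing genomes and clustering them to canonical pure strategies.

Evolved networks implement a continuum of behaviours. To summarise the
strategic composition of a population, each genome is replayed against a
fixed set of short joint-move histories (the probe set), the cooperation
probability it would emit after each history is recorded, and the resulting
behaviour vector is assigned to the nearest of four canonical strategies:

* always-defect, always-cooperate;
* tit-for-tat — cooperate first, then copy the opponent's last move;
* Pavlov (win-stay-lose-shift) — repeat your previous move if your last
  payoff was above a threshold placed between P and R, otherwise switch.

Probing uses output probabilities, not sampled moves, so classification is
deterministic for a given genome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from . import _engine
from .games import Game
from .network import NetworkGenome, activate, fresh_state

__all__ = [
    "STRATEGY_NAMES",
    "ProbeSet",
    "CanonicalStrategy",
    "build_probe_set",
    "probe_payoffs",
    "probe",
    "probe_population",
    "canonical_strategies",
    "classify",
    "classify_population",
]

#: Canonical strategy names in the deterministic tie-break order.
STRATEGY_NAMES: Tuple[str, ...] = (
    "always_defect",
    "always_cooperate",
    "tit_for_tat",
    "pavlov",
)

_MOVE_PAIRS = ((0, 0), (0, 1), (1, 0), (1, 1))  # (own, opp), D=0, C=1


@dataclass(frozen=True)
class ProbeSet:
    """Ordered joint-move histories; each history is a tuple of
    ``(own_move, opp_move)`` pairs (ints, D=0/C=1)."""

    histories: Tuple[Tuple[Tuple[int, int], ...], ...]
    depth: int

    @property
    def n_positions(self) -> int:
        """Length of a behaviour vector: one slot per history plus the
        first-move slot."""
        return len(self.histories) + 1


@dataclass(frozen=True)
class CanonicalStrategy:
    name: str
    vector: np.ndarray


def build_probe_set(depth: int = 2, max_positions: int = 4096) -> ProbeSet:
    """All joint-move histories of length 1..depth, shortest first, each
    length block ordered lexicographically with (D,D) < (D,C) < (C,D) < (C,C).

    Depth 1 yields 4 histories; depth 2 yields 4 + 16 = 20.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    total = sum(4**d for d in range(1, depth + 1))
    if total + 1 > max_positions:
        raise ValueError(
            f"probe set with depth {depth} has {total + 1} positions, above the "
            f"cap {max_positions}"
        )
    histories: List[Tuple[Tuple[int, int], ...]] = []
    for d in range(1, depth + 1):
        histories.extend(itertools.product(_MOVE_PAIRS, repeat=d))
    return ProbeSet(histories=tuple(histories), depth=depth)


def probe_payoffs(probe_set: ProbeSet, game: Game) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-round (own, opponent) payoff inputs implied by each history.

    Returns padded arrays ``(ps, po, lengths)`` of shape (n_histories, depth).
    """
    pay = game.payoff_matrix()
    Q = len(probe_set.histories)
    L = max(len(h) for h in probe_set.histories)
    ps = np.zeros((Q, L), dtype=np.float64)
    po = np.zeros((Q, L), dtype=np.float64)
    lengths = np.zeros(Q, dtype=np.int64)
    for q, hist in enumerate(probe_set.histories):
        lengths[q] = len(hist)
        for t, (own, opp) in enumerate(hist):
            ps[q, t] = pay[own, opp]
            po[q, t] = pay[opp, own]
    return ps, po, lengths


def probe(genome: NetworkGenome, probe_set: ProbeSet, game: Game) -> np.ndarray:
    """Behaviour vector of one genome: ``[first_move, p_after_history_1, ...]``.

    For each history the genome's state is reset, the history's payoffs are
    fed through the network round by round, and the final output probability
    is recorded. A genome with no hidden nodes emits its first move
    everywhere.
    """
    pay = game.payoff_matrix()
    out = np.empty(probe_set.n_positions, dtype=np.float64)
    out[0] = float(int(genome.first_move))
    if genome.n_cognitive == 0:
        out[1:] = out[0]
        return out
    for q, hist in enumerate(probe_set.histories):
        state = fresh_state(genome)
        p = 0.5
        for own, opp in hist:
            p, state = activate(genome, state, float(pay[own, opp]), float(pay[opp, own]))
        out[q + 1] = p
    return out


def probe_population(
    genomes: Sequence[NetworkGenome], probe_set: ProbeSet, game: Game
) -> np.ndarray:
    """Behaviour vectors for a whole population via the packed-array engine."""
    arrs = _engine.encode_population(genomes)
    ps, po, lengths = probe_payoffs(probe_set, game)
    return _engine.run_probe(arrs, ps, po, lengths)


def canonical_strategies(game: Game, probe_set: ProbeSet) -> List[CanonicalStrategy]:
    """Exact behaviour vectors of the four canonical strategies on this
    probe set, in tie-break order.

    Pavlov's win threshold sits between P and R: payoffs in {T, R} mean
    "stay", payoffs in {P, S} mean "shift".
    """
    pay = game.payoff_matrix()
    win_threshold = (game.R + game.P) / 2.0
    vectors = {name: [first] for name, first in
               zip(STRATEGY_NAMES, (0.0, 1.0, 1.0, 1.0))}
    for hist in probe_set.histories:
        own_last, opp_last = hist[-1]
        vectors["always_defect"].append(0.0)
        vectors["always_cooperate"].append(1.0)
        vectors["tit_for_tat"].append(float(opp_last))
        stay = pay[own_last, opp_last] > win_threshold
        vectors["pavlov"].append(float(own_last) if stay else float(1 - own_last))
    return [
        CanonicalStrategy(name, np.asarray(vectors[name], dtype=np.float64))
        for name in STRATEGY_NAMES
    ]


def classify(behavior: np.ndarray, canon: Sequence[CanonicalStrategy]) -> str:
    """Nearest canonical strategy by Euclidean distance; ties break in the
    order the canonical strategies are listed."""
    behavior = np.asarray(behavior, dtype=np.float64)
    for c in canon:
        if c.vector.shape != behavior.shape:
            raise ValueError(
                f"behaviour vector length {behavior.shape[0]} does not match "
                f"canonical vector length {c.vector.shape[0]}"
            )
    d2 = [float(np.sum((behavior - c.vector) ** 2)) for c in canon]
    return canon[int(np.argmin(d2))].name


def classify_population(
    behaviors: np.ndarray, canon: Sequence[CanonicalStrategy]
) -> np.ndarray:
    """Index (into ``canon``) of the nearest strategy for each row."""
    mat = np.stack([c.vector for c in canon])
    if mat.shape[1] != behaviors.shape[1]:
        raise ValueError(
            f"behaviour vectors have {behaviors.shape[1]} positions but the "
            f"canonical vectors have {mat.shape[1]}"
        )
    d2 = ((behaviors[:, None, :] - mat[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)
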