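"""Iterated matches and the within-generation round robin.

A match is a fixed number of rounds between two genomes. Round 0 is decided
by the heritable first-move traits; every later round is a Bernoulli draw
from each network's output probability given the previous round's payoffs.
Context memory is blank at the start of every pairing.

``play_match`` pre-draws its uniforms as a ``(rounds, 2)`` block so that a
full round robin played match-by-match from one generator reproduces, bit for
bit, the packed-array fast path used inside evolution runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Tuple

import numpy as np

from . import _engine
from .games import Game, Move, payoff
from .network import NetworkGenome, activate, fresh_state

__all__ = ["MatchResult", "RoundRobinResult", "play_match", "round_robin"]


@dataclass(frozen=True)
class MatchResult:
    """Move and payoff sequences of one iterated match."""

    moves_a: Tuple[Move, ...]
    moves_b: Tuple[Move, ...]
    payoffs_a: Tuple[float, ...]
    payoffs_b: Tuple[float, ...]

    @property
    def rounds(self) -> int:
        return len(self.moves_a)

    @property
    def mean_payoff_a(self) -> float:
        return sum(self.payoffs_a) / self.rounds

    @property
    def mean_payoff_b(self) -> float:
        return sum(self.payoffs_b) / self.rounds


@dataclass(frozen=True)
class RoundRobinResult:
    """Per-individual mean payoffs and population-level move aggregates."""

    mean_payoffs: np.ndarray  # (n,) mean payoff per round, averaged over matches
    cooperation_count: int
    move_count: int
    @property
    def n_matches(self) -> int:
        n = self.mean_payoffs.shape[0]
        return n * (n - 1) // 2

    @property
    def cooperation_frequency(self) -> float:
        return self.cooperation_count / self.move_count


def _decide(genome: NetworkGenome, state, prev_self: float, prev_opp: float, u: float):
    """One in-match decision after round 0 (mirrors the kernel's branch)."""
    if genome.n_cognitive == 0:
        return genome.first_move, state
    p, new_state = activate(genome, state, prev_self, prev_opp)
    return (Move.C if u < p else Move.D), new_state


def play_match(
    genome_a: NetworkGenome,
    genome_b: NetworkGenome,
    game: Game,
    rounds: int,
    rng: np.random.Generator,
) -> MatchResult:
    """Play one iterated match of ``rounds`` rounds.

    Consumes exactly ``rounds * 2`` uniforms from ``rng`` (drawn up front),
    indexing them by (round, player); round-0 positions are unused since the
    first move is the deterministic trait.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    u = rng.random((rounds, 2))
    state_a = fresh_state(genome_a)
    state_b = fresh_state(genome_b)
    ma, mb = genome_a.first_move, genome_b.first_move
    moves_a, moves_b = [ma], [mb]
    pa, pb = payoff(game, ma, mb)
    payoffs_a, payoffs_b = [pa], [pb]
    for t in range(1, rounds):
        ma_new, state_a = _decide(genome_a, state_a, pa, pb, u[t, 0])
        mb_new, state_b = _decide(genome_b, state_b, pb, pa, u[t, 1])
        ma, mb = ma_new, mb_new
        pa, pb = payoff(game, ma, mb)
        moves_a.append(ma)
        moves_b.append(mb)
        payoffs_a.append(pa)
        payoffs_b.append(pb)
    return MatchResult(tuple(moves_a), tuple(moves_b), tuple(payoffs_a), tuple(payoffs_b))


def round_robin(
    population: Sequence[NetworkGenome],
    game: Game,
    rounds: int,
    rng: np.random.Generator,
    engine: Literal["fast", "reference"] = "fast",
) -> RoundRobinResult:
    """Every unordered pair plays exactly one match (no self-play).

    Pairs are visited in lexicographic index order, so a fixed seed gives a
    fixed outcome. The default packed-array engine and the genome-object
    reference engine consume the generator identically and return the same
    result.
    """
    n = len(population)
    if n < 2:
        raise ValueError("round robin requires a population of at least 2")
    if engine == "fast":
        arrs = _engine.encode_population(population)
        n_pairs = n * (n - 1) // 2
        u = rng.random((n_pairs, rounds, 2))
        mean_pay, coop = _engine.run_round_robin(
            arrs, _engine.payoff_table(game), rounds, u
        )
        return RoundRobinResult(
            mean_payoffs=mean_pay,
            cooperation_count=coop,
            move_count=n_pairs * 2 * rounds,
        )
    # reference path: explicit match-by-match play
    sums = np.zeros(n, dtype=np.float64)
    coop = 0
    total = 0
    for a in range(n - 1):
        for b in range(a + 1, n):
            m = play_match(population[a], population[b], game, rounds, rng)
            sums[a] += m.mean_payoff_a
            sums[b] += m.mean_payoff_b
            coop += sum(int(x) for x in m.moves_a) + sum(int(x) for x in m.moves_b)
            total += 2 * m.rounds
    return RoundRobinResult(
        mean_payoffs=sums / (n - 1), cooperation_count=coop, move_count=total
    )
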