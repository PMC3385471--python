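"""Evolvable neural-network genomes that decide moves in repeated dilemmas.

Each individual carries a small recurrent network. Two input nodes receive
the focal player's and the opponent's payoff from the previous round. A
hidden layer of *cognitive* nodes computes logistic activations of the
weighted inputs; a cognitive node may own one *context* node that stores the
node's previous activation and feeds it back (times a weight) on the next
round, giving the network memory of the interaction history without storing
it explicitly. The output node squashes the weighted sum of cognitive
activations into the probability of cooperating this round.

Because the network has no input before the first round, the genome also
carries a heritable first-move trait. A genome with no hidden nodes plays its
first move unconditionally in every round.

Intelligence is measured structurally as the total number of hidden nodes
(cognitive + context), i.e. the capacity for contingent behaviour rather than
its quality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import IO, Optional, Sequence, Tuple, Union

import numpy as np

from .games import Move

__all__ = [
    "ContextGene",
    "CognitiveGene",
    "NetworkGenome",
    "NetworkState",
    "sigmoid",
    "activate",
    "decide_move",
    "intelligence",
    "fresh_state",
]

SCHEMA_VERSION = 1


def sigmoid(z: float) -> float:
    """Numerically stable logistic function 1 / (1 + exp(-z))."""
    if z >= 0.0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _check_finite(label: str, v: float) -> None:
    if not math.isfinite(v):
        raise ValueError(f"{label} must be finite, got {v!r}")


@dataclass(frozen=True)
class ContextGene:
    """Memory unit: weight on the stored previous activation of its owner."""

    w_context: float

    def __post_init__(self) -> None:
        _check_finite("w_context", self.w_context)


@dataclass(frozen=True)
class CognitiveGene:
    """One hidden node: input weights, threshold (subtractive bias), output
    weight, and an optional attached context node."""

    w_in_self: float
    w_in_opp: float
    threshold: float
    w_out: float
    context: Optional[ContextGene] = None

    def __post_init__(self) -> None:
        for label in ("w_in_self", "w_in_opp", "threshold", "w_out"):
            _check_finite(label, getattr(self, label))


@dataclass(frozen=True)
class NetworkGenome:
    """The heritable unit: first-move trait, hidden-layer structure/weights,
    and the output node's threshold."""

    first_move: Move
    cognitive_nodes: Tuple[CognitiveGene, ...] = ()
    output_threshold: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "first_move", Move(self.first_move))
        object.__setattr__(self, "cognitive_nodes", tuple(self.cognitive_nodes))
        _check_finite("output_threshold", self.output_threshold)

    @property
    def n_cognitive(self) -> int:
        return len(self.cognitive_nodes)

    @property
    def n_context(self) -> int:
        return sum(1 for g in self.cognitive_nodes if g.context is not None)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "first_move": "C" if self.first_move == Move.C else "D",
            "output_threshold": self.output_threshold,
            "cognitive_nodes": [
                {
                    "w_in_self": g.w_in_self,
                    "w_in_opp": g.w_in_opp,
                    "threshold": g.threshold,
                    "w_out": g.w_out,
                    "context": (
                        None if g.context is None else {"w_context": g.context.w_context}
                    ),
                }
                for g in self.cognitive_nodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkGenome":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported genome schema version {version}")
        nodes = tuple(
            CognitiveGene(
                w_in_self=g["w_in_self"],
                w_in_opp=g["w_in_opp"],
                threshold=g["threshold"],
                w_out=g["w_out"],
                context=(
                    None if g.get("context") is None else ContextGene(g["context"]["w_context"])
                ),
            )
            for g in d["cognitive_nodes"]
        )
        return cls(
            first_move=Move.C if d["first_move"] == "C" else Move.D,
            cognitive_nodes=nodes,
            output_threshold=d["output_threshold"],
        )

    def to_json(self, fp: Optional[IO[str]] = None) -> str:
        s = json.dumps(self.to_dict())
        if fp is not None:
            fp.write(s)
        return s

    @classmethod
    def from_json(cls, s: Union[str, bytes]) -> "NetworkGenome":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class NetworkState:
    """Per-opponent memory: one value in [0, 1] per context node, ordered by
    the owning cognitive node's position in the genome."""

    context_values: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "context_values", tuple(self.context_values))
        for v in self.context_values:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"context values must lie in [0, 1], got {v!r}")


def fresh_state(genome: NetworkGenome) -> NetworkState:
    """Blank memory for the start of a new pairing (all context values 0)."""
    return NetworkState((0.0,) * genome.n_context)


def intelligence(genome: NetworkGenome) -> int:
    """Structural intelligence: number of cognitive plus context nodes."""
    return genome.n_cognitive + genome.n_context


def activate(
    genome: NetworkGenome,
    state: NetworkState,
    payoff_self: float,
    payoff_opp: float,
) -> Tuple[float, NetworkState]:
    """One synchronous forward pass of the network.

    Each cognitive node j computes ``a_j = sigma(w_in_self*payoff_self +
    w_in_opp*payoff_opp [+ w_context*c_j] - threshold_j)`` from the *old*
    context values; every context node then stores its node's new activation.
    The output is ``p = sigma(sum_j w_out_j*a_j - output_threshold)``, the
    probability of cooperating this round.

    Returns ``(p_cooperate, new_state)``.
    """
    if genome.n_cognitive == 0:
        raise ValueError("activate requires at least one cognitive node")
    if len(state.context_values) != genome.n_context:
        raise ValueError(
            f"state has {len(state.context_values)} context values but genome "
            f"has {genome.n_context} context nodes"
        )
    new_ctx = []
    s = 0.0
    k = 0
    for g in genome.cognitive_nodes:
        z = g.w_in_self * payoff_self + g.w_in_opp * payoff_opp
        if g.context is not None:
            z = z + g.context.w_context * state.context_values[k]
        z = z - g.threshold
        a = sigmoid(z)
        if g.context is not None:
            new_ctx.append(a)
            k += 1
        s = s + g.w_out * a
    s = s - genome.output_threshold
    return sigmoid(s), NetworkState(tuple(new_ctx))


def decide_move(
    genome: NetworkGenome,
    state: NetworkState,
    round_index: int,
    prev_payoffs: Optional[Sequence[float]],
    rng: np.random.Generator,
) -> Tuple[Move, NetworkState]:
    """Choose this round's move.

    Round 0 plays the first-move trait deterministically. A genome with no
    hidden nodes plays its first move in every round. Otherwise the move is a
    Bernoulli draw from the network's cooperation probability given last
    round's payoffs ``prev_payoffs = (payoff_self, payoff_opp)``.
    """
    if round_index < 0:
        raise ValueError("round_index must be >= 0")
    if round_index == 0 or genome.n_cognitive == 0:
        return genome.first_move, state
    if prev_payoffs is None:
        raise ValueError("prev_payoffs is required after round 0")
    p, new_state = activate(genome, state, float(prev_payoffs[0]), float(prev_payoffs[1]))
    move = Move.C if rng.random() < p else Move.D
    return move, new_state
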