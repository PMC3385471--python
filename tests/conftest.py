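import numpy as np
import pytest

from dilemmanet.games import Move, ipd_default, isd_default
from dilemmanet.network import CognitiveGene, ContextGene, NetworkGenome


@pytest.fixture
def ipd():
    return ipd_default()


@pytest.fixture
def isd():
    return isd_default()


def zero_node(first_move: Move) -> NetworkGenome:
    return NetworkGenome(first_move=first_move, cognitive_nodes=(), output_threshold=0.0)


@pytest.fixture
def always_cooperate():
    return zero_node(Move.C)


@pytest.fixture
def always_defect():
    return zero_node(Move.D)


@pytest.fixture
def tft_detector():
    """Saturated one-node tit-for-tat.

    Own previous payoff is >= R iff the opponent cooperated (own payoff in
    {R, T} vs {S, P}), so a single threshold unit at 4*w on the own-payoff
    input reads the opponent's last move. Cooperates first.
    """
    return NetworkGenome(
        first_move=Move.C,
        cognitive_nodes=(
            CognitiveGene(w_in_self=10.0, w_in_opp=0.0, threshold=40.0, w_out=10.0),
        ),
        output_threshold=5.0,
    )


@pytest.fixture
def pavlov_two_node():
    """Two-node win-stay-lose-shift for the default prisoner's dilemma.

    Own previous payoff orders the four outcomes 1 < 2 < 6 < 7 and Pavlov
    must cooperate after {2, 6} but defect after {1, 7} — a non-monotone
    target needing two detectors: node 0 fires for payoff > 1.5, node 1 for
    payoff > 6.5; the output is (node0 AND NOT node1).
    """
    return NetworkGenome(
        first_move=Move.C,
        cognitive_nodes=(
            CognitiveGene(w_in_self=20.0, w_in_opp=0.0, threshold=30.0, w_out=20.0),
            CognitiveGene(w_in_self=20.0, w_in_opp=0.0, threshold=130.0, w_out=-40.0),
        ),
        output_threshold=10.0,
    )


def random_genome_factory(rng: np.random.Generator, n_cog=None, max_cog=4):
    """Small random genome for property tests."""
    if n_cog is None:
        n_cog = int(rng.integers(0, max_cog + 1))
    nodes = tuple(
        CognitiveGene(
            w_in_self=float(rng.normal(0, 2)),
            w_in_opp=float(rng.normal(0, 2)),
            threshold=float(rng.normal(0, 2)),
            w_out=float(rng.normal(0, 2)),
            context=ContextGene(float(rng.normal(0, 2))) if rng.random() < 0.5 else None,
        )
        for _ in range(n_cog)
    )
    return NetworkGenome(
        first_move=Move.C if rng.random() < 0.5 else Move.D,
        cognitive_nodes=nodes,
        output_threshold=float(rng.normal(0, 2)),
    )
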