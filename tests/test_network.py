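import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dilemmanet.games import Move
from dilemmanet.network import (
    CognitiveGene,
    ContextGene,
    NetworkGenome,
    NetworkState,
    activate,
    decide_move,
    fresh_state,
    intelligence,
    sigmoid,
)
from .conftest import random_genome_factory

SIG5 = 1.0 / (1.0 + math.exp(-5.0))  # 0.9933071490757153


def test_zero_weight_network_outputs_one_half():
    g = NetworkGenome(
        first_move=Move.C,
        cognitive_nodes=(CognitiveGene(0.0, 0.0, 0.0, 0.0),),
        output_threshold=0.0,
    )
    p, _ = activate(g, fresh_state(g), 7.0, 1.0)
    assert p == pytest.approx(0.5, abs=1e-15)


def test_tft_detector_probabilities(tft_detector):
    # opponent cooperated last round -> own payoff was R=6 or T=7
    p_after_coop, _ = activate(tft_detector, fresh_state(tft_detector), 7.0, 1.0)
    assert p_after_coop == pytest.approx(SIG5, abs=1e-6)
    # opponent defected -> own payoff was S=1 or P=2
    p_after_defect, _ = activate(tft_detector, fresh_state(tft_detector), 1.0, 7.0)
    assert p_after_defect == pytest.approx(1 - SIG5, abs=1e-6)


def test_context_node_single_step_memory():
    g = NetworkGenome(
        first_move=Move.C,
        cognitive_nodes=(
            CognitiveGene(0.0, 0.0, 0.0, 1.0, context=ContextGene(10.0)),
        ),
        output_threshold=0.0,
    )
    p, new_state = activate(g, NetworkState((1.0,)), 0.0, 0.0)
    expected_a = 1.0 / (1.0 + math.exp(-10.0))
    assert new_state.context_values[0] == pytest.approx(expected_a, abs=1e-12)
    assert p == pytest.approx(sigmoid(expected_a), abs=1e-12)


def test_activate_requires_matching_state(tft_detector):
    with pytest.raises(ValueError):
        activate(tft_detector, NetworkState((0.5,)), 1.0, 1.0)


def test_activate_requires_hidden_nodes(always_cooperate):
    with pytest.raises(ValueError):
        activate(always_cooperate, fresh_state(always_cooperate), 1.0, 1.0)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=50)
def test_activate_output_strictly_interior(seed):
    rng = np.random.default_rng(seed)
    g = random_genome_factory(rng, n_cog=int(rng.integers(1, 5)))
    p, state = activate(g, fresh_state(g), float(rng.uniform(1, 8)), float(rng.uniform(1, 8)))
    assert 0.0 < p < 1.0
    assert all(0.0 <= c <= 1.0 for c in state.context_values)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=30)
def test_synchronous_update_node_order_irrelevant(seed):
    """Permuting cognitive nodes (with their weights) leaves the output
    probability unchanged: all activations read the pre-update state."""
    rng = np.random.default_rng(seed)
    g = random_genome_factory(rng, n_cog=int(rng.integers(2, 5)))
    perm = rng.permutation(g.n_cognitive)
    g2 = NetworkGenome(
        first_move=g.first_move,
        cognitive_nodes=tuple(g.cognitive_nodes[j] for j in perm),
        output_threshold=g.output_threshold,
    )
    # permute the state to follow its owners
    ctx_owner = [j for j, node in enumerate(g.cognitive_nodes) if node.context is not None]
    state = NetworkState(tuple(rng.uniform(0, 1) for _ in ctx_owner))
    by_owner = dict(zip(ctx_owner, state.context_values))
    state2 = NetworkState(
        tuple(by_owner[j] for j in perm if g.cognitive_nodes[j].context is not None)
    )
    p1, _ = activate(g, state, 6.0, 6.0)
    p2, _ = activate(g2, state2, 6.0, 6.0)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_saturated_network_is_effectively_deterministic(tft_detector, ipd):
    """With every squashing input at magnitude >= 30 before the output layer,
    behaviour is deterministic to within 1e-12 per round: non-contingent or
    sharply contingent strategies can be near-noiseless."""
    sat = NetworkGenome(
        first_move=Move.C,
        cognitive_nodes=(CognitiveGene(30.0, 0.0, 0.0, 100.0, None),),
        output_threshold=50.0,
    )
    for ps in (1.0, 2.0, 6.0, 7.0):
        p, _ = activate(sat, fresh_state(sat), ps, 1.0)
        assert min(p, 1 - p) < 1e-12


def test_decide_move_round_zero_is_first_move_trait(tft_detector):
    rng = np.random.default_rng(0)
    move, state = decide_move(tft_detector, fresh_state(tft_detector), 0, None, rng)
    assert move == Move.C
    assert state == fresh_state(tft_detector)


def test_decide_move_zero_node_ignores_history(always_cooperate, always_defect):
    rng = np.random.default_rng(0)
    for rnd in range(5):
        prev = (1.0, 7.0) if rnd else None
        mc, _ = decide_move(always_cooperate, fresh_state(always_cooperate), rnd, prev, rng)
        md, _ = decide_move(always_defect, fresh_state(always_defect), rnd, prev, rng)
        assert (mc, md) == (Move.C, Move.D)


def test_decide_move_missing_history_is_an_error(tft_detector):
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        decide_move(tft_detector, fresh_state(tft_detector), 1, None, rng)


def test_decide_move_tft_vs_defector_rate(tft_detector):
    """Against constant defection the detector cooperates at ~sigma(-5) per
    round after round 0."""
    rng = np.random.default_rng(42)
    n = 20000
    coop = 0
    state = fresh_state(tft_detector)
    for _ in range(n):
        move, _ = decide_move(tft_detector, state, 1, (1.0, 7.0), rng)
        coop += move == Move.C
    p = 1 - SIG5
    se = math.sqrt(p * (1 - p) / n)
    assert abs(coop / n - p) < 4 * se


@pytest.mark.parametrize(
    "n_cog, ctx_flags, expected",
    [(0, (), 0), (3, (True, False, False), 4), (10, (True,) * 10, 20)],
)
def test_intelligence_counts_all_hidden_nodes(n_cog, ctx_flags, expected):
    nodes = tuple(
        CognitiveGene(0.0, 0.0, 0.0, 0.0, context=ContextGene(0.0) if flag else None)
        for flag in ctx_flags
    )
    g = NetworkGenome(first_move=Move.C, cognitive_nodes=nodes)
    assert intelligence(g) == expected
    assert g.n_cognitive == n_cog


def test_fresh_state_is_blank_and_immutable():
    g = NetworkGenome(
        first_move=Move.D,
        cognitive_nodes=(
            CognitiveGene(1.0, 1.0, 0.0, 1.0, context=ContextGene(1.0)),
            CognitiveGene(1.0, 1.0, 0.0, 1.0, context=ContextGene(1.0)),
        ),
    )
    s = fresh_state(g)
    assert s.context_values == (0.0, 0.0)
    activate(g, s, 7.0, 7.0)
    assert s.context_values == (0.0, 0.0)
    assert fresh_state(NetworkGenome(first_move=Move.C)).context_values == ()


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=25)
def test_genome_json_roundtrip_bit_exact(seed):
    rng = np.random.default_rng(seed)
    g = random_genome_factory(rng)
    assert NetworkGenome.from_json(g.to_json()) == g


def test_genome_rejects_nonfinite_weights():
    with pytest.raises(ValueError):
        CognitiveGene(w_in_self=float("nan"), w_in_opp=0.0, threshold=0.0, w_out=0.0)
    with pytest.raises(ValueError):
        NetworkGenome(first_move=Move.C, output_threshold=float("inf"))
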