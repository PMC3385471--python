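import math

import numpy as np
import pytest
from scipy import stats

from dilemmanet.evolution import (
    SELECTION_EPS,
    EvolutionConfig,
    fitness,
    mutate,
    random_genome,
    records_to_frame,
    run_replicate,
    select_parents,
)
from dilemmanet.games import Move
from dilemmanet.network import intelligence
from .conftest import zero_node


def make_cfg(**kw):
    base = dict(game={"name": "ipd"}, generations=10, replicates=1, population_size=10)
    base.update(kw)
    return EvolutionConfig(**base)


# -- fitness ---------------------------------------------------------------


def test_fitness_is_mean_payoff_minus_linear_penalty():
    assert fitness(6.0, 0, 0.5) == 6.0
    assert fitness(6.0, 4, 0.01) == pytest.approx(5.96)
    assert fitness(2.0, 20, 0.1) == pytest.approx(0.0)


def test_selection_survives_nonpositive_fitness():
    """A zero/negative fitness is floored, not dropped: the roulette wheel
    stays well defined."""
    rng = np.random.default_rng(0)
    idx = select_parents([0.0, -1.0], 1000, rng)
    assert set(np.unique(idx)) <= {0, 1}
    # both are at the floor -> uniform
    frac = np.mean(idx == 0)
    assert abs(frac - 0.5) < 0.05


def test_select_parents_uniform_when_equal():
    rng = np.random.default_rng(1)
    draws = select_parents([1.0, 1.0, 1.0, 1.0], 100_000, rng)
    counts = np.bincount(draws, minlength=4)
    chi2 = ((counts - 25_000.0) ** 2 / 25_000.0).sum()
    assert stats.chi2.sf(chi2, df=3) > 1e-4


def test_select_parents_proportional():
    rng = np.random.default_rng(2)
    n = 100_000
    draws = select_parents([3.0, 1.0], n, rng)
    frac0 = np.mean(draws == 0)
    se = math.sqrt(0.75 * 0.25 / n)
    assert abs(frac0 - 0.75) < 3 * se


def test_select_parents_rejects_empty():
    with pytest.raises(ValueError):
        select_parents([], 5, np.random.default_rng(0))


# -- mutation --------------------------------------------------------------


def test_mutation_identity_when_all_rates_zero():
    rng = np.random.default_rng(3)
    cfg = make_cfg(
        weight_mutation_prob=0.0, structural_mutation_prob=0.0, first_move_flip_prob=0.0
    )
    for _ in range(20):
        g = random_genome(cfg, rng)
        assert mutate(g, cfg, rng) == g


def test_structural_mutation_respects_caps_and_coupling():
    """Random mutation walks never exceed the node caps, never attach two
    context nodes to one cognitive node, and losing a cognitive node removes
    its context node."""
    rng = np.random.default_rng(4)
    cfg = make_cfg(structural_mutation_prob=1.0, weight_mutation_prob=0.0)
    g = random_genome(cfg, rng)
    for _ in range(20_000):
        g = mutate(g, cfg, rng)
        assert 0 <= g.n_cognitive <= cfg.max_cognitive
        assert g.n_context <= g.n_cognitive
        assert intelligence(g) <= 2 * cfg.max_cognitive


def test_losing_cognitive_node_takes_context_node():
    rng = np.random.default_rng(5)
    cfg = make_cfg(structural_mutation_prob=1.0, weight_mutation_prob=0.0,
                   first_move_flip_prob=0.0, max_cognitive=1)
    # single cognitive node owning the only context node: the only feasible
    # events are lose_cognitive and lose_context
    from dilemmanet.network import CognitiveGene, ContextGene, NetworkGenome

    g = NetworkGenome(
        first_move=Move.C,
        cognitive_nodes=(CognitiveGene(1.0, 1.0, 0.0, 1.0, ContextGene(1.0)),),
    )
    seen_full_loss = False
    for _ in range(100):
        m = mutate(g, cfg, rng)
        if m.n_cognitive == 0:
            assert m.n_context == 0  # i drops by 2 in one event
            seen_full_loss = True
    assert seen_full_loss


def test_first_move_flip_rate():
    rng = np.random.default_rng(6)
    cfg = make_cfg(weight_mutation_prob=0.0, structural_mutation_prob=0.0,
                   first_move_flip_prob=0.5)
    g = zero_node(Move.C)
    flips = sum(mutate(g, cfg, rng).first_move == Move.D for _ in range(10_000))
    assert abs(flips / 10_000 - 0.5) < 0.02


# -- generation loop -------------------------------------------------------


def test_all_defector_population_is_absorbing():
    cfg = make_cfg(
        generations=30,
        structural_mutation_prob=0.0,
        first_move_flip_prob=0.0,
        init_max_cognitive=0,
        max_cognitive=0,
        seed=7,
    )
    # initial population is random C/D zero-node; force defectors via a run
    # where flips are impossible and cooperators are exploited away: instead
    # construct the absorbing state directly through the config seed sweep
    res = run_replicate(cfg, 0)
    freqs = [r.cooperation_frequency for r in res.records]
    # defection fixes quickly and, with no mutation pathways back, stays fixed
    assert freqs[-1] == 0.0
    tail = freqs[freqs.index(0.0):]
    assert all(f == 0.0 for f in tail)


def test_run_replicate_is_reproducible_bit_exact():
    cfg = make_cfg(generations=12, population_size=12, seed=123)
    a = run_replicate(cfg, 0)
    b = run_replicate(cfg, 0)
    assert a.records == b.records
    assert a.final_population == b.final_population
    c = run_replicate(cfg, 1)
    assert c.records != a.records  # different replicate stream


def test_population_size_and_intelligence_bounds():
    cfg = make_cfg(generations=40, population_size=14, seed=9,
                   structural_mutation_prob=0.3)
    res = run_replicate(cfg, 0)
    df = records_to_frame(res)
    counts = df[[f"n_{s}" for s in
                 ("always_defect", "always_cooperate", "tit_for_tat", "pavlov")]]
    assert (counts.sum(axis=1) == 14).all()
    assert (df.mean_intelligence >= 0).all()
    assert (df.mean_intelligence <= 20).all()
    assert df.cooperation_frequency.between(0, 1).all()
    assert len(res.final_population) == 14
    assert math.isnan(df.delta_cooperation.iloc[0])
    d = df.cooperation_frequency.diff().iloc[1:]
    assert np.allclose(df.delta_cooperation.iloc[1:], d)


def test_neutral_drift_is_a_martingale():
    """With a flat payoff table, no penalty and no mutation, the cooperator
    frequency is a martingale under resampling: across many seeds the mean
    final frequency stays at its initial value."""
    cfg = EvolutionConfig(
        game={"name": "ipd", "T": 1.0, "R": 1.0, "P": 1.0, "S": 1.0,
              "check_order": False},
        generations=20,
        population_size=20,
        rounds=1,
        penalty_coefficient=0.0,
        weight_mutation_prob=0.0,
        structural_mutation_prob=0.0,
        first_move_flip_prob=0.0,
        max_cognitive=0,
        init_max_cognitive=0,
        replicates=1,
        seed=0,
    )
    finals = []
    for s in range(400):
        res = run_replicate(cfg.model_copy(update={"seed": 20_000 + s}), 0)
        # initial composition is random; track the change, not the level
        finals.append(
            res.records[-1].cooperation_frequency - res.records[0].cooperation_frequency
        )
    # E[change] = 0; each trajectory's variance is bounded by the drift to
    # absorption, se ~ sqrt(var/400)
    assert abs(np.mean(finals)) < 3 * np.std(finals) / math.sqrt(400)


def test_config_validation():
    with pytest.raises(Exception):
        EvolutionConfig(game={"name": "ipd"}, population_size=1)
    with pytest.raises(Exception):
        EvolutionConfig(game={"name": "isd", "S": 0.5})  # breaks T>R>S>P
    with pytest.raises(Exception):
        EvolutionConfig(game={"name": "ipd"}, weight_mutation_prob=1.5)
    with pytest.raises(Exception):
        EvolutionConfig(game={"name": "ipd"}, bogus_field=1)


def test_flat_game_config_requires_valid_ordering_override():
    cfg = EvolutionConfig(game={"name": "ipd", "T": 10.0})
    g = cfg.game.to_game()
    assert (g.T, g.R, g.P, g.S) == (10.0, 6.0, 2.0, 1.0)
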