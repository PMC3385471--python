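"""The genetic algorithm evolving network genomes.

Each generation: every individual plays every other in a round robin of
iterated games; fitness is the mean payoff per round minus a linear
intelligence penalty ``k * i``; parents are drawn with probability
proportional to (floored) fitness; offspring are mutated copies; the old
generation is replaced wholesale. Per-generation summaries — cooperation
frequency, mean intelligence, the fitness-intelligence covariance (the
selection differential for intelligence), and counts of the four canonical
strategy classes — are recorded throughout.

Mutation acts on weights/thresholds (independent Gaussian perturbations),
on structure (gain/lose one cognitive or context node per event, respecting
the caps and the rule that a context node lives and dies with its cognitive
node), and on the first-move trait (rare flips).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import _engine
from .games import Game, Move, ipd_default, isd_default
from .network import CognitiveGene, ContextGene, NetworkGenome
from .strategy_analysis import (
    STRATEGY_NAMES,
    build_probe_set,
    canonical_strategies,
    classify_population,
    probe_payoffs,
)

__all__ = [
    "GameConfig",
    "EvolutionConfig",
    "GenerationRecord",
    "ReplicateResult",
    "fitness",
    "select_parents",
    "random_genome",
    "mutate",
    "run_replicate",
    "run",
    "records_to_frame",
]

#: Floor applied to fitness before roulette selection. Mean payoff minus the
#: intelligence penalty can reach zero or below (e.g. all-sucker payoffs with
#: a full brain); the floor keeps the roulette wheel well defined without
#: reordering positive fitnesses.
SELECTION_EPS = 1e-6


class GameConfig(BaseModel):
    """Game selection by name with optional payoff overrides."""

    model_config = ConfigDict(extra="forbid")

    name: Literal["ipd", "isd"]
    T: Optional[float] = None
    R: Optional[float] = None
    P: Optional[float] = None
    S: Optional[float] = None
    #: disable the payoff-ordering check (controlled experiments only,
    #: e.g. a selectively neutral flat payoff table)
    check_order: bool = True

    def to_game(self) -> Game:
        base = ipd_default() if self.name == "ipd" else isd_default()
        return Game(
            self.name,
            T=base.T if self.T is None else self.T,
            R=base.R if self.R is None else self.R,
            P=base.P if self.P is None else self.P,
            S=base.S if self.S is None else self.S,
            check_order=self.check_order,
        )


class EvolutionConfig(BaseModel):
    """All knobs of an evolution experiment.

    Defaults reproduce the standard study conditions: populations of 50
    playing 50-round pairings, 10 replicates of 50,000 generations each.
    """

    model_config = ConfigDict(extra="forbid")

    game: GameConfig
    population_size: int = Field(default=50, ge=2)
    generations: int = Field(default=50_000, ge=1)
    replicates: int = Field(default=10, ge=1)
    rounds: int = Field(default=50, ge=1)
    penalty_coefficient: float = Field(default=0.01, ge=0.0)
    weight_mutation_prob: float = Field(default=0.1, ge=0.0, le=1.0)
    weight_mutation_sd: float = Field(default=0.5, gt=0.0)
    structural_mutation_prob: float = Field(default=0.05, ge=0.0, le=1.0)
    first_move_flip_prob: float = Field(default=0.01, ge=0.0, le=1.0)
    max_cognitive: int = Field(default=10, ge=0)
    seed: int = Field(default=1, ge=0)
    probe_depth: int = Field(default=2, ge=1)
    # initial population shape
    init_max_cognitive: int = Field(default=3, ge=0)
    init_context_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    init_weight_sd: float = Field(default=1.0, gt=0.0)
    snapshot_every: Optional[int] = Field(default=None, ge=1)

    @model_validator(mode="after")
    def _check_game(self) -> "EvolutionConfig":
        self.game.to_game()  # validates payoff ordering
        return self


@dataclass(frozen=True)
class GenerationRecord:
    """Summary of one generation of one replicate."""

    generation: int
    cooperation_frequency: float
    delta_cooperation: float  # vs previous generation; NaN at generation 0
    mean_intelligence: float
    mean_fitness: float
    cov_fitness_intelligence: float
    strategy_counts: Tuple[int, int, int, int]  # order = STRATEGY_NAMES


@dataclass
class ReplicateResult:
    replicate: int
    seed: int
    records: List[GenerationRecord]
    final_population: List[NetworkGenome]
    snapshots: List[Tuple[int, List[NetworkGenome]]]


def fitness(mean_payoff_per_round: float, i: int, k: float) -> float:
    """Fitness = mean payoff per round minus the linear intelligence penalty."""
    return mean_payoff_per_round - k * i


def select_parents(
    fitnesses: Sequence[float], n_offspring: int, rng: np.random.Generator
) -> np.ndarray:
    """Fitness-proportional (roulette) sampling of parent indices.

    Fitnesses are floored at ``SELECTION_EPS``; an all-equal (e.g. all-floored)
    vector degenerates to uniform sampling.
    """
    f = np.asarray(fitnesses, dtype=np.float64)
    if f.ndim != 1 or f.shape[0] < 1:
        raise ValueError("fitnesses must be a non-empty 1-d sequence")
    f = np.maximum(f, SELECTION_EPS)
    p = f / f.sum()
    return rng.choice(f.shape[0], size=n_offspring, replace=True, p=p)


def random_genome(cfg: EvolutionConfig, rng: np.random.Generator) -> NetworkGenome:
    """Initial-population genome: fair-coin first move, 0..init_max_cognitive
    cognitive nodes each owning a context node with probability
    ``init_context_prob``, all weights/thresholds ~ Normal(0, init_weight_sd)."""
    sd = cfg.init_weight_sd
    n_cog = int(rng.integers(0, min(cfg.init_max_cognitive, cfg.max_cognitive) + 1))
    nodes = []
    for _ in range(n_cog):
        ctx = ContextGene(float(rng.normal(0.0, sd))) if rng.random() < cfg.init_context_prob else None
        nodes.append(
            CognitiveGene(
                w_in_self=float(rng.normal(0.0, sd)),
                w_in_opp=float(rng.normal(0.0, sd)),
                threshold=float(rng.normal(0.0, sd)),
                w_out=float(rng.normal(0.0, sd)),
                context=ctx,
            )
        )
    return NetworkGenome(
        first_move=Move.C if rng.random() < 0.5 else Move.D,
        cognitive_nodes=tuple(nodes),
        output_threshold=float(rng.normal(0.0, sd)),
    )


def _perturb(value: float, prob: float, sd: float, rng: np.random.Generator) -> float:
    if rng.random() < prob:
        return value + float(rng.normal(0.0, sd))
    return value


def mutate(
    genome: NetworkGenome, cfg: EvolutionConfig, rng: np.random.Generator
) -> NetworkGenome:
    """Mutated copy of a genome.

    Every weight and threshold is independently perturbed with probability
    ``weight_mutation_prob`` by Gaussian noise. With probability
    ``structural_mutation_prob`` one structural event is drawn uniformly from
    the currently feasible subset of {gain cognitive, lose cognitive, gain
    context, lose context}: cognitive gains are blocked at ``max_cognitive``,
    a context node can only be added to a cognitive node lacking one, and a
    cognitive node takes its context node with it when lost. The first-move
    trait flips with probability ``first_move_flip_prob``.
    """
    pw, sd = cfg.weight_mutation_prob, cfg.weight_mutation_sd
    nodes: List[CognitiveGene] = []
    for g in genome.cognitive_nodes:
        ctx = g.context
        if ctx is not None:
            ctx = ContextGene(_perturb(ctx.w_context, pw, sd, rng))
        nodes.append(
            CognitiveGene(
                w_in_self=_perturb(g.w_in_self, pw, sd, rng),
                w_in_opp=_perturb(g.w_in_opp, pw, sd, rng),
                threshold=_perturb(g.threshold, pw, sd, rng),
                w_out=_perturb(g.w_out, pw, sd, rng),
                context=ctx,
            )
        )
    output_threshold = _perturb(genome.output_threshold, pw, sd, rng)

    if rng.random() < cfg.structural_mutation_prob:
        feasible = []
        if len(nodes) < cfg.max_cognitive:
            feasible.append("gain_cognitive")
        if len(nodes) > 0:
            feasible.append("lose_cognitive")
        if any(g.context is None for g in nodes):
            feasible.append("gain_context")
        if any(g.context is not None for g in nodes):
            feasible.append("lose_context")
        if feasible:
            event = feasible[int(rng.integers(len(feasible)))]
            isd = cfg.init_weight_sd  # fresh structure drawn from the initializer
            if event == "gain_cognitive":
                nodes.append(
                    CognitiveGene(
                        w_in_self=float(rng.normal(0.0, isd)),
                        w_in_opp=float(rng.normal(0.0, isd)),
                        threshold=float(rng.normal(0.0, isd)),
                        w_out=float(rng.normal(0.0, isd)),
                        context=None,
                    )
                )
            elif event == "lose_cognitive":
                # the context node (if any) is lost with its cognitive node
                del nodes[int(rng.integers(len(nodes)))]
            elif event == "gain_context":
                cands = [j for j, g in enumerate(nodes) if g.context is None]
                j = cands[int(rng.integers(len(cands)))]
                nodes[j] = CognitiveGene(
                    w_in_self=nodes[j].w_in_self,
                    w_in_opp=nodes[j].w_in_opp,
                    threshold=nodes[j].threshold,
                    w_out=nodes[j].w_out,
                    context=ContextGene(float(rng.normal(0.0, isd))),
                )
            else:  # lose_context
                cands = [j for j, g in enumerate(nodes) if g.context is not None]
                j = cands[int(rng.integers(len(cands)))]
                nodes[j] = CognitiveGene(
                    w_in_self=nodes[j].w_in_self,
                    w_in_opp=nodes[j].w_in_opp,
                    threshold=nodes[j].threshold,
                    w_out=nodes[j].w_out,
                    context=None,
                )

    first_move = genome.first_move
    if rng.random() < cfg.first_move_flip_prob:
        first_move = Move.D if first_move == Move.C else Move.C
    return NetworkGenome(
        first_move=first_move,
        cognitive_nodes=tuple(nodes),
        output_threshold=output_threshold,
    )


def _population_cov(x: np.ndarray, y: np.ndarray) -> float:
    """Population covariance (divide by n) — the selection differential."""
    return float(np.mean((x - x.mean()) * (y - y.mean())))


def run_replicate(
    cfg: EvolutionConfig,
    replicate_index: int = 0,
    progress: Optional[callable] = None,
) -> ReplicateResult:
    """Run one replicate: a full generation loop from a fresh random
    population, reproducible from ``cfg.seed + replicate_index``.

    ``progress``, if given, is called as ``progress(generation)`` every 1000
    generations.
    """
    seed = cfg.seed + replicate_index
    rng = np.random.default_rng(seed)
    game = cfg.game.to_game()
    pay = _engine.payoff_table(game)
    n = cfg.population_size
    n_pairs = n * (n - 1) // 2
    probe_set = build_probe_set(cfg.probe_depth)
    ps, po, plens = probe_payoffs(probe_set, game)
    canon = canonical_strategies(game, probe_set)
    canon_mat = np.stack([c.vector for c in canon])
    k = cfg.penalty_coefficient

    population = [random_genome(cfg, rng) for _ in range(n)]
    records: List[GenerationRecord] = []
    snapshots: List[Tuple[int, List[NetworkGenome]]] = []
    prev_freq = math.nan

    for gen in range(cfg.generations):
        arrs = _engine.encode_population(population, cfg.max_cognitive)
        if (arrs.n_cog > 0).any():
            u = rng.random((n_pairs, cfg.rounds, 2))
        else:
            # no network ever consults the uniforms; skip drawing the block
            u = np.empty((1, 1, 2), dtype=np.float64)
        mean_pay, coop = _engine.run_round_robin(arrs, pay, cfg.rounds, u)
        freq = coop / (n_pairs * 2 * cfg.rounds)
        i_vec = arrs.intelligence
        fit = mean_pay - k * i_vec

        behaviors = _engine.run_probe(arrs, ps, po, plens)
        d2 = ((behaviors[:, None, :] - canon_mat[None, :, :]) ** 2).sum(axis=2)
        cls = np.argmin(d2, axis=1)
        counts = np.bincount(cls, minlength=len(STRATEGY_NAMES))

        records.append(
            GenerationRecord(
                generation=gen,
                cooperation_frequency=freq,
                delta_cooperation=freq - prev_freq if gen > 0 else math.nan,
                mean_intelligence=float(i_vec.mean()),
                mean_fitness=float(fit.mean()),
                cov_fitness_intelligence=_population_cov(fit, i_vec.astype(np.float64)),
                strategy_counts=tuple(int(c) for c in counts),
            )
        )
        prev_freq = freq
        if cfg.snapshot_every is not None and gen % cfg.snapshot_every == 0:
            snapshots.append((gen, list(population)))

        parents = select_parents(fit, n, rng)
        population = [mutate(population[j], cfg, rng) for j in parents]

        if progress is not None and (gen + 1) % 1000 == 0:
            progress(gen + 1)

    return ReplicateResult(
        replicate=replicate_index,
        seed=seed,
        records=records,
        final_population=population,
        snapshots=snapshots,
    )


def run(
    cfg: EvolutionConfig, progress: Optional[callable] = None
) -> List[ReplicateResult]:
    """Run all replicates of the configured experiment sequentially."""
    out = []
    for r in range(cfg.replicates):
        cb = (lambda g, _r=r: progress(_r, g)) if progress is not None else None
        out.append(run_replicate(cfg, r, cb))
    return out


def records_to_frame(results, include_replicate: bool = True):
    """Flatten replicate records into a pandas DataFrame (one row per
    generation)."""
    import pandas as pd

    if isinstance(results, ReplicateResult):
        results = [results]
    rows = []
    for res in results:
        for rec in res.records:
            row = {
                "replicate": res.replicate,
                "generation": rec.generation,
                "cooperation_frequency": rec.cooperation_frequency,
                "delta_cooperation": rec.delta_cooperation,
                "mean_intelligence": rec.mean_intelligence,
                "mean_fitness": rec.mean_fitness,
                "cov_fitness_intelligence": rec.cov_fitness_intelligence,
            }
            for name, c in zip(STRATEGY_NAMES, rec.strategy_counts):
                row[f"n_{name}"] = c
            rows.append(row)
    df = pd.DataFrame(rows)
    if not include_replicate and "replicate" in df:
        df = df.drop(columns=["replicate"])
    return df
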