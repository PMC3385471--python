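# dilemmanet

Evolutionary simulation of decision-making "brains" in repeated social
dilemmas, built to study when cooperation selects for intelligence.

A population of 50 individuals plays iterated prisoner's dilemma (IPD,
payoffs `T=7 > R=6 > P=2 > S=1`) or iterated snowdrift (ISD,
`T=8 > R=5 > S=2 > P=1`). Each individual's strategy is computed by a small
Elman-style recurrent network: two inputs (both players' previous payoffs),
up to 10 evolvable cognitive nodes — each optionally owning a context
(memory) node — and a logistic output giving the probability of cooperating.
A heritable trait fixes the first move. Intelligence is structural:
`i = n_cognitive + n_context ∈ [0, 20]`.

A genetic algorithm evolves the networks: round-robin iterated games, then
`fitness = mean payoff per round − k·i` (a brain cost, default `k = 0.01`),
fitness-proportional reproduction, and mutation of weights, thresholds,
topology and first move. The analysis toolkit measures per generation the
cooperation frequency, the selection gradient for intelligence as the
Price-equation differential `cov(fitness, i)`, and the strategic composition
of the population — each genome is probed against all joint-move histories
of depth ≤ 2 and clustered to the nearest canonical strategy
(always-defect, always-cooperate, tit-for-tat, Pavlov). On top of that it
builds Gaussian-kernel selection surfaces over (cooperation, Δcooperation)
and the Spearman / Breusch–Pagan statistics linking intelligence,
cooperation and strategy frequencies.

The intended users are modellers in evolutionary game theory / behavioural
evolution who want a fast, tested, fully reproducible re-implementation of
this class of neuroevolution experiments.

## Worked example

Library use — evolve two short IPD replicates and summarise them:

```python
from dilemmanet.evolution import EvolutionConfig, records_to_frame, run
from dilemmanet.metrics_stats import analyze_runs

cfg = EvolutionConfig(game={"name": "ipd"}, generations=2000, replicates=2, seed=7)
df = records_to_frame(run(cfg))
rep = analyze_runs(df)
ic = rep.intelligence_cooperation
print("rho(mean_i, coop) = %.4f (p = %.3g, n = %d)" % (ic.rho, ic.p_value, ic.n))
```

prints

```
rho(mean_i, coop) = 0.1898 (p = 9.31e-34, n = 4000)
```

i.e. across these 4000 pooled generations, generations with bigger average
brains had *more* cooperation — short runs are dominated by the initial
decay of cooperation and drift; the defended negative IPD correlation
emerges at the full experiment scale used by `scripts/acceptance.py` (8
replicates × 10,000 generations). Each record row carries the cooperation
frequency, its change, mean intelligence, mean fitness, `cov(fitness, i)`
and the four strategy counts for one generation.

Probing a hand-built saturated tit-for-tat network (one cognitive node
reading its own previous payoff, which in these games reveals the opponent's
move):

```python
from dilemmanet.games import Move, ipd_default
from dilemmanet.network import CognitiveGene, NetworkGenome
from dilemmanet.strategy_analysis import build_probe_set, canonical_strategies, classify, probe

tft = NetworkGenome(
    first_move=Move.C,
    cognitive_nodes=(CognitiveGene(w_in_self=10.0, w_in_opp=0.0, threshold=40.0, w_out=10.0),),
    output_threshold=5.0,
)
ps, game = build_probe_set(2), ipd_default()
vec = probe(tft, ps, game)
print(vec[:5].round(4), "->", classify(vec, canonical_strategies(game, ps)))
```

prints

```
[1.     0.0067 0.9933 0.0067 0.9933] -> tit_for_tat
```

— cooperate first, then cooperate with probability σ(5) ≈ 0.9933 exactly
when the opponent's last move was cooperation.

Command line (`dilemmanet simulate / probe / analyze / surface`):

```sh
cat > cfg.toml <<'EOF'
[game]
name = "isd"
EOF
dilemmanet simulate --config cfg.toml --out run/ --generations 2000 --replicates 2 --seed 7
dilemmanet analyze --runs run/ --out report.json
dilemmanet surface --runs run/ --out surface.csv
```

`run/` holds one records CSV per replicate, the echoed config and a manifest
(config hash, derived seeds, row counts); identical config + seed reproduces
the CSVs byte for byte.

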