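# Methods

## The model

`dilemmanet` simulates the evolution of decision-making machinery in repeated
two-player social dilemmas. Each of the `N = 50` individuals in a population
carries a small recurrent neural network (an Elman-style architecture) that
maps last round's payoffs to a probability of cooperating this round:

* **Inputs.** Two nodes receive the focal player's and the opponent's payoff
  from the previous round, fed raw on the payoff scale of the game (1–8 for
  the default tables). No input exists before round 0, so a heritable binary
  trait fixes the first move.
* **Hidden layer.** 0–10 *cognitive* nodes; cognitive node *j* computes
  `a_j = σ(w_self·p_self + w_opp·p_opp + w_ctx·c_j − θ_j)` with
  `σ(x) = 1/(1+e^(−x))`. A cognitive node may own one *context* node, which
  stores `a_j` (unweighted) after every round and returns it, times `w_ctx`,
  as input on the next round — memory without an explicit event record.
  Updates are synchronous: all activations are computed from the pre-update
  context values. The intelligence of an individual is the structural count
  `i = n_cognitive + n_context ∈ [0, 20]`.
* **Output.** `p_cooperate = σ(Σ_j w_out_j·a_j − θ_out)`; the move is a
  Bernoulli draw from it. Because σ only asymptotes to 0/1, contingent
  (switching) behaviour is inherently noisier than saturated constant
  behaviour; we add no extraneous noise. Strictly interior outputs hold up
  to float64 underflow (|pre-activation| ≲ 745), far beyond the weight
  magnitudes evolution reaches in practice.
* **Games.** Prisoner's dilemma `T=7 > R=6 > P=2 > S=1` and snowdrift
  `T=8 > R=5 > S=2 > P=1`. One-shot equilibria: 0 cooperation for the PD and
  the mixed `x = (S−P)/((S−P)+(T−R)) = 0.25` for the snowdrift defaults. The
  equilibrium returned by `games.single_shot_equilibrium` is the analytic
  value; finite-population simulations settle slightly below it (~0.24 across
  our runs). Note that with the default snowdrift table the total payoff of
  mutual cooperation ties unilateral defection (`2R = T+S = 10`); the social
  optimum is strictly unique only in the PD table.

## The genetic algorithm

Per generation: every individual plays every other exactly once (C(50,2) =
1225 pairings, no self-play, memory reset per pairing) for 50 rounds;
`fitness = mean payoff per round − k·i` with `k = 0.01`; parents are drawn
fitness-proportionally (fitness floored at 1e−6 so the wheel stays defined —
the floor never reorders positive fitnesses); each of the 50 offspring is a
mutated copy; the parent generation dies. One PCG64 stream per replicate,
seeded `seed + replicate_index`.

Mutation: every weight/threshold independently gains N(0, 0.5²) noise with
probability 0.1; with probability 0.05 one structural event is drawn
uniformly from the *feasible* subset of {gain cognitive, lose cognitive,
gain context, lose context} (gains blocked at the caps; a context node needs
a free cognitive host; losing a cognitive node removes its context node);
the first move flips with probability 0.01. New structure is initialised
N(0, 1), like the founding population (first moves fair-coin, 0–3 cognitive
nodes each with a context node with probability 1/2).

Rounds per pairing, mutation rates, the linear penalty form and size, and
the initialiser are deliberate package defaults (exposed in the config and
logged): 50 rounds lets memory strategies matter at desk scale; `k = 0.01`
prices a full 20-node brain at 0.2 payoff units per round, i.e. 3–20% of
achievable payoffs; linear cost is the minimal monotone choice. All were
fixed from these considerations before the statistical checks were run, and
the k-sensitivity test sweeps `k ∈ {0, 0.01, 0.05}`.

## Measurements

* **Cooperation frequency**: cooperative moves over all moves of a
  generation (each individual contributes its moves in all 49 pairings);
  `delta_cooperation` is its change from the previous generation (NaN at
  generation 0).
* **Selection gradient for intelligence**: the within-generation *population*
  covariance `cov(fitness, i)` (divide by n) — the Price-equation selection
  differential of the realised population, not a sample estimate.
* **Strategy classification**: each genome is replayed from a blank state
  against all joint-move histories of length ≤ 2 (4 + 16 = 20 probes); the
  behaviour vector is the first move followed by the final output
  probability after each history (probabilities, not sampled moves, so
  classification is deterministic). It is assigned to the Euclidean-nearest
  of four canonical vectors: always-defect, always-cooperate, tit-for-tat,
  and Pavlov with the win threshold at `(R+P)/2` (so T, R → stay; P, S →
  shift, in both default games). Ties break in that listed order. The probe
  depth and metric are configurable for sensitivity analysis.
* **Selection surface**: Nadaraya–Watson Gaussian-kernel mean of
  `cov(fitness, i)` on a 41×81 grid over (cooperation frequency ∈ [0,1],
  delta ∈ [−1,1]); per-axis bandwidths default to Silverman's rule (with a
  0.1 fallback when the spread is degenerate); cells whose implied previous
  frequency `freq − delta` leaves [0,1] are masked as impossible.
* **Correlation report**: Spearman ρ (scipy) between mean intelligence and
  cooperation, and between each strategy-class frequency and the selection
  gradient, overall and stratified at cooperation frequency 0.5. The
  Breusch–Pagan test regresses cooperation on mean intelligence and the
  squared residuals on intelligence again; we report the auxiliary
  intercept/slope on the raw residual-squared scale and the classical
  (ESS/2) LM p-value by default, with the Koenker n·R² variant available.
  Generations are pooled across replicates by default; passing a single
  replicate's frame gives the per-replicate variant.

## Numerical and implementation choices

The round-robin and probe inner loops run numba-JIT-compiled over padded
arrays; the genome-object code path is the reference implementation, and the
two are held to bit-exact agreement by tests (both consume pre-drawn uniform
blocks indexed by (pair, round, player), so zero-hidden-node decisions use
no randomness and a pairing's outcome depends only on the genomes and its
block). A pair of memory-free genomes plays a provably constant match, which
the kernel scores in closed form — this makes the contingency-disabled
control experiments (`max_cognitive = 0`) effectively free.

The sigmoid is evaluated in its numerically stable two-branch form; context
values live in [0,1] by construction. All CSV output round-trips float64
exactly (`%.17g` out, `float_precision="round_trip"` in).

## Problem sizes and what the synthetic runs show

Desk-scale experiments use population 50 with 10,000 generations per
prisoner's-dilemma replicate (so that the rarer high-cooperation epochs
accumulate enough generations for stratified statistics; 8 replicates in the
acceptance script, 5 in the test suite), 5,000 generations for each of 5
snowdrift replicates, and 10,000 for the contingency-disabled equilibrium
controls. These are the package's chosen default experiment sizes; longer
runs sharpen, but do not qualitatively change, the reported correlations,
and the stratified statistics remain the most seed-sensitive numbers at
this scale.

The simulator generates all of its own data; nothing is fit to external
observations. Passing tests therefore demonstrate internal consistency of
the model and the robustness of its qualitative claims (cooperation cycles,
equilibrium recovery without contingency, heteroskedasticity of cooperation
in intelligence, strategy/selection-gradient correlations) — they say
nothing about real animal cognition, and the intelligence measure is a
structural capacity proxy, blind to whether the evolved computation is
"wise".

## Known limitations

* Single game per population; no partner choice, spatial structure, noise in
  payoff perception, or crossover.
* Strategy classification is a coarse 4-class projection; evolved behaviour
  is continuous and often uses longer memory than the depth-2 probes
  resolve.
* Stratified high-cooperation correlations rest on a small fraction of
  generations (~1% in the prisoner's dilemma at desk scale) and carry the
  widest error bars of the reported statistics.
* The per-generation records keep population summaries, not per-individual
  trajectories; genome snapshots are optional and periodic.
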