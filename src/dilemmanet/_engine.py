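"""Array-based fast path for tournaments and probing.

Populations are packed into padded arrays (one row per individual, one column
per cognitive-node slot) and the inner round-robin / probe loops are JIT
compiled with numba. The arithmetic mirrors :func:`dilemmanet.network.activate`
operation-for-operation so that the fast path and the genome-object reference
path produce bit-identical trajectories when fed the same uniform variates.

Randomness is externalised: callers pre-draw a block of uniforms
``u[pair, round, player_slot]`` and the kernels consume them positionally, so
a match's outcome depends only on the genomes and the block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from numba import njit

from .games import Game, Move
from .network import CognitiveGene, ContextGene, NetworkGenome

__all__ = ["PopulationArrays", "encode_population", "decode_population"]


@dataclass
class PopulationArrays:
    """Padded array view of a population of genomes.

    ``n_cog[i]`` cognitive slots of row ``i`` are live; ``has_ctx`` marks
    which live slots own a context node.
    """

    first_move: np.ndarray  # int64 (n,)
    n_cog: np.ndarray  # int64 (n,)
    has_ctx: np.ndarray  # bool (n, M)
    w_self: np.ndarray  # float64 (n, M)
    w_opp: np.ndarray  # float64 (n, M)
    thr: np.ndarray  # float64 (n, M)
    w_out: np.ndarray  # float64 (n, M)
    w_ctx: np.ndarray  # float64 (n, M)
    out_thr: np.ndarray  # float64 (n,)

    @property
    def n(self) -> int:
        return self.first_move.shape[0]

    @property
    def intelligence(self) -> np.ndarray:
        return self.n_cog + self.has_ctx.sum(axis=1)


def encode_population(genomes: Sequence[NetworkGenome], max_cognitive: int | None = None) -> PopulationArrays:
    """Pack genome objects into padded arrays for the kernels."""
    n = len(genomes)
    if max_cognitive is None:
        max_cognitive = max((g.n_cognitive for g in genomes), default=0)
    M = max(max_cognitive, 1)  # keep 2-d arrays well-formed for numba
    arrs = PopulationArrays(
        first_move=np.zeros(n, dtype=np.int64),
        n_cog=np.zeros(n, dtype=np.int64),
        has_ctx=np.zeros((n, M), dtype=np.bool_),
        w_self=np.zeros((n, M), dtype=np.float64),
        w_opp=np.zeros((n, M), dtype=np.float64),
        thr=np.zeros((n, M), dtype=np.float64),
        w_out=np.zeros((n, M), dtype=np.float64),
        w_ctx=np.zeros((n, M), dtype=np.float64),
        out_thr=np.zeros(n, dtype=np.float64),
    )
    for i, g in enumerate(genomes):
        if g.n_cognitive > M:
            raise ValueError(
                f"genome {i} has {g.n_cognitive} cognitive nodes, above the cap {M}"
            )
        arrs.first_move[i] = int(g.first_move)
        arrs.n_cog[i] = g.n_cognitive
        arrs.out_thr[i] = g.output_threshold
        for j, node in enumerate(g.cognitive_nodes):
            arrs.w_self[i, j] = node.w_in_self
            arrs.w_opp[i, j] = node.w_in_opp
            arrs.thr[i, j] = node.threshold
            arrs.w_out[i, j] = node.w_out
            if node.context is not None:
                arrs.has_ctx[i, j] = True
                arrs.w_ctx[i, j] = node.context.w_context
    return arrs


def decode_population(arrs: PopulationArrays) -> List[NetworkGenome]:
    """Inverse of :func:`encode_population`."""
    out = []
    for i in range(arrs.n):
        nodes = tuple(
            CognitiveGene(
                w_in_self=float(arrs.w_self[i, j]),
                w_in_opp=float(arrs.w_opp[i, j]),
                threshold=float(arrs.thr[i, j]),
                w_out=float(arrs.w_out[i, j]),
                context=(
                    ContextGene(float(arrs.w_ctx[i, j])) if arrs.has_ctx[i, j] else None
                ),
            )
            for j in range(arrs.n_cog[i])
        )
        out.append(
            NetworkGenome(
                first_move=Move(int(arrs.first_move[i])),
                cognitive_nodes=nodes,
                output_threshold=float(arrs.out_thr[i]),
            )
        )
    return out


def payoff_table(game: Game) -> np.ndarray:
    """``pay[own_move, opp_move]`` lookup used by the kernels."""
    return game.payoff_matrix()


@njit(cache=True, inline="always")
def _sig(z):
    if z >= 0.0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


@njit(cache=True, inline="always")
def _net_step(i, n_cog, has_ctx, w_self, w_opp, thr, w_out, w_ctx, out_thr, ps, po, c, new_c):
    """Forward pass for individual ``i``; fills ``new_c`` with the next
    context values and returns the cooperation probability."""
    s = 0.0
    for j in range(n_cog[i]):
        z = w_self[i, j] * ps + w_opp[i, j] * po
        if has_ctx[i, j]:
            z = z + w_ctx[i, j] * c[j]
        z = z - thr[i, j]
        a = _sig(z)
        new_c[j] = a
        s = s + w_out[i, j] * a
    s = s - out_thr[i]
    return _sig(s)


@njit(cache=True)
def _round_robin_kernel(
    first_move,
    n_cog,
    has_ctx,
    w_self,
    w_opp,
    thr,
    w_out,
    w_ctx,
    out_thr,
    pay,
    rounds,
    u,
    mean_pay,
):
    """Play every unordered pair once; accumulate per-individual mean payoff
    per round (summed over matches) into ``mean_pay`` and return the total
    number of cooperative moves."""
    n = first_move.shape[0]
    M = w_self.shape[1]
    ca = np.empty(M, dtype=np.float64)
    cb = np.empty(M, dtype=np.float64)
    na = np.empty(M, dtype=np.float64)
    nb = np.empty(M, dtype=np.float64)
    coop = 0
    pair = 0
    for a in range(n - 1):
        for b in range(a + 1, n):
            if n_cog[a] == 0 and n_cog[b] == 0:
                # non-contingent pair: every round repeats the first moves
                ma = first_move[a]
                mb = first_move[b]
                mean_pay[a] += pay[ma, mb]
                mean_pay[b] += pay[mb, ma]
                coop += (ma + mb) * rounds
            else:
                for j in range(n_cog[a]):
                    ca[j] = 0.0
                for j in range(n_cog[b]):
                    cb[j] = 0.0
                ma = first_move[a]
                mb = first_move[b]
                coop += ma + mb
                ppa = pay[ma, mb]
                ppb = pay[mb, ma]
                tot_a = ppa
                tot_b = ppb
                for t in range(1, rounds):
                    if n_cog[a] > 0:
                        pa = _net_step(
                            a, n_cog, has_ctx, w_self, w_opp, thr, w_out, w_ctx,
                            out_thr, ppa, ppb, ca, na,
                        )
                        ma_new = 1 if u[pair, t, 0] < pa else 0
                        for j in range(n_cog[a]):
                            ca[j] = na[j]
                    else:
                        ma_new = first_move[a]
                    if n_cog[b] > 0:
                        pb = _net_step(
                            b, n_cog, has_ctx, w_self, w_opp, thr, w_out, w_ctx,
                            out_thr, ppb, ppa, cb, nb,
                        )
                        mb_new = 1 if u[pair, t, 1] < pb else 0
                        for j in range(n_cog[b]):
                            cb[j] = nb[j]
                    else:
                        mb_new = first_move[b]
                    ma = ma_new
                    mb = mb_new
                    coop += ma + mb
                    ppa = pay[ma, mb]
                    ppb = pay[mb, ma]
                    tot_a += ppa
                    tot_b += ppb
                mean_pay[a] += tot_a / rounds
                mean_pay[b] += tot_b / rounds
            pair += 1
    return coop


@njit(cache=True)
def _probe_kernel(
    first_move,
    n_cog,
    has_ctx,
    w_self,
    w_opp,
    thr,
    w_out,
    w_ctx,
    out_thr,
    probe_ps,
    probe_po,
    probe_len,
    out,
):
    """Behaviour vectors for every individual: first move, then the final
    cooperation probability after replaying each probe history from a blank
    state. Non-contingent genomes emit their first move at every position."""
    n = first_move.shape[0]
    Q = probe_len.shape[0]
    M = w_self.shape[1]
    c = np.empty(M, dtype=np.float64)
    nc = np.empty(M, dtype=np.float64)
    for i in range(n):
        out[i, 0] = first_move[i]
        if n_cog[i] == 0:
            for q in range(Q):
                out[i, q + 1] = first_move[i]
        else:
            for q in range(Q):
                for j in range(n_cog[i]):
                    c[j] = 0.0
                p = 0.5
                for t in range(probe_len[q]):
                    p = _net_step(
                        i, n_cog, has_ctx, w_self, w_opp, thr, w_out, w_ctx,
                        out_thr, probe_ps[q, t], probe_po[q, t], c, nc,
                    )
                    for j in range(n_cog[i]):
                        c[j] = nc[j]
                out[i, q + 1] = p


def run_round_robin(
    arrs: PopulationArrays, pay: np.ndarray, rounds: int, u: np.ndarray
) -> tuple[np.ndarray, int]:
    """Round robin over a packed population.

    Returns ``(mean_payoffs, cooperation_count)`` where ``mean_payoffs[i]`` is
    individual i's mean payoff per round averaged over its ``n-1`` matches.
    """
    n = arrs.n
    if n < 2:
        raise ValueError("round robin requires a population of at least 2")
    mean_pay = np.zeros(n, dtype=np.float64)
    coop = _round_robin_kernel(
        arrs.first_move, arrs.n_cog, arrs.has_ctx, arrs.w_self, arrs.w_opp,
        arrs.thr, arrs.w_out, arrs.w_ctx, arrs.out_thr,
        pay, rounds, u, mean_pay,
    )
    mean_pay /= n - 1
    return mean_pay, int(coop)


def run_probe(
    arrs: PopulationArrays,
    probe_ps: np.ndarray,
    probe_po: np.ndarray,
    probe_len: np.ndarray,
) -> np.ndarray:
    """Behaviour vectors (n, n_probes + 1) for a packed population."""
    out = np.empty((arrs.n, probe_len.shape[0] + 1), dtype=np.float64)
    _probe_kernel(
        arrs.first_move, arrs.n_cog, arrs.has_ctx, arrs.w_self, arrs.w_opp,
        arrs.thr, arrs.w_out, arrs.w_ctx, arrs.out_thr,
        probe_ps, probe_po, probe_len, out,
    )
    return out
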