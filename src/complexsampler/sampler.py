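"""Metropolis-Hastings chain over set partitions of the protein set.

The chain samples partitions C with stationary probability
P(C) proportional to exp(-f(C) / T).  Each step relocates a single,
uniformly chosen protein ``u``: with probability ``beta`` it becomes a new
singleton cluster; otherwise it joins an existing cluster ``c`` of the
partition-after-removal with probability proportional to

    S(c) = sum over ranks i with v_i in c of 1 / i**2,

where v_1, v_2, ... are u's interaction partners sorted by decreasing
weight w({u, v}).  At the default temperature T = 1e-9 the chain is
near-greedy and the run is effectively a stochastic hill climb; at larger
T (with the Hastings correction on) the chain genuinely samples from the
Boltzmann distribution, which is what the stationary-distribution tests
verify.

The output is the minimum-f state seen over the whole run, with its
singleton clusters removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .network import WeightedNetwork
from .scoring import NEW_SINGLETON, Move, PartitionState, ScoreParams

logger = logging.getLogger(__name__)

__all__ = ["SamplerConfig", "PredictionResult", "initial_state", "propose", "accept", "run"]


@dataclass(frozen=True)
class SamplerConfig:
    """Chain parameters; see the methods note for the rationale of the defaults."""

    T: float = 1e-9  # temperature
    L: int = 2_000_000  # number of iterations
    beta: float = 0.01  # probability of proposing a new singleton cluster
    seed: int = 0
    score: ScoreParams = field(default_factory=ScoreParams)
    hastings_correction: bool = True

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")


@dataclass
class PredictionResult:
    """Best state of a finished run, reduced to clusters of size >= 2."""

    clusters: list[frozenset[str]]
    best_f: float
    g1: float
    g2: float
    g3: float
    best_iteration: int
    n_iterations: int
    n_accepted: int
    seed: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_iterations if self.n_iterations else 0.0

    @property
    def n_proteins(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def avg_size(self) -> float:
        return self.n_proteins / len(self.clusters) if self.clusters else 0.0


def initial_state(net: WeightedNetwork, params: ScoreParams | None = None) -> PartitionState:
    """Start state: the maximum-weight pair as one cluster, all else singletons.

    Weight ties are broken by lexicographic pair order so the start is
    deterministic regardless of input file order.
    """
    params = params or ScoreParams()
    (u, v), _ = net.max_weight_edge()
    clusters: list[set[str]] = [{u, v}]
    clusters.extend({p} for p in sorted(net.proteins) if p != u and p != v)
    return PartitionState(clusters, net, params)


def _rank_weights(net: WeightedNetwork, u: str) -> tuple[tuple[str, ...], np.ndarray]:
    """u's neighbors in rank order and their proposal weights 1/i^2."""
    nbrs = net.neighbor_rank(u)
    inv = 1.0 / (np.arange(1, len(nbrs) + 1, dtype=float) ** 2)
    return nbrs, inv


def propose(
    state: PartitionState,
    net: WeightedNetwork,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> Move:
    """Draw a relocation move together with its forward/reverse log-probabilities.

    The reverse probability is evaluated by the same formulas on the proposed
    state; since removing ``u`` again yields the same partition-after-removal,
    the cluster weights S(c) and their normalizer are shared between the two
    directions.
    """
    proteins = state.protein_order
    u = proteins[int(rng.integers(len(proteins)))]
    return _propose_for(state, net, config, u, float(rng.random()), float(rng.random()))


def _propose_for(
    state: PartitionState,
    net: WeightedNetwork,
    config: SamplerConfig,
    u: str,
    r_branch: float,
    r_cluster: float,
) -> Move:
    log_nv = math.log(len(state.protein_order))
    src = state.membership[u]
    src_size = len(state.clusters[src])
    nbrs = net.neighbor_rank(u)
    d_u = len(nbrs)

    if d_u == 0:
        # no positive-weight partner anywhere: the only reachable state is
        # u-as-singleton, taken deterministically (q = (beta + (1-beta))/|V|)
        move_dst = NEW_SINGLETON
        log_q_fwd = -log_nv
        log_q_rev = -log_nv  # u must be a singleton already, so C' = C
        return Move(u, src, move_dst, log_q_fwd, log_q_rev)

    # cluster weights S(c) over the partition after u's removal
    inv = state.inv_rank_sq(u)
    S: dict[int, float] = {}
    membership = state.membership
    for i, v in enumerate(nbrs):
        cid = membership[v]
        S[cid] = S.get(cid, 0.0) + inv[i]
    Z = float(sum(S.values()))

    log_beta = math.log(config.beta)
    log_1mbeta = math.log1p(-config.beta)

    if r_branch < config.beta:
        dst = NEW_SINGLETON
        log_q_fwd = log_beta - log_nv
    else:
        r = r_cluster * Z
        acc = 0.0
        dst = next(iter(S))
        for cid, sc in S.items():
            acc += sc
            dst = cid
            if r < acc:
                break
        log_q_fwd = log_1mbeta + math.log(S[dst]) - math.log(Z) - log_nv

    # reverse: relocate u from its new cluster back where it came from
    if src_size >= 2:
        s_src = S.get(src, 0.0)
        log_q_rev = (
            log_1mbeta + math.log(s_src) - math.log(Z) - log_nv
            if s_src > 0.0
            else -math.inf
        )
    else:
        log_q_rev = log_beta - log_nv
    return Move(u, src, dst, log_q_fwd, log_q_rev)


def accept(
    delta_f: float,
    move: Move,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> bool:
    """Metropolis-Hastings acceptance, entirely in log space.

    Accepts iff log U < min(0, -delta_f/T + log q_rev - log q_fwd); the
    proposal-ratio term is dropped when the Hastings correction is off.
    A +inf delta (forbidden state) always rejects.
    """
    r = float(rng.random())
    return _accept_with(delta_f, move, config, r)


def _accept_with(delta_f: float, move: Move, config: SamplerConfig, r: float) -> bool:
    if math.isinf(delta_f) and delta_f > 0:
        return False
    log_alpha = -delta_f / config.T
    if config.hastings_correction:
        log_alpha += move.log_q_rev - move.log_q_fwd
    if log_alpha >= 0.0:
        return True
    return math.log(r) < log_alpha


def run(
    net: WeightedNetwork,
    config: SamplerConfig,
    log_every: int = 0,
    state_callback=None,
) -> PredictionResult:
    """Execute the full chain and return the best (minimum-f) state seen.

    ``state_callback(state)``, if given, is invoked once per iteration with
    the post-decision state (used by the stationary-distribution tests).
    Fully reproducible given ``config.seed``.
    """
    state = initial_state(net, config.score)
    rng = np.random.default_rng(config.seed)
    proteins = state.protein_order
    n = len(proteins)
    if n < 2:
        raise ValueError("need at least two proteins to sample")

    best_f = state.f
    best_iter = 0
    best_clusters = state.cluster_sets()
    n_accepted = 0

    chunk = 8192
    for start in range(0, config.L, chunk):
        m = min(chunk, config.L - start)
        u_idx = rng.integers(0, n, size=m)
        r_branch = rng.random(size=m)
        r_cluster = rng.random(size=m)
        r_accept = rng.random(size=m)
        for j in range(m):
            it = start + j
            u = proteins[u_idx[j]]
            move = _propose_for(state, net, config, u, r_branch[j], r_cluster[j])
            if move.destination == move.source:
                delta = 0.0
            elif move.destination == NEW_SINGLETON and len(state.clusters[move.source]) == 1:
                delta = 0.0  # C' = C up to cluster relabeling
            else:
                delta = state.score_delta(move)
            if _accept_with(delta, move, config, r_accept[j]):
                n_accepted += 1
                if delta != 0.0 or move.destination != move.source:
                    state.apply_move(move)
                if state.f < best_f:
                    best_f = state.f
                    best_iter = it + 1
                    best_clusters = state.cluster_sets()
            if state_callback is not None:
                state_callback(state)
            if log_every and (it + 1) % log_every == 0:
                logger.info(
                    "iter %d f=%.6g best=%.6g acc=%.3f",
                    it + 1, state.f, best_f, n_accepted / (it + 1),
                )

    # score components of the best state, recomputed cleanly
    best_state = PartitionState([set(c) for c in best_clusters], net, config.score)
    result = PredictionResult(
        clusters=sorted(
            (c for c in best_clusters if len(c) >= 2),
            key=lambda c: (-len(c), tuple(sorted(c))),
        ),
        best_f=best_state.f,
        g1=best_state.g1_total,
        g2=best_state.g2,
        g3=best_state.g3,
        best_iteration=best_iter,
        n_iterations=config.L,
        n_accepted=n_accepted,
        seed=config.seed,
    )
    return result
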