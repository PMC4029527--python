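"""Partition scoring: f(C) = -(g1(C) + g2(C) + g3(C)).

The score of a partition ``C`` of the protein set V combines

* ``g1`` — a generalized density per cluster: the total intra-cluster edge
  weight divided by sqrt(|c|).  Singletons contribute 0; clusters larger
  than ``N`` or containing a member with no positive-weight partner inside
  the cluster score -inf (their partitions have probability zero).
* ``g2`` — a Gaussian penalty pulling the relative frequency of cluster
  sizes (among clusters of size >= 2) toward a truncated power law
  psi(i) ~ i^-gamma on sizes 2..N, with size-dependent variance
  sigma2_i^2 = sigma2_scale * sigma2_base^-i.
* ``g3`` — a Gaussian penalty pulling s(C), the number of proteins inside
  clusters of size >= 2, toward a target lambda.

Pair-sum convention: the intra-cluster weight sum counts each unordered
pair once.  This is a uniform factor-of-2 choice relative to an ordered
double sum; it rescales g1 (and hence the effective temperature) globally
and is fixed here once.

:class:`PartitionState` maintains the partition together with cached score
components and supports O(cluster-size) evaluation and application of
single-protein relocation moves, which is what makes a multi-million
iteration chain affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .network import WeightedNetwork

__all__ = [
    "ScoreParams",
    "Move",
    "NEW_SINGLETON",
    "PartitionState",
    "g1_cluster",
    "psi_target",
    "g2_partition",
    "g3_partition",
    "total_score",
]

#: Sentinel destination for moves that create a new singleton cluster.
NEW_SINGLETON: int = -1


@dataclass(frozen=True)
class ScoreParams:
    """Score hyper-parameters; defaults suit a ~6000-protein normalized network."""

    N: int = 100  # maximum cluster size
    gamma: float = 2.0  # power-law exponent of the target size law
    sigma2_scale: float = 1000.0  # sigma2_i^2 = sigma2_scale * sigma2_base**(-i)
    sigma2_base: float = 1.1
    lam: float = 2000.0  # target number of clustered proteins
    sigma3_sq: float = 1e6  # variance of the g3 Gaussian
    g2_enabled: bool = True

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.sigma2_scale <= 0 or self.sigma2_base <= 0 or self.sigma3_sq <= 0:
            raise ValueError("variances must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    def sigma2_sq(self, i: int) -> float:
        """Variance of the g2 Gaussian at cluster size ``i``."""
        return self.sigma2_scale * self.sigma2_base ** (-i)


@dataclass(frozen=True)
class Move:
    """Relocation of one protein from its cluster to another (or a new singleton)."""

    u: str
    source: int
    destination: int  # cluster id, or NEW_SINGLETON
    log_q_fwd: float = 0.0
    log_q_rev: float = 0.0


# -- pure scoring functions ------------------------------------------------


def g1_cluster(c: frozenset[str] | set[str], net: WeightedNetwork, N: int) -> float:
    """Generalized density of one cluster.

    Returns 0 for singletons; ``-inf`` if ``|c| > N`` or some member has
    weight 0 to every other member; otherwise the sum of intra-cluster pair
    weights (each unordered pair once) divided by sqrt(|c|).
    """
    for u in c:
        if u not in net.proteins:
            raise ValueError(f"protein {u!r} not in the network")
    k = len(c)
    if k == 0:
        raise ValueError("empty cluster")
    if k == 1:
        return 0.0
    if k > N:
        return -math.inf
    total = 0.0
    members = list(c)
    for idx, u in enumerate(members):
        row = net.adj.get(u, {})
        inner = 0.0
        for v in members:
            if v != u:
                inner += row.get(v, 0.0)
        if inner == 0.0:
            return -math.inf
        total += inner
    return (total / 2.0) / math.sqrt(k)


def psi_target(i: int, gamma: float, N: int) -> float:
    """Target relative frequency of clusters of size ``i``: i^-gamma, normalized over 2..N."""
    if not 2 <= i <= N:
        raise ValueError(f"size {i} out of range [2, {N}]")
    denom = sum(j ** (-gamma) for j in range(2, N + 1))
    return i ** (-gamma) / denom


def _psi_vector(params: ScoreParams) -> np.ndarray:
    sizes = np.arange(2, params.N + 1, dtype=float)
    raw = sizes ** (-params.gamma)
    return raw / raw.sum()


def _inv_two_sigma2(params: ScoreParams) -> np.ndarray:
    sizes = np.arange(2, params.N + 1, dtype=float)
    return 1.0 / (2.0 * params.sigma2_scale * params.sigma2_base ** (-sizes))


def g2_partition(size_hist: np.ndarray, params: ScoreParams) -> float:
    """Power-law size regularizer from a size histogram.

    ``size_hist[i]`` counts clusters of size ``i`` (index 0 unused).  The
    empirical frequency psi_C(i) is taken relative to clusters of size >= 2;
    if none exist, psi_C is identically 0.  Returns 0 when g2 is disabled.
    """
    if not params.g2_enabled:
        return 0.0
    counts = np.asarray(size_hist, dtype=float)[2 : params.N + 1]
    if counts.shape[0] < params.N - 1:
        counts = np.pad(counts, (0, params.N - 1 - counts.shape[0]))
    n_ge2 = counts.sum()
    psi_c = counts / n_ge2 if n_ge2 > 0 else np.zeros_like(counts)
    diff = psi_c - _psi_vector(params)
    return float(-(diff * diff * _inv_two_sigma2(params)).sum())


def g3_partition(s: float, params: ScoreParams) -> float:
    """Clustered-protein-count regularizer: -(s - lambda)^2 / (2 sigma3^2)."""
    if s < 0:
        raise ValueError("s must be >= 0")
    d = s - params.lam
    return -(d * d) / (2.0 * params.sigma3_sq)


# -- partition state with incremental scoring ------------------------------


class PartitionState:
    """A partition of V with cached score components and O(|c|) move deltas.

    Internal bookkeeping per cluster id:

    * ``clusters[cid]`` — the member set;
    * ``member_w[cid][u]`` — sum of weights from ``u`` to the other members,
      so the g1 numerator of the cluster is ``sum(member_w[cid].values())/2``;
    * ``member_cnt[cid][u]`` — integer count of positive-weight partners of
      ``u`` inside the cluster; a member is "isolated" exactly when its count
      is 0 (an integer test immune to floating-point cancellation).

    Committed states always have finite ``f``: moves that would create an
    over-size cluster or an isolated member get delta +inf and are rejected
    by the chain before :meth:`apply_move` is ever called on them.
    """

    def __init__(
        self,
        clusters: list[set[str]] | list[frozenset[str]],
        net: WeightedNetwork,
        params: ScoreParams,
    ) -> None:
        self.net = net
        self.params = params
        self._psi = _psi_vector(params)
        self._i2s = _inv_two_sigma2(params)
        self.clusters: dict[int, set[str]] = {}
        self.membership: dict[str, int] = {}
        self.member_w: dict[int, dict[str, float]] = {}
        self.member_cnt: dict[int, dict[str, int]] = {}
        self.g1_terms: dict[int, float] = {}
        self.size_hist = np.zeros(params.N + 2, dtype=float)
        self.protein_order: tuple[str, ...] = tuple(sorted(net.proteins))
        self._inv_rank_sq: dict[str, np.ndarray] = {}
        self._next_cid = 0
        seen: set[str] = set()
        for c in clusters:
            cset = set(c)
            if not cset:
                raise ValueError("empty cluster in partition")
            if cset & seen:
                raise ValueError("clusters are not disjoint")
            seen |= cset
            self._insert_cluster(cset)
        if seen != set(net.proteins):
            raise ValueError("clusters do not cover the protein set exactly")
        self._refresh_totals()

    # -- construction helpers --

    def _insert_cluster(self, cset: set[str]) -> int:
        cid = self._next_cid
        self._next_cid += 1
        self.clusters[cid] = cset
        for u in cset:
            self.membership[u] = cid
        mw: dict[str, float] = {}
        mc: dict[str, int] = {}
        for u in cset:
            row = self.net.adj.get(u, {})
            mw[u] = sum(row.get(v, 0.0) for v in cset if v != u)
            mc[u] = sum(1 for v in cset if v != u and v in row)
        self.member_w[cid] = mw
        self.member_cnt[cid] = mc
        self.g1_terms[cid] = self._g1_from_mw(mw, mc)
        self.size_hist[min(len(cset), self.params.N + 1)] += 1
        return cid

    def _g1_from_mw(self, mw: dict[str, float], mc: dict[str, int]) -> float:
        k = len(mw)
        if k == 1:
            return 0.0
        if k > self.params.N:
            return -math.inf
        total = 0.0
        for u, w in mw.items():
            if mc[u] == 0:
                return -math.inf
            total += w
        return (total / 2.0) / math.sqrt(k)

    def _refresh_totals(self) -> None:
        self.g1_total = 0.0
        n_inf = 0
        for term in self.g1_terms.values():
            if term == -math.inf:
                n_inf += 1
            else:
                self.g1_total += term
        self._n_inf = n_inf
        sizes = np.arange(self.size_hist.shape[0], dtype=float)
        self.s = float((sizes[2:] * self.size_hist[2:]).sum())
        self.g2 = self._g2_of_hist(self.size_hist)
        self.g3 = g3_partition(self.s, self.params)
        self.f = (
            math.inf if n_inf else -(self.g1_total + self.g2 + self.g3)
        )

    def _g2_of_hist(self, hist: np.ndarray) -> float:
        if not self.params.g2_enabled:
            return 0.0
        counts = hist[2 : self.params.N + 1]
        n_ge2 = counts.sum()
        if n_ge2 > 0:
            diff = counts / n_ge2 - self._psi
        else:
            diff = -self._psi
        return float(-(diff * diff * self._i2s).sum())

    # -- queries --

    def inv_rank_sq(self, u: str) -> np.ndarray:
        """Proposal weights 1/i^2 aligned with net.neighbor_rank(u), cached."""
        arr = self._inv_rank_sq.get(u)
        if arr is None:
            d = self.net.degree(u)
            arr = 1.0 / (np.arange(1, d + 1, dtype=float) ** 2)
            self._inv_rank_sq[u] = arr
        return arr

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_sets(self, min_size: int = 1) -> list[frozenset[str]]:
        """The partition as frozensets, optionally dropping small clusters."""
        return [frozenset(c) for c in self.clusters.values() if len(c) >= min_size]

    def check_valid(self) -> None:
        """Assert partition invariants (cover, disjointness, cache coherence)."""
        seen: set[str] = set()
        for cid, c in self.clusters.items():
            assert c, f"cluster {cid} empty"
            assert not (c & seen), "clusters overlap"
            seen |= c
        assert seen == set(self.net.proteins), "partition does not cover V"
        fresh = total_score(self.cluster_sets(), self.net, self.params)
        if math.isfinite(self.f):
            assert abs(fresh - self.f) <= 1e-9, f"cached f {self.f} != fresh {fresh}"
        else:
            assert fresh == self.f

    # -- move evaluation and application --

    def score_delta(self, move: Move) -> float:
        """f(C') - f(C) for a single-protein relocation, touching only the
        two affected clusters, at most four histogram bins, and the s shift."""
        u, src, dst = move.u, move.source, move.destination
        if u not in self.clusters.get(src, ()):
            raise ValueError(f"protein {u!r} is not in cluster {src}")
        if dst == src:
            return 0.0
        if not math.isfinite(self.f):
            # from an infinite state, never subtract infinities: recompute C'
            moved: list[set[str]] = []
            for cid, c in self.clusters.items():
                cc = set(c) - {u}
                if cid == dst:
                    cc.add(u)
                if cc:
                    moved.append(cc)
            if dst == NEW_SINGLETON:
                moved.append({u})
            f_new = total_score(moved, self.net, self.params)
            return f_new - self.f if math.isfinite(f_new) else math.nan
        k = len(self.clusters[src])
        mw_src = self.member_w[src]
        mc_src = self.member_cnt[src]
        row_u = self.net.adj.get(u, {})

        # g1 of the source residue
        if k == 1:
            g1_src_new = None  # cluster disappears
        elif k == 2:
            g1_src_new = 0.0
        else:
            total = 0.0
            for v in self.clusters[src]:
                if v == u:
                    continue
                if v in row_u:
                    if mc_src[v] == 1:
                        return math.inf  # residue member left isolated
                    total += mw_src[v] - row_u[v]
                else:
                    if mc_src[v] == 0:
                        return math.inf
                    total += mw_src[v]
            g1_src_new = (total / 2.0) / math.sqrt(k - 1)

        # g1 of the destination with u added
        if dst == NEW_SINGLETON:
            g1_dst_old = 0.0
            g1_dst_new = 0.0
            m = 0
        else:
            dest_set = self.clusters[dst]
            m = len(dest_set)
            if m + 1 > self.params.N:
                return math.inf
            mw_dst = self.member_w[dst]
            su = 0.0
            cnt_u = 0
            for v in dest_set:
                wuv = row_u.get(v)
                if wuv is not None:
                    su += wuv
                    cnt_u += 1
            if cnt_u == 0:
                return math.inf  # u would be isolated in its new cluster
            total = sum(mw_dst.values()) + 2.0 * su
            g1_dst_new = (total / 2.0) / math.sqrt(m + 1)
            g1_dst_old = self.g1_terms[dst]

        d_g1 = g1_dst_new - g1_dst_old
        if g1_src_new is not None:
            d_g1 += g1_src_new - self.g1_terms[src]
        else:
            d_g1 -= self.g1_terms[src]

        # histogram / s updates
        d_s = (
            (k - 1 if k - 1 >= 2 else 0) - (k if k >= 2 else 0)
            + (m + 1 if m + 1 >= 2 else 0) - (m if m >= 2 else 0)
        )
        if self.params.g2_enabled:
            hist = self.size_hist.copy()
            hist[k] -= 1
            if k > 1:
                hist[k - 1] += 1
            if dst == NEW_SINGLETON:
                hist[1] += 1
            else:
                hist[m] -= 1
                hist[m + 1] += 1
            d_g2 = self._g2_of_hist(hist) - self.g2
        else:
            d_g2 = 0.0
        d_g3 = g3_partition(self.s + d_s, self.params) - self.g3
        return -(d_g1 + d_g2 + d_g3)

    def apply_move(self, move: Move) -> None:
        """Commit a finite-delta move, updating all caches incrementally."""
        u, src, dst = move.u, move.source, move.destination
        if dst == src:
            return
        row_u = self.net.adj.get(u, {})
        src_set = self.clusters[src]
        k = len(src_set)
        m_dst = 0 if dst == NEW_SINGLETON else len(self.clusters[dst])
        # remove u from source
        src_set.discard(u)
        mw_src = self.member_w[src]
        mc_src = self.member_cnt[src]
        del mw_src[u]
        del mc_src[u]
        for v in src_set:
            wuv = row_u.get(v)
            if wuv is not None:
                mc_src[v] -= 1
                # kill float drift: a member with no partners has exactly 0
                mw_src[v] = mw_src[v] - wuv if mc_src[v] else 0.0
        self.size_hist[k] -= 1
        if k > 1:
            self.size_hist[k - 1] += 1
            old = self.g1_terms[src]
            new = self._g1_from_mw(mw_src, mc_src)
            self.g1_terms[src] = new
            self.g1_total += new - old
        else:
            self.g1_total -= self.g1_terms.pop(src)
            del self.clusters[src]
            del self.member_w[src]
            del self.member_cnt[src]
        # add u to destination
        if dst == NEW_SINGLETON:
            cid = self._next_cid
            self._next_cid += 1
            self.clusters[cid] = {u}
            self.member_w[cid] = {u: 0.0}
            self.member_cnt[cid] = {u: 0}
            self.g1_terms[cid] = 0.0
            self.membership[u] = cid
            self.size_hist[1] += 1
        else:
            dest_set = self.clusters[dst]
            m = len(dest_set)
            mw_dst = self.member_w[dst]
            mc_dst = self.member_cnt[dst]
            su = 0.0
            cnt_u = 0
            for v in dest_set:
                wuv = row_u.get(v)
                if wuv is not None:
                    mw_dst[v] += wuv
                    mc_dst[v] += 1
                    su += wuv
                    cnt_u += 1
            mw_dst[u] = su
            mc_dst[u] = cnt_u
            dest_set.add(u)
            self.membership[u] = dst
            self.size_hist[m] -= 1
            self.size_hist[m + 1] += 1
            old = self.g1_terms[dst]
            new = self._g1_from_mw(mw_dst, mc_dst)
            self.g1_terms[dst] = new
            self.g1_total += new - old
        # totals (s updated by the same bin arithmetic used in score_delta)
        self.s += (
            (k - 1 if k - 1 >= 2 else 0) - (k if k >= 2 else 0)
            + (m_dst + 1 if m_dst + 1 >= 2 else 0) - (m_dst if m_dst >= 2 else 0)
        )
        self.g2 = self._g2_of_hist(self.size_hist)
        self.g3 = g3_partition(self.s, self.params)
        self.f = -(self.g1_total + self.g2 + self.g3)


def total_score(
    clusters: list[frozenset[str]] | list[set[str]],
    net: WeightedNetwork,
    params: ScoreParams,
) -> float:
    """f(C) recomputed from scratch; +inf iff any cluster has g1 = -inf."""
    g1 = 0.0
    for c in clusters:
        term = g1_cluster(c, net, params.N)
        if term == -math.inf:
            return math.inf
        g1 += term
    hist = np.zeros(params.N + 2, dtype=float)
    s = 0.0
    for c in clusters:
        k = len(c)
        hist[min(k, params.N + 1)] += 1
        if k >= 2:
            s += k
    return -(g1 + g2_partition(hist, params) + g3_partition(s, params))
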