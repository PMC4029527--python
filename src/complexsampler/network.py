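"""Weighted PPI network and complex-catalog I/O.

The network file dialect is the 3-column whitespace/tab-separated table used
by weighted interaction compendia: ``proteinA proteinB weight`` per line,
``#`` comments ignored.  Weights are positive reals encoding interaction
reliability; self-interactions are dropped on input and an absent pair has
implicit weight 0.

Complex catalogs (gold standards and predicted cluster files alike) are one
protein set per line, tab/whitespace separated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "ComplexCatalog",
    "NetworkParseError",
    "read_weighted_network",
    "normalize_weights",
    "shuffle_network",
    "read_complexes",
    "write_clusters",
]


class NetworkParseError(ValueError):
    """Raised when a network or catalog file is malformed."""


def _pair(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) orientation of an unordered protein pair."""
    return (u, v) if u <= v else (v, u)


class WeightedNetwork:
    """Undirected protein-protein interaction graph with positive weights.

    Parameters
    ----------
    edges
        Mapping (or iterable of pairs) from an unordered protein pair to a
        strictly positive weight.  Self-pairs are rejected.
    extra_proteins
        Proteins that belong to the vertex set even if they have no edge
        (degree-zero nodes are legal and end up as permanent singletons).

    Attributes
    ----------
    proteins : frozenset[str]
        The vertex set V.
    adj : dict[str, dict[str, float]]
        Symmetric adjacency: ``adj[u][v]`` is w({u, v}).
    """

    __slots__ = ("proteins", "adj", "_edges", "_rank_cache")

    def __init__(
        self,
        edges: Mapping[tuple[str, str], float] | Iterable[tuple[tuple[str, str], float]],
        extra_proteins: Iterable[str] = (),
    ) -> None:
        items = edges.items() if isinstance(edges, Mapping) else edges
        self._edges: dict[tuple[str, str], float] = {}
        self.adj: dict[str, dict[str, float]] = {}
        for (u, v), w in items:
            if u == v:
                raise NetworkParseError(f"self-pair {{{u},{u}}} is not allowed")
            w = float(w)
            if not w > 0:
                raise NetworkParseError(f"non-positive weight {w!r} for pair ({u}, {v})")
            self._edges[_pair(u, v)] = w
        for (u, v), w in self._edges.items():
            self.adj.setdefault(u, {})[v] = w
            self.adj.setdefault(v, {})[u] = w
        prots = set(self.adj)
        prots.update(extra_proteins)
        self.proteins = frozenset(prots)
        self._rank_cache: dict[str, tuple[str, ...]] = {}

    # -- basic queries ----------------------------------------------------

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        """Weights keyed by canonically ordered pair (read-only view by convention)."""
        return self._edges

    def weight(self, u: str, v: str) -> float:
        """w({u, v}); 0 for absent pairs and for u == v."""
        return self.adj.get(u, {}).get(v, 0.0)

    def degree(self, u: str) -> int:
        return len(self.adj.get(u, ()))

    def neighbor_rank(self, u: str) -> tuple[str, ...]:
        """Interaction partners of ``u`` sorted by decreasing weight.

        Ties are broken by protein identifier ascending so that the rank ``i``
        entering the proposal weight 1/i^2 is deterministic.
        """
        cached = self._rank_cache.get(u)
        if cached is None:
            nbrs = self.adj.get(u, {})
            cached = tuple(sorted(nbrs, key=lambda v: (-nbrs[v], v)))
            self._rank_cache[u] = cached
        return cached

    def max_weight_edge(self) -> tuple[tuple[str, str], float]:
        """The maximum-weight edge; ties broken by lexicographic pair order."""
        if not self._edges:
            raise NetworkParseError("network has no edges")
        best = min(self._edges.items(), key=lambda kv: (-kv[1], kv[0]))
        return best

    def __len__(self) -> int:
        return len(self.proteins)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"WeightedNetwork(|V|={len(self.proteins)}, |E|={len(self._edges)})"


@dataclass
class ComplexCatalog:
    """A list of known (or predicted) protein complexes, each of size >= 2."""

    complexes: list[frozenset[str]]
    name: str = ""

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        for c in self.complexes:
            if len(c) < 2:
                raise ValueError(f"complex {set(c)!r} has fewer than 2 members")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    @property
    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return frozenset(out)


# -- readers / writers ----------------------------------------------------


def _parse_rows(stream: IO[str]) -> list[tuple[str, str, float]]:
    rows: list[tuple[str, str, float]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise NetworkParseError(
                f"line {lineno}: expected 3 whitespace-separated fields, got {len(fields)}"
            )
        u, v = fields[0], fields[1]
        try:
            w = float(fields[2])
        except ValueError as exc:
            raise NetworkParseError(f"line {lineno}: weight {fields[2]!r} is not a number") from exc
        if not np.isfinite(w) or w <= 0:
            raise NetworkParseError(f"line {lineno}: weight must be a positive real, got {w}")
        rows.append((u, v, w))
    return rows


def _network_from_rows(
    rows: list[tuple[str, str, float]], drop_self: bool = True
) -> WeightedNetwork:
    edges: dict[tuple[str, str], float] = {}
    extra: set[str] = set()
    n_dup = n_self = 0
    for u, v, w in rows:
        if u == v:
            if not drop_self:
                raise NetworkParseError(f"self-interaction {u}-{u} present and drop_self is off")
            n_self += 1
            extra.add(u)  # a protein seen only in self-rows still belongs to V
            continue
        key = _pair(u, v)
        if key in edges:
            n_dup += 1
            # reliability semantics: the strongest evidence wins
            edges[key] = max(edges[key], w)
        else:
            edges[key] = w
    if n_self:
        logger.warning("dropped %d self-interaction line(s)", n_self)
    if n_dup:
        logger.warning("resolved %d duplicate pair line(s) by keeping the maximum weight", n_dup)
    return WeightedNetwork(edges, extra_proteins=extra)


def read_weighted_network(stream: IO[str], drop_self: bool = True) -> WeightedNetwork:
    """Read a 3-column weighted interaction table.

    Duplicate pairs (in either column order) are resolved by keeping the
    maximum weight; self-interactions are dropped when ``drop_self`` is set.
    """
    rows = _parse_rows(stream)
    if not rows:
        raise NetworkParseError("empty network file")
    return _network_from_rows(rows, drop_self=drop_self)


def normalize_weights(net: WeightedNetwork) -> WeightedNetwork:
    """Divide every weight by the maximum weight, mapping weights into (0, 1].

    Rank order of every neighbor list is unchanged; exactly the maximal
    edge(s) attain weight 1.0.
    """
    if not net.edges:
        raise NetworkParseError("cannot normalize an edgeless network")
    wmax = max(net.edges.values())
    scaled = {pair: w / wmax for pair, w in net.edges.items()}
    return WeightedNetwork(scaled, extra_proteins=net.proteins)


def shuffle_network(net: WeightedNetwork, seed: int) -> WeightedNetwork:
    """Randomization control: independently permute the three file columns.

    The original edge table is laid out as three columns (interactor,
    interactor, weight); each column is permuted independently and the result
    is re-read through the normal pipeline, so self-pairs produced by the
    permutation are dropped and duplicate pairs keep the maximum weight.
    Deterministic given ``seed``.
    """
    if not net.edges:
        raise NetworkParseError("cannot shuffle an edgeless network")
    rng = np.random.default_rng(seed)
    pairs = sorted(net.edges)
    col1 = [p[0] for p in pairs]
    col2 = [p[1] for p in pairs]
    col3 = [net.edges[p] for p in pairs]
    col1 = [col1[i] for i in rng.permutation(len(col1))]
    col2 = [col2[i] for i in rng.permutation(len(col2))]
    col3 = [col3[i] for i in rng.permutation(len(col3))]
    rows = list(zip(col1, col2, col3))
    return _network_from_rows(rows, drop_self=True)


def read_complexes(stream: IO[str], name: str = "") -> ComplexCatalog:
    """Read a catalog file: one complex per line, whitespace-separated members.

    Lines with fewer than two distinct identifiers are skipped with a warning.
    """
    complexes: list[frozenset[str]] = []
    n_skipped = 0
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        members = frozenset(line.split())
        if len(members) < 2:
            n_skipped += 1
            continue
        complexes.append(members)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} line(s) with fewer than 2 distinct proteins")
    if not complexes:
        raise NetworkParseError("catalog is empty after filtering")
    return ComplexCatalog(complexes, name=name)


def write_clusters(clusters: Iterable[frozenset[str]], stream: IO[str]) -> None:
    """Write clusters one per line, tab-separated, in a deterministic order.

    Clusters are sorted by size descending then lexicographically by their
    sorted member tuple; members are sorted within a line.  The output
    round-trips through :func:`read_complexes`.
    """
    rows = sorted((tuple(sorted(c)) for c in clusters), key=lambda t: (-len(t), t))
    for row in rows:
        stream.write("\t".join(row) + "\n")
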