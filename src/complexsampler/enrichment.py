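"""Hypergeometric over-representation analysis of predicted clusters.

Given a universe V of proteins, a term annotating the subset M, and a
cluster c containing b annotated proteins, the enrichment p-value is the
hypergeometric upper tail

    p = P(X >= b),  X ~ Hypergeometric(|V|, |M|, |c|)

i.e. the probability that a random |c|-subset of V contains at least b
members of M.  Per cluster, p-values are Bonferroni-corrected by the number
of terms with non-zero overlap, and a cluster is significant for a term
when the corrected p-value falls below the cutoff (default 0.01).

Annotations are supplied pre-propagated as flat term -> protein sets
(2-column TSV); no ontology-graph handling is done here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping

from scipy.stats import hypergeom

from .evaluation import DEFAULT_ETA, overlap_ratio
from .network import ComplexCatalog

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "read_annotations",
    "hypergeom_pvalue",
    "cluster_enrichment",
    "is_significant",
    "extended_precision",
]


@dataclass
class AnnotationMap:
    """Flat term -> protein-set annotations over a fixed protein universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(m) for t, m in self.terms.items()}
        self.universe = frozenset(self.universe)
        for t, m in self.terms.items():
            if not m <= self.universe:
                raise ValueError(f"term {t!r} annotates proteins outside the universe")


@dataclass(frozen=True)
class EnrichmentResult:
    """One (cluster, term) over-representation test."""

    term: str
    b: int  # annotated members of the cluster
    m: int  # |M|, annotated proteins in the universe
    csize: int
    vsize: int
    p_raw: float
    p_corrected: float
    significant: bool


def read_annotations(stream: IO[str], universe: Iterable[str]) -> AnnotationMap:
    """Read 2-column `term protein` TSV into an AnnotationMap.

    Pairs whose protein is outside the universe are ignored.
    """
    universe = frozenset(universe)
    terms: dict[str, set[str]] = {}
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"annotation line needs 2 fields: {line!r}")
        term, protein = fields[0], fields[1]
        if protein in universe:
            terms.setdefault(term, set()).add(protein)
    return AnnotationMap({t: frozenset(m) for t, m in terms.items()}, universe)


def hypergeom_pvalue(b: int, m: int, csize: int, vsize: int) -> float:
    """P(X >= b) for X ~ Hypergeometric(vsize, m, csize); b = 0 gives exactly 1."""
    if b < 0 or m < 0 or csize < 0:
        raise ValueError("counts must be non-negative")
    if b > min(m, csize) or m > vsize or csize > vsize:
        raise ValueError(f"inconsistent counts b={b}, m={m}, c={csize}, v={vsize}")
    if b == 0:
        return 1.0
    return float(hypergeom.sf(b - 1, vsize, m, csize))


def cluster_enrichment(
    cluster: frozenset[str] | set[str],
    ann: AnnotationMap,
    cutoff: float = 0.01,
) -> list[EnrichmentResult]:
    """Test a cluster against every term it overlaps; Bonferroni per cluster.

    The correction family is the number of terms with b >= 1 for this
    cluster.  Results are sorted by corrected p-value ascending.
    """
    c = frozenset(cluster)
    if not c <= ann.universe:
        raise ValueError("cluster contains proteins outside the annotation universe")
    hits = [(t, len(c & mem), len(mem)) for t, mem in ann.terms.items() if c & mem]
    n_tested = len(hits)
    out = []
    for term, b, m in hits:
        p = hypergeom_pvalue(b, m, len(c), len(ann.universe))
        p_corr = min(1.0, p * n_tested)
        out.append(
            EnrichmentResult(
                term=term,
                b=b,
                m=m,
                csize=len(c),
                vsize=len(ann.universe),
                p_raw=p,
                p_corrected=p_corr,
                significant=p_corr < cutoff,
            )
        )
    out.sort(key=lambda r: (r.p_corrected, r.p_raw, r.term))
    return out


def is_significant(cluster: frozenset[str], ann: AnnotationMap, cutoff: float = 0.01) -> bool:
    """Whether any term is significantly over-represented in the cluster."""
    return any(r.significant for r in cluster_enrichment(cluster, ann, cutoff))


def extended_precision(
    clusters: list[frozenset[str]],
    catalog: ComplexCatalog | Iterable[frozenset[str]],
    ann: AnnotationMap,
    eta: float = DEFAULT_ETA,
    cutoff: float = 0.01,
) -> float:
    """Precision extended by significant-but-unmatched clusters.

    (Npc + #{unmatched clusters with >= 1 significant term}) / |C|.  Counts
    clusters unmatched with any known complex but functionally coherent as
    correct, acknowledging incompleteness of complex catalogs.
    """
    cs = [frozenset(c) for c in clusters if len(c) >= 2]
    if not cs:
        raise ValueError("no predicted clusters of size >= 2")
    ks = [frozenset(k) for k in catalog]
    matched = [c for c in cs if any(overlap_ratio(c, k) >= eta for k in ks)]
    unmatched = [c for c in cs if not any(overlap_ratio(c, k) >= eta for k in ks)]
    n_sig = sum(1 for c in unmatched if is_significant(c, ann, cutoff))
    return (len(matched) + n_sig) / len(cs)
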