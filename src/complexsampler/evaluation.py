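"""Matching statistics between predicted clusters and known complexes.

Two protein sets match when their overlap ratio

    ov(s, t) = |s & t| / sqrt(|s| * |t|)   if |s & t| >= 2, else 0

reaches a threshold eta (default sqrt(0.2) ~ 0.4472).  The clip to zero
for single-protein overlaps prevents pairs of hetero-dimers from matching
by sharing one protein (1/sqrt(2*2) = 0.5 would otherwise exceed eta).

Precision counts predicted clusters matched to at least one known complex,
recall counts known complexes matched to at least one cluster; the matching
is many-to-many.  Clusters of size one are excluded from every statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .network import ComplexCatalog

__all__ = [
    "DEFAULT_ETA",
    "MatchReport",
    "geometric_overlap",
    "overlap_ratio",
    "match_counts",
    "prf",
    "size_stratified",
]

#: Default match threshold, sqrt(0.2), computed rather than a rounded literal.
DEFAULT_ETA: float = math.sqrt(0.2)


@dataclass(frozen=True)
class MatchReport:
    """Match counts and derived scores of a prediction against a catalog."""

    eta: float
    npc: int
    nkc: int
    precision: float
    recall: float
    f_measure: float
    n_clusters: int
    n_complexes: int
    n_proteins: int
    avg_size: float

    def as_dict(self) -> dict[str, float]:
        return {
            "eta": self.eta,
            "Npc": self.npc,
            "Nkc": self.nkc,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "n_clusters": self.n_clusters,
            "n_complexes": self.n_complexes,
            "n_proteins": self.n_proteins,
            "avg_size": self.avg_size,
        }


def geometric_overlap(s: frozenset[str] | set[str], t: frozenset[str] | set[str]) -> float:
    """|s & t| divided by the geometric mean of the sizes, without clipping."""
    if not s or not t:
        raise ValueError("overlap of an empty set is undefined")
    return len(set(s) & set(t)) / math.sqrt(len(s) * len(t))


def overlap_ratio(s: frozenset[str] | set[str], t: frozenset[str] | set[str]) -> float:
    """Overlap ratio with the two-protein floor: 0 unless |s & t| >= 2."""
    if not s or not t:
        raise ValueError("overlap of an empty set is undefined")
    inter = len(set(s) & set(t))
    if inter < 2:
        return 0.0
    return inter / math.sqrt(len(s) * len(t))


def _usable(clusters: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    return [frozenset(c) for c in clusters if len(c) >= 2]


def match_counts(
    clusters: Iterable[frozenset[str]],
    catalog: ComplexCatalog | Iterable[frozenset[str]],
    eta: float = DEFAULT_ETA,
) -> tuple[int, int]:
    """(Npc, Nkc): clusters matched to >= 1 complex, complexes matched to >= 1 cluster."""
    if not 0 < eta <= 1:
        raise ValueError("eta must be in (0, 1]")
    cs = _usable(clusters)
    ks = [frozenset(k) for k in catalog]
    npc = sum(1 for c in cs if any(overlap_ratio(c, k) >= eta for k in ks))
    nkc = sum(1 for k in ks if any(overlap_ratio(k, c) >= eta for c in cs))
    return npc, nkc


def _harmonic(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def prf(
    clusters: Iterable[frozenset[str]],
    catalog: ComplexCatalog | Iterable[frozenset[str]],
    eta: float = DEFAULT_ETA,
) -> MatchReport:
    """Precision, recall and F-measure of a prediction against a catalog."""
    cs = _usable(clusters)
    ks = [frozenset(k) for k in catalog]
    if not cs:
        raise ValueError("no predicted clusters of size >= 2")
    if not ks:
        raise ValueError("empty complex catalog")
    npc, nkc = match_counts(cs, ks, eta)
    precision = npc / len(cs)
    recall = nkc / len(ks)
    covered = set().union(*cs)
    return MatchReport(
        eta=eta,
        npc=npc,
        nkc=nkc,
        precision=precision,
        recall=recall,
        f_measure=_harmonic(precision, recall),
        n_clusters=len(cs),
        n_complexes=len(ks),
        n_proteins=len(covered),
        avg_size=sum(len(c) for c in cs) / len(cs),
    )


def size_stratified(
    clusters: Iterable[frozenset[str]],
    catalog: ComplexCatalog | Iterable[frozenset[str]],
    eta: float = DEFAULT_ETA,
) -> dict[str, MatchReport]:
    """Per-size-class report: precision over C|_i, recall over K|_i.

    For classes "2" and "3", C|_i (K|_i) restricts to clusters (complexes) of
    exactly size i; class ">=4" uses size four or more.  Precision of a class
    compares the restricted clusters against the full catalog, recall compares
    the full cluster list against the restricted catalog.  A class with no
    clusters yields NaN precision with a warning.
    """
    cs = _usable(clusters)
    ks = [frozenset(k) for k in catalog]
    classes: dict[str, tuple[list, list]] = {
        "2": ([c for c in cs if len(c) == 2], [k for k in ks if len(k) == 2]),
        "3": ([c for c in cs if len(c) == 3], [k for k in ks if len(k) == 3]),
        ">=4": ([c for c in cs if len(c) >= 4], [k for k in ks if len(k) >= 4]),
    }
    out: dict[str, MatchReport] = {}
    for label, (c_i, k_i) in classes.items():
        if c_i:
            npc, _ = match_counts(c_i, ks, eta)
            precision = npc / len(c_i)
        else:
            warnings.warn(f"no predicted clusters in size class {label}; precision undefined")
            npc, precision = 0, math.nan
        if k_i:
            _, nkc = match_counts(cs, k_i, eta)
            recall = nkc / len(k_i)
        else:
            nkc, recall = 0, math.nan
        if math.isnan(precision) or math.isnan(recall):
            f = math.nan
        else:
            f = _harmonic(precision, recall)
        covered = set().union(*c_i) if c_i else set()
        out[label] = MatchReport(
            eta=eta,
            npc=npc,
            nkc=nkc,
            precision=precision,
            recall=recall,
            f_measure=f,
            n_clusters=len(c_i),
            n_complexes=len(k_i),
            n_proteins=len(covered),
            avg_size=(sum(len(c) for c in c_i) / len(c_i)) if c_i else 0.0,
        )
    return out
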