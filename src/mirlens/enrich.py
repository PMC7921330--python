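"""Hypergeometric gene-set enrichment and cluster-level enrichment scoring.

Per-term significance is the upper-tail hypergeometric probability of drawing
at least the observed overlap when ``n_query`` genes are sampled without
replacement from a universe containing ``n_term`` term members; q-values are
Benjamini-Hochberg across all tested terms.  Terms are then grouped by
member-gene Jaccard similarity (greedy single linkage), and each cluster gets
the enrichment score -log10(geometric mean of member p-values), the convention
of functional-annotation clustering tools; clusters scoring above 1.0 are the
reported "top" clusters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import AnnotationSet, normalize_id

__all__ = ["EnrichmentTerm", "EnrichmentCluster", "term_enrichment", "cluster_terms"]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentTerm:
    term_id: str
    term_name: str
    n_universe: int
    n_term: int
    n_query: int
    n_overlap: int
    p: float
    q: float = float("nan")
    overlap_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_term, self.n_query):
            raise ValueError("overlap exceeds term or query size")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"hypergeometric p out of (0,1]: {self.p!r}")


@dataclass
class EnrichmentCluster:
    """A group of similar terms scored by -log10 geometric-mean p."""

    terms: tuple[EnrichmentTerm, ...]

    @property
    def enrichment_score(self) -> float:
        return -sum(math.log10(t.p) for t in self.terms) / len(self.terms)

    @property
    def member_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.overlap_genes
        return frozenset(out)

    @property
    def best_term(self) -> EnrichmentTerm:
        return min(self.terms, key=lambda t: (t.p, t.term_id))


def term_enrichment(query: Iterable[str], annotation: AnnotationSet) -> list[EnrichmentTerm]:
    """Upper-tail hypergeometric enrichment of a gene set against every term.

    Query genes outside the annotation universe are dropped with a warning;
    matching is case-insensitive.  Results are sorted by ascending p (ties by
    term id) with BH q-values computed across all tested terms.
    """
    if not annotation.universe:
        raise ValueError("annotation universe is empty")
    uni_norm = {normalize_id(g): g for g in annotation.universe}
    query_norm: set[str] = set()
    dropped: list[str] = []
    for gene in query:
        key = normalize_id(gene)
        if key in uni_norm:
            query_norm.add(key)
        else:
            dropped.append(gene)
    if dropped:
        logger.warning(
            "%d query gene(s) not in annotation universe; dropped (e.g. %s)",
            len(dropped),
            ", ".join(dropped[:5]),
        )
    m = len(annotation.universe)
    n_query = len(query_norm)
    results: list[EnrichmentTerm] = []
    for term_id in sorted(annotation.terms):
        name, members = annotation.terms[term_id]
        members_norm = {normalize_id(g) for g in members}
        overlap = query_norm & members_norm
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(M=universe, n=term size, N=query size)
        p = float(hypergeom.sf(k - 1, m, len(members), n_query))
        p = min(max(p, math.ulp(0.0)), 1.0)
        results.append(
            EnrichmentTerm(
                term_id=term_id,
                term_name=name,
                n_universe=m,
                n_term=len(members),
                n_query=n_query,
                n_overlap=k,
                p=p,
                overlap_genes=frozenset(uni_norm[g] for g in overlap),
            )
        )
    if results:
        qvals = multipletests([t.p for t in results], method="fdr_bh")[1]
        for term, q in zip(results, qvals):
            term.q = float(q)
    results.sort(key=lambda t: (t.p, t.term_id))
    return results


def cluster_terms(
    terms: Sequence[EnrichmentTerm],
    similarity_threshold: float = 0.5,
    annotation: AnnotationSet | None = None,
) -> list[EnrichmentCluster]:
    """Greedy single-linkage clustering of terms by member-gene Jaccard similarity.

    Similarity is computed on full term memberships when ``annotation`` is
    given, else on the overlap-gene sets carried by the terms.  Two terms land
    in one cluster whenever a chain of pairwise similarities >= threshold
    connects them; clusters are returned sorted by descending enrichment
    score (ties by first term id).
    """
    if not terms:
        return []

    def genes_of(t: EnrichmentTerm) -> frozenset[str]:
        if annotation is not None and t.term_id in annotation.terms:
            return frozenset(normalize_id(g) for g in annotation.members(t.term_id))
        return frozenset(normalize_id(g) for g in t.overlap_genes)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(terms)))
    sets = [genes_of(t) for t in terms]
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            union = sets[i] | sets[j]
            jac = len(sets[i] & sets[j]) / len(union) if union else 1.0
            if jac >= similarity_threshold:
                graph.add_edge(i, j)
    clusters = [
        EnrichmentCluster(terms=tuple(sorted((terms[i] for i in comp), key=lambda t: t.term_id)))
        for comp in nx.connected_components(graph)
    ]
    clusters.sort(key=lambda c: (-c.enrichment_score, c.terms[0].term_id))
    return clusters


def top_clusters(
    clusters: Sequence[EnrichmentCluster],
    score_floor: float = 1.0,
    alpha: float = 0.05,
) -> list[EnrichmentCluster]:
    """Clusters with enrichment score > floor containing a term at p <= alpha."""
    return [
        c
        for c in clusters
        if c.enrichment_score > score_floor and any(t.p <= alpha for t in c.terms)
    ]
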