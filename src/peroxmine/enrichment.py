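"""GO term enrichment with true-path propagation and redundancy reduction.

Enrichment is the one-sided hypergeometric (Fisher) test of a foreground
protein set against a background universe, per GO term, after annotations
are propagated to all ancestor terms (true-path rule). Benjamini-Hochberg
q-values are computed within each namespace.

Redundancy reduction is a deterministic replacement for semantic-similarity
pruning of enriched term lists: among significant terms, a term is dropped
when a significant ancestor or descendant with a smaller p-value annotates
an almost identical foreground set (Jaccard >= J, default 0.7); p-value
ties are resolved toward the more specific (deeper) term.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import obonet
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class GOTermResult:
    """Hypergeometric enrichment result for one GO term."""

    term: str
    namespace: str
    k: int  # foreground hits
    K: int  # foreground size
    n: int  # background hits
    N: int  # background size
    p: float
    q: float | None = None
    kept_after_reduction: bool = False
    foreground_genes: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# inputs

def load_ontology(path: str | Path) -> nx.MultiDiGraph:
    """Read an OBO 1.2 ontology into a graph with child -> parent edges."""
    graph = obonet.read_obo(str(path))
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("ontology graph contains a cycle")
    return graph


def read_gaf(path: str | Path) -> dict[str, set[str]]:
    """Read a GAF 2.x annotation file into a term -> gene-set map.

    ``NOT``-qualified annotations are skipped. Comment lines start with
    ``!``.
    """
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise ValueError(f"malformed GAF line: {line!r}")
            gene, qualifier, term = cols[1], cols[3], cols[4]
            if "NOT" in qualifier.split("|"):
                continue
            annotations.setdefault(term, set()).add(gene)
    return annotations


def read_term_gene_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column (term_id, gene_id) TSV into a term -> gene-set map."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        reader = csv.reader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        )
        header = next(reader, None)
        if header is None:
            raise ValueError(f"empty annotation table: {path}")
        for row in reader:
            if len(row) < 2:
                continue
            annotations.setdefault(row[0], set()).add(row[1])
    return annotations


# ---------------------------------------------------------------------------
# enrichment

def _ancestors(graph: nx.MultiDiGraph, term: str) -> set[str]:
    # obonet edges point child -> parent, so graph-descendants are ancestors
    return nx.descendants(graph, term) if term in graph else set()


def propagate_annotations(
    annotations: Mapping[str, set[str]], graph: nx.MultiDiGraph
) -> dict[str, set[str]]:
    """Apply the true-path rule: a gene annotated to a term is annotated to
    every ancestor of that term."""
    propagated: dict[str, set[str]] = {}
    for term, genes in annotations.items():
        propagated.setdefault(term, set()).update(genes)
        for anc in _ancestors(graph, term):
            propagated.setdefault(anc, set()).update(genes)
    return propagated


def enrich(
    foreground: set[str],
    background: set[str],
    annotations: Mapping[str, set[str]],
    graph: nx.MultiDiGraph,
    propagate: bool = True,
) -> list[GOTermResult]:
    """One-sided hypergeometric enrichment per GO term with >= 1 foreground hit.

    ``p = P(X >= k)`` for X hypergeometric with population ``N`` (background
    size), ``n`` successes (background genes on the term) and ``K`` draws
    (foreground size). BH q-values are assigned within each namespace.
    """
    if not foreground <= background:
        raise ValueError("foreground is not a subset of background")
    counts = propagate_annotations(annotations, graph) if propagate else dict(annotations)
    N = len(background)
    K = len(foreground)
    results: list[GOTermResult] = []
    for term in sorted(counts):
        genes_bg = counts[term] & background
        genes_fg = counts[term] & foreground
        k, n = len(genes_fg), len(genes_bg)
        if k < 1:
            continue
        p = float(hypergeom.sf(k - 1, N, n, K))
        namespace = "biological_process"
        if term in graph and "namespace" in graph.nodes[term]:
            namespace = graph.nodes[term]["namespace"]
        results.append(
            GOTermResult(
                term=term,
                namespace=namespace,
                k=k,
                K=K,
                n=n,
                N=N,
                p=min(1.0, p),
                foreground_genes=frozenset(genes_fg),
            )
        )
    for ns in sorted({r.namespace for r in results}):
        ns_results = [r for r in results if r.namespace == ns]
        qvals = multipletests([r.p for r in ns_results], method="fdr_bh")[1]
        for r, q in zip(ns_results, qvals):
            r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# redundancy reduction

def _depths(graph: nx.MultiDiGraph, terms: Sequence[str]) -> dict[str, int]:
    """Longest is_a/part_of path length from each term up to a root."""
    memo: dict[str, int] = {}

    def depth(term: str) -> int:
        if term in memo:
            return memo[term]
        parents = list(graph.successors(term)) if term in graph else []
        memo[term] = 0 if not parents else 1 + max(depth(p) for p in parents)
        return memo[term]

    return {t: depth(t) for t in terms}


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def reduce_redundancy(
    results: Sequence[GOTermResult],
    graph: nx.MultiDiGraph,
    alpha: float = 0.05,
    jaccard_threshold: float = 0.7,
) -> list[GOTermResult]:
    """Flag redundant significant terms (in place; returns the list).

    A significant term (q <= alpha) is dropped when a significant ancestor
    or descendant with smaller p exists whose foreground gene set overlaps
    it with Jaccard >= ``jaccard_threshold``; equal p-values resolve toward
    the deeper (more specific) term. ``kept_after_reduction`` marks terms
    that are significant and survive.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("ontology graph contains a cycle")
    significant = [r for r in results if r.q is not None and r.q <= alpha]
    depths = _depths(graph, [r.term for r in significant])
    anc = {r.term: _ancestors(graph, r.term) for r in significant}

    for r in results:
        r.kept_after_reduction = False
    for r in significant:
        dropped = False
        for other in significant:
            if other.term == r.term:
                continue
            related = other.term in anc[r.term] or r.term in anc[other.term]
            if not related:
                continue
            if _jaccard(other.foreground_genes, r.foreground_genes) < jaccard_threshold:
                continue
            if other.p < r.p or (
                other.p == r.p and depths[other.term] > depths[r.term]
            ):
                dropped = True
                break
        r.kept_after_reduction = not dropped
    return list(results)


def write_enrichment_table(results: Sequence[GOTermResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "term\tnamespace\tk\tK\tn\tN\tp\tq\tkept_after_reduction\n"
        )
        for r in sorted(results, key=lambda r: (r.namespace, r.p, r.term)):
            fh.write(
                f"{r.term}\t{r.namespace}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p:.6g}\t{'' if r.q is None else format(r.q, '.6g')}\t"
                f"{int(r.kept_after_reduction)}\n"
            )
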