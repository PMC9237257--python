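"""Hypergeometric term enrichment and level-2 ontology binning.

For a DEG list of size ``n`` drawn from a background of ``N`` genes of which
``K`` are annotated to a term, the enrichment p-value is the upper tail of
the hypergeometric distribution,

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n),

adjusted by the conservative Bonferroni correction (m = number of tested
terms; terms annotating no background gene are excluded from testing and
from m).  Both the Bonferroni-corrected call at padj <= 0.05 and the raw
p <= 0.05 call are reported, since either threshold is used in practice
depending on the analysis.

Level-2 binning places the ontology root at level 0, so level-2 terms sit
two parent edges below the root; a gene contributes (once) to every level-2
ancestor of every term it is annotated to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationMap",
    "hypergeometric_enrichment",
    "level2_classify",
]


@dataclass
class AnnotationMap:
    """Term -> gene-set annotation with optional ontology parent edges.

    ``terms`` maps term id to a set of gene ids; ``meta`` (term_id, name,
    namespace) and ``edges`` (child, parent) are optional.  Namespaces
    follow the BP/CC/MF/pathway convention.
    """

    terms: dict[str, set[str]]
    meta: pd.DataFrame | None = None
    edges: pd.DataFrame | None = None

    @classmethod
    def read_tsv(cls, annotations_path, edges_path=None) -> "AnnotationMap":
        """Read annotations.tsv (term_id, namespace, gene_id) and, optionally,
        ontology_edges.tsv (child, parent)."""
        ann = pd.read_csv(annotations_path, sep="\t", comment="#")
        terms: dict[str, set[str]] = {}
        for term_id, sub in ann.groupby("term_id"):
            terms[str(term_id)] = set(sub["gene_id"].astype(str))
        meta = ann[["term_id"] + [c for c in ("name", "namespace") if c in ann.columns]]
        meta = meta.drop_duplicates("term_id").reset_index(drop=True)
        edges = None
        if edges_path is not None:
            edges = pd.read_csv(edges_path, sep="\t", comment="#")
        return cls(terms=terms, meta=meta, edges=edges)

    def namespace_of(self, term_id: str) -> str:
        if self.meta is None or "namespace" not in self.meta.columns:
            return ""
        row = self.meta.loc[self.meta["term_id"] == term_id, "namespace"]
        return str(row.iloc[0]) if len(row) else ""


def hypergeometric_enrichment(
    deg_genes: Iterable[str],
    background_genes: Iterable[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with Bonferroni correction.

    Returns one row per tested term (K >= 1), sorted by adjusted p then raw
    p, with columns term_id, namespace, k, n, K, N, p, padj, significant
    (padj <= alpha) and significant_raw (p <= alpha).
    """
    degs = set(deg_genes)
    background = set(background_genes)
    stray = degs - background
    if stray:
        preview = ", ".join(sorted(stray)[:5])
        raise ValueError(
            f"{len(stray)} DEG(s) not in the background, e.g. {preview}"
        )
    n = len(degs)
    N = len(background)
    rows = []
    for term_id, term_genes in annotation.terms.items():
        K = len(term_genes & background)
        if K < 1:
            continue  # untestable, excluded from m
        k = len(term_genes & degs)
        # survival function at k-1 gives P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(p, 0.0)) if k > 0 else 1.0
        rows.append(
            {
                "term_id": term_id,
                "namespace": annotation.namespace_of(term_id),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "namespace", "k", "n", "K", "N", "p"]
    )
    m = len(result)
    result["padj"] = (result["p"] * m).clip(upper=1.0) if m else result.get("p")
    result["significant"] = result["padj"] <= alpha
    result["significant_raw"] = result["p"] <= alpha
    return result.sort_values(["padj", "p", "term_id"], ignore_index=True)


def _term_levels(edges: pd.DataFrame) -> tuple[nx.DiGraph, dict[str, int]]:
    """Directed parent->child graph and per-term distance from its root."""
    graph = nx.DiGraph()
    for row in edges.itertuples():
        graph.add_edge(row.parent, row.child)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology edge table contains a cycle: {cycle}")
    roots = [t for t in graph.nodes if graph.in_degree(t) == 0]
    levels: dict[str, int] = {}
    for root in roots:
        for term, dist in nx.single_source_shortest_path_length(graph, root).items():
            # a term reachable from several roots keeps its smallest depth
            levels[term] = min(levels.get(term, dist), dist)
    return graph, levels


def level2_classify(
    genes_by_direction: Mapping[str, Iterable[str]],
    annotation: AnnotationMap,
) -> pd.DataFrame:
    """Bin annotated genes into level-2 ontology terms, split by direction.

    ``genes_by_direction`` maps direction labels (e.g. "up"/"down") to gene
    collections.  Terms without a path to any root are skipped with a
    warning.  Returns columns term_id, namespace, plus one count column per
    direction; a gene counts at most once per level-2 term.
    """
    if annotation.edges is None or not len(annotation.edges):
        raise ValueError("level-2 classification needs an ontology edge table")
    graph, levels = _term_levels(annotation.edges)

    # level-2 ancestors (possibly the term itself) for every annotated term
    level2_of: dict[str, set[str]] = {}
    orphans = []
    for term_id in annotation.terms:
        if term_id not in levels:
            orphans.append(term_id)
            continue
        anc = {term_id} | nx.ancestors(graph, term_id)
        level2_of[term_id] = {t for t in anc if levels.get(t) == 2}
    if orphans:
        warnings.warn(
            f"{len(orphans)} term(s) with no path to an ontology root skipped",
            stacklevel=2,
        )

    gene_terms: dict[str, set[str]] = {}
    for term_id, term_genes in annotation.terms.items():
        for g in term_genes:
            gene_terms.setdefault(g, set()).add(term_id)

    directions = list(genes_by_direction)
    counts: dict[str, dict[str, int]] = {}
    for direction in directions:
        for gene in set(genes_by_direction[direction]):
            hit_terms: set[str] = set()
            for t in gene_terms.get(gene, ()):
                hit_terms |= level2_of.get(t, set())
            for lt in hit_terms:
                counts.setdefault(lt, {d: 0 for d in directions})
                counts[lt][direction] += 1
    rows = [
        {"term_id": term, "namespace": annotation.namespace_of(term), **vals}
        for term, vals in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["term_id", "namespace", *directions])
    return frame.sort_values("term_id", ignore_index=True)
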