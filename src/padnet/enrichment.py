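"""GO term over-representation per module.

One-sided hypergeometric tail P(X >= k) with N background genes, K genes
annotated to the term (or any of its descendants, after true-path
propagation), n module genes and k overlapping genes; Bonferroni correction
over the terms tested for that module; reported terms are filtered to
ontology depth >= 4, with the namespace root at depth 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

_NAMESPACE_SHORT = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}


@dataclass
class EnrichmentRow:
    module_id: str
    term_id: str
    category: str
    depth: int
    k_overlap: int
    n_module: int
    K_annotated: int
    N_background: int
    p_raw: float
    p_adjusted: float
    term_name: str = ""


def ontology_roots(onto: nx.DiGraph) -> dict[str, str]:
    """Namespace -> root term (a term with no outgoing is_a edge)."""
    roots = onto.graph.get("roots")
    if roots:
        return dict(roots)
    found: dict[str, str] = {}
    for node in onto.nodes:
        if onto.out_degree(node) == 0:
            ns = onto.nodes[node].get("namespace", "biological_process")
            found[ns] = node
    return found


def term_depth(onto: nx.DiGraph, term: str) -> int:
    """Depth = 1 + length of the shortest is_a path to the namespace root.

    The root itself has depth 1; with multiple parents the minimum-distance
    path counts.
    """
    if term not in onto:
        raise KeyError(f"unknown term {term}")
    ns = onto.nodes[term].get("namespace", "biological_process")
    roots = ontology_roots(onto)
    root = roots.get(ns)
    if root is None:
        raise ValueError(f"no root found for namespace {ns}")
    try:
        dist = nx.shortest_path_length(onto, source=term, target=root)
    except nx.NetworkXNoPath:
        raise ValueError(f"orphan term {term}: no path to root {root}")
    return int(dist) + 1


def all_term_depths(onto: nx.DiGraph) -> dict[str, int]:
    """Depths for every term, one BFS per namespace root."""
    depths: dict[str, int] = {}
    for ns, root in ontology_roots(onto).items():
        lengths = nx.shortest_path_length(onto, target=root)
        for term, dist in lengths.items():
            if onto.nodes[term].get("namespace", "biological_process") == ns:
                depths[term] = int(dist) + 1
    return depths


def propagate_annotations(
    annotations: pd.DataFrame, onto: nx.DiGraph
) -> pd.DataFrame:
    """True-path propagation: a gene annotated to a term is annotated to all
    its is_a ancestors.  Idempotent; annotations to unknown terms are logged
    and dropped."""
    ancestors_cache: dict[str, set] = {}

    def ancestors(term: str) -> set:
        if term not in ancestors_cache:
            ancestors_cache[term] = set(nx.descendants(onto, term))  # child->parent edges
        return ancestors_cache[term]

    pairs: set[tuple[str, str]] = set()
    dropped = 0
    for row in annotations.itertuples(index=False):
        term = row.term_id
        if term not in onto:
            dropped += 1
            continue
        pairs.add((row.gene_id, term))
        for anc in ancestors(term):
            pairs.add((row.gene_id, anc))
    if dropped:
        logger.info("dropped %d annotations to unknown terms", dropped)
    return pd.DataFrame(sorted(pairs), columns=["gene_id", "term_id"])


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided over-representation tail P(X >= k), X ~ Hypergeom(N, K, n)."""
    if k > min(n, K):
        raise ValueError("overlap k cannot exceed min(n, K)")
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_module(
    module_genes: set[str] | list[str],
    annotations: pd.DataFrame,
    onto: nx.DiGraph,
    background: set[str] | list[str] | None = None,
    min_depth: int = 4,
    min_module_size: int = 10,
    module_id: str = "M1",
    ease: bool = False,
    propagated: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric GO enrichment of one module against a gene background.

    Modules below ``min_module_size`` are skipped (empty result, logged).
    ``ease`` subtracts one from the overlap before taking the tail (the
    DAVID/EASE conservative variant).  Bonferroni uses the number of terms
    with non-zero overlap in this module.  Rows with depth < ``min_depth``
    are filtered out; remaining rows are sorted by raw p.
    """
    module_genes = set(module_genes)
    if background is None:
        background = set(annotations["gene_id"])
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    if not module_genes <= background:
        raise ValueError("module genes must be a subset of the background")
    if len(module_genes) < min_module_size:
        logger.info(
            "module %s skipped: %d genes < %d", module_id, len(module_genes), min_module_size
        )
        return []
    if not propagated:
        annotations = propagate_annotations(annotations, onto)
    annotations = annotations[annotations["gene_id"].isin(background)]
    N = len(background)
    n = len(module_genes)
    depths = all_term_depths(onto)
    rows: list[EnrichmentRow] = []
    term_groups = annotations.groupby("term_id")["gene_id"]
    tested = []
    for term, genes in term_groups:
        gene_set = set(genes)
        k = len(gene_set & module_genes)
        if k < 1:
            continue
        K = len(gene_set)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_tail(k_eff, N, K, n) if k_eff >= 1 else 1.0
        ns = onto.nodes[term].get("namespace", "biological_process")
        tested.append(
            EnrichmentRow(
                module_id=module_id,
                term_id=term,
                category=_NAMESPACE_SHORT.get(ns, ns),
                depth=depths.get(term, 0),
                k_overlap=k,
                n_module=n,
                K_annotated=K,
                N_background=N,
                p_raw=p,
                p_adjusted=p,
                term_name=onto.nodes[term].get("name", ""),
            )
        )
    n_tests = len(tested)
    for row in tested:
        row.p_adjusted = min(1.0, row.p_raw * n_tests)
    rows = [r for r in tested if r.depth >= min_depth]
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module_id,
                "term_id": r.term_id,
                "category": r.category,
                "term_name": r.term_name,
                "depth": r.depth,
                "k_overlap": r.k_overlap,
                "n_module": r.n_module,
                "K_annotated": r.K_annotated,
                "N_background": r.N_background,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
            }
            for r in rows
        ],
        columns=[
            "module", "term_id", "category", "term_name", "depth", "k_overlap",
            "n_module", "K_annotated", "N_background", "p_raw", "p_adjusted",
        ],
    )
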