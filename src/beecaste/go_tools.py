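"""Minimal Gene Ontology machinery for enrichment and subgraph comparison.

Covers true-path annotation propagation, classic one-sided Fisher
enrichment of a study set against a transcriptome background (raw p-values,
no multiplicity correction, matching the p < 0.01 reporting convention),
term depth (root = level 1, shortest is_a path by default), level-k rollups
carrying the mean logFC of the genes under each term, and ancestor-closed
induced subgraphs of enriched terms. Only is_a edges are traversed.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .io_core import OntologyDag, logger


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    study_count: int
    study_size: int
    background_count: int
    background_size: int
    p_value: float


def propagate(annotations: dict[str, set[str]], dag: OntologyDag) -> dict[str, set[str]]:
    """Replace each gene's term set by its ancestor closure (terms + all
    is_a ancestors, roots included). Idempotent. Unknown term ids raise."""
    unknown = {t for terms in annotations.values() for t in terms if t not in dag.terms}
    if unknown:
        raise KeyError(f"annotation uses term(s) absent from the ontology: {sorted(unknown)[:5]}")
    cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in cache:
            cache[term] = {term} | set().union(
                *(closure(p) for p in dag.parents(term))) if dag.parents(term) else {term}
        return cache[term]

    return {g: set().union(*(closure(t) for t in terms)) if terms else set()
            for g, terms in annotations.items()}


def fisher_enrichment(study: "set[str] | list[str]", background: "set[str] | list[str]",
                      annotations: dict[str, set[str]], alpha: float = 0.01,
                      ) -> list[EnrichmentResult]:
    """Classic per-term Fisher (one-sided, greater) enrichment test.

    For each term annotating >= 1 background gene, the one-sided p is the
    hypergeometric tail P(X >= k) for drawing the study set from the
    background. Annotations should already be propagated. Results are sorted
    by ascending p; callers flag p < alpha.
    """
    study_set = set(study)
    bg_set = set(background)
    if not study_set <= bg_set:
        raise ValueError("study set is not a subset of the background")
    n_bg = len(bg_set)
    n_study = len(study_set)
    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for g in bg_set:
        for t in annotations.get(g, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in study_set:
                term_study[t] = term_study.get(t, 0) + 1
    results = []
    for t, k_bg in term_bg.items():
        k_study = term_study.get(t, 0)
        # P(X >= k_study), X ~ Hypergeom(N=n_bg, K=k_bg, n=n_study)
        p = float(stats.hypergeom.sf(k_study - 1, n_bg, k_bg, n_study))
        results.append(EnrichmentResult(
            term_id=t, name=t, study_count=k_study, study_size=n_study,
            background_count=k_bg, background_size=n_bg, p_value=min(p, 1.0)))
    results.sort(key=lambda r: (r.p_value, r.term_id))
    n_sig = sum(1 for r in results if r.p_value < alpha)
    logger.info("fisher enrichment: %d/%d terms at p < %g", n_sig, len(results), alpha)
    return results


def term_depth(dag: OntologyDag, mode: str = "shortest") -> dict[str, int]:
    """Depth of every term: root = 1; depth = 1 + length of the shortest
    (default) or longest is_a path to a root."""
    if mode not in ("shortest", "longest"):
        raise ValueError(f"unknown depth mode {mode!r}")
    kids = dag.children_map()
    depth: dict[str, int] = {}
    # BFS layers from the roots; for "longest", relax until fixpoint
    frontier = list(dag.root_ids)
    for r in frontier:
        depth[r] = 1
    if mode == "shortest":
        while frontier:
            nxt = []
            for t in frontier:
                for c in kids.get(t, ()):
                    if c not in depth:
                        depth[c] = depth[t] + 1
                        nxt.append(c)
            frontier = nxt
    else:
        # topological relaxation: process parents before children
        order = _topological(dag)
        for t in order:
            for c in kids.get(t, ()):
                cand = depth.get(t, 1) + 1
                if cand > depth.get(c, 0):
                    depth[c] = cand
    return depth


def _topological(dag: OntologyDag) -> list[str]:
    indeg = {t: len(dag.parents(t)) for t in dag.terms}
    kids = dag.children_map()
    stack = [t for t, d in indeg.items() if d == 0]
    order = []
    while stack:
        t = stack.pop()
        order.append(t)
        for c in kids.get(t, ()):
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    return order


def rollup_level(gene_logfc: dict[str, float], annotations: dict[str, set[str]],
                 dag: OntologyDag, level: int = 3, depth_mode: str = "shortest",
                 ) -> dict[str, tuple[int, float]]:
    """Summarize genes at every term of a given hierarchy level.

    For each term whose depth equals ``level``, collects the genes whose
    (propagated) annotation contains the term and reports (gene count, mean
    logFC). A gene may appear under several level-k terms.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    depths = term_depth(dag, depth_mode)
    level_terms = {t for t, d in depths.items() if d == level}
    if not level_terms:
        logger.warning("no ontology terms at level %d", level)
        return {}
    out: dict[str, tuple[int, float]] = {}
    for t in sorted(level_terms):
        fcs = [fc for g, fc in gene_logfc.items() if t in annotations.get(g, ())]
        if fcs:
            out[t] = (len(fcs), sum(fcs) / len(fcs))
    return out


def induced_subgraph(enriched: "set[str] | list[str]", dag: OntologyDag,
                     ) -> tuple[set[str], set[tuple[str, str]]]:
    """Ancestor-closed subgraph of a term set: nodes = terms plus all their
    is_a ancestors; edges = is_a edges among those nodes."""
    terms = set(enriched)
    missing = terms - set(dag.terms)
    if missing:
        raise KeyError(f"term(s) not in ontology: {sorted(missing)[:5]}")
    nodes = set(terms)
    for t in terms:
        nodes |= dag.ancestors(t)
    edges = {(c, p) for c in nodes for p in dag.parents(c) if p in nodes}
    return nodes, edges


def top_enriched(results: "list[EnrichmentResult]", k: int = 8) -> list[str]:
    """Term ids of the k smallest enrichment p-values (ties by id)."""
    return [r.term_id for r in sorted(results, key=lambda r: (r.p_value, r.term_id))[:k]]


def subgraph_to_dot(nodes: set[str], edges: "set[tuple[str, str]]",
                    dag: OntologyDag) -> str:
    lines = ["digraph go_subgraph {"]
    for n in sorted(nodes):
        name = dag.terms.get(n, (n, ""))[0]
        lines.append(f'  "{n}" [label="{name}"];')
    for c, p in sorted(edges):
        lines.append(f'  "{c}" -> "{p}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
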