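"""Over-representation analysis (ORA) of candidate gene lists.

One-sided hypergeometric (Fisher-exact, enrichment side) tests of a query
gene list against GMT gene sets, with the retention rule used by common
enrichment portals: raw p below a cutoff, a minimum overlap count, and an
enrichment factor (observed / expected overlap) above a minimum. Retained
terms are grouped by membership similarity: Cohen's kappa on the 2x2
gene-membership table, with terms linked when kappa exceeds a threshold
and clusters taken as connected components of that graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class DomainError(ValueError):
    pass


@dataclass
class EnrichmentConfig:
    p_max: float = 0.01
    min_count: int = 3
    ef_min: float = 1.5
    similarity_min: float = 0.3
    correction: str = "bh"  # none | bonferroni | bh | by
    background: str = "all_genes_in_sets"  # or "user_list"
    background_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if min(self.p_max, self.ef_min, self.similarity_min) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.correction not in {"none", "bonferroni", "bh", "by"}:
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.background not in {"all_genes_in_sets", "user_list"}:
            raise ValueError(f"unknown background mode {self.background!r}")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    K: int  # term size in background
    k: int  # overlap with query
    n: int  # query size (within background)
    N: int  # background size
    p_raw: float
    p_adjusted: float
    enrichment_factor: float
    member_genes: list[str]
    cluster_id: int = -1
    retained: bool = False


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed exactly.

    N: population (background) size, K: marked items (term genes),
    n: draws (query genes), k: observed overlap.
    """
    if not (0 <= k <= min(n, K) + 0 or k <= n):  # k may exceed min only as error
        raise DomainError("k out of range")
    if k < 0 or K > N or n > N or k > min(n, K):
        raise DomainError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    # survival function is P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(p_list: list[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    Methods: ``bonferroni`` (min(1, m*p)), ``bh`` (Benjamini-Hochberg
    step-up), ``by`` (Benjamini-Yekutieli), ``none``.
    """
    if len(p_list) == 0:
        raise DomainError("p_list is empty")
    arr = np.asarray(p_list, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    if method == "none":
        return list(arr)
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh", "by": "fdr_by"}
    if method not in key:
        raise DomainError(f"unknown adjustment method {method!r}")
    _, adjusted, _, _ = multipletests(arr, method=key[method])
    return [float(p) for p in adjusted]


def kappa_similarity(
    term_a_genes: set[str], term_b_genes: set[str], universe: set[str]
) -> float:
    """Cohen's kappa of two gene sets' membership over a gene universe."""
    if not universe:
        raise DomainError("empty universe")
    if not (term_a_genes <= universe and term_b_genes <= universe):
        raise DomainError("term genes must be subsets of the universe")
    N = len(universe)
    both = len(term_a_genes & term_b_genes)
    only_a = len(term_a_genes) - both
    only_b = len(term_b_genes) - both
    neither = N - both - only_a - only_b
    observed = (both + neither) / N
    p_a = len(term_a_genes) / N
    p_b = len(term_b_genes) / N
    expected = p_a * p_b + (1 - p_a) * (1 - p_b)
    if expected == 1.0:
        return 1.0  # degenerate: identical trivial marginals
    return (observed - expected) / (1 - expected)


def run_ora(
    query_genes: set[str] | list[str],
    gene_sets: dict[str, tuple[str, set[str]]],
    cfg: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Test a query gene list against every gene set.

    Returns one result per term with non-empty overlap, ordered by raw p
    (term id as tiebreak). Terms passing the retention thresholds carry
    ``retained=True`` and a similarity-cluster id; non-retained terms keep
    ``cluster_id=-1``.
    """
    cfg = cfg or EnrichmentConfig()
    query = {g.upper() for g in query_genes}
    if cfg.background == "user_list":
        if not cfg.background_genes:
            raise DomainError("background='user_list' requires background_genes")
        background = {g.upper() for g in cfg.background_genes}
    else:
        background = set()
        for _, genes in gene_sets.values():
            background |= genes
    query &= background
    if not query:
        raise DomainError("query has no genes in the enrichment background")
    N, n = len(background), len(query)

    results: list[EnrichmentResult] = []
    for term_id in sorted(gene_sets):
        desc, genes = gene_sets[term_id]
        term = genes & background
        overlap = sorted(term & query)
        k, K = len(overlap), len(term)
        if k == 0 or K == 0:
            continue
        p = hypergeometric_tail(k, n, K, N)
        ef = k / (n * K / N)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=desc,
                K=K,
                k=k,
                n=n,
                N=N,
                p_raw=p,
                p_adjusted=p,
                enrichment_factor=ef,
                member_genes=overlap,
            )
        )
    if not results:
        return results
    adjusted = adjust_pvalues([r.p_raw for r in results], cfg.correction)
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj
        # retention compares the RAW p against p_max (the adjusted value is
        # reported alongside), mirroring the portal defaults this follows
        r.retained = (
            r.p_raw < cfg.p_max and r.k >= cfg.min_count
            and r.enrichment_factor > cfg.ef_min
        )
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    _cluster(results, gene_sets, background, cfg)
    return results


def _cluster(
    results: list[EnrichmentResult],
    gene_sets: dict[str, tuple[str, set[str]]],
    background: set[str],
    cfg: EnrichmentConfig,
) -> None:
    retained = [r for r in results if r.retained]
    graph = nx.Graph()
    graph.add_nodes_from(r.term_id for r in retained)
    for i, a in enumerate(retained):
        genes_a = gene_sets[a.term_id][1] & background
        for b in retained[i + 1:]:
            genes_b = gene_sets[b.term_id][1] & background
            if kappa_similarity(genes_a, genes_b, background) > cfg.similarity_min:
                graph.add_edge(a.term_id, b.term_id)
    by_id = {r.term_id: r for r in retained}
    # cluster ids ordered by the best (lowest-p) member term
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda comp: min((by_id[t].p_raw, t) for t in comp),
    )
    for cid, comp in enumerate(components):
        for term in comp:
            by_id[term].cluster_id = cid
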