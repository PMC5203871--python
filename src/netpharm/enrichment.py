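"""Gene-set over-representation analysis and functional-module partitioning.

For a query gene list of size n drawn from a universe of size N, a term
annotating K universe genes of which k are in the list gets

* fold enrichment  FE = (k/n) / (K/N) = kN / (nK),
* a raw hypergeometric upper-tail p-value  P(X >= k),
* a Benjamini–Hochberg adjusted q over all tested terms.

Significant, non-redundant terms then partition the gene list into
functional modules: terms are scanned in significance order, a term
whose member overlap with an already-kept term exceeds Jaccard 0.5 is
absorbed, and each gene goes to the most significant retained term that
covers it.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import (
    AnnotationCollection,
    EnrichmentResult,
    ModulePartition,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_tail", "enrich", "filter_significant", "partition_modules"]


def hypergeom_tail(N: int, K: int, n: int, k: int, ease: bool = False) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts annotated genes in a size-n list drawn without replacement
    from a universe of N genes of which K are annotated.  With
    ``ease=True`` the tail is evaluated at k-1 (the conservative EASE
    score variant); k <= 1 then gives p = 1.
    """
    k_eff = max(k - 1, 0) if ease else k
    return float(hypergeom.sf(k_eff - 1, N, K, n))


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def enrich(
    gene_list: Iterable[str],
    annotations: AnnotationCollection,
    universe: Iterable[str],
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every term hit by the list.

    Annotation members outside the universe are dropped (with a logged
    count); only terms with k >= 1 are scored.  With ``ease=True`` the
    conservative EASE variant is used: the tail is evaluated at k-1,
    i.e. P(X >= k-1).  Results are sorted by ascending p, ties broken by
    descending fold enrichment then term id.
    """
    universe_set = {g.strip().upper() for g in universe}
    genes = {g.strip().upper() for g in gene_list}
    if not genes or not universe_set:
        raise ValidationError("gene list and universe must be non-empty")
    if not genes <= universe_set:
        missing = sorted(genes - universe_set)
        raise ValidationError(
            f"{len(missing)} query gene(s) outside the universe, e.g. {missing[:5]}"
        )

    N, n = len(universe_set), len(genes)
    rows: list[tuple[str, str, int, int]] = []
    n_outside = 0
    for term in annotations:
        members = term.members & universe_set
        n_outside += len(term.members) - len(members)
        if not members:
            continue
        k = len(members & genes)
        if k >= 1:
            rows.append((term.term_id, term.name, k, len(members)))
    if n_outside:
        logger.info("enrich: dropped %d annotation member(s) outside universe", n_outside)
    if not rows:
        return []

    p_raw = [hypergeom_tail(N, K, n, k, ease=ease) for _, _, k, K in rows]
    q_bh = multipletests(p_raw, method="fdr_bh")[1]

    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=name,
            k=k,
            n=n,
            K=K,
            N=N,
            fold_enrichment=(k * N) / (n * K),
            p_raw=p,
            q_bh=float(q),
        )
        for (tid, name, k, K), p, q in zip(rows, p_raw, q_bh)
    ]
    results.sort(key=lambda r: (r.p_raw, -r.fold_enrichment, r.term_id))
    return results


def filter_significant(
    results: Sequence[EnrichmentResult],
    p_cut: float = 0.05,
    fe_cut: float = 1.0,
) -> list[EnrichmentResult]:
    """Keep results with p_raw strictly below p_cut and FE >= fe_cut."""
    return [r for r in results if r.p_raw < p_cut and r.fold_enrichment >= fe_cut]


def partition_modules(
    gene_list: Iterable[str],
    results: Sequence[EnrichmentResult],
    k_modules: int,
    annotations: AnnotationCollection,
) -> ModulePartition:
    """Partition the gene list into up to k_modules functional modules.

    Greedy redundancy collapse over significance-ordered results: a term
    is absorbed by an earlier retained term when their member overlap
    exceeds Jaccard 0.5.  Each gene is assigned to the retained term of
    smallest p that annotates it; genes covered by no retained term fall
    into the "unassigned" module.
    """
    if k_modules < 1:
        raise ValidationError("k_modules must be >= 1")
    genes = {g.strip().upper() for g in gene_list}
    ordered = sorted(results, key=lambda r: (r.p_raw, -r.fold_enrichment, r.term_id))
    retained: list[EnrichmentResult] = []
    for res in ordered:
        members = annotations[res.term_id].members
        if any(
            _jaccard(members, annotations[kept.term_id].members) > 0.5
            for kept in retained
        ):
            continue
        retained.append(res)
        if len(retained) == k_modules:
            break
    if len(retained) < k_modules:
        logger.info(
            "partition_modules: only %d non-redundant term(s) available "
            "(%d requested)",
            len(retained),
            k_modules,
        )

    modules: dict[str, set[str]] = {res.term_name: set() for res in retained}
    unassigned: set[str] = set()
    for gene in genes:
        for res in retained:  # retained is already in ascending-p order
            if gene in annotations[res.term_id].members:
                modules[res.term_name].add(gene)
                break
        else:
            unassigned.add(gene)
    if unassigned:
        modules["unassigned"] = unassigned
    return ModulePartition(modules)
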