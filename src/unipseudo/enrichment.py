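"""GO-term and protein-domain over-representation testing.

Annotations are propagated up the is_a hierarchy (true-path rule) before
testing; each term is tested with the one-sided hypergeometric upper tail
(equivalently Fisher's exact test on the 2x2 table), and p-values are
adjusted with Benjamini-Hochberg across the tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_model import AnnotationDAG, ValidationError

__all__ = [
    "EnrichmentResult",
    "propagate_annotations",
    "go_enrichment",
    "pfam_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # study genes carrying the term
    n: int  # study size
    big_k: int  # population genes carrying the term
    big_n: int  # population size
    p: float
    q: float = 1.0

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.big_k):
            raise ValidationError(
                f"{self.term}: inconsistent counts "
                f"k={self.k} n={self.n} K={self.big_k}"
            )


def propagate_annotations(dag: AnnotationDAG) -> dict[str, set[str]]:
    """Close every gene's term set under is_a ancestors (idempotent)."""
    cache: dict[str, set[str]] = {}

    def up(term: str) -> set[str]:
        if term not in cache:
            out = {term}
            for p in dag.parents[term]:
                out |= up(p)
            cache[term] = out
        return cache[term]

    return {
        gene: set().union(*(up(t) for t in terms)) if terms else set()
        for gene, terms in dag.gene_terms.items()
    }


def _hypergeom_upper(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def _bh_adjust(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    if not results:
        return []
    _, q, _, _ = multipletests(
        [r.p for r in results], method="fdr_bh"
    )
    adjusted = [
        EnrichmentResult(
            term=r.term, k=r.k, n=r.n, big_k=r.big_k, big_n=r.big_n,
            p=r.p, q=float(qv),
        )
        for r, qv in zip(results, q)
    ]
    adjusted.sort(key=lambda r: (r.q, r.p, r.term))
    return adjusted


def go_enrichment(
    study: set[str],
    population: set[str],
    dag: AnnotationDAG,
    min_population_count: int = 1,
) -> list[EnrichmentResult]:
    """Per-term over-representation of *study* within *population*.

    The test universe is every term carried by at least one study gene
    after propagation; results are sorted by (q, p, term).
    """
    if not study <= population:
        raise ValidationError("study set must be a subset of population")
    annotations = propagate_annotations(dag)
    study_count: dict[str, int] = {}
    pop_count: dict[str, int] = {}
    for gene in population:
        for term in annotations.get(gene, ()):
            pop_count[term] = pop_count.get(term, 0) + 1
            if gene in study:
                study_count[term] = study_count.get(term, 0) + 1
    n, big_n = len(study), len(population)
    results = [
        EnrichmentResult(
            term=term, k=k, n=n, big_k=pop_count[term], big_n=big_n,
            p=_hypergeom_upper(k, big_n, pop_count[term], n),
        )
        for term, k in study_count.items()
        if k > 0 and pop_count[term] >= min_population_count
    ]
    return _bh_adjust(results)


def pfam_enrichment(
    study_counts: dict[str, int],
    population_counts: dict[str, int],
    study_size: int,
    population_size: int,
) -> list[EnrichmentResult]:
    """Domain over-representation by the hypergeometric upper tail.

    Domains absent from the study are skipped; counts must be consistent
    (study <= population per domain and within the set sizes).
    """
    if study_size > population_size:
        raise ValidationError("study larger than population")
    results = []
    for domain, k in sorted(study_counts.items()):
        if k == 0:
            continue
        big_k = population_counts.get(domain)
        if big_k is None or k > big_k or big_k > population_size \
                or k > study_size:
            raise ValidationError(
                f"{domain}: inconsistent counts k={k} K={big_k}"
            )
        results.append(
            EnrichmentResult(
                term=domain, k=k, n=study_size, big_k=big_k,
                big_n=population_size,
                p=_hypergeom_upper(k, population_size, big_k, study_size),
            )
        )
    return _bh_adjust(results)
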