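"""Over-representation statistics for interactome annotation.

The engine is the exact hypergeometric upper tail: drawing ``n`` proteins
without replacement from a background of ``N`` of which ``K`` carry a term,
the enrichment p-value of observing ``k`` carriers in the draw is
``P(X >= k)`` (inclusive tail, the standard over-representation convention).
Families of term tests are corrected with the Benjamini–Hochberg step-up
procedure. On top of these sit the generic term/category enrichment used for
diseases, GO namespaces and gene-set collections, and the two drug analyses:
drug-target over-representation among baits (a single test against the
protein-coding genome) and therapeutic-category enrichment among the
interactome's baits and preys.

The tail computation is delegated to :mod:`scipy.stats` (log-domain stable
survival function); BH to :mod:`statsmodels`. Both are argument-checked here
so that violated bounds fail loudly with the offending argument named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InconsistencyError
from .io import AnnotationTable


@dataclass
class BackgroundSpec:
    """Background population of a term-enrichment family.

    ``population_size`` is N (e.g. 19,008 protein-coding genes);
    ``annotated_in_population`` maps term id → K, the number of background
    members carrying the term.
    """

    population_size: int
    annotated_in_population: dict = field(default_factory=dict)
    label: str = "custom"

    def __post_init__(self):
        if self.population_size <= 0:
            raise DomainError("population_size must be positive")
        for term, K in self.annotated_in_population.items():
            if not 0 < K <= self.population_size:
                raise DomainError(
                    f"background count K={K} for term {term!r} outside "
                    f"(0, N={self.population_size}]"
                )

    @classmethod
    def from_annotations(
        cls, annotations: AnnotationTable, population_size: int | None = None,
        label: str | None = None,
    ) -> "BackgroundSpec":
        """Derive K per term by counting carriers in an annotation table that
        covers the background population. If ``population_size`` is omitted,
        the number of annotated proteins is used."""
        counts = annotations.carrier_counts()
        N = population_size or len(annotations.protein_to_terms)
        return cls(
            population_size=N,
            annotated_in_population=counts,
            label=label or annotations.namespace,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term with its 2x2 counts and p-values."""

    term_id: str
    term_name: str
    k: int
    n_query: int
    K: int
    N: int
    fraction: float
    p_raw: float
    p_adj: float


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact inclusive upper-tail probability P(X >= k), X ~ HG(N, K, n).

    Stable for populations well beyond 1e5 (computed through the log-domain
    survival function). ``k = 0`` returns exactly 1.
    """
    if N < 0:
        raise DomainError(f"N={N} must be >= 0")
    if not 0 <= K <= N:
        raise DomainError(f"K={K} outside [0, N={N}]")
    if not 0 <= n <= N:
        raise DomainError(f"n={n} outside [0, N={N}]")
    if not 0 <= k <= min(n, K):
        raise DomainError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j>=i}(p_(j) * m / j) on the ascending sort, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        bad = p[(p < 0) | (p > 1) | np.isnan(p)][0]
        raise DomainError(f"p-value {bad} outside [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_terms(
    query: Iterable[str],
    annotations: AnnotationTable,
    background: BackgroundSpec,
    min_K: int = 1,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every annotated term in a query.

    One result per term with background count K >= ``min_K`` and query count
    k >= 1; BH adjustment over exactly that family; sorted by
    (p_adj, p_raw, term_id). The query size n includes unannotated query
    members, matching the "% of preys" reporting convention.
    """
    query = set(query)
    if not query:
        raise DomainError("query must be non-empty")
    n = len(query)
    N = background.population_size
    counts: dict = {}
    for protein in query:
        for term in annotations.terms_of(protein):
            counts[term] = counts.get(term, 0) + 1
    tested = []
    for term, k in sorted(counts.items()):
        K = background.annotated_in_population.get(term, 0)
        if K == 0:
            raise InconsistencyError(
                f"term {term!r} has k={k} in query but K=0 in background "
                f"{background.label!r}"
            )
        if K < min_K:
            continue
        if k > K:
            raise InconsistencyError(
                f"term {term!r}: query count k={k} exceeds background K={K}"
            )
        tested.append((term, k, K))
    p_raw = [hypergeom_upper_tail(N, K, n, k) for _, k, K in tested]
    p_adj = bh_adjust(p_raw)
    results = [
        EnrichmentResult(
            term_id=term,
            term_name=annotations.term_names.get(term, term),
            k=k,
            n_query=n,
            K=K,
            N=N,
            fraction=k / n,
            p_raw=pr,
            p_adj=pa,
        )
        for (term, k, K), pr, pa in zip(tested, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term_id))
    return results


def enrich_gene_sets(
    query: Iterable[str], collection, background_size: int
) -> list[EnrichmentResult]:
    """Gene-set (pathway stand-in) enrichment against a fixed background size.

    Each GMT set is treated as one term whose K is its member count.
    """
    table = AnnotationTable(namespace="gene_sets")
    for name, members in collection.sets.items():
        for m in members:
            table.protein_to_terms.setdefault(m, set()).add(name)
        table.term_names[name] = collection.description.get(name, name) or name
    background = BackgroundSpec(
        population_size=background_size,
        annotated_in_population={
            name: len(members) for name, members in collection.sets.items()
        },
        label="gene_sets",
    )
    return enrich_terms(query, table, background)


def enrich_drug_targets(
    baits: Iterable[str], target_set: Iterable[str], genome_size: int
) -> EnrichmentResult:
    """Single-test over-representation of drug targets among baits.

    N = genome_size, K = |target_set|, n = |baits|, k = |baits ∩ targets|.
    With one test, the adjusted p-value equals the raw one.
    """
    baits = set(baits)
    targets = set(target_set)
    if not baits:
        raise DomainError("baits must be non-empty")
    if genome_size < len(targets):
        raise DomainError(
            f"genome_size={genome_size} smaller than target set ({len(targets)})"
        )
    k = len(baits & targets)
    p = hypergeom_upper_tail(genome_size, len(targets), len(baits), k)
    return EnrichmentResult(
        term_id="drug_target",
        term_name="drug target",
        k=k,
        n_query=len(baits),
        K=len(targets),
        N=genome_size,
        fraction=k / len(baits),
        p_raw=p,
        p_adj=p,
    )


def enrich_drug_categories(
    query: Iterable[str],
    category_table: AnnotationTable,
    genome_size: int,
) -> list[EnrichmentResult]:
    """Therapeutic-category enrichment among the interactome's proteins.

    ``query`` is the union of baits and preys of the final interactome; the
    category table is assumed genome-wide so K is its carrier count per
    category. BH-adjusted over all tested categories.
    """
    background = BackgroundSpec.from_annotations(
        category_table, population_size=genome_size, label="drug_category"
    )
    query = set(query)
    if not query:
        raise DomainError("query must be non-empty")
    if not any(category_table.terms_of(p) for p in query):
        return []
    return enrich_terms(query, category_table, background)


ENRICHMENT_SCHEMA = [
    "term_id", "term_name", "k", "n_query", "K", "N", "fraction", "p_raw", "p_adj",
]
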