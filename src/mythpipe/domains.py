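"""Bait–prey domain co-occurrence-set pair enrichment.

Two-step procedure. First, protein domains are grouped into *co-occurrence
sets* separately on the bait side and on the prey side: two domains belong to
the same set iff they annotate exactly the same proteins within the defining
universe (domains that never co-occur with others form sets of length 1).
Testing sets instead of individual domains avoids redundant results, avoids
multiple-testing penalties from perfectly dependent tests, and makes explicit
that enrichment cannot distinguish domains within a set.

Second, every (bait-set, prey-set) pair observed on at least one interaction
is scored with a four-parameter hypergeometric over the space of possible
bait-involving pairs:

    N = n_baits × proteome_size        (possible bait–protein pairs)
    M = number of detected interactions
    n = (#baits carrying the bait set) × (#proteome proteins carrying the prey set)
    m = detected interactions whose bait carries the bait set and whose prey
        carries the prey set

p = P(X >= m), X ~ HG(N, M, n), BH-adjusted across all tested pairs.

Prey-side co-occurrence equivalence is computed over the *detected prey*
universe, while n counts prey-set carriers over the *full proteome* (a
carrier must hold all member domains jointly). A single interaction whose
endpoints carry several sets contributes to every combination; an
interaction whose prey lacks domain annotation contributes to none.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import DomainError, InconsistencyError
from .io import AnnotationTable, InteractionRecord
from .enrich import bh_adjust, hypergeom_upper_tail


@dataclass(frozen=True)
class DomainSet:
    """A co-occurring domain equivalence class within one universe."""

    members: frozenset
    carrier_signature: frozenset
    side: str  # "bait" or "prey"

    @property
    def set_id(self) -> str:
        """Deterministic identifier: the smallest member domain id."""
        return min(self.members)

    def label(self) -> str:
        return "+".join(sorted(self.members))


@dataclass
class DomainPairResult:
    bait_set: DomainSet
    prey_set: DomainSet
    N_pairs: int
    M_detected: int
    n_possible: int
    m_observed: int
    p_raw: float = 1.0
    p_adj: float = 1.0


def cooccurrence_sets(
    universe: Iterable[str],
    domain_annotations: AnnotationTable,
    side: str,
) -> list[DomainSet]:
    """Partition the domains annotated on >= 1 universe protein into
    equivalence classes by identical carrier sets within the universe.

    Deterministically ordered by smallest member domain id.
    """
    universe = set(universe)
    carriers: dict = {}
    for protein in universe:
        for domain in domain_annotations.terms_of(protein):
            carriers.setdefault(domain, set()).add(protein)
    by_signature: dict = {}
    for domain, carrier_set in carriers.items():
        by_signature.setdefault(frozenset(carrier_set), set()).add(domain)
    sets = [
        DomainSet(members=frozenset(domains), carrier_signature=sig, side=side)
        for sig, domains in by_signature.items()
    ]
    sets.sort(key=lambda s: s.set_id)
    return sets


def _inverse_index(annotations: AnnotationTable) -> dict:
    """domain id -> set of annotated proteins, built in one pass."""
    inv: dict = {}
    for protein, terms in annotations.protein_to_terms.items():
        for t in terms:
            inv.setdefault(t, set()).add(protein)
    return inv


def proteome_carrier_count(
    domain_set: DomainSet,
    proteome_annotations: AnnotationTable,
    _inverse: dict | None = None,
) -> int:
    """Number of proteome proteins carrying *all* member domains jointly."""
    inv = _inverse if _inverse is not None else _inverse_index(proteome_annotations)
    members = sorted(domain_set.members)
    joint = set(inv.get(members[0], ()))
    for d in members[1:]:
        joint &= inv.get(d, set())
    return len(joint)


def pair_counts(
    interactions: Sequence[InteractionRecord],
    bait_sets: Sequence[DomainSet],
    prey_sets: Sequence[DomainSet],
    proteome_annotations: AnnotationTable,
    n_baits: int,
    proteome_size: int,
) -> list[DomainPairResult]:
    """Count m for every (bait-set, prey-set) pair with m >= 1.

    ``interactions`` must already be deduplicated. Pairs never observed are
    not returned: they cannot be enriched and would deflate the BH family.
    """
    if n_baits <= 0 or proteome_size <= 0:
        raise DomainError("n_baits and proteome_size must be positive")
    N_pairs = n_baits * proteome_size
    M = len(interactions)
    if M == 0:
        return []
    # protein -> indices of sets it carries, on each side
    bait_membership: dict = {}
    for i, s in enumerate(bait_sets):
        for p in s.carrier_signature:
            bait_membership.setdefault(p, []).append(i)
    prey_membership: dict = {}
    for j, s in enumerate(prey_sets):
        for p in s.carrier_signature:
            prey_membership.setdefault(p, []).append(j)
    m_counts: dict = {}
    for rec in interactions:
        for i in bait_membership.get(rec.bait_id, ()):
            for j in prey_membership.get(rec.prey_id, ()):
                m_counts[(i, j)] = m_counts.get((i, j), 0) + 1
    # prey-set carriers over the full proteome, computed once per set
    inverse = _inverse_index(proteome_annotations)
    prey_proteome: dict = {}
    results = []
    for (i, j), m in sorted(m_counts.items()):
        if j not in prey_proteome:
            prey_proteome[j] = proteome_carrier_count(
                prey_sets[j], proteome_annotations, _inverse=inverse
            )
        n_prey = prey_proteome[j]
        if n_prey == 0:
            raise InconsistencyError(
                f"prey set {prey_sets[j].label()} observed on {m} interactions "
                "but has no proteome carriers"
            )
        n_possible = len(bait_sets[i].carrier_signature) * n_prey
        results.append(
            DomainPairResult(
                bait_set=bait_sets[i],
                prey_set=prey_sets[j],
                N_pairs=N_pairs,
                M_detected=M,
                n_possible=n_possible,
                m_observed=m,
            )
        )
    return results


def pair_enrichment(counted: Sequence[DomainPairResult]) -> list[DomainPairResult]:
    """Score counted pairs: p = P(X >= m), X ~ HG(N, M, n); BH over all pairs.

    Sorted by (p_adj, p_raw, bait set id, prey set id).
    """
    for r in counted:
        if r.m_observed > min(r.M_detected, r.n_possible):
            raise DomainError(
                f"m={r.m_observed} exceeds min(M={r.M_detected}, "
                f"n={r.n_possible}) for pair "
                f"({r.bait_set.label()}, {r.prey_set.label()})"
            )
        if r.n_possible > r.N_pairs:
            raise DomainError(
                f"n={r.n_possible} exceeds N={r.N_pairs} for pair "
                f"({r.bait_set.label()}, {r.prey_set.label()})"
            )
    p_raw = [
        hypergeom_upper_tail(r.N_pairs, r.M_detected, r.n_possible, r.m_observed)
        for r in counted
    ]
    p_adj = bh_adjust(p_raw)
    scored = [
        replace(r, p_raw=pr, p_adj=pa)
        for r, pr, pa in zip(counted, p_raw, p_adj)
    ]
    scored.sort(
        key=lambda r: (r.p_adj, r.p_raw, r.bait_set.set_id, r.prey_set.set_id)
    )
    return scored


def domain_pair_analysis(
    interactions: Sequence[InteractionRecord],
    bait_universe: Iterable[str],
    domain_annotations: AnnotationTable,
    proteome_size: int,
) -> list[DomainPairResult]:
    """End-to-end: co-occurrence sets on both sides, counts, enrichment.

    The bait universe is the full bait panel (including baits without
    surviving interactions); the prey universe is the detected preys.
    """
    bait_universe = set(bait_universe)
    prey_universe = {r.prey_id for r in interactions}
    bait_sets = cooccurrence_sets(bait_universe, domain_annotations, side="bait")
    prey_sets = cooccurrence_sets(prey_universe, domain_annotations, side="prey")
    counted = pair_counts(
        interactions,
        bait_sets,
        prey_sets,
        domain_annotations,
        n_baits=len(bait_universe),
        proteome_size=proteome_size,
    )
    return pair_enrichment(counted)


DOMAIN_PAIR_SCHEMA = [
    "bait_set_members", "prey_set_members", "N", "M", "n", "m", "p_raw", "p_adj",
]


def domain_pairs_to_rows(results: Sequence[DomainPairResult]) -> list[dict]:
    return [
        {
            "bait_set_members": r.bait_set.label(),
            "prey_set_members": r.prey_set.label(),
            "N": r.N_pairs,
            "M": r.M_detected,
            "n": r.n_possible,
            "m": r.m_observed,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
        }
        for r in results
    ]
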