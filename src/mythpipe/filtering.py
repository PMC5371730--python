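"""From raw hit table to the unique interactome.

A membrane two-hybrid screen emits one row per positive colony, so the same
bait→prey pair appears repeatedly, and a handful of "sticky" preys — signal
peptide processing machinery (GO:0006465) and ribosomal proteins — show up
with almost every bait as generic translation/trafficking artifacts. This
module deduplicates hits into distinct ordered bait→prey pairs, removes
contaminant-prey edges, flags edges already present in a reference
interaction database, annotates plasma-membrane localization, and produces
the summary counts (unique interactions / proteins / membrane proteins).

Contaminant removal applies to preys only: baits are pre-validated constructs
and never grounds for removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .io import AnnotationTable, InteractionRecord, ProteinRecord


@dataclass
class FilterConfig:
    """Knobs of the contaminant filter and membrane annotation.

    contaminant_terms
        Term ids whose prey carriers are removed. Default: GO:0006465
        (signal peptide processing).
    contaminant_keywords
        Case-insensitive substrings matched against term *names*; default
        ``["ribosom"]`` catches ribosomal-protein annotations regardless of
        the exact GO id used.
    contaminant_proteins
        Optional explicit accession blacklist.
    membrane_terms
        Term ids marking plasma-membrane localization. Default: GO:0005886.
        Include GO-graph descendants here if desired; no ontology traversal
        is performed.
    """

    contaminant_terms: frozenset = frozenset({"GO:0006465"})
    contaminant_keywords: tuple = ("ribosom",)
    contaminant_proteins: frozenset = frozenset()
    membrane_terms: frozenset = frozenset({"GO:0005886"})

    def __post_init__(self):
        self.contaminant_terms = frozenset(self.contaminant_terms)
        self.contaminant_proteins = frozenset(self.contaminant_proteins)
        self.membrane_terms = frozenset(self.membrane_terms)
        self.contaminant_keywords = tuple(
            k.lower() for k in self.contaminant_keywords
        )


@dataclass(frozen=True)
class InteractomeSummary:
    n_unique_interactions: int
    n_proteins: int
    n_membrane_proteins: int
    n_known: int
    n_removed_contaminant: int = 0


def deduplicate_interactions(
    records: Sequence[InteractionRecord],
) -> list[InteractionRecord]:
    """Collapse hits to one record per distinct ordered (bait, prey) pair.

    Evidence flags of duplicates are unioned; screen ids concatenated with
    ";" in first-seen order; output sorted by (bait_id, prey_id). Idempotent
    and insensitive to input order up to the screen_id concatenation order.
    """
    merged: dict = {}
    screens: dict = {}
    for rec in records:
        key = rec.pair
        if key not in merged:
            merged[key] = replace(rec, screen_id="")
            screens[key] = []
        else:
            merged[key].evidence = merged[key].evidence | rec.evidence
            merged[key].extra = {**rec.extra, **merged[key].extra}
        if rec.screen_id and rec.screen_id not in screens[key]:
            screens[key].append(rec.screen_id)
    out = []
    for key in sorted(merged):
        rec = merged[key]
        rec.screen_id = ";".join(screens[key])
        out.append(rec)
    return out


def _is_contaminant_prey(
    prey_id: str, annotations: AnnotationTable, config: FilterConfig
) -> bool:
    if prey_id in config.contaminant_proteins:
        return True
    terms = annotations.terms_of(prey_id)
    if terms & config.contaminant_terms:
        return True
    for t in terms:
        name = annotations.term_names.get(t, t).lower()
        if any(kw in name for kw in config.contaminant_keywords):
            return True
    return False


def remove_contaminant_preys(
    records: Sequence[InteractionRecord],
    annotations: AnnotationTable,
    config: FilterConfig | None = None,
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Partition records into (kept, removed) by contaminant status of the prey.

    A record is removed iff its prey carries any configured contaminant term,
    carries any term whose name matches a contaminant keyword, or is on the
    explicit blacklist. ``kept + removed`` is an exact partition of the input.
    """
    if annotations is None:
        raise ConfigurationError("contaminant filtering requires an annotation table")
    config = config or FilterConfig()
    kept, removed = [], []
    cache: dict = {}
    for rec in records:
        flag = cache.get(rec.prey_id)
        if flag is None:
            flag = _is_contaminant_prey(rec.prey_id, annotations, config)
            cache[rec.prey_id] = flag
        (removed if flag else kept).append(rec)
    return kept, removed


def flag_known_interactions(
    records: Sequence[InteractionRecord],
    reference_edges: Iterable[tuple],
) -> list[InteractionRecord]:
    """Add the ``known_reference`` evidence flag to records whose unordered
    {bait, prey} pair occurs in the reference edge list."""
    ref = {frozenset(e) for e in reference_edges}
    out = []
    for rec in records:
        if frozenset(rec.pair) in ref:
            rec = replace(rec, evidence=rec.evidence | {"known_reference"})
        out.append(rec)
    return out


def annotate_membrane_localization(
    proteins: Iterable,
    annotations: AnnotationTable,
    config: FilterConfig | None = None,
) -> dict:
    """Map accession → True iff the protein carries >= 1 membrane term.

    ``proteins`` may be ProteinRecords or bare accession strings; proteins
    absent from the annotation table map to False.
    """
    config = config or FilterConfig()
    if not config.membrane_terms:
        raise ConfigurationError("membrane_terms must be non-empty")
    result = {}
    for p in proteins:
        pid = p.protein_id if isinstance(p, ProteinRecord) else p
        result[pid] = bool(annotations.terms_of(pid) & config.membrane_terms)
    return result


def summarize_interactome(
    records: Sequence[InteractionRecord],
    membrane_map: Mapping[str, bool] | None = None,
    n_removed_contaminant: int = 0,
) -> InteractomeSummary:
    """Summary counts of a deduplicated interactome."""
    membrane_map = membrane_map or {}
    proteins = {r.bait_id for r in records} | {r.prey_id for r in records}
    return InteractomeSummary(
        n_unique_interactions=len(records),
        n_proteins=len(proteins),
        n_membrane_proteins=sum(
            1 for p in proteins if membrane_map.get(p, False)
        ),
        n_known=sum(1 for r in records if "known_reference" in r.evidence),
        n_removed_contaminant=n_removed_contaminant,
    )
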