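"""Tabular I/O for screen post-processing.

All on-disk formats are UTF-8, tab-separated text with a header row; lines
starting with ``#`` are comments and are skipped. Identifiers are normalized
on read: surrounding whitespace is stripped and bare gene symbols are
upper-cased, while database-style accessions (anything containing ``:`` or an
InterPro-style ``IPR``/``PF`` prefix) keep their case so that ids like
``GO:0006465`` or ``IPR017452`` survive untouched. Normalization is
idempotent. Unknown extra columns are preserved on read (in ``extra``) and
ignored by every computation, so provenance columns round-trip.

Numeric p-values are written in scientific notation with six significant
digits, which makes output files byte-identical across runs on identical
inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import RowError, SchemaError, MythpipeError

#: Controlled vocabulary for interaction evidence flags.
EVIDENCE_FLAGS = frozenset(
    {"myth", "known_reference", "validated_coip", "validated_bret"}
)

_ACCESSION_RE = re.compile(r"^(?:[A-Za-z]+[\w.]*:|IPR\d|PF\d)")


def normalize_id(raw: str) -> str:
    """Normalize a protein/term identifier.

    Whitespace is stripped; bare symbols are upper-cased; accession-style ids
    (containing a namespace prefix such as ``GO:`` or matching InterPro/Pfam
    patterns) are left as-is apart from the strip. Idempotent by construction.
    """
    s = raw.strip()
    if _ACCESSION_RE.match(s):
        return s
    return s.upper()


@dataclass(frozen=True)
class ProteinRecord:
    """A protein in the screen universe.

    ``role`` records how the protein participates: ``bait`` (tagged membrane
    construct), ``prey`` (library hit), ``both``, or ``background`` (proteome
    member never detected).
    """

    protein_id: str
    symbol: str = ""
    role: str = "background"

    def __post_init__(self):
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.role not in {"bait", "prey", "both", "background"}:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class InteractionRecord:
    """One detected bait→prey hit. Direction matters (ordered pair)."""

    bait_id: str
    prey_id: str
    screen_id: str = ""
    evidence: frozenset = field(default_factory=lambda: frozenset({"myth"}))
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.bait_id or not self.prey_id:
            raise ValueError("bait_id and prey_id must be non-empty")
        bad = set(self.evidence) - EVIDENCE_FLAGS
        if bad:
            raise ValueError(f"unknown evidence flags: {sorted(bad)}")
        self.evidence = frozenset(self.evidence)

    @property
    def pair(self) -> tuple:
        return (self.bait_id, self.prey_id)


@dataclass
class AnnotationTable:
    """Per-namespace protein → term-set mapping with term names."""

    namespace: str
    protein_to_terms: dict = field(default_factory=dict)
    term_names: dict = field(default_factory=dict)

    def __post_init__(self):
        # Every term id must have a name entry (name may equal the id).
        for terms in self.protein_to_terms.values():
            for t in terms:
                self.term_names.setdefault(t, t)

    def terms_of(self, protein_id: str) -> frozenset:
        return frozenset(self.protein_to_terms.get(protein_id, ()))

    def carriers_of(self, term_id: str) -> frozenset:
        return frozenset(
            p for p, ts in self.protein_to_terms.items() if term_id in ts
        )

    def carrier_counts(self) -> dict:
        """Number of annotated proteins per term id."""
        counts: dict = {}
        for ts in self.protein_to_terms.values():
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        return counts


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), the pathway stand-in."""

    sets: dict = field(default_factory=dict)
    description: dict = field(default_factory=dict)


def _data_lines(path: Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based physical line number, split fields), skipping comments
    and blank lines."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.rstrip("\r\n").split("\t")


def read_interactions(path) -> list[InteractionRecord]:
    """Read a bait–prey interaction table.

    Mandatory columns: ``bait_id``, ``prey_id``. Optional: ``screen_id``,
    ``evidence`` (comma-separated flags). Any other columns are kept in the
    record's ``extra`` mapping. Row order is preserved; duplicate rows are
    kept (deduplication is a separate pipeline stage).
    """
    path = Path(path)
    it = _data_lines(path)
    try:
        _, header = next(it)
    except StopIteration:
        raise SchemaError(f"{path}: empty file, no header")
    header = [h.strip() for h in header]
    for col in ("bait_id", "prey_id"):
        if col not in header:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    idx = {name: i for i, name in enumerate(header)}
    known = {"bait_id", "prey_id", "screen_id", "evidence"}
    records = []
    for lineno, parts in it:
        if len(parts) != len(header):
            raise RowError(
                f"expected {len(header)} columns, got {len(parts)}", lineno
            )
        row = dict(zip(header, parts))
        bait = normalize_id(row["bait_id"])
        prey = normalize_id(row["prey_id"])
        if not bait:
            raise RowError("empty bait_id", lineno)
        if not prey:
            raise RowError("empty prey_id", lineno)
        ev = row.get("evidence", "").strip()
        flags = frozenset(f.strip() for f in ev.split(",") if f.strip()) or frozenset(
            {"myth"}
        )
        if not flags <= EVIDENCE_FLAGS:
            raise RowError(
                f"unknown evidence flags {sorted(flags - EVIDENCE_FLAGS)}", lineno
            )
        records.append(
            InteractionRecord(
                bait_id=bait,
                prey_id=prey,
                screen_id=row.get("screen_id", "").strip(),
                evidence=flags,
                extra={k: v for k, v in row.items() if k not in known},
            )
        )
    return records


def read_annotations(path, namespace: str) -> AnnotationTable:
    """Read a protein→term annotation table.

    Columns: ``protein_id``, ``term_id``, optional ``term_name``. Headerless
    two/three-column files are also accepted for convenience when the first
    line literally names the columns. Term sets are deduplicated; proteins
    with no rows are simply absent.
    """
    path = Path(path)
    table = AnnotationTable(namespace=namespace)
    it = _data_lines(path)
    try:
        first_lineno, first = next(it)
    except StopIteration:
        return table
    header_like = [h.strip() for h in first]
    if header_like[:2] == ["protein_id", "term_id"]:
        rows: Iterable[tuple[int, list[str]]] = it
    else:
        rows = iter([(first_lineno, first)])
        rows = _chain(rows, it)
    for lineno, parts in rows:
        if len(parts) not in (2, 3):
            raise RowError(
                f"expected 2 or 3 columns, got {len(parts)}", lineno
            )
        pid = normalize_id(parts[0])
        term = normalize_id(parts[1])
        if not pid or not term:
            raise RowError("empty protein_id or term_id", lineno)
        table.protein_to_terms.setdefault(pid, set()).add(term)
        name = parts[2].strip() if len(parts) == 3 and parts[2].strip() else term
        table.term_names.setdefault(term, name)
    return table


def _chain(a, b):
    yield from a
    yield from b


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: set name, description, then one member per field."""
    path = Path(path)
    coll = GeneSetCollection()
    for lineno, parts in _data_lines(path):
        if len(parts) < 3:
            raise RowError(f"GMT line has {len(parts)} fields, need >= 3", lineno)
        name = parts[0].strip()
        if not name:
            raise RowError("empty set name", lineno)
        if name in coll.sets:
            raise RowError(f"duplicate set name {name!r}", lineno)
        members = {normalize_id(m) for m in parts[2:] if m.strip()}
        coll.sets[name] = members
        coll.description[name] = parts[1].strip()
    return coll


def _format_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.6e}"
    if isinstance(value, (frozenset, set)):
        return ",".join(sorted(value))
    if isinstance(value, (list, tuple)):
        return ",".join(str(v) for v in value)
    return str(value)


def write_table(rows: Sequence, path, schema: Sequence[str]) -> None:
    """Write records as a TSV with columns in ``schema`` order.

    Records may be dataclasses or mappings. Floats are rendered in scientific
    notation with six significant digits; sets are comma-joined sorted.
    Raises if a record lacks a schema column, naming record index and column.
    """
    path = Path(path)
    lines = ["\t".join(schema)]
    for i, row in enumerate(rows):
        if isinstance(row, Mapping):
            get = row.get
            has = row.__contains__
        else:
            names = {f.name for f in dc_fields(row)}
            get = lambda c, _r=row: getattr(_r, c)  # noqa: E731
            has = names.__contains__
        values = []
        for col in schema:
            if not has(col):
                raise MythpipeError(f"record {i} missing column {col!r}")
            values.append(_format_value(get(col)))
        lines.append("\t".join(values))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def interactions_to_rows(records: Sequence[InteractionRecord]) -> list[dict]:
    """Flatten interaction records for `write_table`."""
    return [
        {
            "bait_id": r.bait_id,
            "prey_id": r.prey_id,
            "screen_id": r.screen_id,
            "evidence": r.evidence,
            **r.extra,
        }
        for r in records
    ]


INTERACTION_SCHEMA = ["bait_id", "prey_id", "screen_id", "evidence"]
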