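"""Packaged fixtures.

Two small validation-outcome tables transcribe published aggregate counts of
the GPCR screen's orthogonal validation experiments (40 interactions tested
by co-IP/BRET, 28 validated; 34 co-IP-tested, 22 validated) and of the
known-interaction retest (50 previously reported pairs, 12 confirmed).
Per-row membership is synthetic — only the aggregates were published — and
the files say so in their headers; real per-interaction detail is
user-suppliable through the same schema.
"""

from __future__ import annotations

from importlib.resources import as_file, files

from .pipeline import ValidationOutcome, read_validation_outcomes


def _load(name: str) -> list[ValidationOutcome]:
    resource = files("mythpipe.data").joinpath(name)
    with as_file(resource) as path:
        return read_validation_outcomes(path)


def load_orthogonal_validation() -> list[ValidationOutcome]:
    """Co-IP/BRET validation attempts (synthetic per-row stand-in)."""
    return _load("validation_orthogonal_synthetic.tsv")


def load_known_retest() -> list[ValidationOutcome]:
    """Two-hybrid retest of previously known interactions (synthetic
    per-row stand-in)."""
    return _load("validation_known_retest_synthetic.tsv")
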