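"""Shared fixtures and independent oracles.

The oracles here deliberately avoid scipy/statsmodels so they stay
independent of the implementation paths they check: the hypergeometric tail
is computed by exhaustively enumerating all C(N, n) samples, and BH by a
literal transcription of the step-up definition.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import pytest

from mythpipe.io import AnnotationTable, InteractionRecord


def enumeration_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by enumerating every size-n sample of a population of N
    items of which the first K are successes. Exact rational arithmetic."""
    if k == 0:
        return Fraction(1)
    population = range(N)
    hits = 0
    total = 0
    for sample in itertools.combinations(population, n):
        total += 1
        if sum(1 for x in sample if x < K) >= k:
            hits += 1
    return Fraction(hits, total)


def step_up_bh(p_values):
    """Literal Benjamini–Hochberg step-up: sort ascending,
    adj_(i) = min_{j>=i}(p_(j) * m / j), cap at 1, restore input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


@pytest.fixture
def go_table():
    """Six-protein GO annotation fixture with contaminant and membrane terms."""
    return AnnotationTable(
        namespace="go",
        protein_to_terms={
            "P1": {"GO:0006465"},
            "P2": {"GO:0022626"},
            "P3": {"GO:0005886"},
            "P4": {"GO:0005886", "GO:0008150"},
            "P5": {"GO:0008150"},
        },
        term_names={
            "GO:0006465": "signal peptide processing",
            "GO:0022626": "cytosolic ribosome",
            "GO:0005886": "plasma membrane",
            "GO:0008150": "biological process",
        },
    )


def edge(bait, prey, screen="S1", evidence=frozenset({"myth"})):
    return InteractionRecord(
        bait_id=bait, prey_id=prey, screen_id=screen, evidence=evidence
    )
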