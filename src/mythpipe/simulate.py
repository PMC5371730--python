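"""Synthetic annotated proteomes and raw screen hit tables.

The generator emulates the statistical shape of a membrane two-hybrid screen
hit table — duplicated detections, promiscuous contaminant preys annotated
with signal-peptide-processing/ribosomal terms, variable per-bait degree —
over a synthetic proteome with two planted signals:

* a (bait-domain, prey-domain) affinity: hits whose bait carries the planted
  bait domain and whose prey carries the planted prey domain are drawn with
  their prey weight multiplied by ``planted_odds_multiplier``;
* a prey-category enrichment: the planted category term is carried by
  realized (non-contaminant) preys at ``planted_category_rate_in_preys`` and
  by all other proteins at ``planted_category_rate_in_background``, so the
  category is enriched among preys by construction while remaining
  independent of which bait–prey edges were drawn (at equal rates the
  assignment is homogeneous: the null).

One :class:`numpy.random.Generator` seeded from the single integer seed
drives all draws in a fixed order (proteome → annotations → edges →
contaminants → duplicates → prey-conditional category top-up), so outputs
are byte-stable across refactors.

Domain identities are sampled from a Zipf-skewed vocabulary (a few very
common domains, a long tail of rare ones), mimicking the frequency profile
of real domain annotations. No attempt is made to model the assay's
biochemistry (expression levels, reporter dynamics, 3-AT thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .io import AnnotationTable, InteractionRecord, ProteinRecord

#: GO terms used for contaminant and membrane annotation in synthetic worlds.
SIGNAL_PEPTIDE_TERM = ("GO:0006465", "signal peptide processing")
RIBOSOME_TERM = ("GO:0022626", "cytosolic ribosome")
MEMBRANE_TERM = ("GO:0005886", "plasma membrane")


@dataclass
class SyntheticConfig:
    """The stated world of a synthetic screen.

    Defaults mirror a 48-bait screen yielding ~1,500 raw hits over a reduced
    proteome of 2,000 proteins, sized so the full pipeline runs in seconds.
    """

    seed: int = 0
    proteome_size: int = 2000
    n_baits: int = 48
    domain_vocab: int = 150
    domains_per_protein: float = 1.5  # Poisson mean
    domain_frequency_skew: float = 1.2  # Zipf exponent
    n_raw_hits: int = 1500
    duplicate_fraction: float = 0.1
    n_contaminant_preys: int = 10
    contaminant_bait_fraction: float = 0.5
    planted_bait_domain: str = "D002"
    planted_prey_domain: str = "D005"
    planted_odds_multiplier: float = 20.0
    planted_prey_category: str = "DIS:0001"
    planted_category_rate_in_preys: float = 0.3
    planted_category_rate_in_background: float = 0.05
    membrane_fraction: float = 0.25
    n_null_categories: int = 5
    null_category_rate: float = 0.05

    def __post_init__(self):
        for name in (
            "duplicate_fraction",
            "contaminant_bait_fraction",
            "planted_category_rate_in_preys",
            "planted_category_rate_in_background",
            "membrane_fraction",
            "null_category_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.planted_odds_multiplier < 1:
            raise ConfigurationError("planted_odds_multiplier must be >= 1")
        if self.domain_vocab < 2:
            raise ConfigurationError("domain_vocab must be >= 2")
        if min(self.proteome_size, self.n_baits, self.n_raw_hits) <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_baits > self.proteome_size:
            raise ConfigurationError("n_baits cannot exceed proteome_size")
        if self.domains_per_protein < 0:
            raise ConfigurationError("domains_per_protein must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted parameters plus realized bookkeeping of one generated screen."""

    config: SyntheticConfig
    bait_ids: list = field(default_factory=list)
    contaminant_prey_ids: list = field(default_factory=list)
    planted_bait_carriers: list = field(default_factory=list)
    planted_prey_carriers: list = field(default_factory=list)
    category_carriers: list = field(default_factory=list)
    planted_pair_edges: list = field(default_factory=list)
    contaminant_edges: list = field(default_factory=list)
    n_duplicate_rows: int = 0


@dataclass
class SyntheticWorld:
    proteins: list
    domain_annotations: AnnotationTable
    go_annotations: AnnotationTable
    category_annotations: AnnotationTable
    truth: SyntheticTruth
    _rng: np.random.Generator = None


def _protein_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _domain_ids(n: int) -> list:
    width = max(3, len(str(n)))
    return [f"D{i:0{width}d}" for i in range(1, n + 1)]


def _draw_domains(rng, config: SyntheticConfig) -> list:
    """Per-protein domain sets: Poisson-many distinct domains, weighted
    without replacement by Zipf frequencies (Gumbel top-k trick, which is an
    exact Plackett–Luce weighted draw)."""
    n, v = config.proteome_size, config.domain_vocab
    weights = 1.0 / np.arange(1, v + 1) ** config.domain_frequency_skew
    log_w = np.log(weights)
    counts = np.minimum(rng.poisson(config.domains_per_protein, size=n), v)
    gumbel = rng.gumbel(size=(n, v))
    order = np.argsort(-(log_w[None, :] + gumbel), axis=1)
    return [order[i, : counts[i]].tolist() for i in range(n)]


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate the annotated proteome and its truth record.

    The planted bait domain is guaranteed on >= 3 baits and the planted prey
    domain on >= 20 proteome proteins; the domain draw is repeated (fresh
    randomness from the same stream) until both hold.
    """
    rng = np.random.default_rng(config.seed)
    pids = _protein_ids(config.proteome_size)
    dids = _domain_ids(config.domain_vocab)
    bait_ids = pids[: config.n_baits]

    domain_index = {d: i for i, d in enumerate(dids)}
    planted_b = domain_index.get(config.planted_bait_domain)
    planted_p = domain_index.get(config.planted_prey_domain)
    if planted_b is None or planted_p is None:
        raise ConfigurationError(
            "planted domains must belong to the generated vocabulary "
            f"(D001..{dids[-1]})"
        )

    want_domains = config.domains_per_protein > 0
    for _ in range(200):
        assignment = _draw_domains(rng, config)
        if not want_domains:
            break
        n_bait_carriers = sum(
            1 for i in range(config.n_baits) if planted_b in assignment[i]
        )
        n_prey_carriers = sum(1 for a in assignment if planted_p in a)
        if n_bait_carriers >= 3 and n_prey_carriers >= 20:
            break
    else:
        raise ConfigurationError(
            "could not satisfy planted-domain carrier constraints; "
            "increase domains_per_protein or pick more frequent planted domains"
        )

    domain_table = AnnotationTable(namespace="interpro")
    for pid, idxs in zip(pids, assignment):
        if idxs:
            domain_table.protein_to_terms[pid] = {dids[i] for i in idxs}
    for d in dids:
        domain_table.term_names.setdefault(d, d)

    # contaminant preys: non-bait proteins, half signal-peptide, half ribosomal
    non_baits = np.array(pids[config.n_baits:])
    n_cont = min(config.n_contaminant_preys, len(non_baits))
    contaminants = sorted(rng.choice(non_baits, size=n_cont, replace=False).tolist())

    go_table = AnnotationTable(namespace="go")
    for term_id, term_name in (SIGNAL_PEPTIDE_TERM, RIBOSOME_TERM, MEMBRANE_TERM):
        go_table.term_names[term_id] = term_name
    for i, pid in enumerate(contaminants):
        term = SIGNAL_PEPTIDE_TERM if i % 2 == 0 else RIBOSOME_TERM
        go_table.protein_to_terms.setdefault(pid, set()).add(term[0])
    membrane_mask = rng.random(config.proteome_size) < config.membrane_fraction
    for pid, is_mem in zip(pids, membrane_mask):
        if is_mem:
            go_table.protein_to_terms.setdefault(pid, set()).add(MEMBRANE_TERM[0])

    # disease/category namespace: one planted category + null categories
    cat_table = AnnotationTable(namespace="disease")
    cat_table.term_names[config.planted_prey_category] = "planted synthetic disease"
    carrier_mask = rng.random(config.proteome_size) < (
        config.planted_category_rate_in_background
    )
    category_carriers = [p for p, c in zip(pids, carrier_mask) if c]
    for pid in category_carriers:
        cat_table.protein_to_terms.setdefault(pid, set()).add(
            config.planted_prey_category
        )
    for j in range(config.n_null_categories):
        term = f"DIS:{j + 2:04d}"
        cat_table.term_names[term] = f"null synthetic disease {j + 1}"
        mask = rng.random(config.proteome_size) < config.null_category_rate
        for pid, c in zip(pids, mask):
            if c:
                cat_table.protein_to_terms.setdefault(pid, set()).add(term)

    bait_set = set(bait_ids)
    proteins = [
        ProteinRecord(pid, symbol=pid, role="bait" if pid in bait_set else "background")
        for pid in pids
    ]
    truth = SyntheticTruth(
        config=config,
        bait_ids=list(bait_ids),
        contaminant_prey_ids=contaminants,
        planted_bait_carriers=[
            b for b in bait_ids
            if config.planted_bait_domain in domain_table.terms_of(b)
        ],
        planted_prey_carriers=[
            p for p in pids
            if config.planted_prey_domain in domain_table.terms_of(p)
        ],
        category_carriers=category_carriers,
    )
    return SyntheticWorld(
        proteins=proteins,
        domain_annotations=domain_table,
        go_annotations=go_table,
        category_annotations=cat_table,
        truth=truth,
        _rng=rng,
    )


def generate_screen(
    world: SyntheticWorld, config: SyntheticConfig | None = None
) -> list[InteractionRecord]:
    """Draw the raw hit table from a generated world.

    Hits pick a bait uniformly, then a prey with weight 1, multiplied by the
    planted odds multiplier when bait and prey both carry the planted
    domains. Contaminant preys are then attached to each bait independently;
    a fraction of rows is re-emitted as duplicates; finally the planted
    category is topped up on realized non-contaminant preys so that a prey
    carries it with probability ``planted_category_rate_in_preys`` while
    every other protein stays at the background rate. Updates
    ``world.truth`` with realized edge and carrier lists.
    """
    config = config or world.truth.config
    rng = world._rng
    truth = world.truth
    pids = [p.protein_id for p in world.proteins]
    n = config.proteome_size

    base = np.ones(n)
    boosted = base.copy()
    prey_carriers = set(truth.planted_prey_carriers)
    for i, pid in enumerate(pids):
        if pid in prey_carriers:
            boosted[i] *= config.planted_odds_multiplier
    base /= base.sum()
    boosted /= boosted.sum()

    planted_baits = set(truth.planted_bait_carriers)
    bait_draw = rng.integers(0, config.n_baits, size=config.n_raw_hits)
    is_planted_bait = np.array(
        [truth.bait_ids[b] in planted_baits for b in bait_draw]
    )
    preys = np.empty(config.n_raw_hits, dtype=int)
    n_boost = int(is_planted_bait.sum())
    if n_boost:
        preys[is_planted_bait] = rng.choice(n, size=n_boost, p=boosted)
    if config.n_raw_hits - n_boost:
        preys[~is_planted_bait] = rng.choice(
            n, size=config.n_raw_hits - n_boost, p=base
        )

    records = [
        InteractionRecord(
            bait_id=truth.bait_ids[b],
            prey_id=pids[j],
            screen_id="S1",
        )
        for b, j in zip(bait_draw, preys)
    ]

    # promiscuous contaminants: each prey hits each bait independently
    for prey in truth.contaminant_prey_ids:
        hits = rng.random(config.n_baits) < config.contaminant_bait_fraction
        for bait, h in zip(truth.bait_ids, hits):
            if h:
                records.append(
                    InteractionRecord(bait_id=bait, prey_id=prey, screen_id="S1")
                )

    # duplicated detections: re-emit a random subset as a second replicate
    dup_mask = rng.random(len(records)) < config.duplicate_fraction
    duplicates = [
        InteractionRecord(bait_id=r.bait_id, prey_id=r.prey_id, screen_id="S2")
        for r, d in zip(records, dup_mask) if d
    ]
    records.extend(duplicates)

    truth.n_duplicate_rows = len(duplicates)
    cont = set(truth.contaminant_prey_ids)
    truth.contaminant_edges = sorted(
        {r.pair for r in records if r.prey_id in cont}
    )

    # Prey-conditional category top-up: realized non-contaminant preys carry
    # the planted category at rate_in_preys, everything else stays at the
    # background rate. Independent of which edges were drawn, so the
    # domain-pair null is untouched.
    rp = config.planted_category_rate_in_preys
    rb = config.planted_category_rate_in_background
    realized_preys = sorted({r.prey_id for r in records} - cont)
    cat_table = world.category_annotations
    term = config.planted_prey_category
    carriers = set(truth.category_carriers)
    if rp > rb:
        p_add = (rp - rb) / (1 - rb)
        add = rng.random(len(realized_preys)) < p_add
        for pid, a in zip(realized_preys, add):
            if a and pid not in carriers:
                carriers.add(pid)
                cat_table.protein_to_terms.setdefault(pid, set()).add(term)
    elif rp < rb:
        p_drop = (rb - rp) / rb
        drop = rng.random(len(realized_preys)) < p_drop
        for pid, d in zip(realized_preys, drop):
            if d and pid in carriers:
                carriers.discard(pid)
                cat_table.protein_to_terms[pid].discard(term)
    truth.category_carriers = sorted(carriers)
    truth.planted_pair_edges = sorted(
        {
            r.pair
            for r in records
            if r.bait_id in planted_baits and r.prey_id in prey_carriers
        }
    )
    return records


def simulate_screen(
    config: SyntheticConfig,
) -> tuple[SyntheticWorld, list[InteractionRecord]]:
    """Convenience: generate world and raw hit table in one call."""
    world = generate_world(config)
    records = generate_screen(world, config)
    return world, records
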