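"""Run orchestration and validation-rate summaries.

``run_pipeline`` chains the stages simulate (optional) → filter → enrich →
domain-pairs → summarize into an output directory with a machine-readable
manifest (inputs, seed, per-stage row counts, per-file sha256 digests).
Outputs contain no timestamps, so an identical config + seed reproduces a
byte-identical directory.

``validation_summary`` computes the success-rate table for orthogonal
validation experiments (co-immunoprecipitation variants, BRET, two-hybrid
retest of previously known interactions): an interaction counts as validated
overall when at least one method validated it; attempts scored untestable
(e.g. uninterpretable blots) are excluded from both numerator and
denominator. Rates are rendered to one decimal percent.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError, MythpipeError
from . import io as mio
from .enrich import (
    BackgroundSpec,
    ENRICHMENT_SCHEMA,
    enrich_terms,
)
from .domains import (
    DOMAIN_PAIR_SCHEMA,
    domain_pair_analysis,
    domain_pairs_to_rows,
)
from .filtering import (
    FilterConfig,
    annotate_membrane_localization,
    deduplicate_interactions,
    flag_known_interactions,
    remove_contaminant_preys,
    summarize_interactome,
)
from .simulate import SyntheticConfig, simulate_screen

VALIDATION_METHODS = frozenset(
    {"coip_flag", "coip_native", "bret", "myth_retest"}
)
VALIDATION_OUTCOMES = frozenset({"validated", "not_validated", "untestable"})


@dataclass(frozen=True)
class ValidationOutcome:
    """One (interaction, method) validation attempt."""

    bait_id: str
    prey_id: str
    method: str
    outcome: str

    def __post_init__(self):
        if self.method not in VALIDATION_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.outcome not in VALIDATION_OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


def read_validation_outcomes(path) -> list[ValidationOutcome]:
    """Read a validation-outcome table (columns bait_id, prey_id, method,
    outcome)."""
    outcomes = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\r\n").split("\t")
            if header is None:
                header = parts
                for col in ("bait_id", "prey_id", "method", "outcome"):
                    if col not in header:
                        raise mio.SchemaError(
                            f"{path}: missing mandatory column {col!r}"
                        )
                continue
            row = dict(zip(header, parts))
            outcomes.append(
                ValidationOutcome(
                    bait_id=mio.normalize_id(row["bait_id"]),
                    prey_id=mio.normalize_id(row["prey_id"]),
                    method=row["method"].strip(),
                    outcome=row["outcome"].strip(),
                )
            )
    return outcomes


def validation_summary(
    outcomes: Sequence[ValidationOutcome],
    scopes: Mapping[str, frozenset] | None = None,
) -> list[dict]:
    """Success-rate table over validation attempts.

    Returns rows (scope, n_tested, n_validated, rate_percent) for the
    ``overall`` scope (validated by >= 1 method), each method present in the
    data, and any user-defined scope (name → set of methods). ``rate_percent``
    is rounded to one decimal. Duplicate (interaction, method) rows are an
    error; untestable attempts are dropped before any counting.
    """
    seen = set()
    for o in outcomes:
        key = (o.bait_id, o.prey_id, o.method)
        if key in seen:
            raise MythpipeError(
                f"duplicate validation attempt {key}"
            )
        seen.add(key)
    testable = [o for o in outcomes if o.outcome != "untestable"]

    def _rate(subset: Sequence[ValidationOutcome]) -> dict:
        by_pair: dict = {}
        for o in subset:
            by_pair.setdefault((o.bait_id, o.prey_id), []).append(o.outcome)
        n_tested = len(by_pair)
        n_validated = sum(
            1 for outs in by_pair.values() if "validated" in outs
        )
        rate = round(100.0 * n_validated / n_tested, 1) if n_tested else 0.0
        return {"n_tested": n_tested, "n_validated": n_validated,
                "rate_percent": rate}

    rows = [{"scope": "overall", **_rate(testable)}]
    for method in sorted({o.method for o in outcomes}):
        rows.append(
            {"scope": method,
             **_rate([o for o in testable if o.method == method])}
        )
    for name, methods in (scopes or {}).items():
        rows.append(
            {"scope": name,
             **_rate([o for o in testable if o.method in set(methods)])}
        )
    return rows


VALIDATION_SCHEMA = ["scope", "n_tested", "n_validated", "rate_percent"]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str = "mythpipe_run"
    seed: int = 0
    # synthetic mode (used when interactions_path is None)
    synthetic: SyntheticConfig | None = None
    # real-data mode inputs
    interactions_path: str | None = None
    go_annotations_path: str | None = None
    domain_annotations_path: str | None = None
    category_annotations_path: str | None = None
    reference_edges_path: str | None = None
    validation_outcomes_path: str | None = None
    proteome_size: int | None = None
    background_size: int | None = None
    min_K: int = 1
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    run_filter: bool = True
    run_enrich: bool = True
    run_domain_pairs: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        filt = raw.pop("filter_config", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = SyntheticConfig(**synth)
        if filt is not None:
            cfg.filter_config = FilterConfig(
                contaminant_terms=frozenset(
                    filt.get("contaminant_terms", FilterConfig().contaminant_terms)
                ),
                contaminant_keywords=tuple(
                    filt.get("contaminant_keywords",
                             FilterConfig().contaminant_keywords)
                ),
                contaminant_proteins=frozenset(
                    filt.get("contaminant_proteins", ())
                ),
                membrane_terms=frozenset(
                    filt.get("membrane_terms", FilterConfig().membrane_terms)
                ),
            )
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_reference_edges(path) -> list[tuple]:
    edges = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = [mio.normalize_id(p) for p in line.rstrip("\r\n").split("\t")]
            if header is None and parts[:2] == ["PROTEIN_A", "PROTEIN_B"]:
                header = parts
                continue
            if len(parts) < 2:
                continue
            edges.append((parts[0], parts[1]))
    return edges


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Any stage failure removes partial outputs and re-raises with the stage
    name. Identical config + seed produce byte-identical directories.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    stage = "setup"
    try:
        # --- simulate or load -------------------------------------------
        if config.interactions_path is None:
            stage = "simulate"
            synth = config.synthetic or SyntheticConfig(seed=config.seed)
            if config.synthetic is None:
                synth.seed = config.seed
            world, raw_records = simulate_screen(synth)
            go_table = world.go_annotations
            domain_table = world.domain_annotations
            cat_table = world.category_annotations
            proteome_size = synth.proteome_size
            bait_universe = set(world.truth.bait_ids)
            mio.write_table(
                mio.interactions_to_rows(raw_records),
                out / "interactions.tsv",
                mio.INTERACTION_SCHEMA,
            )
            _write_annotations(domain_table, out / "annotations_interpro.tsv")
            _write_annotations(go_table, out / "annotations_go.tsv")
            _write_annotations(cat_table, out / "annotations_disease.tsv")
            _write_truth(world.truth, out / "truth.tsv")
            manifest["stages"]["simulate"] = {
                "raw_hits": len(raw_records),
                "contaminant_preys": len(world.truth.contaminant_prey_ids),
                "duplicate_rows": world.truth.n_duplicate_rows,
            }
        else:
            stage = "load"
            raw_records = mio.read_interactions(config.interactions_path)
            go_table = (
                mio.read_annotations(config.go_annotations_path, "go")
                if config.go_annotations_path else None
            )
            domain_table = (
                mio.read_annotations(config.domain_annotations_path, "interpro")
                if config.domain_annotations_path else None
            )
            cat_table = (
                mio.read_annotations(config.category_annotations_path, "disease")
                if config.category_annotations_path else None
            )
            proteome_size = config.proteome_size
            bait_universe = {r.bait_id for r in raw_records}
            manifest["stages"]["load"] = {"raw_hits": len(raw_records)}

        # --- filter ------------------------------------------------------
        stage = "filter"
        records = deduplicate_interactions(raw_records)
        n_dedup = len(records)
        removed: list = []
        if config.run_filter:
            if go_table is None:
                raise ConfigurationError(
                    "filter stage requires GO annotations"
                )
            records, removed = remove_contaminant_preys(
                records, go_table, config.filter_config
            )
        if config.reference_edges_path:
            records = flag_known_interactions(
                records, _read_reference_edges(config.reference_edges_path)
            )
        membrane_map = {}
        if go_table is not None:
            proteins = sorted(
                {r.bait_id for r in records} | {r.prey_id for r in records}
            )
            membrane_map = annotate_membrane_localization(
                proteins, go_table, config.filter_config
            )
        summary = summarize_interactome(
            records, membrane_map, n_removed_contaminant=len(removed)
        )
        mio.write_table(
            mio.interactions_to_rows(records), out / "kept.tsv",
            mio.INTERACTION_SCHEMA,
        )
        mio.write_table(
            mio.interactions_to_rows(removed), out / "removed.tsv",
            mio.INTERACTION_SCHEMA,
        )
        mio.write_table(
            [summary.__dict__], out / "summary.tsv",
            list(summary.__dict__),
        )
        manifest["stages"]["filter"] = {
            "deduplicated": n_dedup,
            "kept": len(records),
            "removed_contaminant": len(removed),
        }

        # --- enrich ------------------------------------------------------
        if config.run_enrich and cat_table is not None:
            stage = "enrich"
            preys = {r.prey_id for r in records}
            background = BackgroundSpec.from_annotations(
                cat_table,
                population_size=(
                    config.background_size or proteome_size
                    or len(cat_table.protein_to_terms)
                ),
            )
            results = enrich_terms(preys, cat_table, background,
                                   min_K=config.min_K)
            mio.write_table(
                [r.__dict__ for r in results],
                out / "enrichment_disease.tsv", ENRICHMENT_SCHEMA,
            )
            manifest["stages"]["enrich"] = {"tested_terms": len(results)}

        # --- domain pairs -------------------------------------------------
        if config.run_domain_pairs and domain_table is not None:
            stage = "domain_pairs"
            if not proteome_size:
                raise ConfigurationError(
                    "domain-pair stage requires proteome_size"
                )
            pairs = domain_pair_analysis(
                records, bait_universe, domain_table, proteome_size
            )
            mio.write_table(
                domain_pairs_to_rows(pairs),
                out / "domain_pairs.tsv", DOMAIN_PAIR_SCHEMA,
            )
            manifest["stages"]["domain_pairs"] = {"tested_pairs": len(pairs)}

        # --- summarize ----------------------------------------------------
        if config.validation_outcomes_path:
            stage = "summarize"
            outcomes = read_validation_outcomes(config.validation_outcomes_path)
            rows = validation_summary(
                outcomes, scopes={"coip": frozenset({"coip_flag", "coip_native"})}
            )
            mio.write_table(rows, out / "validation_summary.tsv",
                            VALIDATION_SCHEMA)
            manifest["stages"]["summarize"] = {"scopes": len(rows)}

        stage = "manifest"
        for f in sorted(out.glob("*.tsv")):
            manifest["files"][f.name] = {
                "sha256": _sha256(f),
                "rows": sum(1 for _ in open(f, encoding="utf-8")) - 1,
            }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise MythpipeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _write_annotations(table, path) -> None:
    rows = [
        {"protein_id": p, "term_id": t, "term_name": table.term_names.get(t, t)}
        for p in sorted(table.protein_to_terms)
        for t in sorted(table.protein_to_terms[p])
    ]
    mio.write_table(rows, path, ["protein_id", "term_id", "term_name"])


def _write_truth(truth, path) -> None:
    rows = [
        {"key": "bait_ids", "value": ",".join(truth.bait_ids)},
        {"key": "contaminant_prey_ids",
         "value": ",".join(truth.contaminant_prey_ids)},
        {"key": "planted_bait_carriers",
         "value": ",".join(truth.planted_bait_carriers)},
        {"key": "planted_prey_carriers",
         "value": ",".join(truth.planted_prey_carriers)},
        {"key": "planted_pair_edges",
         "value": ";".join(f"{b}|{p}" for b, p in truth.planted_pair_edges)},
        {"key": "contaminant_edges",
         "value": ";".join(f"{b}|{p}" for b, p in truth.contaminant_edges)},
        {"key": "n_duplicate_rows", "value": str(truth.n_duplicate_rows)},
        {"key": "seed", "value": str(truth.config.seed)},
    ]
    mio.write_table(rows, path, ["key", "value"])
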