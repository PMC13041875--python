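"""End-to-end orchestration: ingest → map → regions → agree → stats → enrich.

A single YAML-serializable :class:`RunConfig` drives the whole workflow.
Each stage writes its artifact into the output directory and contributes
counters to a run report (record counts, skip counts, per-source
unmapped tallies, artifact checksums); identical config + seed yields
byte-identical artifacts and an identical report.  Stage summaries are
logged as JSON lines on stderr so runs are machine-checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from collections import Counter
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import (
    aggregation_stats, agreement_core, annotation_io, enrichment,
    id_mapping, region_classification, synthetic_data,
)
from .agreement_core import COMBINED, Strategy, strategy_grid

logger = logging.getLogger("annoconcord")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input path."""


class RunConfig(BaseModel):
    """Everything one pipeline run needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    table: Optional[str] = None
    schema_file: Optional[str] = None
    crosswalk: Optional[str] = None
    gmt: Optional[str] = None
    tools: list[str] = Field(default_factory=lambda: list(agreement_core.TOOLS))
    gene_models: list[str] = Field(
        default_factory=lambda: list(agreement_core.GENE_MODELS)
    )
    region_reference_model: str = "Ensembl"
    strategies: Optional[list[list[str]]] = None  # [tool, model] pairs
    seed: int = 0
    sim: dict[str, Any] = Field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def resolve_strategies(self) -> list[Strategy]:
        if self.strategies is None:
            return list(strategy_grid(self.tools, self.gene_models))
        valid_tools = set(self.tools) | {COMBINED}
        valid_models = set(self.gene_models) | {COMBINED}
        out = []
        for entry in self.strategies:
            if len(entry) != 2 or entry[0] not in valid_tools or \
                    entry[1] not in valid_models:
                raise ValueError(f"undefined strategy {entry!r}")
            out.append(Strategy(entry[0], entry[1]))
        return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log_stage(stage: str, **fields: Any) -> None:
    logger.info("%s", json.dumps({"stage": stage, **fields}, sort_keys=True))


def simulate_inputs(config: RunConfig) -> dict[str, Path]:
    """Generate table, schema, crosswalk and GMT artifacts from `config.sim`."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = synthetic_data.SimConfig(
        tools=tuple(config.tools),
        gene_models=tuple(config.gene_models),
        seed=config.seed,
        **config.sim,
    )
    records = synthetic_data.generate_annotation_table(sim)
    table_path = out / "table.tsv"
    schema = synthetic_data.write_wide_table(records, table_path)
    schema_path = out / "schema.yaml"
    schema.to_yaml(schema_path)
    xwalk = synthetic_data.generate_id_map(
        sim.universe_size, sim.frac_deprecated, sim.frac_noncoding, seed=sim.seed
    )
    xwalk_path = out / "crosswalk.tsv"
    id_mapping.write_crosswalk(xwalk, xwalk_path)
    db, _query = synthetic_data.generate_pathway_db(
        n_pathways=25,
        pathway_size=max(10, sim.universe_size // 100),
        reference_size=sim.universe_size,
        planted=0,
        planted_overlap=0,
        seed=sim.seed,
    )
    gmt_path = out / "pathways.gmt"
    enrichment.write_gmt(db, gmt_path)
    _log_stage("simulate", n_variants=len(records),
               table=str(table_path), crosswalk=str(xwalk_path))
    return {
        "table": table_path, "schema": schema_path,
        "crosswalk": xwalk_path, "gmt": gmt_path,
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    strategies = config.resolve_strategies()  # fail fast on bad names
    report: dict[str, Any] = {"seed": config.seed, "stages": {}, "checksums": {}}

    if config.table is None:
        paths = simulate_inputs(config)
    else:
        paths = {
            "table": Path(config.table),
            "schema": Path(config.schema_file) if config.schema_file else None,
            "crosswalk": Path(config.crosswalk) if config.crosswalk else None,
            "gmt": Path(config.gmt) if config.gmt else None,
        }

    # ingest -----------------------------------------------------------------
    stage = "ingest"
    try:
        schema = (
            annotation_io.TableSchema.from_yaml(paths["schema"])
            if paths["schema"] is not None
            else synthetic_data.default_schema(config.tools, config.gene_models)
        )
        records, read_report = annotation_io.read_annotation_table(
            paths["table"], schema
        )
        long_df = annotation_io.write_long_format(records, out / "long.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"{stage} failed on {paths['table']}: {exc}") from exc
    report["stages"][stage] = {
        "n_rows": read_report.n_rows,
        "n_records": read_report.n_records,
        "n_skipped": read_report.n_skipped,
        "n_long_rows": int(len(long_df)),
    }
    _log_stage(stage, **report["stages"][stage])

    # map --------------------------------------------------------------------
    stage = "map"
    try:
        if paths["crosswalk"] is None:
            raise ValueError("no crosswalk configured")
        xwalk = id_mapping.load_crosswalk(paths["crosswalk"])
        per_variant_genes = {
            rec.variant_id: rec.gene_calls for rec in records
        }
        counters: dict[str, Counter] = {}
        per_variant = id_mapping.map_long_frame(per_variant_genes, xwalk, counters)
        prot_rows = [
            (vid, tool, model, acc)
            for vid, srcs in per_variant.items()
            for (tool, model), accs in srcs.items()
            for acc in sorted(accs)
        ]
        prot_df = pd.DataFrame(
            prot_rows, columns=["variant_id", "tool", "gene_model", "accession"]
        ).sort_values(["variant_id", "tool", "gene_model", "accession"],
                      kind="mergesort")
        prot_df.to_csv(out / "proteins.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"{stage} failed on {paths['crosswalk']}: {exc}") from exc
    report["stages"][stage] = {
        "n_protein_rows": int(len(prot_df)),
        "unmapped_by_source": {
            k: dict(v) for k, v in sorted(counters.items())
        },
    }
    _log_stage(stage, **report["stages"][stage])

    # regions ----------------------------------------------------------------
    stage = "regions"
    try:
        labels = region_classification.classify_regions(
            records, config.gene_models
        )
        std = region_classification.standardize_regions(
            labels, config.region_reference_model
        )
        region_rows = [
            (vid, model, lab.region)
            for model in config.gene_models
            for vid, lab in sorted(labels[model].items())
        ] + [(vid, "standardized", reg) for vid, reg in sorted(std.items())]
        region_df = pd.DataFrame(
            region_rows, columns=["variant_id", "gene_model", "region"]
        )
        region_df.to_csv(out / "regions.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"{stage} failed: {exc}") from exc
    counts = region_df[region_df["gene_model"] == "standardized"][
        "region"].value_counts().to_dict()
    report["stages"][stage] = {"standardized_counts": counts}
    _log_stage(stage, **report["stages"][stage])

    # agree ------------------------------------------------------------------
    stage = "agree"
    try:
        chrom_map = {rec.variant_id: rec.chrom for rec in records}
        cov = agreement_core.coverage_frame(
            per_variant, strategies, chrom=chrom_map, region=std,
            tools=config.tools, models=config.gene_models,
        )
        cov.to_csv(out / "agreement.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"{stage} failed: {exc}") from exc
    n_annotated = cov["variant_id"].nunique()
    report["stages"][stage] = {
        "n_annotated_variants": int(n_annotated),
        "n_unannotated_variants": int(len(records) - n_annotated),
        "n_coverage_rows": int(len(cov)),
    }
    _log_stage(stage, **report["stages"][stage])

    # stats ------------------------------------------------------------------
    stage = "stats"
    try:
        agg = aggregation_stats.aggregate_by_chromosome(cov)
        agg.to_csv(out / "chrom_aggregates.tsv", sep="\t", index=False)
        comparisons = aggregation_stats.pairwise_grid(agg)
        comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        cov_table = aggregation_stats.coverage_table(cov)
        cov_table.to_csv(out / "coverage_table.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"{stage} failed: {exc}") from exc
    report["stages"][stage] = {
        "n_comparisons": int(len(comparisons)),
        "n_strategies": len(strategies),
    }
    _log_stage(stage, **report["stages"][stage])

    # enrich -----------------------------------------------------------------
    stage = "enrich"
    if paths["gmt"] is not None:
        try:
            db = enrichment.read_gmt(paths["gmt"])
            queries = {
                s.label: frozenset().union(
                    *(
                        agreement_core.integrate(
                            s, srcs, config.tools, config.gene_models
                        )
                        for srcs in per_variant.values()
                        if srcs
                    )
                ) & db.background
                for s in strategies
            }
            queries = {k: v for k, v in queries.items() if v}
            full_label = Strategy.full().label
            if len(queries) >= 2 and full_label in queries:
                matrix, summary = enrichment.compare_strategies(
                    queries, db, full_strategy=full_label
                )
                matrix.to_csv(out / "enrichment_matrix.tsv", sep="\t",
                              index=False)
                summary.to_csv(out / "enrichment_summary.tsv", sep="\t",
                               index=False)
                report["stages"][stage] = {
                    "n_pathways": len(db.pathways),
                    "n_strategies_tested": len(queries),
                }
            else:
                report["stages"][stage] = {"skipped": "insufficient queries"}
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"{stage} failed on {paths['gmt']}: {exc}") from exc
        _log_stage(stage, **report["stages"][stage])

    for artifact in sorted(out.glob("*.tsv")) + sorted(out.glob("*.gmt")):
        report["checksums"][artifact.name] = _checksum(artifact)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
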