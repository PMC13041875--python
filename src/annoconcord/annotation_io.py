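"""Ingestion of per-variant annotation tables and the standardized long format.

Annotation platforms export one wide row per variant with a separate
gene-identifier column per tool and gene model (e.g. an "ANNOVAR Gene
ID" column next to an "ANNOVAR Closest Gene ID" column).  A YAML schema
maps those physical columns to logical (tool, gene_model, field_role)
sources, so exports from different platforms and synthetic tables share
one reader.  Downstream stages consume the *long* format: one row per
(variant, source, field role, gene identifier).

The parser is deliberately lenient: malformed rows are skipped and
counted, unknown columns ignored, and missing-value markers produce
empty gene sets rather than errors.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

GENE = "gene"
CLOSEST_GENE = "closest_gene"
FIELD_ROLES = (GENE, CLOSEST_GENE)

# Namespaces a gene identifier can live in.
NS_SYMBOL = "symbol"
NS_ENTREZ = "entrez"
NS_ENSEMBL = "ensembl_gene"
NAMESPACES = (NS_SYMBOL, NS_ENTREZ, NS_ENSEMBL)

#: chromosome units 1-22 and X (23 matched units for statistics)
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

_DIST_SUFFIX = re.compile(r"\(dist=\d+\)\s*$")

SourceKey = tuple[str, str, str]  # (tool, gene_model, field_role)


class SchemaError(ValueError):
    """The declared schema does not match the physical table."""


class DuplicateVariantError(ValueError):
    """Two rows share one variant_id."""


@dataclass(frozen=True)
class GeneFieldDialect:
    """Separator/missing-value conventions of one export's gene columns."""

    separators: tuple[str, ...] = (";", ",")
    missing: frozenset[str] = frozenset({".", "", "NA", "-"})

    def split(self, raw: str) -> list[str]:
        pattern = "|".join(re.escape(s) for s in self.separators)
        return re.split(pattern, raw)


DEFAULT_DIALECT = GeneFieldDialect()


def parse_gene_field(
    raw: str | float | None,
    dialect: GeneFieldDialect = DEFAULT_DIALECT,
    namespace: str = NS_SYMBOL,
) -> frozenset[tuple[str, str]]:
    """Parse one raw gene cell into a set of (namespace, identifier) pairs.

    Deduplicates, strips surrounding whitespace and trailing
    ``(dist=N)`` suffixes, and maps missing-value markers to the empty
    set.  Never raises on content.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return frozenset()
    text = str(raw).strip()
    if text in dialect.missing:
        return frozenset()
    out = set()
    for token in dialect.split(text):
        token = _DIST_SUFFIX.sub("", token.strip()).strip()
        if token and token not in dialect.missing:
            out.add((namespace, token))
    return frozenset(out)


@dataclass(frozen=True)
class SourceSpec:
    """Schema entry tying one (tool, gene_model) to its physical columns."""

    tool: str
    gene_model: str
    gene_column: str
    closest_gene_column: str | None = None
    namespace: str = NS_SYMBOL

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise SchemaError(f"unknown namespace {self.namespace!r}")


@dataclass(frozen=True)
class TableSchema:
    """Column map for a wide annotation table."""

    sources: tuple[SourceSpec, ...]
    chrom_column: str = "chrom"
    pos_column: str = "pos"
    ref_column: str = "ref"
    alt_column: str = "alt"
    id_column: str | None = "variant_id"
    dialect: GeneFieldDialect = DEFAULT_DIALECT
    chromosomes: tuple[str, ...] = CHROMOSOMES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableSchema":
        doc = yaml.safe_load(Path(path).read_text())
        sources = tuple(
            SourceSpec(
                tool=s["tool"],
                gene_model=s["gene_model"],
                gene_column=s["gene"],
                closest_gene_column=s.get("closest_gene"),
                namespace=s.get("namespace", NS_SYMBOL),
            )
            for s in doc["sources"]
        )
        dialect = GeneFieldDialect(
            separators=tuple(doc.get("separators", [";", ","])),
            missing=frozenset(doc.get("missing", [".", "", "NA", "-"])),
        )
        return cls(
            sources=sources,
            chrom_column=doc.get("chrom", "chrom"),
            pos_column=doc.get("pos", "pos"),
            ref_column=doc.get("ref", "ref"),
            alt_column=doc.get("alt", "alt"),
            id_column=doc.get("variant_id", "variant_id"),
            dialect=dialect,
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "chrom": self.chrom_column,
            "pos": self.pos_column,
            "ref": self.ref_column,
            "alt": self.alt_column,
            "variant_id": self.id_column,
            "separators": list(self.dialect.separators),
            "missing": sorted(self.dialect.missing),
            "sources": [
                {
                    "tool": s.tool,
                    "gene_model": s.gene_model,
                    "gene": s.gene_column,
                    "closest_gene": s.closest_gene_column,
                    "namespace": s.namespace,
                }
                for s in self.sources
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class VariantRecord:
    """One SNP with its raw and parsed per-source gene fields."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    raw_fields: dict[SourceKey, str] = field(default_factory=dict)
    gene_calls: dict[SourceKey, frozenset[tuple[str, str]]] = field(
        default_factory=dict
    )


@dataclass
class ReadReport:
    n_rows: int = 0
    n_records: int = 0
    n_skipped: int = 0
    skipped_rows: list[int] = field(default_factory=list)


def read_annotation_table(
    path: str | Path,
    schema: TableSchema,
) -> tuple[list[VariantRecord], ReadReport]:
    """Read a wide TSV into VariantRecords.

    Rows with malformed coordinates (non-integer position, chromosome
    outside the configured unit set) are skipped and counted in the
    report.  A missing declared column or a duplicate variant_id is an
    error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = [schema.chrom_column, schema.pos_column, schema.ref_column,
              schema.alt_column]
    for spec in schema.sources:
        needed.append(spec.gene_column)
        if spec.closest_gene_column:
            needed.append(spec.closest_gene_column)
    if schema.id_column and schema.id_column in df.columns:
        id_col: str | None = schema.id_column
    else:
        id_col = None
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"declared columns absent from table: {missing}")

    report = ReadReport(n_rows=len(df))
    records: list[VariantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        chrom = str(row_d[schema.chrom_column]).removeprefix("chr")
        pos_raw = str(row_d[schema.pos_column])
        if chrom not in schema.chromosomes or not pos_raw.isdigit():
            report.n_skipped += 1
            report.skipped_rows.append(i)
            continue
        pos = int(pos_raw)
        ref, alt = row_d[schema.ref_column], row_d[schema.alt_column]
        vid = row_d[id_col] if id_col else f"{chrom}:{pos}:{ref}:{alt}"
        if vid in seen:
            raise DuplicateVariantError(f"duplicate variant_id {vid!r} at row {i}")
        seen.add(vid)
        rec = VariantRecord(vid, chrom, pos, ref, alt)
        for spec in schema.sources:
            cols = [(GENE, spec.gene_column)]
            if spec.closest_gene_column:
                cols.append((CLOSEST_GENE, spec.closest_gene_column))
            for role, col in cols:
                key = (spec.tool, spec.gene_model, role)
                raw = row_d[col]
                rec.raw_fields[key] = raw
                rec.gene_calls[key] = parse_gene_field(
                    raw, schema.dialect, spec.namespace
                )
        records.append(rec)
    report.n_records = len(records)
    if report.n_skipped:
        logger.warning(
            "skipped %d of %d rows with malformed coordinates",
            report.n_skipped, report.n_rows,
        )
    return records, report


LONG_COLUMNS = (
    "variant_id", "chrom", "pos", "tool", "gene_model",
    "field_role", "namespace", "gene_id",
)


def to_long_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """One row per (variant, source, field role, gene id), stably sorted."""
    rows = []
    for rec in records:
        for (tool, model, role), ids in rec.gene_calls.items():
            for ns, gid in ids:
                rows.append((rec.variant_id, rec.chrom, rec.pos, tool, model,
                             role, ns, gid))
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    return df.sort_values(
        ["variant_id", "tool", "gene_model", "field_role", "gene_id"],
        kind="mergesort",
    ).reset_index(drop=True)


def write_long_format(
    records: Iterable[VariantRecord] | pd.DataFrame, path: str | Path
) -> pd.DataFrame:
    """Write the long-format TSV; returns the frame written."""
    df = records if isinstance(records, pd.DataFrame) else to_long_frame(records)
    df = df.sort_values(
        ["variant_id", "tool", "gene_model", "field_role", "gene_id"],
        kind="mergesort",
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_long_format(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in LONG_COLUMNS
                                            if c != "pos"})
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"long-format file missing columns: {missing}")
    return df


def gene_sets_from_long(
    df: pd.DataFrame,
) -> dict[str, dict[SourceKey, frozenset[tuple[str, str]]]]:
    """Group a long frame back into per-variant, per-source gene sets."""
    out: dict[str, dict[SourceKey, frozenset[tuple[str, str]]]] = {}
    for (vid, tool, model, role), grp in df.groupby(
        ["variant_id", "tool", "gene_model", "field_role"], sort=False
    ):
        out.setdefault(str(vid), {})[(str(tool), str(model), str(role))] = frozenset(
            zip(grp["namespace"], grp["gene_id"])
        )
    return out
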