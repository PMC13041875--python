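"""Gene-identifier to UniProt crosswalk.

Protein-level comparison requires a common currency.  An HGNC-style
crosswalk table links gene symbols, Entrez IDs and Ensembl gene IDs to
UniProt accessions; mapping enforces exactly one accession per gene (to
avoid inflation from transcript isoforms) and restricts to approved,
protein-coding genes.  Identifier routing follows the gene model that
produced the annotation: Ensembl-model identifiers resolve through the
Ensembl-gene-ID index, RefSeq-model identifiers through Entrez first
with a gene-symbol fallback.

Unmappable identifiers (e.g. deprecated Ensembl IDs absent from the
crosswalk) never abort a run: they are returned, tallied and excluded.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation_io import NS_ENSEMBL, NS_ENTREZ, NS_SYMBOL

logger = logging.getLogger(__name__)

CROSSWALK_COLUMNS = (
    "symbol", "entrez_id", "ensembl_gene_id", "uniprot_accession",
    "locus_type", "status",
)

PROTEIN_CODING = "protein-coding gene"
APPROVED = "Approved"

#: index lookup order per gene model
MODEL_NAMESPACE_ORDER: dict[str, tuple[str, ...]] = {
    "Ensembl": (NS_ENSEMBL,),
    "RefSeq": (NS_ENTREZ, NS_SYMBOL),
}


class CrosswalkError(ValueError):
    """Structurally invalid crosswalk table."""


@dataclass(frozen=True)
class CrosswalkRow:
    symbol: str
    entrez_id: str
    ensembl_gene_id: str
    uniprot_accession: str | None
    locus_type: str
    status: str

    @property
    def is_coding(self) -> bool:
        return (
            self.locus_type == PROTEIN_CODING
            and self.status == APPROVED
            and bool(self.uniprot_accession)
        )


@dataclass
class IdMapTable:
    """Crosswalk with one lookup index per identifier namespace."""

    rows: list[CrosswalkRow]
    indices: dict[str, dict[str, CrosswalkRow]] = field(default_factory=dict)
    multi_accession_resolved: int = 0

    def __post_init__(self) -> None:
        if not self.indices:
            self.indices = {NS_SYMBOL: {}, NS_ENTREZ: {}, NS_ENSEMBL: {}}
            for row in self.rows:
                for ns, key in (
                    (NS_SYMBOL, row.symbol),
                    (NS_ENTREZ, row.entrez_id),
                    (NS_ENSEMBL, row.ensembl_gene_id),
                ):
                    if not key:
                        continue
                    if key in self.indices[ns]:
                        raise CrosswalkError(
                            f"duplicate {ns} key {key!r} in crosswalk"
                        )
                    self.indices[ns][key] = row

    def lookup(self, namespace: str, identifier: str) -> CrosswalkRow | None:
        return self.indices[namespace].get(identifier)


def _resolve_accession(cell: str) -> tuple[str | None, bool]:
    """Collapse a possibly multi-valued accession cell to one accession.

    Tie-break: lexicographically smallest accession.  Returns the
    accession (or None for an empty cell) and whether a tie-break fired.
    """
    parts = sorted(p.strip() for p in str(cell).split(";") if p.strip())
    if not parts:
        return None, False
    if len(parts) > 1:
        return parts[0], True
    return parts[0], False


def load_crosswalk(path: str | Path) -> IdMapTable:
    """Load a crosswalk TSV and build the three namespace indices.

    Multi-accession cells are resolved to the lexicographically smallest
    accession (logged); duplicate keys within a namespace are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CROSSWALK_COLUMNS if c not in df.columns]
    if missing:
        raise CrosswalkError(f"crosswalk missing required columns: {missing}")
    rows: list[CrosswalkRow] = []
    n_resolved = 0
    for r in df.itertuples(index=False):
        acc, tied = _resolve_accession(getattr(r, "uniprot_accession"))
        if tied:
            n_resolved += 1
            logger.warning(
                "multi-accession cell for %s resolved to %s",
                getattr(r, "symbol"), acc,
            )
        rows.append(
            CrosswalkRow(
                symbol=getattr(r, "symbol"),
                entrez_id=getattr(r, "entrez_id"),
                ensembl_gene_id=getattr(r, "ensembl_gene_id"),
                uniprot_accession=acc,
                locus_type=getattr(r, "locus_type"),
                status=getattr(r, "status"),
            )
        )
    table = IdMapTable(rows=rows)
    table.multi_accession_resolved = n_resolved
    return table


def write_crosswalk(table: IdMapTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.symbol, r.entrez_id, r.ensembl_gene_id,
             r.uniprot_accession or "", r.locus_type, r.status)
            for r in table.rows
        ],
        columns=CROSSWALK_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ProteinSet:
    """UniProt accessions attributed to one variant by one source."""

    variant_id: str
    source: str
    accessions: frozenset[str]


def map_genes_to_uniprot(
    gene_ids: Iterable[tuple[str, str]],
    gene_model: str,
    table: IdMapTable,
    counters: Counter | None = None,
) -> tuple[frozenset[str], frozenset[tuple[str, str]]]:
    """Map namespaced gene identifiers to accessions under one gene model.

    Returns ``(accessions, unmapped)``.  Identifiers found in the
    crosswalk but non-protein-coding or accession-less are excluded
    (tallied under ``excluded_noncoding``), not reported as unmapped;
    unmapped means absent from every index the model consults.
    """
    if gene_model not in MODEL_NAMESPACE_ORDER:
        raise ValueError(
            f"unknown gene model {gene_model!r}; "
            f"expected one of {sorted(MODEL_NAMESPACE_ORDER)}"
        )
    order = MODEL_NAMESPACE_ORDER[gene_model]
    accessions: set[str] = set()
    unmapped: set[tuple[str, str]] = set()
    for ns, gid in gene_ids:
        row = None
        for try_ns in order:
            row = table.lookup(try_ns, gid)
            if row is not None:
                break
        if row is None:
            unmapped.add((ns, gid))
            if counters is not None:
                counters["unmapped"] += 1
            continue
        if not row.is_coding:
            if counters is not None:
                counters["excluded_noncoding"] += 1
            continue
        if row.uniprot_accession in accessions and counters is not None:
            counters["shared_accession_collapsed"] += 1
        accessions.add(row.uniprot_accession)
    return frozenset(accessions), frozenset(unmapped)


def map_long_frame(
    per_variant_genes: Mapping[str, Mapping[tuple[str, str, str],
                                            frozenset[tuple[str, str]]]],
    table: IdMapTable,
    counters_by_source: dict[str, Counter] | None = None,
) -> dict[str, dict[tuple[str, str], frozenset[str]]]:
    """Map every (variant, tool, gene model) gene set to a protein set.

    Gene- and closest-gene-role identifiers are pooled per source: a
    source's protein set for a variant is everything it attributed to
    that variant, regardless of which field carried it.
    """
    out: dict[str, dict[tuple[str, str], frozenset[str]]] = {}
    for vid, calls in per_variant_genes.items():
        per_source: dict[tuple[str, str], set[str]] = {}
        for (tool, model, _role), gene_ids in calls.items():
            acc, _unmapped = map_genes_to_uniprot(
                gene_ids,
                model,
                table,
                counters=(
                    counters_by_source.setdefault(f"{tool}|{model}", Counter())
                    if counters_by_source is not None
                    else None
                ),
            )
            per_source.setdefault((tool, model), set()).update(acc)
        out[vid] = {k: frozenset(v) for k, v in per_source.items()}
    return out
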