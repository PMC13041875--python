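"""Synthetic annotation tables, crosswalks and pathway databases.

Every downstream stage is testable without the multi-million-SNP
external resources the method was developed on.  The generator emulates
their *structure*:

* per-SNP gene-set outputs from three tools under two gene models, where
  each variant's sets realize an agreement category drawn from a
  configurable mixture (planting is the exact inverse of the
  classifier, so ``classify(plant(label)) == label``);
* tool-native intergenic behavior — VEP's sets are emptied with a
  configurable probability on intergenic variants, mimicking its
  near-absent nearest-gene assignment there;
* an HGNC-style crosswalk containing deprecated entries (absent rows)
  and non-protein-coding entries (rows without an accession);
* chromosome assignments over units 1–22 and X;
* GMT pathway databases with a planted enriched pathway.

Gene identifiers are opaque strings with per-namespace prefixes
(``GENE7`` / ``100006`` / ``ENSG00000000007``) so identifier-namespace
routing is genuinely exercised.  Positions are arbitrary integers; no
linkage structure or allele-frequency realism is attempted.  A single
seeded generator is threaded through all draws: a fixed seed yields
byte-identical artifacts.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement_core import (
    FULL, GENE_MODELS, NONE, PARTIAL, TOOLS, classify_tool_pattern,
    tool_category_labels,
)
from .annotation_io import (
    CHROMOSOMES, CLOSEST_GENE, GENE, NS_ENSEMBL, NS_ENTREZ,
    SourceSpec, TableSchema, VariantRecord,
)
from .enrichment import PathwayDB
from .id_mapping import APPROVED, PROTEIN_CODING, CrosswalkRow, IdMapTable


class ConfigurationError(ValueError):
    """Invalid or unrealizable simulation configuration."""


# --- deterministic gene-universe naming ------------------------------------

def gene_symbol(i: int) -> str:
    return f"GENE{i + 1}"


def gene_entrez(i: int) -> str:
    return str(100000 + i + 1)


def gene_ensembl(i: int) -> str:
    return f"ENSG{i + 1:011d}"


def gene_uniprot(i: int) -> str:
    return f"P{i + 1:05d}"


MODEL_NAMESPACE = {"Ensembl": NS_ENSEMBL, "RefSeq": NS_ENTREZ}
_MODEL_NAMER = {"Ensembl": gene_ensembl, "RefSeq": gene_entrez}

# Default category mixture: dominated by three-tool exact matches, with
# ANNOVAR–SnpEff-only agreement as the second mode and a thin tail of
# subset/no-full patterns — the genome-wide shape observed under Ensembl.
DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "Exact Match": 0.699,
    "ANNOVAR and SnpEff": 0.230,
    "SnpEff": 0.040,
    "ANNOVAR and SnpEff; VEP subset": 0.021,
    "No full match; ANNOVAR subset; SnpEff subset; VEP subset": 0.010,
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic annotation table.

    Defaults mirror the observed structure of real multi-tool output:
    ~61.5% genic variants, a category mixture led by exact three-tool
    agreement, and near-total VEP dropout on intergenic variants.
    """

    n_variants: int = 1000
    n_chromosomes: int = 23
    tools: tuple[str, ...] = TOOLS
    gene_models: tuple[str, ...] = GENE_MODELS
    class_mixture: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    genic_fraction: float = 0.615
    vep_intergenic_dropout: float = 0.95
    universe_size: int = 5000
    max_ref_size: int = 3  # cap on per-variant reference-set size (multi-gene SNPs)
    frac_deprecated: float = 0.02
    frac_noncoding: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants <= 0:
            raise ConfigurationError("n_variants must be positive")
        if not 1 <= self.n_chromosomes <= 23:
            raise ConfigurationError("n_chromosomes must be in [1, 23]")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_mixture probabilities sum to {total}, not 1"
            )
        if any(p < 0 for p in self.class_mixture.values()):
            raise ConfigurationError("class_mixture probabilities must be >= 0")
        realizable = set(tool_category_labels(self.tools))
        bad = [lab for lab in self.class_mixture if lab not in realizable]
        if bad:
            raise ConfigurationError(
                f"unrealizable categories in class_mixture: {bad}"
            )
        for name in ("genic_fraction", "vep_intergenic_dropout",
                     "frac_deprecated", "frac_noncoding"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.universe_size < 3:
            raise ConfigurationError(
                "universe_size too small: planting category "
                f"{next(iter(self.class_mixture))!r} needs >= 3 genes"
            )
        if self.max_ref_size < 3:
            raise ConfigurationError("max_ref_size must be >= 3")


# --- agreement-class planting ----------------------------------------------

def _label_status_map(tools: Sequence[str]) -> dict[str, tuple[str, ...]]:
    import itertools

    out = {}
    for combo in itertools.product((FULL, PARTIAL, NONE), repeat=len(tools)):
        nonempty = [s for s in combo if s != NONE]
        if not nonempty or (len(nonempty) == 1 and nonempty[0] == PARTIAL):
            continue
        out[classify_tool_pattern(dict(zip(tools, combo)))] = combo
    return out


def plant_agreement_class(
    label: str,
    universe: Sequence,
    rng: np.random.Generator,
    tools: Sequence[str] = TOOLS,
    max_ref_size: int = 3,
) -> dict[str, frozenset]:
    """Construct per-tool gene sets whose classification is exactly `label`.

    The inverse of the agreement classifier under the identity protein
    mapping: full tools receive the whole reference set, partial tools a
    random proper nonempty subset, and the no-full patterns are realized
    by leave-one-out subsets whose union restores the reference.
    """
    status_map = _label_status_map(tools)
    if label not in status_map:
        raise ConfigurationError(
            f"unrealizable category {label!r}; realizable labels: "
            f"{sorted(status_map)}"
        )
    if len(universe) < 3:
        raise ConfigurationError(
            f"universe too small ({len(universe)} genes) to plant {label!r}"
        )
    statuses = status_map[label]
    n_full = statuses.count(FULL)
    n_partial = statuses.count(PARTIAL)

    if n_full:
        lo = 2 if n_partial else 1
        size = int(rng.integers(lo, max(min(max_ref_size, len(universe)), lo) + 1))
        ref = [universe[j] for j in rng.choice(len(universe), size, replace=False)]
        out: dict[str, frozenset] = {}
        for tool, st in zip(tools, statuses):
            if st == FULL:
                out[tool] = frozenset(ref)
            elif st == NONE:
                out[tool] = frozenset()
            else:
                k = int(rng.integers(1, size))
                out[tool] = frozenset(
                    ref[j] for j in rng.choice(size, k, replace=False)
                )
        return out

    # No tool recovers the full union: give each partial tool the
    # reference minus one distinct element (proper, nonempty, union = ref).
    size = max(n_partial, 2)
    ref = [universe[j] for j in rng.choice(len(universe), size, replace=False)]
    out = {}
    drop = iter(range(size))
    for tool, st in zip(tools, statuses):
        if st == NONE:
            out[tool] = frozenset()
        else:
            j = next(drop)
            out[tool] = frozenset(ref[:j] + ref[j + 1:])
    return out


# --- annotation-table generation -------------------------------------------

def generate_annotation_table(config: SimConfig) -> list[VariantRecord]:
    """Draw a full synthetic annotation table under the given conditions.

    Per variant: a chromosome uniform over the configured units, a
    genic/intergenic status from ``genic_fraction``, an agreement
    category from ``class_mixture``, and per-model planted gene sets
    realizing that category (independently sampled genes per model).
    Gene identifiers land in the gene-role field for genic variants and
    the closest-gene-role field for intergenic ones; intergenic VEP
    sets are emptied with probability ``vep_intergenic_dropout``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = CHROMOSOMES[: config.n_chromosomes]
    labels = list(config.class_mixture)
    probs = np.array([config.class_mixture[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    universe = np.arange(config.universe_size)
    alphabet = np.array(list("ACGT"))

    records: list[VariantRecord] = []
    used: set[tuple[str, int]] = set()
    for _ in range(config.n_variants):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, 250_000_000))
        while (chrom, pos) in used:
            pos = int(rng.integers(1, 250_000_000))
        used.add((chrom, pos))
        ref_a, alt_a = alphabet[rng.choice(4, 2, replace=False)]
        label = labels[int(rng.choice(len(labels), p=probs))]
        genic = bool(rng.random() < config.genic_fraction)
        vep_drop = (not genic) and bool(
            rng.random() < config.vep_intergenic_dropout
        )

        rec = VariantRecord(
            variant_id=f"{chrom}:{pos}:{ref_a}:{alt_a}",
            chrom=chrom, pos=pos, ref=str(ref_a), alt=str(alt_a),
        )
        role, empty_role = (GENE, CLOSEST_GENE) if genic else (CLOSEST_GENE, GENE)
        for model in config.gene_models:
            planted = plant_agreement_class(
                label, universe, rng, config.tools, config.max_ref_size
            )
            ns = MODEL_NAMESPACE.get(model, NS_ENTREZ)
            namer = _MODEL_NAMER.get(model, gene_entrez)
            for tool in config.tools:
                genes = planted[tool]
                if vep_drop and tool == "VEP":
                    genes = frozenset()
                ids = frozenset((ns, namer(int(g))) for g in genes)
                rec.gene_calls[(tool, model, role)] = ids
                rec.gene_calls[(tool, model, empty_role)] = frozenset()
                rec.raw_fields[(tool, model, role)] = (
                    ";".join(sorted(i for _n, i in ids)) if ids else "."
                )
                rec.raw_fields[(tool, model, empty_role)] = "."
        records.append(rec)
    return records


def default_schema(
    tools: Sequence[str] = TOOLS, gene_models: Sequence[str] = GENE_MODELS
) -> TableSchema:
    """Schema matching the wide tables this module writes."""
    sources = tuple(
        SourceSpec(
            tool=t,
            gene_model=m,
            gene_column=f"{t}_{m}_gene",
            closest_gene_column=f"{t}_{m}_closest_gene",
            namespace=MODEL_NAMESPACE.get(m, NS_ENTREZ),
        )
        for t in tools
        for m in gene_models
    )
    return TableSchema(sources=sources)


def write_wide_table(
    records: Sequence[VariantRecord],
    path: str | Path,
    schema: TableSchema | None = None,
) -> TableSchema:
    """Serialize records to the wide TSV dialect the reader ingests."""
    if schema is None:
        tools = list(dict.fromkeys(t for (t, _m, _r) in records[0].gene_calls))
        models = list(dict.fromkeys(m for (_t, m, _r) in records[0].gene_calls))
        schema = default_schema(tools, models)
    rows = []
    for rec in records:
        row = {
            "variant_id": rec.variant_id,
            schema.chrom_column: rec.chrom,
            schema.pos_column: rec.pos,
            schema.ref_column: rec.ref,
            schema.alt_column: rec.alt,
        }
        for spec in schema.sources:
            for role, col in (
                (GENE, spec.gene_column),
                (CLOSEST_GENE, spec.closest_gene_column),
            ):
                if col is None:
                    continue
                raw = rec.raw_fields.get((spec.tool, spec.gene_model, role))
                if raw is None:
                    ids = rec.gene_calls.get((spec.tool, spec.gene_model, role),
                                             frozenset())
                    raw = ";".join(sorted(i for _n, i in ids)) if ids else "."
                row[col] = raw
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return schema


# --- crosswalk generation ---------------------------------------------------

def generate_id_map(
    n_genes: int,
    frac_deprecated: float = 0.0,
    frac_noncoding: float = 0.0,
    seed: int = 0,
) -> IdMapTable:
    """Synthetic HGNC-style crosswalk over the deterministic gene universe.

    ``round(frac_deprecated * n_genes)`` genes are dropped from the
    table entirely (deprecated identifiers resolve to nothing) and
    ``round(frac_noncoding * n_genes)`` are kept as pseudogene rows with
    no accession (excluded by the coding filter).  The chosen gene
    indices are recorded on the returned table as ``deprecated_genes``
    and ``noncoding_genes``.
    """
    if n_genes <= 0:
        raise ConfigurationError("n_genes must be positive")
    for name, v in (("frac_deprecated", frac_deprecated),
                    ("frac_noncoding", frac_noncoding)):
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1]")
    if frac_deprecated + frac_noncoding > 1.0:
        raise ConfigurationError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n_dep = round(frac_deprecated * n_genes)
    n_nc = round(frac_noncoding * n_genes)
    perm = rng.permutation(n_genes)
    deprecated = set(int(i) for i in perm[:n_dep])
    noncoding = set(int(i) for i in perm[n_dep : n_dep + n_nc])

    rows = []
    for i in range(n_genes):
        if i in deprecated:
            continue
        if i in noncoding:
            rows.append(CrosswalkRow(
                symbol=gene_symbol(i), entrez_id=gene_entrez(i),
                ensembl_gene_id=gene_ensembl(i), uniprot_accession=None,
                locus_type="pseudogene", status=APPROVED,
            ))
        else:
            rows.append(CrosswalkRow(
                symbol=gene_symbol(i), entrez_id=gene_entrez(i),
                ensembl_gene_id=gene_ensembl(i),
                uniprot_accession=gene_uniprot(i),
                locus_type=PROTEIN_CODING, status=APPROVED,
            ))
    table = IdMapTable(rows=rows)
    table.deprecated_genes = sorted(deprecated)  # type: ignore[attr-defined]
    table.noncoding_genes = sorted(noncoding)  # type: ignore[attr-defined]
    return table


# --- pathway-database generation --------------------------------------------

def generate_pathway_db(
    n_pathways: int,
    pathway_size: int,
    reference_size: int,
    planted: str | int,
    planted_overlap: int,
    seed: int = 0,
    query_size: int | None = None,
) -> tuple[PathwayDB, frozenset[str]]:
    """Pathway database plus a query sharing `planted_overlap` members
    with the planted pathway and only background-level overlap elsewhere.
    """
    if reference_size < pathway_size or n_pathways < 1:
        raise ConfigurationError("reference must be larger than a pathway")
    pid_of = lambda j: f"PW{j + 1:04d}"  # noqa: E731
    planted_id = pid_of(planted) if isinstance(planted, int) else planted
    if query_size is None:
        query_size = pathway_size
    if planted_overlap > min(pathway_size, query_size):
        raise ConfigurationError(
            f"planted_overlap {planted_overlap} exceeds "
            f"min(pathway_size={pathway_size}, query_size={query_size})"
        )
    rng = np.random.default_rng(seed)
    background = frozenset(gene_uniprot(i) for i in range(reference_size))
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for j in range(n_pathways):
        members = frozenset(
            gene_uniprot(int(i))
            for i in rng.choice(reference_size, pathway_size, replace=False)
        )
        pathways[pid_of(j)] = (f"synthetic pathway {j + 1}", members)
    if planted_id not in pathways:
        raise ConfigurationError(f"planted pathway {planted_id!r} not generated")
    members = sorted(pathways[planted_id][1])
    inside = [members[int(i)] for i in
              rng.choice(len(members), planted_overlap, replace=False)]
    outside_pool = sorted(background - pathways[planted_id][1])
    n_out = query_size - planted_overlap
    outside = [outside_pool[int(i)] for i in
               rng.choice(len(outside_pool), n_out, replace=False)]
    query = frozenset(inside) | frozenset(outside)
    return PathwayDB(pathways=pathways, background=background), query
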