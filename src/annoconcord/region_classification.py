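"""Genic/intergenic assignment from annotator field roles.

Region status is derived from ANNOVAR's output convention: a variant
inside gene boundaries carries identifiers in the gene-role field, one
outside carries its nearest gene in the closest-gene-role field.  No
interval arithmetic is done — the annotator's own field routing is the
evidence.  Because "genic" depends on gene-model boundaries, within-model
analyses use each model's native labels while cross-model comparisons
standardize every variant to a fixed reference model (Ensembl by
default) so that boundary differences are not conflated with tool
behavior.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from .annotation_io import CLOSEST_GENE, GENE, VariantRecord

GENIC = "genic"
INTERGENIC = "intergenic"
UNANNOTATED = "unannotated"
REGIONS = (GENIC, INTERGENIC, UNANNOTATED)

REGION_TOOL = "ANNOVAR"  # classification is ANNOVAR-based by design


class RegionConfigError(ValueError):
    """The source needed for region classification is absent."""


@dataclass(frozen=True)
class RegionLabel:
    variant_id: str
    gene_model: str
    region: str
    basis: str  # which field role carried the evidence


def classify_region(record: VariantRecord, gene_model: str) -> RegionLabel:
    """Genic if the gene-role field is populated; else intergenic if the
    closest-gene field is; else unannotated.

    When both fields are populated the genic call dominates (a nearest
    gene listed alongside a genic hit does not demote the variant).
    """
    gene_key = (REGION_TOOL, gene_model, GENE)
    closest_key = (REGION_TOOL, gene_model, CLOSEST_GENE)
    if gene_key not in record.gene_calls and closest_key not in record.gene_calls:
        raise RegionConfigError(
            f"no {REGION_TOOL} columns for gene model {gene_model!r}; "
            "region classification requires them"
        )
    if record.gene_calls.get(gene_key):
        return RegionLabel(record.variant_id, gene_model, GENIC, GENE)
    if record.gene_calls.get(closest_key):
        return RegionLabel(record.variant_id, gene_model, INTERGENIC, CLOSEST_GENE)
    return RegionLabel(record.variant_id, gene_model, UNANNOTATED, "none")


def classify_regions(
    records: Iterable[VariantRecord], gene_models: Iterable[str]
) -> dict[str, dict[str, RegionLabel]]:
    """Per-model labels for every record: {gene_model: {variant_id: label}}."""
    models = list(gene_models)
    out: dict[str, dict[str, RegionLabel]] = {m: {} for m in models}
    for rec in records:
        for m in models:
            out[m][rec.variant_id] = classify_region(rec, m)
    return out


def standardize_regions(
    labels_per_model: Mapping[str, Mapping[str, RegionLabel]],
    reference_model: str = "Ensembl",
) -> dict[str, str]:
    """Fixed-boundary region map for cross-model analyses.

    Every variant appearing under any model takes its *reference-model*
    region; variants missing from the reference model's labels are
    unannotated.  Within-model analyses keep native labels and never go
    through this function.
    """
    if reference_model not in labels_per_model:
        raise RegionConfigError(
            f"reference model {reference_model!r} has no region labels"
        )
    ref = labels_per_model[reference_model]
    all_variants = {
        vid for labels in labels_per_model.values() for vid in labels
    }
    return {
        vid: (ref[vid].region if vid in ref else UNANNOTATED)
        for vid in all_variants
    }


def native_regions(
    labels_per_model: Mapping[str, Mapping[str, RegionLabel]], gene_model: str
) -> dict[str, str]:
    """Native region map for within-model analyses."""
    return {vid: lab.region for vid, lab in labels_per_model[gene_model].items()}
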