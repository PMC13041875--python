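"""Per-SNP agreement against the union reference set.

Every comparison in this package happens at the protein level: each
annotation source (a tool under a gene model, or an integration strategy)
attributes a set of UniProt accessions to a variant, and the *union
reference set* — the union over all sources in scope — serves as the
pragmatic gold standard.  Against that reference a source is in

* ``full`` agreement when it recovers the complete reference set,
* ``partial`` agreement when it recovers a proper, nonempty subset,
* ``none`` when it recovers nothing.

The per-variant combination of statuses defines a qualitative category
(23 realizable categories for three tools, 7 for the two-gene-model
comparison), and the captured/total accession counts define quantitative
coverage.  Both views are computed here.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

# Canonical orderings used in every label and every output column.
TOOLS: tuple[str, ...] = ("ANNOVAR", "SnpEff", "VEP")
GENE_MODELS: tuple[str, ...] = ("Ensembl", "RefSeq")
COMBINED = "Combined"

FULL = "full"
PARTIAL = "partial"
NONE = "none"

EXACT_MATCH_LABEL = "Exact Match"
NO_FULL_PREFIX = "No full match"

# Gene-model-level category labels (7 realizable).
GM_EXACT = "Exact Match"
GM_REFSEQ_WITH_ENS_SUBSET = "RefSeq with Ensembl Subset"
GM_ENS_WITH_REFSEQ_SUBSET = "Ensembl with RefSeq Subset"
GM_REFSEQ_ONLY = "RefSeq only"
GM_ENSEMBL_ONLY = "Ensembl only"
GM_PARTIAL_OVERLAP = "Partial Overlap"
GM_FULLY_DISJOINT = "Fully Disjoint"

MODEL_CATEGORY_LABELS: tuple[str, ...] = (
    GM_EXACT,
    GM_REFSEQ_WITH_ENS_SUBSET,
    GM_ENS_WITH_REFSEQ_SUBSET,
    GM_REFSEQ_ONLY,
    GM_ENSEMBL_ONLY,
    GM_PARTIAL_OVERLAP,
    GM_FULLY_DISJOINT,
)


class ScopeMismatchError(ValueError):
    """A source set is not contained in the reference it is compared to."""


@dataclass(frozen=True)
class ReferenceSet:
    """Union of the in-scope sources' protein sets for one variant."""

    variant_id: str
    scope: tuple[str, ...]
    accessions: frozenset[str]


@dataclass
class AgreementResult:
    """Qualitative category plus per-source coverage for one variant."""

    variant_id: str
    category_label: str
    statuses: dict[str, str]  # source label -> full|partial|none
    coverage: dict[str, tuple[int, int]]  # source label -> (numerator, denominator)


def reference_set(
    per_source: Mapping[str, frozenset[str] | set[str]],
    variant_id: str = "",
) -> ReferenceSet:
    """Exact union of the given sources' accession sets.

    An empty union is permitted; such variants are excluded from
    agreement denominators downstream and counted as unannotated.
    """
    if not per_source:
        raise ValueError("reference_set requires at least one source")
    union: frozenset[str] = frozenset().union(*per_source.values())
    return ReferenceSet(variant_id, tuple(per_source), union)


def source_status(source_set: Iterable[str], ref: frozenset[str] | ReferenceSet) -> str:
    """Classify one source against the reference: full, partial or none."""
    ref_acc = ref.accessions if isinstance(ref, ReferenceSet) else frozenset(ref)
    s = frozenset(source_set)
    if not s <= ref_acc:
        raise ScopeMismatchError(
            f"source set {sorted(s - ref_acc)} not contained in reference"
        )
    if not s:
        return NONE
    if s == ref_acc:
        return FULL
    return PARTIAL


def classify_tool_pattern(statuses: Mapping[str, str]) -> str:
    """Canonical label for a (tool -> status) assignment.

    Grammar: tools in full agreement are listed by name joined by
    ``" and "``; partial tools are appended each as ``"; X subset"``;
    tools with no annotation are omitted.  The all-full case is
    ``"Exact Match"`` and the no-full case starts with ``"No full
    match"``.  Tool order is canonical (ANNOVAR, SnpEff, VEP).
    """
    order = [t for t in TOOLS if t in statuses] + [
        t for t in statuses if t not in TOOLS
    ]
    fulls = [t for t in order if statuses[t] == FULL]
    partials = [t for t in order if statuses[t] == PARTIAL]
    for t in order:
        if statuses[t] not in (FULL, PARTIAL, NONE):
            raise ValueError(f"unknown status {statuses[t]!r} for {t}")
    if not fulls and not partials:
        raise ValueError(
            "all sources have status 'none'; unannotated variants must be "
            "excluded before classification"
        )
    if len(fulls) == len(order):
        return EXACT_MATCH_LABEL
    head = " and ".join(fulls) if fulls else NO_FULL_PREFIX
    tail = "".join(f"; {t} subset" for t in partials)
    return head + tail


def tool_category_labels(tools: Sequence[str] = TOOLS) -> tuple[str, ...]:
    """All realizable category labels for the given tool set.

    A status assignment is realizable iff not every tool is ``none`` and
    it is not the case that exactly one tool is nonempty with status
    ``partial`` (a lone nonempty source necessarily equals the union).
    For three tools this yields 23 labels.
    """
    labels = []
    for combo in itertools.product((FULL, PARTIAL, NONE), repeat=len(tools)):
        nonempty = [s for s in combo if s != NONE]
        if not nonempty:
            continue
        if len(nonempty) == 1 and nonempty[0] == PARTIAL:
            continue
        labels.append(classify_tool_pattern(dict(zip(tools, combo))))
    return tuple(dict.fromkeys(labels))


TOOL_CATEGORY_LABELS: tuple[str, ...] = tool_category_labels()


def classify_model_pattern(
    ens: Iterable[str], ref_seq: Iterable[str]
) -> str:
    """One of the 7 gene-model agreement categories.

    Compares the Ensembl-derived and RefSeq-derived accession sets for a
    variant (each already unioned across tools within its model).
    """
    e, r = frozenset(ens), frozenset(ref_seq)
    if not e and not r:
        raise ValueError("both gene models empty; variant is unannotated")
    if not e:
        return GM_REFSEQ_ONLY
    if not r:
        return GM_ENSEMBL_ONLY
    if e == r:
        return GM_EXACT
    if e < r:
        return GM_REFSEQ_WITH_ENS_SUBSET
    if r < e:
        return GM_ENS_WITH_REFSEQ_SUBSET
    if e & r:
        return GM_PARTIAL_OVERLAP
    return GM_FULLY_DISJOINT


def coverage(
    source_set: Iterable[str], ref: frozenset[str] | ReferenceSet
) -> tuple[int, int]:
    """(numerator, denominator): accessions captured out of the reference."""
    ref_acc = ref.accessions if isinstance(ref, ReferenceSet) else frozenset(ref)
    s = frozenset(source_set)
    return len(s & ref_acc), len(ref_acc)


# ---------------------------------------------------------------------------
# Integration strategies
# ---------------------------------------------------------------------------

Source = tuple[str, str]  # (tool, gene_model)


@dataclass(frozen=True)
class Strategy:
    """Which (tool, gene model) sources are unioned.

    ``tool`` and/or ``model`` may be ``"Combined"`` to union over that
    axis; ``Strategy.full()`` unions everything and by construction
    recovers the global reference set for every variant.
    """

    tool: str
    model: str

    @property
    def label(self) -> str:
        return f"{self.tool} / {self.model}"

    @classmethod
    def full(cls) -> "Strategy":
        return cls(COMBINED, COMBINED)

    def sources(
        self,
        tools: Sequence[str] = TOOLS,
        models: Sequence[str] = GENE_MODELS,
    ) -> tuple[Source, ...]:
        ts = tuple(tools) if self.tool == COMBINED else (self.tool,)
        ms = tuple(models) if self.model == COMBINED else (self.model,)
        return tuple(itertools.product(ts, ms))


def strategy_grid(
    tools: Sequence[str] = TOOLS, models: Sequence[str] = GENE_MODELS
) -> tuple[Strategy, ...]:
    """The default 12-strategy grid: (tools + Combined) x (models + Combined)."""
    return tuple(
        Strategy(t, m)
        for t in (*tools, COMBINED)
        for m in (*models, COMBINED)
    )


def integrate(
    strategy: Strategy,
    per_source: Mapping[Source, frozenset[str] | set[str]],
    tools: Sequence[str] = TOOLS,
    models: Sequence[str] = GENE_MODELS,
) -> frozenset[str]:
    """Union the strategy's in-scope sources; no prioritization is applied."""
    scope = [s for s in strategy.sources(tools, models) if s in per_source]
    if not scope:
        raise ValueError(f"strategy {strategy.label} selects no available source")
    return frozenset().union(*(per_source[s] for s in scope))


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def classify_variant(
    per_source: Mapping[str, frozenset[str] | set[str]],
    variant_id: str = "",
    tools: Sequence[str] | None = None,
) -> AgreementResult:
    """Full agreement result (category + coverage) for one variant."""
    ref = reference_set(per_source, variant_id)
    statuses = {s: source_status(per_source[s], ref) for s in per_source}
    cov = {s: coverage(per_source[s], ref) for s in per_source}
    label = classify_tool_pattern(statuses)
    return AgreementResult(variant_id, label, statuses, cov)


def coverage_frame(
    per_variant: Mapping[str, Mapping[Source, frozenset[str]]],
    strategies: Sequence[Strategy],
    chrom: Mapping[str, str] | None = None,
    region: Mapping[str, str] | None = None,
    tools: Sequence[str] = TOOLS,
    models: Sequence[str] = GENE_MODELS,
) -> pd.DataFrame:
    """Long coverage table: one row per (variant, strategy).

    The denominator for every strategy is the *global* union reference
    over all (tool, model) sources present for the variant, so the fully
    combined strategy attains 100% coverage by construction.  Variants
    with an empty reference are excluded (they carry no annotation
    events in any stratum).
    """
    rows = []
    for vid, per_source in per_variant.items():
        ref = frozenset().union(*per_source.values()) if per_source else frozenset()
        if not ref:
            continue
        for strat in strategies:
            s = integrate(strat, per_source, tools, models)
            num, den = coverage(s, ref)
            rows.append(
                {
                    "variant_id": vid,
                    "strategy": strat.label,
                    "numerator": num,
                    "denominator": den,
                    "chrom": chrom.get(vid) if chrom else None,
                    "region": region.get(vid, "unannotated") if region else None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "strategy", "numerator", "denominator", "chrom", "region"],
    )
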