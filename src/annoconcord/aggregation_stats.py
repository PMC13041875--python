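"""Chromosome-level aggregation and paired comparisons of annotation output.

Hypothesis tests on individual SNPs would treat linkage-correlated
variants as independent, so formal testing happens on chromosome-level
aggregates: for each chromosome (units 1–22 and X, n = 23) the number of
SNP-to-protein annotation *events* produced by each strategy is summed
(a SNP annotated to k proteins contributes k events).  Strategies are
compared with paired t-tests treating chromosomes as matched units,
Bonferroni-corrected within each genomic context (whole / genic /
intergenic).  Coverage summaries report summed numerators over summed
union-reference denominators as percentages.
"""

from __future__ import annotations

import itertools
from collections.abc import Sequence
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import CHROMOSOMES
from .region_classification import GENIC, INTERGENIC

WHOLE = "whole"
STRATA = (WHOLE, GENIC, INTERGENIC)

#: significance tiers on the adjusted p-value
TIER_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p_adj: float) -> str:
    if np.isnan(p_adj):
        return "na"
    for thr, tier in TIER_THRESHOLDS:
        if p_adj < thr:
            return tier
    return "ns"


class PairedT(NamedTuple):
    t: float
    p: float
    degenerate: bool


@dataclass(frozen=True)
class ComparisonResult:
    strategy_a: str
    strategy_b: str
    stratum: str
    t: float
    p: float
    p_adj: float
    tier: str


def aggregate_by_chromosome(
    cov: pd.DataFrame,
    strata: Sequence[str] = STRATA,
    chromosomes: Sequence[str] = CHROMOSOMES,
) -> pd.DataFrame:
    """Annotation events per (chromosome, strategy, stratum).

    `cov` is a per-variant coverage frame (variant_id, strategy,
    numerator, denominator, chrom, region).  The whole stratum sums
    events over every region, including unannotated-region variants;
    the genic/intergenic strata restrict to their region label.
    Chromosome-strategy combinations absent from the data appear with
    zero events so paired vectors stay aligned.
    """
    unknown = set(cov["chrom"].unique()) - set(chromosomes)
    if unknown:
        raise ValueError(f"chromosome outside configured units: {sorted(unknown)}")
    present = [c for c in chromosomes if c in set(cov["chrom"])]
    strategies = list(dict.fromkeys(cov["strategy"]))
    frames = []
    for stratum in strata:
        sub = cov if stratum == WHOLE else cov[cov["region"] == stratum]
        pivot = (
            sub.pivot_table(
                index="chrom", columns="strategy", values="numerator",
                aggfunc="sum", fill_value=0,
            )
            .reindex(index=present, columns=strategies, fill_value=0)
            .astype(int)
        )
        long = pivot.reset_index().melt(
            id_vars="chrom", var_name="strategy", value_name="annotation_events"
        )
        long["stratum"] = stratum
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out[["chrom", "strategy", "stratum", "annotation_events"]]


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> PairedT:
    """Two-sided paired t-test on matched per-chromosome event counts.

    Identical vectors give (t=0, p=1); constant nonzero differences have
    undefined p (zero variance) and are flagged degenerate rather than
    reported as 0 or 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_ttest needs two matched vectors of length >= 2")
    d = a - b
    if np.all(d == 0):
        return PairedT(0.0, 1.0, True)
    if np.ptp(d) == 0:
        return PairedT(np.inf if d[0] > 0 else -np.inf, np.nan, True)
    t, p = stats.ttest_rel(a, b)
    return PairedT(float(t), float(p), False)


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """min(1, p*m) for each p; m defaults to the family size len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    finite = p[~np.isnan(p)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} smaller than {len(p)} p-values")
    return np.minimum(1.0, p * m)


def pairwise_grid(
    chrom_agg: pd.DataFrame,
    strategies: Sequence[str] | None = None,
    strata: Sequence[str] = STRATA,
) -> pd.DataFrame:
    """All unordered strategy pairs per stratum, Bonferroni within stratum.

    With the default 12-strategy grid this yields C(12,2) = 66
    comparisons per genomic context, each corrected with m = 66.
    """
    if strategies is None:
        strategies = list(dict.fromkeys(chrom_agg["strategy"]))
    if len(strategies) < 2:
        raise ValueError("pairwise_grid needs at least 2 strategies")
    pairs = list(itertools.combinations(strategies, 2))
    rows: list[ComparisonResult] = []
    for stratum in strata:
        sub = chrom_agg[chrom_agg["stratum"] == stratum]
        vectors = {
            s: sub[sub["strategy"] == s].sort_values("chrom")[
                "annotation_events"].to_numpy()
            for s in strategies
        }
        raw = []
        for a, b in pairs:
            res = paired_ttest(vectors[a], vectors[b])
            raw.append((a, b, res))
        adj = bonferroni([r.p for _a, _b, r in raw], m=len(pairs))
        for (a, b, res), p_adj in zip(raw, adj):
            rows.append(ComparisonResult(
                a, b, stratum, res.t, res.p, float(p_adj),
                significance_tier(float(p_adj)),
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


def coverage_table(
    cov: pd.DataFrame, strata: Sequence[str] = STRATA
) -> pd.DataFrame:
    """Events and coverage percentages per strategy and stratum.

    Cells report the summed numerators and the percentage of the summed
    union-reference denominators they capture, rendered to one decimal.
    The fully combined strategy's cells are 100.0 by construction; a
    zero-denominator stratum is reported as NaN (undefined), never 0%.
    """
    strategies = list(dict.fromkeys(cov["strategy"]))
    out = pd.DataFrame(index=strategies)
    out.index.name = "strategy"
    for stratum in strata:
        sub = cov if stratum == WHOLE else cov[cov["region"] == stratum]
        g = sub.groupby("strategy")[["numerator", "denominator"]].sum()
        g = g.reindex(strategies, fill_value=0)
        events = g["numerator"].astype(int)
        pct = np.where(
            g["denominator"] > 0,
            np.round(100.0 * g["numerator"] / g["denominator"], 1),
            np.nan,
        )
        out[f"{stratum}_events"] = events
        out[f"{stratum}_pct"] = pct
    return out.reset_index()
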