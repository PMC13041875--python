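"""Pathway overrepresentation testing and cross-strategy stability.

A mapped protein set (the "query") is tested against each pathway in a
GMT database with a one-sided Fisher's exact test (hypergeometric upper
tail) relative to a background reference list, followed by
Benjamini–Hochberg FDR correction across all pathways.  Because
different annotation strategies yield different query sets for the same
variants, the module also reports per-pathway significance across
strategies and which pathways a strategy gains or loses relative to the
fully integrated union strategy.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FDR_ALPHA = 0.05


class GmtParseError(ValueError):
    """Malformed GMT line."""


@dataclass
class PathwayDB:
    """Pathways plus the background reference list they are tested against."""

    pathways: dict[str, tuple[str, frozenset[str]]]  # id -> (name, members)
    background: frozenset[str]
    dropped_members: int = 0

    def __post_init__(self) -> None:
        for pid, (_name, members) in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid!r} is empty after filtering")
            if not members <= self.background:
                raise ValueError(f"pathway {pid!r} has members outside background")


def read_gmt(
    path: str | Path, background: Iterable[str] | None = None
) -> PathwayDB:
    """Read a GMT file (id, description, members per tab-separated line).

    Duplicate members within a line are deduplicated; members absent
    from the background are dropped with a logged count.  When no
    background is given, the union of all pathway members is used.
    """
    lines = Path(path).read_text().splitlines()
    raw: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"line {lineno}: expected >=3 tab-separated fields, got "
                f"{len(fields)}"
            )
        pid, name, *members = fields
        raw[pid] = (name, frozenset(m for m in members if m))
    bg = (
        frozenset(background)
        if background is not None
        else frozenset().union(*(m for _n, m in raw.values()))
    )
    dropped = 0
    pathways = {}
    for pid, (name, members) in raw.items():
        kept = members & bg
        dropped += len(members - bg)
        if kept:
            pathways[pid] = (name, kept)
    if dropped:
        logger.warning("dropped %d pathway members outside background", dropped)
    db = PathwayDB(pathways=pathways, background=bg)
    db.dropped_members = dropped
    return db


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    lines = [
        "\t".join([pid, name, *sorted(members)])
        for pid, (name, members) in db.pathways.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def fisher_enrich(
    query: Iterable[str], db: PathwayDB, alpha: float = FDR_ALPHA
) -> pd.DataFrame:
    """One-sided overrepresentation test of `query` against every pathway.

    For background size N, query size n, pathway size K and overlap k,
    the p-value is the hypergeometric upper tail P(X >= k).  BH step-up
    adjustment runs across all pathways in the database.  Query members
    outside the background are dropped with a warning.
    """
    q = frozenset(query)
    outside = q - db.background
    if outside:
        logger.warning(
            "dropped %d query members outside the background", len(outside)
        )
    q &= db.background
    if not q:
        raise ValueError("query is empty after restricting to the background")
    N, n = len(db.background), len(q)
    rows = []
    for pid, (name, members) in db.pathways.items():
        K = len(members)
        k = len(q & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        a, b, c = k, n - k, K - k
        d = N - n - K + k
        odds = (a * d) / (b * c) if b * c else float("inf")
        rows.append((pid, name, a, b, c, d, odds, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "name", "n_query_in_pathway", "n_query_not_pathway",
            "n_pathway_not_query", "n_background_rest", "odds_ratio", "p_value",
        ],
    )
    reject, fdr, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
    df["fdr"] = fdr
    df["significant"] = reject
    return df.sort_values(["p_value", "pathway_id"]).reset_index(drop=True)


def compare_strategies(
    queries: Mapping[str, Iterable[str]],
    db: PathwayDB,
    full_strategy: str | None = None,
    alpha: float = FDR_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pathway FDR/significance matrix across annotation strategies.

    Returns ``(matrix, summary)``: the matrix holds one row per pathway
    with an ``fdr:<strategy>`` and ``sig:<strategy>`` column pair; the
    summary lists, per strategy, the significant-pathway count and the
    pathways gained/lost relative to the full-integration strategy
    (default: the last strategy given).
    """
    if len(queries) < 2:
        raise ValueError("compare_strategies requires at least 2 strategies")
    labels = list(queries)
    if full_strategy is None:
        full_strategy = labels[-1]
    if full_strategy not in queries:
        raise ValueError(f"unknown full-integration strategy {full_strategy!r}")

    per_strategy = {
        lab: fisher_enrich(q, db, alpha).set_index("pathway_id")
        for lab, q in queries.items()
    }
    matrix = pd.DataFrame(index=sorted(db.pathways))
    matrix.index.name = "pathway_id"
    for lab in labels:
        matrix[f"fdr:{lab}"] = per_strategy[lab]["fdr"]
        matrix[f"sig:{lab}"] = per_strategy[lab]["significant"]
    full_sig = set(matrix.index[matrix[f"sig:{full_strategy}"]])
    rows = []
    for lab in labels:
        sig = set(matrix.index[matrix[f"sig:{lab}"]])
        rows.append(
            {
                "strategy": lab,
                "n_significant": len(sig),
                "lost_vs_full": ",".join(sorted(full_sig - sig)),
                "gained_vs_full": ",".join(sorted(sig - full_sig)),
            }
        )
    return matrix.reset_index(), pd.DataFrame(rows)
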