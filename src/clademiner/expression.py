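"""Per-group expression means, specific-vs-shared class comparison, and the
expression-ranked candidate shortlist.

"Highly expressed" is operationalized as top-k by mean over all samples
(default k = 36, the size of the published shortlist); the class
comparison is a two-sided Wilcoxon rank-sum test on log2(mean + 1), exact
for small tie-free samples and normal-approximated (tie-corrected, with
continuity correction) otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .phylo import SubfamilyAssignment
from .simulate import ExpressionTable
from .specificity import SpecificityCall

__all__ = [
    "RankSumResult",
    "CandidateRanking",
    "group_mean_expression",
    "compare_specific_vs_nonspecific",
    "rank_candidates",
]

PSEUDOCOUNT = 1.0  # added before any log transform


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of the specific class
    p_value: float
    n_specific: int
    n_shared: int
    method: str


@dataclass
class CandidateRanking:
    """Expression-ordered shortlist of clade-specific genes.

    ``entries`` columns: gene, subfamily_id, mean_wild, mean_cultivated,
    mean_all, rank (1..n, descending mean_all, ties broken by gene id).
    """

    entries: pd.DataFrame
    top_k: int


def group_mean_expression(
    table: ExpressionTable, group_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Arithmetic per-gene means over wild columns, cultivated columns and
    all columns; returns a frame with columns mean_wild / mean_cultivated /
    mean_all indexed by gene."""
    groups = group_map if group_map is not None else table.groups
    missing = [c for c in table.values.columns if c not in groups]
    if missing:
        raise ValueError(f"samples missing from group map: {missing}")
    cols = list(table.values.columns)
    wild = [i for i, c in enumerate(cols) if groups[c] == "wild"]
    cult = [i for i, c in enumerate(cols) if groups[c] == "cultivated"]
    # canonical C-contiguous layout so results are bit-reproducible no
    # matter how the table was materialized (in memory vs read from TSV)
    vals = np.ascontiguousarray(table.values.to_numpy(dtype=float))
    frame = pd.DataFrame(
        {
            "mean_wild": np.ascontiguousarray(vals[:, wild]).mean(axis=1),
            "mean_cultivated": np.ascontiguousarray(vals[:, cult]).mean(axis=1),
            "mean_all": vals.mean(axis=1),
        },
        index=table.values.index,
    )
    frame.index.name = "gene"
    return frame


def _split_classes(
    means: pd.DataFrame,
    calls: list[SpecificityCall],
    assignment: SubfamilyAssignment,
) -> tuple[list[str], list[str]]:
    specific_sf = {c.subfamily_id for c in calls if c.specific}
    specific, shared = [], []
    for sf_id in assignment.subfamily_ids:
        bucket = specific if sf_id in specific_sf else shared
        bucket.extend(g for g in assignment.members[sf_id] if g in means.index)
    return specific, shared


def compare_specific_vs_nonspecific(
    means: pd.DataFrame,
    calls: list[SpecificityCall],
    assignment: SubfamilyAssignment,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of log2(mean_all + 1) between
    clade-specific and shared superfamily members."""
    specific, shared = _split_classes(means, calls, assignment)
    if not specific or not shared:
        raise ValueError("both classes must be non-empty for the rank-sum test")
    x = np.log2(means.loc[specific, "mean_all"].to_numpy() + PSEUDOCOUNT)
    y = np.log2(means.loc[shared, "mean_all"].to_numpy() + PSEUDOCOUNT)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_specific=len(x),
        n_shared=len(y),
        method=f"wilcoxon-rank-sum/{method}",
    )


def rank_candidates(
    calls: list[SpecificityCall],
    means: pd.DataFrame,
    assignment: SubfamilyAssignment,
    top_k: int = 36,
) -> CandidateRanking:
    """Shortlist of clade-specific genes, descending by mean over all
    samples, ties broken lexicographically by gene id; at most ``top_k``
    entries (all candidates if fewer)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    specific, _ = _split_classes(means, calls, assignment)
    if not specific:
        warnings.warn("no clade-specific genes: returning an empty ranking")
        empty = pd.DataFrame(
            columns=["gene", "subfamily_id", "mean_wild", "mean_cultivated", "mean_all", "rank"]
        )
        return CandidateRanking(entries=empty, top_k=top_k)
    frame = means.loc[sorted(specific)].copy()
    frame["subfamily_id"] = [assignment.gene_to_subfamily[g] for g in frame.index]
    frame = frame.reset_index()
    frame = frame.sort_values(
        by=["mean_all", "gene"], ascending=[False, True], kind="mergesort"
    ).head(top_k)
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame = frame[
        ["gene", "subfamily_id", "mean_wild", "mean_cultivated", "mean_all", "rank"]
    ]
    return CandidateRanking(entries=frame, top_k=top_k)
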