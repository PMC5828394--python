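"""Joining elements with in vivo activity labels and group comparisons.

The level comparison is a one-sided Wilcoxon rank-sum (Mann-Whitney) test
in the direction "group a exceeds group b" (active > inactive), with
midranks for ties: exact permutation enumeration for small samples
(n_a + n_b <= 20, ties included), normal approximation with tie and
continuity corrections otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import LABEL_STATUSES, SignalTrack, ValidationError
from .metrics import count_window

log = logging.getLogger(__name__)

EXACT_MAX_N = 20


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # rank-sum of group a (midranks)
    p_value: float
    direction: str = "a > b"
    method: str = "exact"


def join_activity(
    elements_df: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Left-join activity labels onto an element table by id.

    Labels whose id matches no element are logged and skipped; duplicate
    conflicting labels for one (element, stage, tissue) key are an error.
    Elements may carry multiple (stage, tissue) labels, one row each;
    unlabelled elements keep NaN label columns.
    """
    labels = labels.copy()
    bad = set(labels["status"]) - LABEL_STATUSES
    if bad:
        raise ValidationError(f"unknown status values {sorted(bad)}")
    key = ["id", "stage", "tissue"]
    grouped = labels.groupby(key)["status"].nunique()
    conflicts = grouped[grouped > 1]
    if len(conflicts):
        raise ValidationError(
            f"conflicting labels for keys: {list(conflicts.index)[:5]}"
        )
    labels = labels.drop_duplicates(subset=key)
    known = set(elements_df["id"])
    unknown = labels.loc[~labels["id"].isin(known), "id"]
    if len(unknown):
        log.warning(
            "%d labels reference unknown element ids (e.g. %s); skipped",
            len(unknown), unknown.iloc[0],
        )
        labels = labels[labels["id"].isin(known)]
    return elements_df.merge(labels, on="id", how="left")


def _ranksum_exact_p(pooled_ranks: np.ndarray, n_a: int, observed: float) -> float:
    """Pr[rank-sum of a random n_a-subset >= observed] by full enumeration."""
    n = len(pooled_ranks)
    total = 0
    hits = 0
    eps = 1e-9
    for comb in combinations(range(n), n_a):
        total += 1
        if pooled_ranks[list(comb)].sum() >= observed - eps:
            hits += 1
    return hits / total


def compare_groups(
    levels_a, levels_b, alternative: str = "greater"
) -> GroupComparison:
    """One-sided Wilcoxon rank-sum test for a > b.

    Ties are handled by midranks. For n_a + n_b <= 20 the p-value is the
    exact permutation tail Pr[W >= W_obs]; larger samples use the normal
    approximation with tie-corrected variance and continuity correction.
    """
    if alternative != "greater":
        raise ValidationError("only alternative='greater' is supported")
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w_obs = float(ranks[: len(a)].sum())
    n = len(pooled)
    if n <= EXACT_MAX_N:
        p = _ranksum_exact_p(ranks, len(a), w_obs)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="greater", method="asymptotic"
        )
        p = float(res.pvalue)
        method = "normal"
    return GroupComparison(
        group_a="a", group_b="b", n_a=len(a), n_b=len(b),
        statistic=w_obs, p_value=min(max(p, 0.0), 1.0), method=method,
    )


_PAIRWISE = [
    ("active", "inactive"),
    ("active", "nonenhancer"),
    ("inactive", "nonenhancer"),
]


def stratified_summary(
    annotated: pd.DataFrame,
    track: SignalTrack,
    stage: str,
    tissue: str,
    halfwidth: int = 250,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-status level distributions and pairwise one-sided comparisons.

    Selects labels for one (stage, tissue), computes both-strand window
    counts per element, summarises quartiles of log2(count + 1) per status,
    and runs the three pairwise comparisons (active > inactive,
    active > nonenhancer, inactive > nonenhancer). Comparisons with an
    empty side are skipped with a log entry.
    """
    sel = annotated[
        (annotated["stage"] == stage) & (annotated["tissue"] == tissue)
    ].copy()
    if "total" in sel.columns:
        sel["level"] = sel["total"].astype(float)
    else:
        sel["level"] = [
            count_window(track, r.chrom, int(r.summit), halfwidth, "+")
            + count_window(track, r.chrom, int(r.summit), halfwidth, "-")
            for r in sel.itertuples()
        ]
    sel["log2_level"] = np.log2(sel["level"] + 1.0)
    summary_rows = []
    groups: dict[str, np.ndarray] = {}
    for status in ("active", "inactive", "nonenhancer"):
        vals = sel.loc[sel["status"] == status, "level"].to_numpy(dtype=float)
        groups[status] = vals
        if len(vals) == 0:
            continue
        logs = np.log2(vals + 1.0)
        q1, q2, q3 = np.percentile(logs, [25, 50, 75])
        summary_rows.append(
            {"status": status, "n": len(vals), "log2_q1": q1,
             "log2_median": q2, "log2_q3": q3}
        )
    summary = pd.DataFrame(
        summary_rows, columns=["status", "n", "log2_q1", "log2_median", "log2_q3"]
    )
    comp_rows = []
    for ga, gb in _PAIRWISE:
        if len(groups[ga]) == 0 or len(groups[gb]) == 0:
            log.info("comparison %s > %s skipped: empty group", ga, gb)
            continue
        gc = compare_groups(groups[ga], groups[gb])
        comp_rows.append(
            {"group_a": ga, "group_b": gb, "n_a": gc.n_a, "n_b": gc.n_b,
             "statistic": gc.statistic, "p_value": gc.p_value,
             "method": gc.method}
        )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["group_a", "group_b", "n_a", "n_b", "statistic", "p_value",
                 "method"],
    )
    return summary, comparisons


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (optional across the pairwise tests)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
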