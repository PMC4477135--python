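"""Two-group comparison of degree and edge metrics.

The comparison has three stages, all two-sample t-tests (pooled
Student by default, Welch by flag), two-sided, uncorrected at
alpha = 0.05 unless requested otherwise:

1. per node, on the normalised degree Gamma-bar (raw Gamma by flag);
2. per edge incident to a chosen node (typically a node found
   significant in stage 1), on the edge weight eta;
3. per unordered network pair, on the inter-network degree Gamma_MN.

Group A is the first group label encountered in the cohort, so for the
synthetic generator's ordering t > 0 means the control mean is larger.
An optional Benjamini-Hochberg correction is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnMatrix, DegreeTable

__all__ = [
    "GroupComparison",
    "two_sample_t",
    "compare_node_degrees",
    "compare_edges_for_node",
    "compare_network_degrees",
    "significant_metrics",
]

VARIANTS = ("pooled", "welch")


@dataclass(frozen=True)
class GroupComparison:
    """One metric's two-group summary: means, SDs, t, p and significance."""

    metric: str
    group_a: str
    mean_a: float
    sd_a: float
    group_b: str
    mean_b: float
    sd_b: float
    t: float
    p: float
    significant: bool
    alpha: float


def two_sample_t(a: Sequence[float], b: Sequence[float], variant: str = "pooled") -> tuple[float, float]:
    """Two-sided two-sample t statistic and p value.

    ``variant="pooled"`` assumes equal variances (Student);
    ``"welch"`` does not.  Both groups zero-variance with equal means is
    treated as no evidence of difference (t = 0, p = 1); with unequal
    means the difference is certain at this sample (t = +-inf, p = 0).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >= 2 observations, got {a.size} and {b.size}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def _split_groups(labels: Sequence[str]) -> tuple[str, str]:
    order: list[str] = []
    for g in labels:
        if g not in order:
            order.append(g)
    if len(order) != 2:
        raise ValueError(f"need exactly 2 groups, got {order}")
    return order[0], order[1]


def _compare_frame(
    metrics: Sequence[str],
    values: np.ndarray,
    labels: Sequence[str],
    alpha: float,
    variant: str,
    correction: str | None,
) -> pd.DataFrame:
    """Assemble one comparison table; values is (n_subjects, n_metrics)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    group_a, group_b = _split_groups(labels)
    labels = np.asarray(labels)
    va = values[labels == group_a]
    vb = values[labels == group_b]
    if va.shape[0] < 2 or vb.shape[0] < 2:
        raise ValueError(
            f"each group needs >= 2 subjects, got {va.shape[0]} ({group_a}) "
            f"and {vb.shape[0]} ({group_b})"
        )
    rows = []
    for j, metric in enumerate(metrics):
        t, p = two_sample_t(va[:, j], vb[:, j], variant=variant)
        rows.append(
            {
                "metric": metric,
                "group_a": group_a,
                "mean_a": va[:, j].mean(),
                "sd_a": va[:, j].std(ddof=1),
                "group_b": group_b,
                "mean_b": vb[:, j].mean(),
                "sd_b": vb[:, j].std(ddof=1),
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if correction is None:
        df["significant"] = df["p"] < alpha
    elif correction == "fdr_bh":
        reject, p_adj, _, _ = multipletests(df["p"].to_numpy(), alpha=alpha, method="fdr_bh")
        df["p_adjusted"] = p_adj
        df["significant"] = reject
    else:
        raise ValueError(f"unknown correction {correction!r}; use None or 'fdr_bh'")
    return df


def compare_node_degrees(
    tables: Sequence[DegreeTable],
    alpha: float = 0.05,
    use_normalized: bool = True,
    variant: str = "pooled",
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-node two-group comparison of (normalised) connectivity degree."""
    if not tables:
        raise ValueError("empty cohort")
    names = tables[0].node_names
    for tab in tables:
        if tab.node_names != names:
            raise ValueError("degree tables have inconsistent node order")
    values = np.vstack([(t.gamma_norm if use_normalized else t.gamma) for t in tables])
    labels = [t.group for t in tables]
    return _compare_frame(list(names), values, labels, alpha, variant, correction)


def compare_edges_for_node(
    conns: Sequence[ConnMatrix],
    node: str,
    alpha: float = 0.05,
    variant: str = "pooled",
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-edge comparison of eta over all edges incident to ``node``."""
    if not conns:
        raise ValueError("empty cohort")
    names = conns[0].node_names
    if node not in names:
        raise KeyError(f"unknown node {node!r}; have {list(names)}")
    k = names.index(node)
    partners = [m for m in names if m != node]
    cols = [names.index(m) for m in partners]
    values = np.vstack([c.eta[k, cols] for c in conns])
    labels = [c.group for c in conns]
    metrics = [f"{node}-{m}" for m in partners]
    return _compare_frame(metrics, values, labels, alpha, variant, correction)


def compare_network_degrees(
    tables: Sequence[DegreeTable],
    alpha: float = 0.05,
    variant: str = "pooled",
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-network-pair comparison of the inter-network degree Gamma_MN."""
    if not tables:
        raise ValueError("empty cohort")
    pairs = tables[0].network_pairs
    if not pairs:
        raise ValueError("atlas has fewer than 2 networks; no network pairs to compare")
    for tab in tables:
        if tab.network_pairs != pairs:
            raise ValueError("degree tables have inconsistent network pairs")
    values = np.vstack([t.network_gamma for t in tables])
    labels = [t.group for t in tables]
    metrics = ["-".join(p) for p in pairs]
    return _compare_frame(metrics, values, labels, alpha, variant, correction)


def significant_metrics(df: pd.DataFrame) -> list[str]:
    """Metric names flagged significant in a comparison table."""
    return df.loc[df["significant"], "metric"].tolist()
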