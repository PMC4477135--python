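"""Replicate studies: type-I error and planted-effect recovery.

These helpers rerun the full simulate -> connectivity -> comparison
pipeline many times with independently seeded cohorts, to calibrate the
false-positive rate of each comparison stage under a null generator and
to measure how reliably the planted effects (raised rAI coupling,
lowered DMN-CEN cross-correlation) are detected with the expected sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .atlas import NetworkAtlas
from .connectivity import ConnParams, analyze_cohort
from .simulate import GROUP_AFFECTED, GROUP_CONTROL, RAI_NODE, SimulationConfig, simulate_cohort
from .stats import compare_edges_for_node, compare_network_degrees, compare_node_degrees

__all__ = [
    "replicate_seeds",
    "run_group_analysis",
    "null_rejection_rates",
    "effect_detection_rates",
]


def replicate_seeds(seed: int, n_replicates: int) -> list[int]:
    """Deterministic per-replicate integer seeds (< 2**31) from one seed."""
    state = np.random.SeedSequence(seed).generate_state(n_replicates, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_group_analysis(
    atlas: NetworkAtlas,
    config: SimulationConfig,
    params: ConnParams = ConnParams(),
    alpha: float = 0.05,
    variant: str = "pooled",
    edge_node: str = RAI_NODE,
) -> dict[str, pd.DataFrame]:
    """Simulate one cohort and run all three comparison stages."""
    cohort = simulate_cohort(atlas, config)
    conns, tables = analyze_cohort(cohort, atlas, params)
    return {
        "nodes": compare_node_degrees(tables, alpha=alpha, variant=variant),
        "edges": compare_edges_for_node(conns, edge_node, alpha=alpha, variant=variant),
        "networks": compare_network_degrees(tables, alpha=alpha, variant=variant),
    }


@dataclass(frozen=True)
class RejectionRates:
    """Pooled per-stage rejection rates over replicates."""

    node_rate: float
    edge_rate: float
    network_rate: float
    n_replicates: int
    n_node_tests: int
    n_edge_tests: int
    n_network_tests: int


def null_rejection_rates(
    atlas: NetworkAtlas,
    config: SimulationConfig,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    params: ConnParams = ConnParams(),
    edge_node: str = RAI_NODE,
) -> RejectionRates:
    """Stage-wise false-positive rates under the no-effect generator.

    ``config`` is forced to its null (both planted effects zero); each
    replicate gets an independent cohort seed.  Rates pool rejections
    over all tests of a stage across replicates.
    """
    null_cfg = config.null()
    node_hits = edge_hits = net_hits = 0
    node_n = edge_n = net_n = 0
    for rep_seed in replicate_seeds(seed, n_replicates):
        reports = run_group_analysis(
            atlas, replace(null_cfg, seed=rep_seed), params, alpha=alpha, edge_node=edge_node
        )
        node_hits += int(reports["nodes"]["significant"].sum())
        node_n += len(reports["nodes"])
        edge_hits += int(reports["edges"]["significant"].sum())
        edge_n += len(reports["edges"])
        net_hits += int(reports["networks"]["significant"].sum())
        net_n += len(reports["networks"])
    return RejectionRates(
        node_rate=node_hits / node_n,
        edge_rate=edge_hits / edge_n,
        network_rate=net_hits / net_n,
        n_replicates=n_replicates,
        n_node_tests=node_n,
        n_edge_tests=edge_n,
        n_network_tests=net_n,
    )


@dataclass(frozen=True)
class DetectionRates:
    """Planted-effect recovery over replicates."""

    rai_degree_power: float            # rAI degree significant AND higher in affected
    dmn_cen_power: float               # DMN-CEN degree significant AND lower in affected
    edge_direction_all_rate: float     # replicates where all rAI edges are higher in affected
    edge_mean_diff: np.ndarray         # mean (affected - control) eta per rAI edge, pooled
    edge_metrics: tuple[str, ...]
    n_replicates: int


def effect_detection_rates(
    atlas: NetworkAtlas,
    config: SimulationConfig,
    n_replicates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    params: ConnParams = ConnParams(),
) -> DetectionRates:
    """Detection rate and direction of the planted group effects."""
    rai_hits = net_hits = all_dir_hits = 0
    edge_diff_sum: np.ndarray | None = None
    edge_metrics: tuple[str, ...] = ()
    for rep_seed in replicate_seeds(seed, n_replicates):
        reports = run_group_analysis(atlas, replace(config, seed=rep_seed), params, alpha=alpha)
        nodes = reports["nodes"].set_index("metric")
        row = nodes.loc[RAI_NODE]
        affected_col, control_col = _direction_columns(row)
        if bool(row["significant"]) and row[affected_col] > row[control_col]:
            rai_hits += 1
        nets = reports["networks"].set_index("metric")
        net_row = nets.loc["DMN-CEN"] if "DMN-CEN" in nets.index else nets.loc["CEN-DMN"]
        affected_col, control_col = _direction_columns(net_row)
        if bool(net_row["significant"]) and net_row[affected_col] < net_row[control_col]:
            net_hits += 1
        edges = reports["edges"]
        affected_col, control_col = _direction_columns(edges.iloc[0])
        diff = edges[affected_col].to_numpy() - edges[control_col].to_numpy()
        if (diff > 0).all():
            all_dir_hits += 1
        edge_diff_sum = diff if edge_diff_sum is None else edge_diff_sum + diff
        edge_metrics = tuple(edges["metric"])
    assert edge_diff_sum is not None
    return DetectionRates(
        rai_degree_power=rai_hits / n_replicates,
        dmn_cen_power=net_hits / n_replicates,
        edge_direction_all_rate=all_dir_hits / n_replicates,
        edge_mean_diff=edge_diff_sum / n_replicates,
        edge_metrics=edge_metrics,
        n_replicates=n_replicates,
    )


def _direction_columns(row: pd.Series) -> tuple[str, str]:
    """Map (group_a, group_b) columns to (affected, control) mean columns."""
    if row["group_a"] == GROUP_AFFECTED:
        return "mean_a", "mean_b"
    if row["group_b"] == GROUP_AFFECTED:
        return "mean_b", "mean_a"
    raise ValueError(
        f"expected groups {GROUP_CONTROL!r}/{GROUP_AFFECTED!r}, "
        f"got {row['group_a']!r}/{row['group_b']!r}"
    )
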