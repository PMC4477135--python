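"""Graph connectivity measures: exponential edge weights and degree sums.

An edge between nodes i and j is weighted

    eta_ij = exp(-xi * d_ij),        d_ij = (1 - c_ij) / (1 + c_ij),

where c_ij is the Pearson correlation of the two node time series and
xi > 0 (default 2) sets how fast connectivity decays with correlation
distance.  eta maps c in (-1, 1] strictly monotonically onto (0, 1]:
perfectly correlated series give eta = 1, uncorrelated series give
exp(-xi), and c -> -1 gives eta -> 0 (d is taken as +inf at c = -1 so
eta stays defined).

Degrees are weighted sums over these edges with self-edges excluded:
Gamma_i sums eta over all partners of node i in the single combined
graph; the normalised degree divides by the total over all nodes and
therefore sums to 1 per subject; the inter-network degree Gamma_MN sums
eta over all cross-pairs between two disjoint networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import NetworkAtlas
from .preprocess import SubjectSeries

__all__ = [
    "ConnParams",
    "ConnMatrix",
    "DegreeTable",
    "pearson",
    "corr_to_distance",
    "edge_connectivity",
    "connectivity_matrix",
    "node_degree",
    "normalize_degree",
    "network_degree",
    "degree_table",
    "analyze_cohort",
]


@dataclass(frozen=True)
class ConnParams:
    """Connectivity parameters; ``xi`` is the positive decay constant."""

    xi: float = 2.0

    def __post_init__(self) -> None:
        if not self.xi > 0:
            raise ValueError(f"xi must be > 0, got {self.xi}")


@dataclass
class ConnMatrix:
    """Per-subject symmetric edge-weight matrix with intermediates.

    ``eta``, ``c`` and ``d`` are ``(n, n)`` arrays in ``node_names``
    order.  Diagonals hold the degenerate self-values (eta 0, c 1, d 0)
    and are excluded from every degree sum.
    """

    node_names: tuple[str, ...]
    c: np.ndarray
    d: np.ndarray
    eta: np.ndarray
    xi: float = 2.0
    subject_id: str = ""
    group: str = ""

    def edge(self, a: str, b: str) -> float:
        """eta between two named nodes."""
        i, j = self.node_names.index(a), self.node_names.index(b)
        return float(self.eta[i, j])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form table of unordered node pairs with c, d and eta."""
        rows = []
        n = len(self.node_names)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "subject_id": self.subject_id,
                        "group": self.group,
                        "node_i": self.node_names[i],
                        "node_j": self.node_names[j],
                        "c": self.c[i, j],
                        "d": self.d[i, j],
                        "eta": self.eta[i, j],
                    }
                )
        return pd.DataFrame(rows)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series must be 1-D of equal length, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0:
        raise ValueError("first series has zero variance")
    if sy == 0:
        raise ValueError("second series has zero variance")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def corr_to_distance(c):
    """Correlation-to-distance transform d = (1 - c) / (1 + c).

    Strictly decreasing on (-1, 1] with d(1) = 0; the c = -1 singularity
    is mapped to +inf (continuous limit) rather than raising.  Accepts
    scalars or arrays.
    """
    arr = np.asarray(c, dtype=float)
    if np.any(arr > 1.0) or np.any(arr < -1.0):
        raise ValueError("correlation must lie in [-1, 1]")
    with np.errstate(divide="ignore"):
        d = np.where(arr <= -1.0, np.inf, (1.0 - arr) / (1.0 + arr))
    return float(d) if np.isscalar(c) else d


def edge_connectivity(d, params: ConnParams | float = ConnParams()):
    """Exponential edge weight eta = exp(-xi * d) in (0, 1]; eta(+inf) = 0."""
    xi = params.xi if isinstance(params, ConnParams) else float(params)
    if not xi > 0:
        raise ValueError(f"xi must be > 0, got {xi}")
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distance must be >= 0")
    eta = np.exp(-xi * arr)
    return float(eta) if np.isscalar(d) else eta


def connectivity_matrix(subject: SubjectSeries, params: ConnParams = ConnParams()) -> ConnMatrix:
    """All-pairs eta for one subject via Pearson -> distance -> exponential."""
    data = subject.data
    variances = data.var(axis=1)
    flat = np.flatnonzero(np.isclose(variances, 0.0))
    if flat.size:
        names = [subject.node_names[i] for i in flat]
        raise ValueError(f"subject {subject.subject_id!r}: zero-variance node series {names}")
    c = np.corrcoef(data)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)  # exact symmetry at the last ulp
    d = corr_to_distance(c)
    np.fill_diagonal(d, 0.0)
    eta = edge_connectivity(d, params)
    np.fill_diagonal(eta, 0.0)  # self-edges excluded from all sums
    np.fill_diagonal(c, 1.0)
    xi = params.xi if isinstance(params, ConnParams) else float(params)
    return ConnMatrix(
        tuple(subject.node_names), c, d, eta, xi=xi,
        subject_id=subject.subject_id, group=subject.group,
    )


def node_degree(conn: ConnMatrix) -> np.ndarray:
    """Gamma_i: sum of eta over all partners of node i (self excluded)."""
    return conn.eta.sum(axis=1)


def normalize_degree(gamma: np.ndarray) -> np.ndarray:
    """Gamma_i divided by the total degree over all nodes; sums to 1."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("all degrees must be > 0 to normalize")
    return gamma / gamma.sum()


def network_degree(conn: ConnMatrix, atlas: NetworkAtlas, m: str, n: str) -> float:
    """Gamma_MN: sum of eta over all cross-pairs between networks m and n."""
    if m == n:
        raise ValueError(f"network degree is defined between distinct networks, got {m!r} twice")
    rows = atlas.network_indices(m)
    cols = atlas.network_indices(n)
    return float(conn.eta[np.ix_(rows, cols)].sum())


@dataclass
class DegreeTable:
    """Per-subject degree summary: Gamma, normalised Gamma, and Gamma_MN."""

    subject_id: str
    group: str
    node_names: tuple[str, ...]
    gamma: np.ndarray
    gamma_norm: np.ndarray
    network_pairs: tuple[tuple[str, str], ...]
    network_gamma: np.ndarray

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "node": list(self.node_names),
                "gamma": self.gamma,
                "gamma_norm": self.gamma_norm,
            }
        )

    def network_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "pair": ["-".join(p) for p in self.network_pairs],
                "gamma_mn": self.network_gamma,
            }
        )


def degree_table(conn: ConnMatrix, atlas: NetworkAtlas) -> DegreeTable:
    """Compute all degree statistics for one subject's ConnMatrix."""
    if tuple(conn.node_names) != tuple(atlas.names):
        raise ValueError("ConnMatrix node order does not match atlas")
    gamma = node_degree(conn)
    pairs = tuple(atlas.network_pairs())
    net_gamma = np.array([network_degree(conn, atlas, m, n) for m, n in pairs])
    return DegreeTable(
        subject_id=conn.subject_id,
        group=conn.group,
        node_names=tuple(conn.node_names),
        gamma=gamma,
        gamma_norm=normalize_degree(gamma),
        network_pairs=pairs,
        network_gamma=net_gamma,
    )


def analyze_cohort(
    cohort: list[SubjectSeries],
    atlas: NetworkAtlas,
    params: ConnParams = ConnParams(),
) -> tuple[list[ConnMatrix], list[DegreeTable]]:
    """Connectivity matrices and degree tables for every subject."""
    conns = [connectivity_matrix(s, params) for s in cohort]
    tables = [degree_table(c, atlas) for c in conns]
    return conns, tables
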