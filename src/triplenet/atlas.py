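"""Node atlas for triple-network (DMN / CEN / SN) connectivity analysis.

A :class:`NetworkAtlas` is an ordered collection of named nodes, each
belonging to exactly one functional network and located at an MNI
millimetre coordinate with a spherical extraction radius.  The built-in
default atlas (:func:`default_atlas`) carries the eleven canonical
triple-network nodes: four default-mode (DMN), four central-executive
(CEN) and three salience (SN) regions, with peak coordinates from a
group ICA of resting-state scans.  Brodmann area and peak t-value are
kept as annotation only and never enter any computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["NodeSpec", "NetworkAtlas", "default_atlas", "DEFAULT_ATLAS_NAME"]

#: Sentinel accepted by loaders in place of a file path.
DEFAULT_ATLAS_NAME = "default-table2"


@dataclass(frozen=True)
class NodeSpec:
    """One graph node: a named sphere in MNI space assigned to a network.

    Parameters
    ----------
    name:
        Unique node label, e.g. ``"rAI"`` for the right anterior insula.
    network:
        Functional network label, e.g. ``"DMN"``, ``"CEN"`` or ``"SN"``.
    x, y, z:
        MNI coordinates of the sphere centre, in millimetres.
    radius:
        Sphere radius in millimetres (default 3).
    ba, t_value:
        Optional Brodmann area and ICA-map peak t-value; annotation only.
    """

    name: str
    network: str
    x: float
    y: float
    z: float
    radius: float = 3.0
    ba: int | None = None
    t_value: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("node name must be non-empty")
        if not self.network:
            raise ValueError(f"node {self.name!r}: network must be non-empty")
        if not self.radius > 0:
            raise ValueError(f"node {self.name!r}: radius must be > 0, got {self.radius}")

    @property
    def coords(self) -> np.ndarray:
        """MNI centre as a float array ``[x, y, z]`` (mm)."""
        return np.array([self.x, self.y, self.z], dtype=float)


class NetworkAtlas:
    """Ordered set of :class:`NodeSpec` partitioned into networks.

    Node order is preserved exactly as given and defines the row/column
    order of every downstream matrix.  Network membership partitions the
    node set: every node belongs to exactly one network.
    """

    def __init__(self, nodes: Iterable[NodeSpec]):
        nodes = tuple(nodes)
        if not nodes:
            raise ValueError("atlas must contain at least one node")
        names = [n.name for n in nodes]
        dupes = {m for m in names if names.count(m) > 1}
        if dupes:
            raise ValueError(f"duplicate node names in atlas: {sorted(dupes)}")
        self.nodes: tuple[NodeSpec, ...] = nodes
        self._index = {n.name: i for i, n in enumerate(nodes)}
        # networks ordered by first appearance
        nets: list[str] = []
        for n in nodes:
            if n.network not in nets:
                nets.append(n.network)
        self._networks = tuple(nets)

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[NodeSpec]:
        return iter(self.nodes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NetworkAtlas) and self.nodes == other.nodes

    def __repr__(self) -> str:
        return f"NetworkAtlas({len(self)} nodes, networks={list(self.networks)})"

    # -- lookups -------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def networks(self) -> tuple[str, ...]:
        """Network labels in order of first appearance."""
        return self._networks

    def node(self, name: str) -> NodeSpec:
        try:
            return self.nodes[self._index[name]]
        except KeyError:
            raise KeyError(f"unknown node {name!r}; atlas has {list(self.names)}") from None

    def index(self, name: str) -> int:
        if name not in self._index:
            raise KeyError(f"unknown node {name!r}; atlas has {list(self.names)}")
        return self._index[name]

    def network_indices(self, network: str) -> np.ndarray:
        """Positions (into node order) of all nodes in ``network``."""
        idx = np.array([i for i, n in enumerate(self.nodes) if n.network == network], dtype=int)
        if idx.size == 0:
            raise KeyError(f"unknown or empty network {network!r}; atlas has {list(self.networks)}")
        return idx

    def network_nodes(self, network: str) -> tuple[str, ...]:
        return tuple(self.nodes[i].name for i in self.network_indices(network))

    def network_pairs(self) -> list[tuple[str, str]]:
        """All unordered pairs of distinct networks, in atlas order."""
        nets = self.networks
        return [(nets[i], nets[j]) for i in range(len(nets)) for j in range(i + 1, len(nets))]

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(n) for n in self.nodes])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([asdict(n) for n in self.nodes], indent=2) + "\n")

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "NetworkAtlas":
        nodes = []
        for i, rec in enumerate(records):
            rec = dict(rec)
            unknown = set(rec) - {"name", "network", "x", "y", "z", "radius", "ba", "t_value"}
            if unknown:
                raise ValueError(f"atlas record {i + 1}: unknown columns {sorted(unknown)}")
            missing = {"name", "network", "x", "y", "z"} - set(rec)
            if missing:
                raise ValueError(f"atlas record {i + 1}: missing columns {sorted(missing)}")
            ba = rec.get("ba")
            nodes.append(
                NodeSpec(
                    name=str(rec["name"]),
                    network=str(rec["network"]),
                    x=float(rec["x"]),
                    y=float(rec["y"]),
                    z=float(rec["z"]),
                    radius=float(rec.get("radius", 3.0)),
                    ba=None if ba is None or (isinstance(ba, float) and np.isnan(ba)) else int(ba),
                    t_value=rec.get("t_value"),
                )
            )
        return cls(nodes)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NetworkAtlas":
        df = pd.read_csv(path, sep="\t")
        df = df.where(pd.notna(df), None)
        return cls.from_records(df.to_dict("records"))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkAtlas":
        return cls.from_records(json.loads(Path(path).read_text()))


# Canonical triple-network nodes: (name, network, x, y, z, BA, peak t).
# Coordinates are MNI mm; BA / t are annotation only.
_TRIPLE_NETWORK_TABLE = [
    ("lAng", "DMN", -48, -67, 34, 39, 8.94),
    ("rAng", "DMN", 54, -61, 30, 39, 5.58),
    ("PCC", "DMN", 0, -52, 18, 30, 13.90),
    ("vmPFC", "DMN", -1, 56, 10, 10, 5.05),
    ("lPPC", "CEN", -33, -70, 50, 7, 7.73),
    ("rPPC", "CEN", 42, -62, 50, 7, 7.56),
    ("ldlPFC", "CEN", -27, 20, 58, 6, 6.03),
    ("rdlPFC", "CEN", 27, 20, 62, 6, 3.60),
    ("dACC", "SN", 2, 34, 25, 32, 3.27),
    ("lAI", "SN", -34, 23, 4, 45, 4.46),
    ("rAI", "SN", 34, 23, 5, 45, 3.50),
]


def default_atlas(radius: float = 3.0) -> NetworkAtlas:
    """The built-in 11-node triple-network atlas (4 DMN, 4 CEN, 3 SN).

    Parameters
    ----------
    radius:
        Sphere radius in mm applied to every node (default 3).
    """
    return NetworkAtlas(
        NodeSpec(name, net, x, y, z, radius=radius, ba=ba, t_value=t)
        for name, net, x, y, z, ba, t in _TRIPLE_NETWORK_TABLE
    )
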