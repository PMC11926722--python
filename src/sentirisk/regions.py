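"""Region graphs: the spatial neighbourhood structure of the model.

A :class:`RegionGraph` records areal units (e.g. federal states) and the
symmetric "shares a border" relation between them.  It is the sole source
of the adjacency used by the intrinsic CAR (Besag) precision and by the
synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["RegionGraph", "make_region_graph", "germany_graph"]


@dataclass(frozen=True)
class RegionGraph:
    """Undirected, connected graph over areal units.

    Parameters
    ----------
    region_ids
        Ordered region identifiers; their order defines the index
        convention used everywhere downstream.
    edges
        Unordered pairs of region *indices* (stored as ``i < j``).
    names
        Optional human-readable names, same order as ``region_ids``.
    """

    region_ids: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if n < 2:
            raise ValueError("a region graph needs at least 2 regions")
        if len(set(self.region_ids)) != n:
            raise ValueError("duplicate region identifiers")
        canon = []
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on region index {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a},{b}) out of range [0,{n})")
            canon.append((min(a, b), max(a, b)))
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate edges")
        object.__setattr__(self, "edges", tuple(sorted(canon)))
        if not nx.is_connected(self.to_networkx()):
            raise ValueError("region graph must be connected")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        g.add_edges_from(self.edges)
        return g

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency in region-index order."""
        n = self.n_regions
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows, cols = zip(*self.edges)
        rows, cols = np.asarray(rows), np.asarray(cols)
        data = np.ones(len(rows))
        a = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
        return (a + a.T).tocsr()

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency_matrix().sum(axis=1)).ravel()

    def neighbors(self, i: int) -> list[int]:
        return sorted(b if a == i else a for a, b in self.edges if i in (a, b))

    # -- I/O ------------------------------------------------------------
    def to_edge_csv(self, path) -> None:
        df = pd.DataFrame(
            [(self.region_ids[a], self.region_ids[b]) for a, b in self.edges],
            columns=["region_a", "region_b"],
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_edge_csv(cls, path) -> "RegionGraph":
        df = pd.read_csv(path, dtype=str)
        if not {"region_a", "region_b"} <= set(df.columns):
            raise ValueError("edge CSV needs columns region_a, region_b")
        ids = sorted(set(df["region_a"]) | set(df["region_b"]))
        idx = {r: i for i, r in enumerate(ids)}
        edges = tuple(
            (idx[a], idx[b]) for a, b in zip(df["region_a"], df["region_b"])
        )
        return cls(tuple(ids), edges)


def make_region_graph(
    n_rows: int, n_cols: int, seed: int = 0, p_diagonal: float = 0.15
) -> RegionGraph:
    """Connected lattice with random diagonal augmentation.

    Builds the ``n_rows x n_cols`` 4-neighbour lattice, then adds each
    unit cell's "\\" diagonal independently with probability
    ``p_diagonal``.  Deterministic given ``seed``.
    """
    if n_rows < 1 or n_cols < 1 or n_rows * n_cols < 2:
        raise ValueError("need at least 2 regions (n_rows*n_cols >= 2)")
    rng = np.random.default_rng(seed)

    def node(r, c):
        return r * n_cols + c

    edges: list[tuple[int, int]] = []
    for r in range(n_rows):
        for c in range(n_cols):
            if c + 1 < n_cols:
                edges.append((node(r, c), node(r, c + 1)))
            if r + 1 < n_rows:
                edges.append((node(r, c), node(r + 1, c)))
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            if rng.random() < p_diagonal:
                edges.append((node(r, c), node(r + 1, c + 1)))
    ids = tuple(f"R{i:02d}" for i in range(n_rows * n_cols))
    return RegionGraph(ids, tuple(edges))


# 13 areal units: the 16 German federal states with the city-states merged
# into a neighbouring state (Berlin->Brandenburg, Bremen->Niedersachsen,
# Hamburg->Schleswig-Holstein).  Edges are the actual state borders.
_GERMANY_IDS = (
    "SH",  # Schleswig-Holstein (+ Hamburg)
    "NI",  # Niedersachsen (+ Bremen)
    "MV",  # Mecklenburg-Vorpommern
    "BB",  # Brandenburg (+ Berlin)
    "ST",  # Sachsen-Anhalt
    "SN",  # Sachsen
    "TH",  # Thueringen
    "HE",  # Hessen
    "NW",  # Nordrhein-Westfalen
    "RP",  # Rheinland-Pfalz
    "SL",  # Saarland
    "BW",  # Baden-Wuerttemberg
    "BY",  # Bayern
)

_GERMANY_EDGES = (
    ("SH", "NI"), ("SH", "MV"),
    ("NI", "MV"), ("NI", "BB"), ("NI", "ST"), ("NI", "TH"),
    ("NI", "HE"), ("NI", "NW"),
    ("MV", "BB"),
    ("BB", "ST"), ("BB", "SN"),
    ("ST", "SN"), ("ST", "TH"),
    ("SN", "TH"), ("SN", "BY"),
    ("TH", "HE"), ("TH", "BY"),
    ("HE", "NW"), ("HE", "RP"), ("HE", "BW"), ("HE", "BY"),
    ("NW", "RP"),
    ("RP", "BW"), ("RP", "SL"),
    ("BW", "BY"),
)

#: Regions most exposed to the July 2021 flood (contiguous western block).
GERMANY_FLOOD_REGIONS = ("NW", "RP", "SL", "HE")


def germany_graph() -> RegionGraph:
    """Adjacency of the 13 merged German federal states."""
    idx = {r: i for i, r in enumerate(_GERMANY_IDS)}
    edges = tuple((idx[a], idx[b]) for a, b in _GERMANY_EDGES)
    return RegionGraph(_GERMANY_IDS, edges)
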