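"""Region adjacency graphs and the intrinsic-CAR (ICAR) precision matrix.

The spatial prior for region effects is a Gaussian Markov random field with
precision proportional to the graph Laplacian ``Q = D - A`` (degree minus
adjacency).  ``Q`` is positive semidefinite with one zero eigenvalue per
connected component, so the prior is improper; identifiability is restored
downstream by a sum-to-zero constraint on the region effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AdjacencyGraph",
    "ICARPrecision",
    "read_edge_list",
    "egypt_governorates",
    "egypt_governorate_names",
    "build_icar_precision",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected region neighbourhood graph with integer region ids."""

    region_ids: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    _nx: nx.Graph = field(repr=False, compare=False, default=None)

    @staticmethod
    def from_edges(region_ids, edges) -> "AdjacencyGraph":
        ids = tuple(sorted(int(i) for i in region_ids))
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        if not ids:
            raise ValueError("empty graph: no region ids")
        norm = []
        for a, b in edges:
            a, b = int(a), int(b)
            if a == b:
                raise ValueError(f"self-loop on region {a}")
            if a not in ids or b not in ids:
                raise ValueError(f"edge ({a},{b}) references unknown region id")
            norm.append((min(a, b), max(a, b)))
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(norm)
        return AdjacencyGraph(ids, tuple(sorted(set(norm))), g)

    @property
    def graph(self) -> nx.Graph:
        return self._nx

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self._nx)]

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self._nx)

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1

    def component_labels(self) -> np.ndarray:
        """Component index per region, aligned with ``region_ids``."""
        lab = np.empty(self.n_regions, dtype=np.int64)
        for ci, comp in enumerate(sorted(self.components, key=min)):
            for rid in comp:
                lab[self.region_ids.index(rid)] = ci
        return lab

    def index_of(self, region_id) -> np.ndarray:
        """Positions of ``region_id`` values within ``region_ids`` (vectorised)."""
        lookup = {rid: i for i, rid in enumerate(self.region_ids)}
        arr = np.asarray(region_id)
        try:
            return np.vectorize(lookup.__getitem__, otypes=[np.int64])(arr)
        except KeyError as err:
            raise KeyError(f"region id {err} not in graph") from None


@dataclass(frozen=True)
class ICARPrecision:
    """Laplacian precision structure ``Q = D - A`` of an adjacency graph."""

    Q: np.ndarray
    region_ids: tuple[int, ...]
    n_components: int

    @property
    def rank(self) -> int:
        return len(self.region_ids) - self.n_components


def read_edge_list(path, region_ids=None) -> AdjacencyGraph:
    """Read a plain-text edge list: one ``"region_a region_b"`` pair per line.

    Lines starting with ``#`` are comments.  ``region_ids`` defaults to the
    set of ids appearing in the edges; pass it explicitly if isolated
    regions exist.
    """
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed edge line: {line!r}")
        edges.append((int(parts[0]), int(parts[1])))
    if not edges and region_ids is None:
        raise ValueError(f"no edges found in {path}")
    if region_ids is None:
        region_ids = sorted({i for e in edges for i in e})
    return AdjacencyGraph.from_edges(region_ids, edges)


def _data_path(name: str):
    return resources.files("morbmap.data").joinpath(name)


def egypt_governorates() -> AdjacencyGraph:
    """The bundled 27-governorate adjacency fixture.

    Curated from public administrative maps (desert borders approximate);
    the ids follow ``egypt_governorate_names()``.  Every analysis records
    which graph it used, so a user-supplied edge list is a drop-in
    replacement via :func:`read_edge_list`.
    """
    with resources.as_file(_data_path("egypt_governorates_adjacency.txt")) as p:
        return read_edge_list(p, region_ids=range(1, 28))


def egypt_governorate_names() -> pd.DataFrame:
    """id -> governorate name and EDHS macro-region lookup table."""
    with resources.as_file(_data_path("egypt_governorates.csv")) as p:
        return pd.read_csv(p)


def build_icar_precision(graph: AdjacencyGraph) -> ICARPrecision:
    """Build ``Q = D - A`` aligned with ``graph.region_ids`` (sorted).

    An isolated region contributes a zero row/column (its structured effect
    is unidentified and handled by the constraint policy); a warning is
    emitted rather than an error.
    """
    nodes = list(graph.region_ids)
    A = nx.to_numpy_array(graph.graph, nodelist=nodes)
    deg = A.sum(axis=1)
    if (deg == 0).any():
        isolated = [nodes[i] for i in np.flatnonzero(deg == 0)]
        warnings.warn(
            f"isolated region(s) {isolated}: structured effect unidentified, "
            "resolved only by the sum-to-zero constraint",
            stacklevel=2,
        )
    Q = np.diag(deg) - A
    return ICARPrecision(Q=Q, region_ids=tuple(nodes), n_components=graph.n_components)
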