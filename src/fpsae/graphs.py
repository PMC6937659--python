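"""Area adjacency graphs.

The spatial smoothing components operate on a neighbourhood graph over
administrative areas (states).  The graph is undirected, has no self loops,
and may be disconnected; connected components matter because the intrinsic
CAR prior is improper with one flat direction per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected neighbourhood structure over an ordered set of areas.

    Parameters
    ----------
    areas
        Ordered area identifiers; the order fixes matrix row/column order
        everywhere downstream.
    edges
        Unordered pairs of neighbouring areas.
    """

    areas: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        area_set = set(self.areas)
        if len(area_set) != len(self.areas):
            raise ValueError("duplicate area identifiers")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-edge or malformed edge: {set(e)}")
            if not e <= area_set:
                raise ValueError(f"edge references unknown area: {set(e)}")
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.areas)})

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str]], areas: list[str] | None = None
    ) -> "AdjacencyGraph":
        """Build from a pair list; `areas` adds isolated areas / fixes order."""
        if areas is None:
            seen: dict[str, None] = {}
            for a, b in edges:
                seen.setdefault(str(a))
                seen.setdefault(str(b))
            areas = list(seen)
        eset = set()
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-edge at area {a!r}")
            eset.add(frozenset((a, b)))
        return cls(tuple(str(a) for a in areas), frozenset(eset))

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def index(self, area: str) -> int:
        return self._index[area]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.areas)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    @property
    def components(self) -> list[list[str]]:
        """Connected components, each ordered by the global area order."""
        comps = nx.connected_components(self.to_networkx())
        out = [sorted(c, key=self.index) for c in comps]
        return sorted(out, key=lambda c: self.index(c[0]))

    @property
    def n_components(self) -> int:
        return len(self.components)

    def neighbours(self, area: str) -> list[str]:
        out = [next(iter(e - {area})) for e in self.edges if area in e]
        return sorted(out, key=self.index)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_areas, dtype=int)
        for e in self.edges:
            for a in e:
                d[self.index(a)] += 1
        return d

    # -- edge-list file round trip -------------------------------------------

    def write_edgelist(self, path) -> None:
        """Two-column whitespace edge list; isolated areas on singleton lines."""
        touched = {a for e in self.edges for a in e}
        with open(path, "w") as fh:
            for e in sorted((sorted(e, key=self.index) for e in self.edges),
                            key=lambda p: (self.index(p[0]), self.index(p[1]))):
                fh.write(f"{e[0]}\t{e[1]}\n")
            for a in self.areas:
                if a not in touched:
                    fh.write(f"{a}\n")

    @classmethod
    def read_edgelist(cls, path) -> "AdjacencyGraph":
        edges: list[tuple[str, str]] = []
        areas: dict[str, None] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) == 1:
                    areas.setdefault(parts[0])
                elif len(parts) == 2:
                    edges.append((parts[0], parts[1]))
                    areas.setdefault(parts[0])
                    areas.setdefault(parts[1])
                else:
                    raise ValueError(f"malformed edge-list line: {line!r}")
        return cls.from_edges(edges, list(areas))


def synthetic_graph(n_areas: int, seed: int = 0) -> AdjacencyGraph:
    """Planar-like connected adjacency over `n_areas` synthetic areas.

    Scatters points uniformly and takes Delaunay triangulation edges, which
    mimics the contiguity structure of administrative maps (average degree
    around 6, no long-range links).  Deterministic given seed.
    """
    if n_areas < 1:
        raise ValueError("n_areas must be positive")
    names = [f"A{i:02d}" for i in range(n_areas)]
    if n_areas == 1:
        return AdjacencyGraph.from_edges([], names)
    if n_areas <= 3:
        return AdjacencyGraph.from_edges(
            [(names[i], names[i + 1]) for i in range(n_areas - 1)], names
        )
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n_areas, 2))
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((names[a], names[b]))
    return AdjacencyGraph.from_edges(sorted(edges), names)
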