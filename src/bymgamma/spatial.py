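"""Region adjacency graphs and the intrinsic CAR (ICAR) precision structure.

The spatially structured random intercept of a Besag–York–Mollié (BYM) model
penalises squared differences between adjacent areas.  Its (improper) Gaussian
prior has precision matrix ``Q`` with the vertex degree on the diagonal and
``-1`` for each neighbour pair, so the prior kernel is

    u' Q u = sum over edges (i, j) of (u_i - u_j)^2.

``Q`` is singular: each connected component contributes one zero eigenvalue
(the component-wise constant), which is why a sum-to-zero constraint per
component is imposed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SpatialGraph",
    "ICARStructure",
    "read_adjacency",
    "build_icar_structure",
    "icar_quadratic_form",
    "lattice_graph",
]


@dataclass(frozen=True)
class SpatialGraph:
    """Undirected region adjacency.

    Region ids are opaque strings kept in lexicographic order; every matrix or
    vector indexed by region elsewhere in the package follows this order.
    """

    region_ids: tuple[str, ...]
    edges: frozenset[frozenset]

    def __post_init__(self):
        if len(self.region_ids) < 1:
            raise ValueError("graph must contain at least one region")
        if list(self.region_ids) != sorted(set(self.region_ids)):
            raise ValueError("region_ids must be sorted and unique")
        known = set(self.region_ids)
        for e in self.edges:
            pair = tuple(e)
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not set(pair) <= known:
                raise ValueError(f"edge endpoint not a known region: {set(e)}")

    @classmethod
    def from_edges(cls, edges, extra_regions=()) -> "SpatialGraph":
        """Build from an iterable of (a, b) pairs; symmetrises and dedupes."""
        eset = set()
        regions = set(extra_regions)
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on region {a!r}")
            regions.update((a, b))
            eset.add(frozenset((a, b)))
        return cls(tuple(sorted(regions)), frozenset(eset))

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self) -> dict:
        return {r: i for i, r in enumerate(self.region_ids)}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def edge_index_array(self) -> np.ndarray:
        """(n_edges, 2) integer array of edge endpoints, rows sorted."""
        idx = self.index()
        rows = sorted(tuple(sorted(e)) for e in self.edges)
        if not rows:
            return np.empty((0, 2), dtype=np.intp)
        return np.array([[idx[a], idx[b]] for a, b in rows], dtype=np.intp)


@dataclass(frozen=True)
class ICARStructure:
    """ICAR precision matrix and connected components of a region graph."""

    region_ids: tuple[str, ...]
    precision: np.ndarray
    components: tuple[tuple[str, ...], ...]
    # integer component label per region, aligned with region_ids
    component_labels: np.ndarray = field(repr=False, default=None)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def rank(self) -> int:
        """Rank of the precision: n_regions minus number of components."""
        return self.n_regions - self.n_components

    def degrees(self) -> np.ndarray:
        return np.diag(self.precision).copy()


def read_adjacency(path) -> SpatialGraph:
    """Read a plain-text edge list into a :class:`SpatialGraph`.

    Format: one edge per line, two whitespace-separated region ids; ``#``
    starts a comment; an optional ``REGIONS:`` line enumerates region ids
    (used to declare isolated regions with no edges).
    """
    edges = []
    extra = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.upper().startswith("REGIONS:"):
                extra.extend(line.split(":", 1)[1].split())
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two region ids, got {len(tokens)}: {raw.strip()!r}"
                )
            a, b = tokens
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on region {a!r}")
            edges.append((a, b))
    return SpatialGraph.from_edges(edges, extra_regions=extra)


def write_adjacency(graph: SpatialGraph, path) -> None:
    """Write the edge-list format read by :func:`read_adjacency`."""
    with open(path, "w") as fh:
        fh.write("# region adjacency: one undirected edge per line\n")
        fh.write("REGIONS: " + " ".join(graph.region_ids) + "\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a} {b}\n")


def build_icar_structure(graph: SpatialGraph) -> ICARStructure:
    """ICAR precision Q (degree on diagonal, -1 for neighbours) + components."""
    n = graph.n_regions
    idx = graph.index()
    Q = np.zeros((n, n))
    for e in graph.edges:
        i, j = (idx[r] for r in e)
        Q[i, j] = Q[j, i] = -1.0
        Q[i, i] += 1.0
        Q[j, j] += 1.0
    comps = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(graph.to_networkx())),
        key=lambda c: c[0],
    )
    labels = np.empty(n, dtype=np.intp)
    for k, comp in enumerate(comps):
        for r in comp:
            labels[idx[r]] = k
    return ICARStructure(graph.region_ids, Q, tuple(comps), labels)


def icar_quadratic_form(structure: ICARStructure, u) -> float:
    """u' Q u = sum over neighbour pairs of (u_i - u_j)^2; >= 0 always."""
    u = np.asarray(u, dtype=float)
    if u.shape != (structure.n_regions,):
        raise ValueError(
            f"effect vector has length {u.shape}, expected ({structure.n_regions},)"
        )
    return float(u @ structure.precision @ u)


def lattice_graph(rows: int, cols: int) -> SpatialGraph:
    """Rook-contiguity grid of ``rows x cols`` regions (test/synthetic fixture).

    Region ids are ``r{i:02d}c{j:02d}`` so lexicographic order equals raster
    order.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    name = lambda i, j: f"r{i:02d}c{j:02d}"
    edges = []
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                edges.append((name(i, j), name(i, j + 1)))
            if i + 1 < rows:
                edges.append((name(i, j), name(i + 1, j)))
    regions = [name(i, j) for i in range(rows) for j in range(cols)]
    return SpatialGraph.from_edges(edges, extra_regions=regions)


def greedy_coloring(graph: SpatialGraph) -> np.ndarray:
    """Proper vertex colouring (no edge within a colour class).

    Used by the sampler to update structured intercepts in vectorised batches:
    regions of one colour share no edge, so their full conditionals do not
    involve each other and may be updated simultaneously.
    """
    coloring = nx.greedy_color(graph.to_networkx(), strategy="largest_first")
    idx = graph.index()
    out = np.zeros(graph.n_regions, dtype=np.intp)
    for r, c in coloring.items():
        out[idx[r]] = c
    return out
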