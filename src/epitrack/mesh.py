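"""Polygonal tessellation of a single segmented frame and its dual cell network.

A segmented epithelial sheet is approximated by a planar tessellation: each
cell is a simple polygon whose vertices sit at junctions where three or more
cells meet.  The dual of the tessellation is the *cell network*: one graph
node per cell, one edge per pair of cells sharing at least one polygon edge.
The tracking algorithm operates almost entirely on this dual network, falling
back on polygon geometry (centroids, areas) only for distance cutoffs and
for resolving ambiguous division events.
"""

from __future__ import annotations

import json
import math
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "InvalidMeshError",
    "Mesh",
    "build_network",
    "neighbourhood_graph",
    "boundary_cells",
]


class InvalidMeshError(ValueError):
    """Raised when a tessellation violates a mesh invariant."""


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (falls back to vertex mean if degenerate)."""
    x, y = points[:, 0], points[:, 1]
    xr, yr = np.roll(x, -1), np.roll(y, -1)
    cross = x * yr - xr * y
    a = 0.5 * float(cross.sum())
    if abs(a) < 1e-12:
        return points.mean(axis=0)
    cx = float(((x + xr) * cross).sum()) / (6.0 * a)
    cy = float(((y + yr) * cross).sum()) / (6.0 * a)
    return np.array([cx, cy])


class Mesh:
    """Vertices plus counter-clockwise ordered polygonal cells.

    Parameters
    ----------
    vertices :
        Mapping from integer vertex id to a finite 2-vector position.
    cells :
        Mapping from integer cell id to an ordered list of vertex ids.
        Orientation is normalised counter-clockwise on construction so that
        areas and centroids have unambiguous signs.
    """

    def __init__(
        self,
        vertices: Mapping[int, Iterable[float]] | None = None,
        cells: Mapping[int, Iterable[int]] | None = None,
    ) -> None:
        self.vertices: dict[int, np.ndarray] = {}
        self.cells: dict[int, list[int]] = {}
        if vertices:
            for vid, pos in vertices.items():
                self.add_vertex(int(vid), pos)
        if cells:
            for cid, vids in cells.items():
                self.add_cell(int(cid), vids)

    # -- construction -------------------------------------------------

    def add_vertex(self, vid: int, position: Iterable[float]) -> None:
        pos = np.asarray(tuple(position), dtype=float)
        if pos.shape != (2,) or not np.all(np.isfinite(pos)):
            raise InvalidMeshError(f"vertex {vid}: position must be a finite 2-vector")
        if vid in self.vertices:
            raise InvalidMeshError(f"duplicate vertex id {vid}")
        self.vertices[vid] = pos

    def add_cell(self, cid: int, vertex_ids: Iterable[int]) -> None:
        vids = [int(v) for v in vertex_ids]
        if cid in self.cells:
            raise InvalidMeshError(f"duplicate cell id {cid}")
        if len(vids) < 3:
            raise InvalidMeshError(f"cell {cid}: a polygon needs at least 3 vertices")
        if len(set(vids)) != len(vids):
            raise InvalidMeshError(f"cell {cid}: repeated vertex in polygon")
        missing = [v for v in vids if v not in self.vertices]
        if missing:
            raise InvalidMeshError(f"cell {cid}: unknown vertices {missing}")
        pts = np.array([self.vertices[v] for v in vids])
        area = _signed_area(pts)
        if area == 0.0:
            raise InvalidMeshError(f"cell {cid}: degenerate polygon (zero area)")
        if area < 0.0:
            vids = vids[::-1]
        self.cells[cid] = vids

    def copy(self) -> "Mesh":
        out = Mesh()
        out.vertices = {v: p.copy() for v, p in self.vertices.items()}
        out.cells = {c: list(vs) for c, vs in self.cells.items()}
        return out

    # -- per-cell geometry --------------------------------------------

    def points_of(self, cid: int) -> np.ndarray:
        return np.array([self.vertices[v] for v in self.cells[cid]])

    def area(self, cid: int) -> float:
        return abs(_signed_area(self.points_of(cid)))

    def centroid(self, cid: int) -> np.ndarray:
        return _polygon_centroid(self.points_of(cid))

    def num_sides(self, cid: int) -> int:
        return len(self.cells[cid])

    def edges_of(self, cid: int) -> list[frozenset[int]]:
        vids = self.cells[cid]
        return [frozenset((vids[i], vids[(i + 1) % len(vids)])) for i in range(len(vids))]

    # -- mesh-level derived quantities --------------------------------

    def edge_owners(self) -> dict[frozenset[int], list[int]]:
        """Map each polygon edge (unordered vertex pair) to the cells owning it."""
        owners: dict[frozenset[int], list[int]] = {}
        for cid in self.cells:
            for e in self.edges_of(cid):
                owners.setdefault(e, []).append(cid)
        return owners

    def vertex_owners(self) -> dict[int, list[int]]:
        owners: dict[int, list[int]] = {}
        for cid, vids in self.cells.items():
            for v in vids:
                owners.setdefault(v, []).append(cid)
        return owners

    @property
    def average_cell_length(self) -> float:
        """Characteristic cell size: sqrt of the mean cell area."""
        if not self.cells:
            raise InvalidMeshError("empty mesh has no cell length scale")
        mean_area = float(np.mean([self.area(c) for c in self.cells]))
        return math.sqrt(mean_area)

    def centroids(self) -> dict[int, np.ndarray]:
        return {cid: self.centroid(cid) for cid in self.cells}

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check mesh invariants; raise :class:`InvalidMeshError` on violation."""
        referenced: set[int] = set()
        for cid, vids in self.cells.items():
            referenced.update(vids)
            pts = self.points_of(cid)
            if _signed_area(pts) <= 0:
                raise InvalidMeshError(f"cell {cid}: not counter-clockwise / zero area")
        dangling = set(self.vertices) - referenced
        if dangling:
            raise InvalidMeshError(f"vertices referenced by no cell: {sorted(dangling)}")
        for edge, cids in self.edge_owners().items():
            if len(cids) > 2:
                raise InvalidMeshError(
                    f"edge {tuple(sorted(edge))} shared by more than two cells: {cids}"
                )

    def prune_unused_vertices(self) -> None:
        used = {v for vids in self.cells.values() for v in vids}
        self.vertices = {v: p for v, p in self.vertices.items() if v in used}

    # -- serialization (internal interchange format) ------------------

    def to_json(self) -> str:
        obj = {
            "vertices": [
                {"id": v, "x": float(p[0]), "y": float(p[1])}
                for v, p in sorted(self.vertices.items())
            ],
            "cells": [{"id": c, "vertices": list(vs)} for c, vs in sorted(self.cells.items())],
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Mesh":
        obj = json.loads(text)
        mesh = cls()
        for v in obj["vertices"]:
            mesh.add_vertex(int(v["id"]), (v["x"], v["y"]))
        for c in obj["cells"]:
            mesh.add_cell(int(c["id"]), c["vertices"])
        return mesh

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Mesh":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def __len__(self) -> int:
        return len(self.cells)

    def __repr__(self) -> str:
        return f"Mesh(n_vertices={len(self.vertices)}, n_cells={len(self.cells)})"


def boundary_cells(mesh: Mesh) -> set[int]:
    """Cells owning at least one polygon edge not shared with another cell."""
    out: set[int] = set()
    for edge, cids in mesh.edge_owners().items():
        if len(cids) == 1:
            out.add(cids[0])
    return out


def build_network(mesh: Mesh) -> nx.Graph:
    """Dual adjacency graph of a tessellation.

    Nodes are cell ids carrying ``centroid``, ``num_sides`` and
    ``is_boundary`` attributes; an edge joins two cells iff they share at
    least one polygon edge (multiple shared polygon edges collapse to a
    single graph edge).
    """
    boundary = boundary_cells(mesh)
    net = nx.Graph()
    for cid in sorted(mesh.cells):
        net.add_node(
            cid,
            centroid=mesh.centroid(cid),
            num_sides=mesh.num_sides(cid),
            is_boundary=cid in boundary,
        )
    for edge, cids in mesh.edge_owners().items():
        if len(cids) > 2:
            raise InvalidMeshError(
                f"edge {tuple(sorted(edge))} shared by more than two cells: {cids}"
            )
        if len(cids) == 2:
            net.add_edge(cids[0], cids[1])
    return net


def neighbourhood_graph(net: nx.Graph, cell: int, order: int = 2) -> nx.Graph:
    """Induced subgraph on a cell, its neighbours and (order 2) their neighbours.

    The centre cell is recorded as the graph attribute ``centre``.
    """
    if cell not in net:
        raise KeyError(f"cell {cell} not in network")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    nodes = {cell} | set(net.adj[cell])
    if order == 2:
        for nb in list(net.adj[cell]):
            nodes |= set(net.adj[nb])
    sub = net.subgraph(nodes).copy()
    sub.graph["centre"] = cell
    return sub
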