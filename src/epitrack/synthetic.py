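"""In-silico epithelial tissues and ground-truthed perturbation test cases.

Tissues are generated as Voronoi tessellations of uniformly random seeds,
homogenised by a few steps of Lloyd's relaxation.  This produces cell
packings with side-number and area distributions similar to those measured
in many proliferating epithelia (e.g. the *Drosophila* wing imaginal disc),
which makes them a realistic substrate for testing graph-based tracking.

On top of the generator, this module implements the elementary tissue
rearrangements of vertex-model tissue mechanics as mesh operators:

* T1 transition (neighbour exchange): an interior cell-cell interface is
  replaced by a short perpendicular interface, swapping adjacency among the
  four surrounding cells.
* T2 transition (cell removal): an interior cell collapses onto a single
  vertex shared by its former neighbours (a rosette).
* Division: a cell is bisected by a straight line through its centroid in a
  random direction.

Each ``*_case`` helper builds a two-frame tracking problem (second frame
with shuffled cell ids) together with the known ground-truth correspondence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

from .mesh import Mesh, _polygon_centroid, boundary_cells

__all__ = [
    "GenerationConfig",
    "GroundTruth",
    "TrackingCase",
    "generate_tissue",
    "hexagonal_mesh",
    "permute_ids",
    "translation_pair",
    "t1_edges",
    "apply_t1",
    "apply_t2",
    "apply_division",
    "NotApplicableError",
    "permutation_case",
    "translation_case",
    "t1_case",
    "t2_case",
    "division_case",
]


class NotApplicableError(ValueError):
    """A perturbation operator was applied where its preconditions fail."""


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the Voronoi/Lloyd tissue generator.

    ``m`` x ``n`` is the size of the returned tissue in average cell
    diameters; ``g`` pads the random-seed domain so that the evenly spaced
    guard seeds outside it do not imprint their regularity on the returned
    cells; ``n_lloyd`` counts Lloyd's relaxation steps.
    """

    m: int
    n: int
    g: int = 8
    n_lloyd: int = 4
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 3 or self.n < 3:
            raise ValueError("tissue dimensions m, n must be >= 3")
        if self.g < 0 or self.n_lloyd < 0:
            raise ValueError("g and n_lloyd must be >= 0")


@dataclass
class GroundTruth:
    """Known frame-1 -> frame-2 correspondence of a synthetic test case."""

    map: dict[int, int] = field(default_factory=dict)
    divisions: list[tuple[int, int, int]] = field(default_factory=list)
    removals: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.map.values())) != len(self.map):
            raise ValueError("ground-truth map must be injective")


@dataclass
class TrackingCase:
    """A two-frame tracking problem with ground truth."""

    mesh1: Mesh
    mesh2: Mesh
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Voronoi / Lloyd generator
# ---------------------------------------------------------------------------


def _guard_seeds(width: float, height: float) -> np.ndarray:
    """Two rows of evenly spaced seeds surrounding [0,width] x [0,height].

    Inner row at distance 0.5 with spacing 1.0; outer row at distance 1.5,
    shifted parallel to the inner row by 0.5.  They keep every Voronoi
    region of an interior seed bounded.
    """
    pts: list[tuple[float, float]] = []
    xs = np.arange(-0.5, width + 0.5 + 1e-9, 1.0)
    for x in xs:
        pts.append((x, -0.5))
        pts.append((x, height + 0.5))
    ys = np.arange(0.5, height - 0.5 + 1e-9, 1.0)
    for y in ys:
        pts.append((-0.5, y))
        pts.append((width + 0.5, y))
    xs = np.arange(-1.0, width + 1.0 + 1e-9, 1.0)
    for x in xs:
        pts.append((x, -1.5))
        pts.append((x, height + 1.5))
    ys = np.arange(0.0, height + 1e-9, 1.0)
    for y in ys:
        pts.append((-1.5, y))
        pts.append((width + 1.5, y))
    return np.array(pts)


def _ordered_region(vor: Voronoi, point_index: int) -> list[int]:
    """Vertex indices of a bounded Voronoi region, ordered counter-clockwise."""
    region = vor.regions[vor.point_region[point_index]]
    if -1 in region or len(region) < 3:
        raise RuntimeError("unbounded or degenerate Voronoi region for interior seed")
    pts = vor.vertices[region]
    centre = pts.mean(axis=0)
    angles = np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0])
    order = np.argsort(angles, kind="stable")
    return [region[i] for i in order]


def generate_tissue(cfg: GenerationConfig, rng: np.random.Generator | None = None) -> Mesh:
    """Generate an in-silico tissue of roughly ``m * n`` cells of mean area 1.

    Seeds are drawn uniformly in the padded ``(m+g) x (n+g)`` domain,
    surrounded by guard seeds, relaxed for ``n_lloyd`` Lloyd steps (each
    step replaces interior seeds by their Voronoi-region area centroids and
    re-adds the guard rows), and only the cells whose polygon centroids lie
    in the central ``m x n`` rectangle are kept.  The returned mesh is
    translated so that this central rectangle is ``[0, m] x [0, n]``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    width, height = cfg.m + cfg.g, cfg.n + cfg.g
    n_seeds = width * height
    seeds = rng.uniform(0.0, 1.0, size=(n_seeds, 2)) * (width, height)

    for _ in range(cfg.n_lloyd + 1):
        rounded = np.round(seeds, 9)
        _, first = np.unique(rounded, axis=0, return_index=True)
        if len(first) != len(seeds):
            warnings.warn("coincident Voronoi seeds perturbed", stacklevel=2)
            dup = np.setdiff1d(np.arange(len(seeds)), first)
            seeds[dup] += rng.uniform(-1e-6, 1e-6, size=(len(dup), 2))
        vor = Voronoi(np.vstack([seeds, _guard_seeds(width, height)]))
        centroids = np.array(
            [
                _polygon_centroid(vor.vertices[_ordered_region(vor, i)])
                for i in range(n_seeds)
            ]
        )
        seeds = centroids
    # ``vor`` is the tessellation of the last relaxed seeds.

    x0, y0 = (width - cfg.m) / 2.0, (height - cfg.n) / 2.0
    mesh = Mesh()
    known_vertices: set[int] = set()
    next_cell = 0
    for i in range(n_seeds):
        region = _ordered_region(vor, i)
        centroid = _polygon_centroid(vor.vertices[region])
        if not (x0 <= centroid[0] <= x0 + cfg.m and y0 <= centroid[1] <= y0 + cfg.n):
            continue
        for v in region:
            if v not in known_vertices:
                mesh.add_vertex(v, vor.vertices[v] - (x0, y0))
                known_vertices.add(v)
        mesh.add_cell(next_cell, region)
        next_cell += 1
    return mesh


def hexagonal_mesh(rows: int, cols: int) -> Mesh:
    """Regular pointy-top hexagonal lattice of ``rows`` x ``cols`` unit cells."""
    s = 1.0
    w = np.sqrt(3.0) * s
    vertex_ids: dict[tuple[float, float], int] = {}
    mesh = Mesh()

    def vid(p: np.ndarray) -> int:
        key = (round(float(p[0]), 6), round(float(p[1]), 6))
        if key not in vertex_ids:
            vertex_ids[key] = len(vertex_ids)
            mesh.add_vertex(vertex_ids[key], key)
        return vertex_ids[key]

    angles = np.deg2rad(30 + 60 * np.arange(6))
    offsets = np.stack([np.cos(angles), np.sin(angles)], axis=1) * s
    cid = 0
    for r in range(rows):
        for c in range(cols):
            centre = np.array([c * w + (r % 2) * w / 2.0, r * 1.5 * s])
            mesh.add_cell(cid, [vid(centre + o) for o in offsets])
            cid += 1
    return mesh


# ---------------------------------------------------------------------------
# Id permutation and translation
# ---------------------------------------------------------------------------


def relabel_cells(mesh: Mesh, mapping: dict[int, int]) -> Mesh:
    """Return a mesh with cell ids renamed through ``mapping`` (geometry shared)."""
    out = Mesh()
    out.vertices = {v: p.copy() for v, p in mesh.vertices.items()}
    for cid, vids in mesh.cells.items():
        out.cells[mapping.get(cid, cid)] = list(vids)
    if len(out.cells) != len(mesh.cells):
        raise ValueError("relabelling map is not injective on cell ids")
    return out


def permute_ids(mesh: Mesh, rng: np.random.Generator) -> tuple[Mesh, GroundTruth]:
    """Shuffle cell ids; return the shuffled mesh and the id ground truth."""
    ids = sorted(mesh.cells)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    mapping = dict(zip(ids, shuffled))
    return relabel_cells(mesh, mapping), GroundTruth(map=mapping)


def _submesh(mesh: Mesh, cell_ids: set[int]) -> Mesh:
    out = Mesh()
    out.vertices = {v: p.copy() for v, p in mesh.vertices.items()}
    out.cells = {c: list(mesh.cells[c]) for c in sorted(cell_ids)}
    out.prune_unused_vertices()
    return out


def _shift(mesh: Mesh, delta: np.ndarray) -> None:
    for v in mesh.vertices:
        mesh.vertices[v] = mesh.vertices[v] + delta


def translation_pair(
    rng: np.random.Generator,
    m: int = 15,
    n: int = 8,
    window: float = 7.0,
    offset: float = 2.0,
    n_lloyd: int = 4,
) -> tuple[Mesh, Mesh, GroundTruth]:
    """Two overlapping full-height windows of one tissue, offset horizontally.

    From an ``m x n`` tissue, two windows of width ``window`` are cut whose
    left edges differ by ``offset`` average cell lengths; each window is
    re-anchored so that its leftmost junction has x-coordinate 0.  The
    ground truth covers cells whose centroids fall inside both windows.
    """
    tissue = generate_tissue(GenerationConfig(m=m, n=n, n_lloyd=n_lloyd), rng=rng)
    x0 = (m - window - offset) / 2.0
    win1 = (x0, x0 + window)
    win2 = (x0 + offset, x0 + offset + window)
    cents = tissue.centroids()
    cells1 = {c for c, p in cents.items() if win1[0] <= p[0] <= win1[1]}
    cells2 = {c for c, p in cents.items() if win2[0] <= p[0] <= win2[1]}
    mesh1 = _submesh(tissue, cells1)
    mesh2 = _submesh(tissue, cells2)
    for mesh in (mesh1, mesh2):
        left = min(p[0] for p in mesh.vertices.values())
        _shift(mesh, np.array([-left, 0.0]))
    mesh2, perm = permute_ids(mesh2, rng)
    shared = sorted(cells1 & cells2)
    return mesh1, mesh2, GroundTruth(map={c: perm.map[c] for c in shared})


# ---------------------------------------------------------------------------
# T1 transition
# ---------------------------------------------------------------------------


def t1_edges(mesh: Mesh) -> list[tuple[int, int]]:
    """Interior interfaces on which a T1 transition is applicable.

    An interface qualifies if it is shared by two cells with at least four
    sides each, both of its end junctions are three-way, and the two cells
    that would gain adjacency are not already adjacent.
    """
    owners = mesh.edge_owners()
    vown = mesh.vertex_owners()
    adjacency = {e for e, cs in owners.items() if len(cs) == 2}
    adj_pairs = {frozenset(owners[e]) for e in adjacency}
    result = []
    for e in sorted(adjacency, key=lambda e: tuple(sorted(e))):
        v1, v2 = sorted(e)
        a, b = owners[e]
        if mesh.num_sides(a) < 4 or mesh.num_sides(b) < 4:
            continue
        if len(vown[v1]) != 3 or len(vown[v2]) != 3:
            continue
        c = [x for x in vown[v1] if x not in (a, b)]
        d = [x for x in vown[v2] if x not in (a, b)]
        if len(c) != 1 or len(d) != 1 or c[0] == d[0]:
            continue
        if frozenset((c[0], d[0])) in adj_pairs:
            continue
        result.append((v1, v2))
    return result


def _directed_pair_index(vids: list[int], v1: int, v2: int) -> int | None:
    """Index i such that vids[i] == v1 and vids[i+1] == v2 (cyclic), else None."""
    k = len(vids)
    for i in range(k):
        if vids[i] == v1 and vids[(i + 1) % k] == v2:
            return i
    return None


def apply_t1(mesh: Mesh, edge: tuple[int, int], l_t1: float = 0.2) -> Mesh:
    """Perform a neighbour exchange on the interface ``edge``.

    The interface between cells A and B is deleted and replaced by a new
    interface of length ``l_t1`` perpendicular to it through its midpoint,
    so that the junction cells C and D become adjacent instead.  Exactly
    four cells change their neighbour count.
    """
    v1, v2 = edge
    owners = mesh.edge_owners()
    vown = mesh.vertex_owners()
    e = frozenset((v1, v2))
    if e not in owners or len(owners[e]) != 2:
        raise NotApplicableError(f"edge {edge} is not an interior interface")
    a, b = owners[e]
    if len(vown[v1]) != 3 or len(vown[v2]) != 3:
        raise NotApplicableError(f"edge {edge} does not end in two three-way junctions")
    c = [x for x in vown[v1] if x not in (a, b)]
    d = [x for x in vown[v2] if x not in (a, b)]
    if len(c) != 1 or len(d) != 1 or c[0] == d[0]:
        raise NotApplicableError(f"edge {edge} has no two distinct junction cells")
    c, d = c[0], d[0]
    if mesh.num_sides(a) < 4 or mesh.num_sides(b) < 4:
        raise NotApplicableError("a side cell would drop below three vertices")

    p1, p2 = mesh.vertices[v1], mesh.vertices[v2]
    mid = (p1 + p2) / 2.0
    # orient by A's traversal: interior of a CCW polygon is left of travel
    if _directed_pair_index(mesh.cells[a], v1, v2) is not None:
        direction = p2 - p1
    else:
        direction = p1 - p2
    normal = np.array([-direction[1], direction[0]])
    normal = normal / np.linalg.norm(normal)
    new = mesh.copy()
    wa = max(new.vertices) + 1
    wb = wa + 1
    new.vertices[wa] = mid + normal * (l_t1 / 2.0)
    new.vertices[wb] = mid - normal * (l_t1 / 2.0)

    def replace_pair(cell: int, w: int) -> None:
        vids = new.cells[cell]
        i = _directed_pair_index(vids, v1, v2)
        if i is None:
            i = _directed_pair_index(vids, v2, v1)
        k = len(vids)
        out = [vids[j] for j in range(k) if j not in (i, (i + 1) % k)]
        out.insert(min(i, len(out)), w)
        new.cells[cell] = out

    def replace_junction(cell: int, v: int) -> None:
        vids = new.cells[cell]
        i = vids.index(v)
        prev_v = vids[i - 1]
        # the new edge neighbour adjacent to prev_v is whichever of A/B
        # shares the polygon edge (prev_v, v) with this cell
        shared = owners[frozenset((prev_v, v))]
        first_cell = shared[0] if shared[0] != cell else shared[1]
        first, second = (wa, wb) if first_cell == a else (wb, wa)
        new.cells[cell] = vids[:i] + [first, second] + vids[i + 1 :]

    replace_pair(a, wa)
    replace_pair(b, wb)
    replace_junction(c, v1)
    replace_junction(d, v2)
    del new.vertices[v1]
    del new.vertices[v2]
    return new


# ---------------------------------------------------------------------------
# T2 transition (cell removal)
# ---------------------------------------------------------------------------


def apply_t2(mesh: Mesh, cell: int) -> Mesh:
    """Remove an interior cell, collapsing it onto a vertex at its centroid.

    All former neighbours afterwards share the new vertex, forming a
    rosette; the cell count decreases by exactly one.
    """
    if cell not in mesh.cells:
        raise KeyError(f"cell {cell} not in mesh")
    if cell in boundary_cells(mesh):
        raise NotApplicableError(f"cell {cell} lies on the tissue boundary")
    removed = set(mesh.cells[cell])
    w = max(mesh.vertices) + 1
    centre = mesh.centroid(cell)
    new = mesh.copy()
    del new.cells[cell]
    new.vertices[w] = centre
    for cid, vids in list(new.cells.items()):
        if not removed.intersection(vids):
            continue
        out: list[int] = []
        for v in vids:
            if v in removed:
                if not out or out[-1] != w:
                    out.append(w)
            else:
                out.append(v)
        if out[0] == w and out[-1] == w:
            out.pop()
        if out.count(w) > 1:
            raise NotApplicableError(
                f"cell {cid} touches cell {cell} on disjoint interfaces"
            )
        if len(out) < 3:
            raise NotApplicableError(f"removal would degenerate cell {cid}")
        new.cells[cid] = out
    new.prune_unused_vertices()
    return new


# ---------------------------------------------------------------------------
# Division
# ---------------------------------------------------------------------------


def apply_division(
    mesh: Mesh,
    cell: int,
    rng: np.random.Generator | None = None,
    angle: float | None = None,
    snap_tol: float = 1e-6,
) -> tuple[Mesh, tuple[int, int, int]]:
    """Bisect ``cell`` by a straight line through its centroid.

    The line direction is ``angle`` if given, otherwise drawn uniformly.
    New vertices are inserted where the line crosses the cell boundary
    (snapping to an existing vertex within ``snap_tol``, which is how three-
    and four-sided daughters arise); the cells sharing the crossed edges
    each gain one interface.  Returns the new mesh and the division record
    ``(mother, daughter1, daughter2)``.
    """
    if cell not in mesh.cells:
        raise KeyError(f"cell {cell} not in mesh")
    if cell in boundary_cells(mesh):
        raise NotApplicableError(f"cell {cell} lies on the tissue boundary")
    if angle is None:
        if rng is None:
            raise ValueError("either rng or angle must be given")
        angle = float(rng.uniform(0.0, np.pi))
    centre = mesh.centroid(cell)
    d = np.array([np.cos(angle), np.sin(angle)])

    vids = mesh.cells[cell]
    k = len(vids)
    crossings = []  # (t, edge index, s, point)
    for i in range(k):
        p = mesh.vertices[vids[i]]
        q = mesh.vertices[vids[(i + 1) % k]]
        e_vec = q - p
        denom = _cross2(e_vec, d)
        if abs(denom) < 1e-12:
            continue
        s = _cross2(centre - p, d) / denom
        t = _cross2(centre - p, e_vec) / denom
        if 0.0 <= s < 1.0:
            crossings.append((t, i, s, p + s * e_vec))
    neg = [c for c in crossings if c[0] < 0]
    pos = [c for c in crossings if c[0] > 0]
    if not neg or not pos:
        raise NotApplicableError("division line does not produce a chord")
    cross_a = max(neg, key=lambda c: c[0])
    cross_b = min(pos, key=lambda c: c[0])

    owners = mesh.edge_owners()
    new = mesh.copy()
    next_vid = max(new.vertices) + 1
    cut_ids = []
    for _, i, s, point in (cross_a, cross_b):
        va, vb = vids[i], vids[(i + 1) % k]
        if np.linalg.norm(point - mesh.vertices[va]) < snap_tol:
            cut_ids.append(va)
            continue
        if np.linalg.norm(point - mesh.vertices[vb]) < snap_tol:
            cut_ids.append(vb)
            continue
        w = next_vid
        next_vid += 1
        new.vertices[w] = point
        cut_ids.append(w)
        # insert into the mother's cycle after va
        cyc = new.cells[cell]
        cyc.insert(cyc.index(va) + 1, w)
        # and into the neighbour sharing this interface (reversed direction)
        shared = owners[frozenset((va, vb))]
        other = [x for x in shared if x != cell]
        if other:
            nvids = new.cells[other[0]]
            nvids.insert(nvids.index(vb) + 1, w)

    wa, wb = cut_ids
    if wa == wb:
        raise NotApplicableError("division chord collapsed to a point")
    cyc = new.cells[cell]
    ia, ib = cyc.index(wa), cyc.index(wb)
    if ia < ib:
        chain1 = cyc[ia : ib + 1]
        chain2 = cyc[ib:] + cyc[: ia + 1]
    else:
        chain1 = cyc[ia:] + cyc[: ib + 1]
        chain2 = cyc[ib : ia + 1]
    if len(chain1) < 3 or len(chain2) < 3:
        raise NotApplicableError("division chord grazes the cell boundary")
    d1 = max(new.cells) + 1
    d2 = d1 + 1
    del new.cells[cell]
    new.cells[d1] = chain1
    new.cells[d2] = chain2
    return new, (cell, d1, d2)


# ---------------------------------------------------------------------------
# Ground-truthed two-frame test cases
# ---------------------------------------------------------------------------


def _central_cell(mesh: Mesh, exclude_boundary: bool = True) -> list[int]:
    """Cell ids ordered by centroid distance to the tissue centre."""
    pts = np.array(list(mesh.vertices.values()))
    centre = (pts.min(axis=0) + pts.max(axis=0)) / 2.0
    ids = sorted(mesh.cells)
    if exclude_boundary:
        skip = boundary_cells(mesh)
        ids = [c for c in ids if c not in skip]
    return sorted(ids, key=lambda c: float(np.linalg.norm(mesh.centroid(c) - centre)))


def permutation_case(rng: np.random.Generator, m: int = 9, n: int = 9,
                     n_lloyd: int = 4) -> TrackingCase:
    """Identical tissues, shuffled ids."""
    mesh1 = generate_tissue(GenerationConfig(m=m, n=n, n_lloyd=n_lloyd), rng=rng)
    mesh2, truth = permute_ids(mesh1, rng)
    return TrackingCase(mesh1, mesh2, truth)


def translation_case(rng: np.random.Generator, n_lloyd: int = 4) -> TrackingCase:
    mesh1, mesh2, truth = translation_pair(rng, n_lloyd=n_lloyd)
    return TrackingCase(mesh1, mesh2, truth)


def t1_case(rng: np.random.Generator, m: int = 9, n: int = 9,
            n_lloyd: int = 4) -> TrackingCase:
    """One T1 transition on an interface near the centre of the tissue."""
    mesh1 = generate_tissue(GenerationConfig(m=m, n=n, n_lloyd=n_lloyd), rng=rng)
    edges = t1_edges(mesh1)
    if not edges:
        raise NotApplicableError("tissue has no T1-applicable interface")
    centre = np.array([m / 2.0, n / 2.0])
    edge = min(
        edges,
        key=lambda e: float(
            np.linalg.norm((mesh1.vertices[e[0]] + mesh1.vertices[e[1]]) / 2 - centre)
        ),
    )
    mesh2 = apply_t1(mesh1, edge)
    mesh2, perm = permute_ids(mesh2, rng)
    return TrackingCase(mesh1, mesh2, GroundTruth(map=dict(perm.map)))


def t2_case(rng: np.random.Generator, m: int = 9, n: int = 9,
            n_lloyd: int = 4) -> TrackingCase:
    """Removal of the central cell (T2 transition)."""
    mesh1 = generate_tissue(GenerationConfig(m=m, n=n, n_lloyd=n_lloyd), rng=rng)
    for cid in _central_cell(mesh1):
        try:
            mesh2 = apply_t2(mesh1, cid)
        except NotApplicableError:
            continue
        mesh2, perm = permute_ids(mesh2, rng)
        truth = GroundTruth(
            map={c: perm.map[c] for c in mesh1.cells if c != cid}, removals=[cid]
        )
        return TrackingCase(mesh1, mesh2, truth)
    raise NotApplicableError("no removable interior cell found")


def division_case(rng: np.random.Generator, m: int = 9, n: int = 9,
                  n_lloyd: int = 4) -> TrackingCase:
    """Division of the central cell along a random orientation."""
    mesh1 = generate_tissue(GenerationConfig(m=m, n=n, n_lloyd=n_lloyd), rng=rng)
    for cid in _central_cell(mesh1):
        for _ in range(20):
            try:
                mesh2, (mother, d1, d2) = apply_division(mesh1, cid, rng=rng)
            except NotApplicableError:
                continue
            mesh2, perm = permute_ids(mesh2, rng)
            da, db = sorted((perm.map[d1], perm.map[d2]))
            truth = GroundTruth(
                map={c: perm.map[c] for c in mesh1.cells if c != mother},
                divisions=[(mother, da, db)],
            )
            return TrackingCase(mesh1, mesh2, truth)
    raise NotApplicableError("no divisible interior cell found")
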