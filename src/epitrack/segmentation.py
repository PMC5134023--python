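"""Conversion between segmented label images, meshes and tracking tables.

A segmented frame is a 16-bit greyscale label image: every pixel of a cell
carries that cell's positive integer label, and the background (or membrane
skeleton, depending on the segmentation tool) carries ``background_label``.
Junctions are detected where pixels of three or more different cells meet;
the polygonal tessellation is assembled by assigning those junction vertices
to cells.  Cells touching the image border or the background are removed,
since their outlines are not closed polygons.

The module also rasterises meshes back into label images (used to validate
the extraction round trip) and reads/writes tracking results as
tab-separated tables.
"""

from __future__ import annotations

import warnings
from math import ceil

import numpy as np
import shapely

from .matching import CellMapping
from .mesh import Mesh
from .tracking import TrackingResult

__all__ = [
    "InvalidLabelImageError",
    "DegenerateFrameError",
    "TrackingTableError",
    "mesh_from_label_image",
    "rasterize_mesh",
    "read_label_image",
    "write_tracking",
    "read_tracking",
]


class InvalidLabelImageError(ValueError):
    """The label image violates its contract (e.g. a label is not connected)."""


class DegenerateFrameError(ValueError):
    """Fewer than three interior cells remain after boundary removal."""


class TrackingTableError(ValueError):
    """A tracking table could not be parsed."""


def read_label_image(path) -> np.ndarray:
    """Read a 16-bit label image from TIFF or PNG."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _validate_connectivity(img: np.ndarray, background_label: int) -> None:
    from skimage import measure

    # equal pixel values form one component; different labels split apart
    comps = measure.label(img, background=background_label, connectivity=1)
    # each label must live in exactly one 4-connected component
    pairs = np.unique(
        np.stack([img.ravel(), comps.ravel()]), axis=1
    )
    pairs = pairs[:, pairs[0] != background_label]
    labels, counts = np.unique(pairs[0], return_counts=True)
    split = labels[counts > 1]
    if len(split):
        raise InvalidLabelImageError(
            f"labels split into several 4-connected regions: {split.tolist()[:10]}"
        )


def mesh_from_label_image(
    img: np.ndarray,
    background_label: int = 0,
    min_edge_px: float = 2.0,
    validate: bool = True,
) -> Mesh:
    """Extract the polygonal tessellation from a segmented label image.

    Vertices are emitted wherever a 2x2 pixel window contains three or more
    distinct labels (the background counts as a label, so two cells meeting
    the background also produce a junction); the vertex sits at the window
    centre, so half-integer pixel coordinates occur.  Polygon edges shorter
    than ``min_edge_px`` are contracted to a single vertex at their
    midpoint, which merges duplicate detections of one junction and turns
    near-degenerate junctions into higher-order vertices.  Cells adjacent
    to the background or the image border are removed.

    Coordinates are pixels with x = column, y = row, origin at the top-left
    pixel centre.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise InvalidLabelImageError("label image must be two-dimensional")
    if validate:
        _validate_connectivity(img, background_label)
    padded = np.pad(img, 1, constant_values=background_label)

    # 2x2 windows: stack the four corners, count distinct labels
    corners = np.stack(
        [padded[:-1, :-1], padded[:-1, 1:], padded[1:, :-1], padded[1:, 1:]]
    )
    sorted_corners = np.sort(corners, axis=0)
    n_distinct = 1 + (np.diff(sorted_corners, axis=0) != 0).sum(axis=0)
    vr, vc = np.nonzero(n_distinct >= 3)

    # vertex positions in original image coordinates: window (r, c) of the
    # padded image covers original pixels (r-1, c-1)..(r, c)
    positions = np.stack([vc - 0.5, vr - 0.5], axis=1).astype(float)
    window_labels = [set(corners[:, r, c].tolist()) for r, c in zip(vr, vc)]

    # cells adjacent to the background (incl. the padded border) are boundary
    boundary_labels = {background_label}
    for a, b in ((padded[:, :-1], padded[:, 1:]), (padded[:-1, :], padded[1:, :])):
        diff = a != b
        for x, y in zip(a[diff].ravel(), b[diff].ravel()):
            if x == background_label:
                boundary_labels.add(int(y))
            elif y == background_label:
                boundary_labels.add(int(x))

    all_labels = [
        int(l) for l in np.unique(img) if l != background_label
    ]
    interior = [l for l in all_labels if l not in boundary_labels]
    if len(interior) < 3:
        raise DegenerateFrameError(
            f"only {len(interior)} interior cells after boundary removal"
        )

    # vertices per cell, ordered by angle about the pixel centroid
    cells_vertices: dict[int, list[int]] = {l: [] for l in interior}
    for vid, labels in enumerate(window_labels):
        for l in labels:
            if l in cells_vertices:
                cells_vertices[l].append(vid)
    rows, cols = np.nonzero(img != background_label)
    flat = img[rows, cols]
    cx = np.zeros(int(img.max()) + 1)
    cy = np.zeros(int(img.max()) + 1)
    np.add.at(cx, flat, cols)
    np.add.at(cy, flat, rows)
    counts = np.bincount(flat, minlength=int(img.max()) + 1)
    ordered: dict[int, list[int]] = {}
    for l, vids in cells_vertices.items():
        if len(vids) < 3:
            warnings.warn(f"cell {l} has fewer than 3 junctions; dropped", stacklevel=2)
            continue
        centre = np.array([cx[l] / counts[l], cy[l] / counts[l]])
        pts = positions[vids]
        angles = np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0])
        order = np.argsort(angles, kind="stable")
        ordered[l] = [vids[i] for i in order]

    # contract short polygon edges onto their midpoints
    uf = _UnionFind(len(positions))
    for vids in ordered.values():
        for i, v in enumerate(vids):
            w = vids[(i + 1) % len(vids)]
            if np.linalg.norm(positions[v] - positions[w]) < min_edge_px:
                uf.union(v, w)
    groups: dict[int, list[int]] = {}
    for v in range(len(positions)):
        groups.setdefault(uf.find(v), []).append(v)
    merged_pos = {root: positions[members].mean(axis=0) for root, members in groups.items()}

    mesh = Mesh()
    used: set[int] = set()
    for l, vids in ordered.items():
        reduced: list[int] = []
        for v in vids:
            r = uf.find(v)
            if not reduced or reduced[-1] != r:
                reduced.append(r)
        if len(reduced) > 1 and reduced[0] == reduced[-1]:
            reduced.pop()
        if len(reduced) < 3:
            warnings.warn(
                f"cell {l} degenerated after short-edge removal; dropped", stacklevel=2
            )
            continue
        for r in reduced:
            if r not in used:
                mesh.add_vertex(r, merged_pos[r])
                used.add(r)
        mesh.add_cell(l, reduced)
    if len(mesh.cells) < 3:
        raise DegenerateFrameError("fewer than 3 cells extracted")
    mesh.prune_unused_vertices()
    return mesh


def rasterize_mesh(
    mesh: Mesh,
    scale: float = 20.0,
    background_label: int = 0,
    pad_px: int = 3,
) -> tuple[np.ndarray, dict[int, int]]:
    """Draw a mesh as a synthetic 16-bit label image.

    Each pixel whose centre lies inside a cell polygon receives that cell's
    label; labels are the cell ids shifted to start at 1.  Returns the
    image and the label -> cell-id map.
    """
    pts = np.array(list(mesh.vertices.values()))
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    width = int(ceil((hi[0] - lo[0]) * scale)) + 2 * pad_px
    height = int(ceil((hi[1] - lo[1]) * scale)) + 2 * pad_px
    img = np.full((height, width), background_label, dtype=np.uint16)
    label_of = {}
    next_label = background_label + 1
    xs = (np.arange(width) + 0.5 - pad_px) / scale + lo[0]
    ys = (np.arange(height) + 0.5 - pad_px) / scale + lo[1]
    for cid in sorted(mesh.cells):
        poly = shapely.Polygon(mesh.points_of(cid))
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = np.searchsorted(xs, [minx, maxx])
        r0, r1 = np.searchsorted(ys, [miny, maxy])
        if c1 <= c0 or r1 <= r0:
            continue
        gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        block = img[r0:r1, c0:c1]
        block[inside] = next_label
        label_of[next_label] = cid
        next_label += 1
    return img, label_of


# ---------------------------------------------------------------------------
# Tracking tables
# ---------------------------------------------------------------------------

_HEADER = "frame\tcell_id\ttrack_id\tevent"
_MAP_EVENTS = {"seed", "mcs", "post"}


def write_tracking(result: TrackingResult, path) -> None:
    """Write a tracking result as a tab-separated table.

    One row per cell role: mapped cells appear once per frame sharing a
    track id (the frame-1 cell id), division mothers/daughters share a
    track id, deaths and untracked cells carry track id -1.
    """
    lines = [_HEADER]
    for c1 in sorted(result.mapping.pairs):
        c2 = result.mapping.pairs[c1]
        event = result.mapping.provenance.get(c1, "mcs")
        lines.append(f"1\t{c1}\t{c1}\t{event}")
        lines.append(f"2\t{c2}\t{c1}\t{event}")
    for mother, d1, d2 in sorted(result.divisions):
        lines.append(f"1\t{mother}\t{mother}\tdivision")
        lines.append(f"2\t{d1}\t{mother}\tdaughter")
        lines.append(f"2\t{d2}\t{mother}\tdaughter")
    for c in sorted(result.deaths):
        lines.append(f"1\t{c}\t-1\tdeath")
    for c in sorted(result.untracked1):
        lines.append(f"1\t{c}\t-1\tuntracked")
    for c in sorted(result.untracked2):
        lines.append(f"2\t{c}\t-1\tuntracked")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_tracking(path) -> TrackingResult:
    """Read a tracking table written by :func:`write_tracking`."""
    mapping = CellMapping()
    frame1_track: dict[int, tuple[int, str]] = {}
    frame2_track: dict[int, int] = {}
    mothers: dict[int, int] = {}
    daughters: dict[int, list[int]] = {}
    deaths: list[int] = []
    untracked1: list[int] = []
    untracked2: list[int] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _HEADER:
        raise TrackingTableError("line 1: missing or malformed header")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise TrackingTableError(f"line {lineno}: expected 4 columns, got {len(parts)}")
        try:
            frame, cell, tid = int(parts[0]), int(parts[1]), int(parts[2])
        except ValueError as err:
            raise TrackingTableError(f"line {lineno}: non-integer field ({err})")
        event = parts[3]
        if frame not in (1, 2):
            raise TrackingTableError(f"line {lineno}: frame must be 1 or 2")
        if event in _MAP_EVENTS:
            if frame == 1:
                frame1_track[tid] = (cell, event)
            else:
                frame2_track[tid] = cell
        elif event == "division":
            mothers[tid] = cell
        elif event == "daughter":
            daughters.setdefault(tid, []).append(cell)
        elif event == "death":
            deaths.append(cell)
        elif event == "untracked":
            (untracked1 if frame == 1 else untracked2).append(cell)
        else:
            raise TrackingTableError(f"line {lineno}: unknown event {event!r}")
    for tid, (c1, event) in frame1_track.items():
        if tid not in frame2_track:
            raise TrackingTableError(f"track {tid} has no frame-2 row")
        mapping.add(c1, frame2_track[tid], event)
    divisions = []
    for tid, mother in sorted(mothers.items()):
        ds = sorted(daughters.get(tid, []))
        if len(ds) != 2:
            raise TrackingTableError(f"division track {tid} has {len(ds)} daughters")
        divisions.append((mother, ds[0], ds[1]))
    return TrackingResult(
        mapping=mapping,
        divisions=divisions,
        deaths=sorted(deaths),
        untracked1=sorted(untracked1),
        untracked2=sorted(untracked2),
    )
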