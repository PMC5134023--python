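"""Post-processing of the cleaned MCS: growth, divisions, deaths, sequences.

The cleaned MCS covers cells whose local connectivity is unchanged between
frames.  Post-processing grows the tracking onto rearranging cells by
repeatedly adding the untracked pair with the most preserved connections to
already tracked cells; division events are then resolved from the
characteristic connectivity change around a dividing cell (two neighbours
gain an interface, mother and daughters are their shared neighbours), and
deaths are untracked first-frame cells that lie in the interior of the
tracked region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .matching import (
    CellMapping,
    TrackerConfig,
    _displacement_coherent,
    clean_mcs,
    extend_mcs,
    iter_seeds,
)
from .mesh import Mesh, build_network

__all__ = [
    "TrackingError",
    "TrackingResult",
    "SequenceResult",
    "post_process",
    "resolve_divisions",
    "detect_deaths",
    "track",
    "track_sequence",
]


class TrackingError(RuntimeError):
    """Raised when no initial match between two frames can be found."""


@dataclass
class TrackingResult:
    """Outcome of tracking one frame pair."""

    mapping: CellMapping
    divisions: list[tuple[int, int, int]] = field(default_factory=list)
    deaths: list[int] = field(default_factory=list)
    untracked1: list[int] = field(default_factory=list)
    untracked2: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        self.mapping.validate_injective()
        image = set(self.mapping.pairs.values())
        for mother, d1, d2 in self.divisions:
            if mother in self.mapping.pairs:
                raise ValueError(f"division mother {mother} still mapped")
            if d1 in image or d2 in image:
                raise ValueError(f"daughters of {mother} present in mapping image")
        if set(self.deaths) & set(self.mapping.pairs):
            raise ValueError("death recorded for a mapped cell")


@dataclass
class SequenceResult:
    """Pairwise tracking results chained with persistent track ids."""

    results: list[TrackingResult]
    track_ids: list[dict[int, int]]  # per frame: cell id -> track id
    lineage: dict[int, int] = field(default_factory=dict)  # daughter tid -> mother tid


def _dist(net1: nx.Graph, net2: nx.Graph, a: int, b: int) -> float:
    return float(np.linalg.norm(net1.nodes[a]["centroid"] - net2.nodes[b]["centroid"]))


def post_process(
    mapping: CellMapping,
    net1: nx.Graph,
    net2: nx.Graph,
    d_max: float,
    cfg: TrackerConfig | None = None,
) -> CellMapping:
    """Grow the tracking beyond the cleaned MCS.

    Repeatedly adds the untracked pair with the largest number of preserved
    connections to tracked cells, requiring at least
    ``post_min_tracked_neighbours`` preserved connections, that no cell
    gains more tracked neighbours than it preserves, and the distance
    cutoff.  Pairs are only ever added, never removed.
    """
    cfg = cfg or TrackerConfig()
    m = dict(mapping.pairs)
    prov = dict(mapping.provenance)
    inv = {v: k for k, v in m.items()}
    while True:
        best = None  # (-preserved, dist, a, b)
        for a in sorted(net1):
            if a in m:
                continue
            counts: dict[int, int] = {}
            for u in net1.adj[a]:
                v = m.get(u)
                if v is None:
                    continue
                for b in net2.adj[v]:
                    if b not in inv:
                        counts[b] = counts.get(b, 0) + 1
            for b, preserved in sorted(counts.items()):
                if preserved < cfg.post_min_tracked_neighbours:
                    continue
                gained = sum(1 for v in net2.adj[b] if v in inv) - preserved
                if gained > preserved:
                    continue
                d = _dist(net1, net2, a, b)
                if d > d_max:
                    continue
                if not _displacement_coherent(a, b, m, net1, net2, d_max, cfg):
                    continue
                key = (-preserved, d, a, b)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, _, a, b = best
        m[a] = b
        inv[b] = a
        prov[a] = "post"
    out = CellMapping(pairs=m, provenance=prov)
    out.validate_injective()
    return out


# ---------------------------------------------------------------------------
# Division resolution
# ---------------------------------------------------------------------------


def _division_candidates(
    cluster: set[int],
    mapping: CellMapping,
    inv: dict[int, int],
    net1: nx.Graph,
    net2: nx.Graph,
) -> list[tuple[int, int, int]]:
    """Enumerate consistent (mother, daughter1, daughter2) triples.

    A triple is consistent when the two adjacent frame-2 cells could jointly
    replace the frame-1 mother: every tracked neighbour of the mother maps
    to a neighbour of a daughter and every tracked neighbour of a daughter
    maps back to a neighbour of the mother.
    """
    m = mapping.pairs
    untracked1 = [a for a in sorted(net1) if a not in m]
    out = []
    seen: set[tuple[int, frozenset[int]]] = set()
    for p in sorted(cluster):
        for q in sorted(net2.adj[p]):
            if q in cluster and q < p:
                continue
            # an untracked neighbour of p is necessarily in the same cluster
            mothers = [inv[q]] if q in inv else untracked1
            for mother in mothers:
                key = (mother, frozenset((p, q)))
                if key in seen:
                    continue
                if _division_consistent(mother, p, q, m, inv, net1, net2):
                    seen.add(key)
                    out.append((mother, min(p, q), max(p, q)))
    return out


def _division_consistent(mother, p, q, m, inv, net1, net2) -> bool:
    # cells truncated by the image border also gain interfaces between
    # frames; genuine division signatures are only trusted in the interior
    if net1.nodes[mother].get("is_boundary", False):
        return False
    if net2.nodes[p].get("is_boundary", False) or net2.nodes[q].get("is_boundary", False):
        return False
    if mother in m and m[mother] not in (p, q):
        return False
    tracked_nbrs = [u for u in net1.adj[mother] if u in m and m[u] not in (p, q)]
    if len(tracked_nbrs) < 2:
        return False
    for u in tracked_nbrs:
        if m[u] not in net2.adj[p] and m[u] not in net2.adj[q]:
            return False
    daughter_nbrs = (set(net2.adj[p]) | set(net2.adj[q])) - {p, q}
    for v in daughter_nbrs:
        u = inv.get(v)
        if u is not None and u != mother and u not in net1.adj[mother]:
            return False
    # division evidence: a tracked cell bordering the cut is a common
    # neighbour of both daughters, gained an interface, and bordered the
    # mother before the division
    for v in set(net2.adj[p]) & set(net2.adj[q]) - {p, q}:
        u = inv.get(v)
        if (
            u is not None
            and u in net1.adj[mother]
            and net2.degree(v) > net1.degree(u)
        ):
            return True
    return False


def resolve_divisions(
    mapping: CellMapping,
    net1: nx.Graph,
    net2: nx.Graph,
    mesh1: Mesh,
    mesh2: Mesh,
) -> tuple[CellMapping, list[tuple[int, int, int]], list[str]]:
    """Identify (mother, daughter, daughter) triples among untracked cells.

    Division sites appear as clusters of untracked frame-2 cells.  Network
    evidence (neighbours that gained an interface, shared neighbours of
    those) usually determines the triple; when a daughter is three- or
    four-sided the evidence is ambiguous and the triple whose daughters lie
    closest to the mother is chosen.  Unresolvable clusters with division
    evidence are left untracked with a warning.
    """
    m = dict(mapping.pairs)
    prov = dict(mapping.provenance)
    inv = {v: k for k, v in m.items()}
    untracked2 = set(net2) - set(inv)
    divisions: list[tuple[int, int, int]] = []
    warnings_: list[str] = []
    clusters = sorted(
        (sorted(c) for c in nx.connected_components(net2.subgraph(untracked2))),
        key=lambda c: c[0],
    )
    work = CellMapping(pairs=m, provenance=prov)
    for cluster_nodes in clusters:
        cluster = set(cluster_nodes)
        cands = _division_candidates(cluster, work, inv, net1, net2)
        if not cands:
            if _gain_evidence(cluster, work, inv, net1, net2):
                warnings_.append(
                    f"possible division near frame-2 cells {cluster_nodes} "
                    "could not be resolved"
                )
            continue

        def geom_key(t):
            mother, p, q = t
            c1 = mesh1.centroid(mother)
            return (
                float(np.linalg.norm(c1 - mesh2.centroid(p)))
                + float(np.linalg.norm(c1 - mesh2.centroid(q))),
                t,
            )

        mother, p, q = min(cands, key=geom_key)
        if mother in work.pairs:
            old = work.pairs.pop(mother)
            work.provenance.pop(mother, None)
            inv.pop(old, None)
        divisions.append((mother, p, q))
    work.validate_injective()
    return work, divisions, warnings_


def _gain_evidence(cluster, mapping, inv, net1, net2) -> bool:
    for p in cluster:
        for v in net2.adj[p]:
            u = inv.get(v)
            if u is not None and net2.degree(v) > net1.degree(u):
                return True
    return False


def detect_deaths(
    mapping: CellMapping,
    divisions: list[tuple[int, int, int]],
    net1: nx.Graph,
    net2: nx.Graph | None = None,
) -> list[int]:
    """Untracked frame-1 cells interior to the tracked region.

    A cell counts as dead when it has no tracked match, is not a division
    mother, does not lie on the tissue boundary, and all of its neighbours
    are tracked (or mothers) — i.e. it vanished from the interior.  When
    the second frame's network is supplied, corroborating evidence is also
    required: a removal takes an interface away from each surrounding cell,
    so at least half of the tracked neighbours must show a net loss of
    edges.
    """
    mothers = {d[0] for d in divisions}
    accounted = set(mapping.pairs) | mothers
    deaths = []
    for u in sorted(net1):
        if u in accounted or net1.nodes[u].get("is_boundary", False):
            continue
        if not all(w in accounted for w in net1.adj[u]):
            continue
        if net2 is not None:
            tracked_nbrs = [w for w in net1.adj[u] if w in mapping.pairs]
            lost = sum(
                1
                for w in tracked_nbrs
                if net2.degree(mapping.pairs[w]) < net1.degree(w)
            )
            if 2 * lost < len(tracked_nbrs):
                continue
        deaths.append(u)
    return deaths


# ---------------------------------------------------------------------------
# Frame-pair and sequence drivers
# ---------------------------------------------------------------------------


def track(
    mesh1: Mesh,
    mesh2: Mesh,
    cfg: TrackerConfig | None = None,
) -> TrackingResult:
    """Track cells between two consecutive frames.

    Runs seeding, iterative MCS extension, cleaning, post-processing,
    division resolution and death detection in order.  Raises
    :class:`TrackingError` if no initial match exists (e.g. every
    neighbourhood in the tissue has changed).
    """
    cfg = cfg or TrackerConfig()
    net1 = build_network(mesh1)
    net2 = build_network(mesh2)
    d_max = cfg.d_max_cell_lengths * mesh1.average_cell_length
    # Several seeds may need to be searched before one whose extension
    # survives cleaning is found; near-homogeneous tissues can even support
    # self-consistent but shifted alignments, so seeds are searched until a
    # dominant (majority) alignment is found and the largest one is kept.
    mapping = None
    seen_seed = False
    nonempty = 0
    early_attempts = 0
    later_attempts = 0
    dominant = (2.0 / 3.0) * min(len(net1), len(net2))
    for seed in iter_seeds(net1, net2, d_max, cfg):
        seen_seed = True
        if mapping is not None:
            # a seed the best alignment already contains would only
            # reproduce it; spend effort on disagreeing seeds
            if mapping.pairs.get(seed[0]) == seed[1]:
                continue
            later_attempts += 1
        else:
            early_attempts += 1
        candidate = extend_mcs(seed, net1, net2, d_max, cfg)
        candidate = clean_mcs(candidate, net1, net2, cfg)
        if len(candidate) > 0:
            nonempty += 1
            if mapping is None or len(candidate) > len(mapping):
                mapping = candidate
        if mapping is not None and (
            len(mapping) >= dominant or nonempty >= 3 or later_attempts >= 6
        ):
            break
        if mapping is None and early_attempts >= 600:
            # a heavily rearranged pair whose seeds all die; give up
            # rather than scan every remaining pair
            break
    if mapping is None:
        if seen_seed:
            raise TrackingError("maximum common subgraph empty after cleaning")
        raise TrackingError("no initial cell match found between the two frames")
    mapping = post_process(mapping, net1, net2, d_max, cfg)
    mapping, divisions, warns = resolve_divisions(mapping, net1, net2, mesh1, mesh2)
    deaths = detect_deaths(mapping, divisions, net1, net2)
    daughters = {d for _, d1, d2 in divisions for d in (d1, d2)}
    mothers = {mother for mother, _, _ in divisions}
    inv = mapping.inverse()
    result = TrackingResult(
        mapping=mapping,
        divisions=divisions,
        deaths=deaths,
        untracked1=[
            c
            for c in sorted(net1)
            if c not in mapping.pairs and c not in mothers and c not in deaths
        ],
        untracked2=[c for c in sorted(net2) if c not in inv and c not in daughters],
        warnings=warns,
    )
    result.validate()
    return result


def track_sequence(
    meshes: list[Mesh],
    cfg: TrackerConfig | None = None,
) -> SequenceResult:
    """Chain pairwise tracking over a frame sequence with persistent ids.

    Track ids propagate along mappings; each daughter of a division gets a
    fresh id whose mother id is recorded in ``lineage``; unmatched cells
    entering the field of view get fresh ids.
    """
    if len(meshes) < 2:
        raise ValueError("need at least two frames")
    results = []
    for i in range(len(meshes) - 1):
        try:
            results.append(track(meshes[i], meshes[i + 1], cfg))
        except TrackingError as err:
            raise TrackingError(f"tracking failed between frames {i} and {i + 1}: {err}")
    next_tid = 0
    track_ids: list[dict[int, int]] = [{}]
    for c in sorted(meshes[0].cells):
        track_ids[0][c] = next_tid
        next_tid += 1
    lineage: dict[int, int] = {}
    for i, res in enumerate(results):
        ids: dict[int, int] = {}
        for u, v in sorted(res.mapping.pairs.items()):
            ids[v] = track_ids[i][u]
        for mother, d1, d2 in res.divisions:
            for d in (d1, d2):
                ids[d] = next_tid
                lineage[next_tid] = track_ids[i][mother]
                next_tid += 1
        for c in sorted(meshes[i + 1].cells):
            if c not in ids:
                ids[c] = next_tid
                next_tid += 1
        track_ids.append(ids)
    return SequenceResult(results=results, track_ids=track_ids, lineage=lineage)
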