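"""Seeded, iterative construction of the maximum common subgraph (MCS).

Finding a maximum common subgraph of two graphs is NP-hard in general, but
cell networks of epithelial sheets are planar and locally heterogeneous, so
the global MCS can be assembled from *exact* MCSs of small neighbourhood
graphs (a cell, its neighbours and second-nearest neighbours; around twenty
nodes).  The construction has three stages:

1. ``find_seed``: locate a pair of cells whose second-order neighbourhood
   networks are identical (isomorphic with matching centre), falling back to
   first-order neighbourhoods away from the tissue boundary.
2. ``extend_mcs``: iteratively add the most constrained untracked cell,
   choosing among candidate partners by the size of an exact local MCS of
   their neighbourhood graphs; the optimal choice may exclude a cell from
   the tracking altogether (e.g. a removed cell).
3. ``clean_mcs``: remove weakly connected pairs and small isolated clusters,
   which are the dominant source of mismatches.

Neighbourhood graphs are represented as adjacency bitmasks, which keeps the
exact branch-and-bound search fast enough to be run thousands of times per
frame pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "TrackerConfig",
    "CellMapping",
    "find_seed",
    "local_mcs",
    "extend_mcs",
    "clean_mcs",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Tracking parameters.

    ``d_max_cell_lengths`` is the centroid-distance cutoff (in frame-1
    average cell lengths) beyond which two cells are never paired.
    ``rel_disp_max_cell_lengths`` bounds how far a cell may move relative
    to its already-tracked neighbours when its pairing rests on imperfect
    structural evidence; adjacent cells of an epithelium move coherently,
    so a pairing that disagrees with its neighbours' displacement by more
    than a couple of cell lengths is spurious.
    ``min_mcs_connections`` is the minimum number of tracked neighbours with
    preserved adjacency a pair needs to survive cleaning, and clusters
    smaller than ``min_cluster_size`` are discarded entirely.  Cells added
    during post-processing need ``post_min_tracked_neighbours`` preserved
    connections.  These defaults are deliberately tissue-agnostic.
    """

    d_max_cell_lengths: float = 10.0
    min_mcs_connections: int = 3
    min_cluster_size: int = 11
    post_min_tracked_neighbours: int = 2
    rel_disp_max_cell_lengths: float = 0.75
    mcs_node_budget: int = 100_000

    def __post_init__(self) -> None:
        if min(
            self.d_max_cell_lengths,
            self.min_mcs_connections,
            self.min_cluster_size,
            self.post_min_tracked_neighbours,
        ) <= 0:
            raise ValueError("all tracker parameters must be positive")


@dataclass
class CellMapping:
    """Partial one-to-one correspondence between cells of two frames."""

    pairs: dict[int, int] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)

    def inverse(self) -> dict[int, int]:
        return {v: k for k, v in self.pairs.items()}

    def add(self, c1: int, c2: int, source: str) -> None:
        self.pairs[c1] = c2
        self.provenance[c1] = source

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, c1: int) -> bool:
        return c1 in self.pairs

    def validate_injective(self) -> None:
        if len(set(self.pairs.values())) != len(self.pairs):
            raise ValueError("mapping is not injective")


# ---------------------------------------------------------------------------
# Bitmask neighbourhood graphs
# ---------------------------------------------------------------------------


class _NeighbourhoodIndex:
    """Cached bitmask encodings of order-k neighbourhood graphs of a network."""

    def __init__(self, net: nx.Graph, order: int = 2) -> None:
        self.net = net
        self.order = order
        self._cache: dict[int, tuple[list[int], dict[int, int], list[int]]] = {}

    def get(self, cell: int) -> tuple[list[int], dict[int, int], list[int]]:
        """Return (nodes, node->bit index, adjacency bitmasks) for a cell."""
        hit = self._cache.get(cell)
        if hit is not None:
            return hit
        adj = self.net.adj
        nodes = {cell} | set(adj[cell])
        if self.order == 2:
            for nb in adj[cell]:
                nodes |= set(adj[nb])
        ordered = sorted(nodes)
        index = {n: i for i, n in enumerate(ordered)}
        masks = [0] * len(ordered)
        for n in ordered:
            i = index[n]
            m = 0
            for nb in adj[n]:
                j = index.get(nb)
                if j is not None:
                    m |= 1 << j
            masks[i] = m
        out = (ordered, index, masks)
        self._cache[cell] = out
        return out


def _iter_bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _mcs_size(
    adj1: list[int],
    adj2: list[int],
    seed_pairs: list[tuple[int, int]],
    labels1: list[int] | None = None,
    labels2: list[int] | None = None,
    budget: int = 100_000,
    target: int | None = None,
) -> int:
    """Size of a maximum common connected induced subgraph of two small graphs.

    ``seed_pairs`` are taken as given (counted, never revised).  A new pair
    (i, j) may be added when i is adjacent to the mapped set and the mapped
    neighbours of i correspond exactly to the mapped neighbours of j, so the
    correspondence is an induced-subgraph isomorphism outside the seeds.
    ``budget`` caps branch-and-bound expansions deterministically, and the
    search stops as soon as ``target`` (by default the largest conceivable
    size) is reached, so callers that only need a threshold decision pay a
    fraction of the full search.
    """
    n1, n2 = len(adj1), len(adj2)
    all1 = (1 << n1) - 1
    goal = min(n1, n2) if target is None else min(target, min(n1, n2))
    map12 = [-1] * n1
    mapped1 = 0
    used2 = 0
    for i, j in seed_pairs:
        map12[i] = j
        mapped1 |= 1 << i
        used2 |= 1 << j
    best = len(seed_pairs)
    if best >= goal:
        return best
    nbrs1 = [[k for k in range(n1) if adj1[i] >> k & 1] for i in range(n1)]
    state = {"calls": 0, "best": best, "done": False}

    def rec(mapped1: int, used2: int, excluded1: int, size: int) -> None:
        if state["done"]:
            return
        if size > state["best"]:
            state["best"] = size
            if size >= goal:
                state["done"] = True
                return
        state["calls"] += 1
        if state["calls"] > budget:
            state["done"] = True
            return
        free1 = all1 & ~mapped1 & ~excluded1
        if size + min(free1.bit_count(), n2 - used2.bit_count()) <= state["best"]:
            return
        # most constrained frontier node of graph 1 (early break at <=1)
        pick = -1
        pick_cands: list[int] | None = None
        m = free1
        while m:
            low = m & -m
            i = low.bit_length() - 1
            m ^= low
            if mapped1 and not (adj1[i] & mapped1):
                continue
            img = 0
            for k in nbrs1[i]:
                if mapped1 >> k & 1:
                    img |= 1 << map12[k]
            li = labels1[i] if labels1 is not None else None
            cands = []
            for j in range(n2):
                if not (used2 >> j & 1) and (adj2[j] & used2) == img:
                    if li is not None and labels2[j] != li:
                        continue
                    cands.append(j)
            if pick < 0 or len(cands) < len(pick_cands):
                pick, pick_cands = i, cands
                if len(cands) <= 1:
                    break
        if pick < 0:
            return
        pb = 1 << pick
        for j in pick_cands:
            map12[pick] = j
            rec(mapped1 | pb, used2 | (1 << j), excluded1, size + 1)
            if state["done"]:
                map12[pick] = -1
                return
        map12[pick] = -1
        rec(mapped1, used2, excluded1 | pb, size)

    rec(mapped1, used2, 0, len(seed_pairs))
    return state["best"]


def local_mcs(
    nbhd1: nx.Graph, nbhd2: nx.Graph, anchor: tuple[int, int] | None = None
) -> CellMapping:
    """Exact maximum common connected subgraph mapping of two neighbourhood graphs.

    The centre cells (graph attribute ``centre``, or ``anchor``) are forced
    to correspond.  Returns the mapping; its size is the match score used
    during iterative MCS extension.
    """
    if anchor is None:
        anchor = (nbhd1.graph.get("centre"), nbhd2.graph.get("centre"))
    nodes1 = sorted(nbhd1)
    nodes2 = sorted(nbhd2)
    idx1 = {n: i for i, n in enumerate(nodes1)}
    idx2 = {n: i for i, n in enumerate(nodes2)}
    adj1 = [0] * len(nodes1)
    adj2 = [0] * len(nodes2)
    for u, v in nbhd1.edges:
        adj1[idx1[u]] |= 1 << idx1[v]
        adj1[idx1[v]] |= 1 << idx1[u]
    for u, v in nbhd2.edges:
        adj2[idx2[u]] |= 1 << idx2[v]
        adj2[idx2[v]] |= 1 << idx2[u]
    seed = []
    if anchor[0] is not None and anchor[1] is not None:
        seed = [(idx1[anchor[0]], idx2[anchor[1]])]
    # rerun the bitmask search, recording the best mapping
    best_map: dict[int, int] = {}

    n1 = len(nodes1)
    best_size = _mcs_size(adj1, adj2, seed)
    # reconstruct one optimal mapping by greedy re-search with forced pairs
    forced = list(seed)
    while True:
        extended = False
        mapped = {i for i, _ in forced}
        used = {j for _, j in forced}
        for i in range(n1):
            if i in mapped:
                continue
            for j in range(len(nodes2)):
                if j in used:
                    continue
                trial = forced + [(i, j)]
                if not _seed_consistent(adj1, adj2, trial):
                    continue
                if _mcs_size(adj1, adj2, trial) == best_size:
                    forced = trial
                    extended = True
                    break
            if extended:
                break
        if not extended:
            break
    for i, j in forced:
        best_map[nodes1[i]] = nodes2[j]
    out = CellMapping()
    for u, v in best_map.items():
        out.add(u, v, "mcs")
    return out


def _seed_consistent(adj1, adj2, pairs) -> bool:
    m12 = {i: j for i, j in pairs}
    for i, j in pairs:
        for i2, j2 in pairs:
            if i == i2:
                continue
            if bool(adj1[i] & (1 << i2)) != bool(adj2[j] & (1 << j2)):
                return False
    # connectivity of the common subgraph (ignoring singleton seed)
    if len(pairs) > 1:
        seen = {pairs[0][0]}
        frontier = [pairs[0][0]]
        nodes = set(m12)
        while frontier:
            i = frontier.pop()
            for k in _iter_bits(adj1[i]):
                if k in nodes and k not in seen:
                    seen.add(k)
                    frontier.append(k)
        if seen != nodes:
            return False
    return True


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def _subgraph_degree_signature(adj_masks: list[int]) -> tuple:
    return tuple(sorted(bin(m).count("1") for m in adj_masks))


def _touches_boundary(net: nx.Graph, cell: int) -> bool:
    if net.nodes[cell].get("is_boundary", False):
        return True
    return any(net.nodes[nb].get("is_boundary", False) for nb in net.adj[cell])


def find_seed(
    net1: nx.Graph,
    net2: nx.Graph,
    d_max: float,
    cfg: TrackerConfig | None = None,
) -> tuple[int, int] | None:
    """First cell-to-cell match: identical surrounding network structure.

    A pair qualifies if the induced graphs on their second-order
    neighbourhoods are isomorphic (with centres corresponding and
    whole-network degrees respected) and their centroids are within
    ``d_max``.  If no such pair exists, first-order neighbourhoods that do
    not touch the tissue boundary are tried instead.  Returns ``None`` if
    both passes fail; the caller reports the tracking failure.
    """
    for pair in iter_seeds(net1, net2, d_max, cfg):
        return pair
    return None


def iter_seeds(
    net1: nx.Graph,
    net2: nx.Graph,
    d_max: float,
    cfg: TrackerConfig | None = None,
):
    """Yield qualifying seed pairs in deterministic scan order.

    Several cells may have to be tried before a seed whose extension
    survives cleaning is found (isolated boundary cells can have small,
    accidentally isomorphic neighbourhoods), so the caller consumes pairs
    lazily.
    """
    cfg = cfg or TrackerConfig()
    if len(net1) == 0 or len(net2) == 0:
        return
    deg2_index: dict[int, list[int]] = {}
    for c2 in sorted(net2):
        deg2_index.setdefault(net2.degree(c2), []).append(c2)
    # last resort: unrestricted first-order pass, reached only when every
    # stricter seed has failed to survive extension and cleaning; by then
    # structure carries little information, so its pairs are tried nearest
    # first instead of in id order
    for order, interior_only in ((2, False), (1, True), (1, False)):
        cache1 = _NeighbourhoodIndex(net1, order)
        cache2 = _NeighbourhoodIndex(net2, order)
        sig2_cache: dict[int, tuple] = {}
        iso_cache1: dict[int, nx.Graph] = {}
        iso_cache2: dict[int, nx.Graph] = {}

        def iso_graph(net, cache_nbhd, iso_cache, cell):
            g = iso_cache.get(cell)
            if g is None:
                nodes, _, _ = cache_nbhd.get(cell)
                g = nx.Graph()
                g.add_nodes_from(nodes)
                sub = net.subgraph(nodes)
                g.add_edges_from(sub.edges)
                for n in nodes:
                    g.nodes[n]["ctr"] = n == cell
                iso_cache[cell] = g
            return g

        def sig(c1):
            nodes1, _, adj1 = cache1.get(c1)
            return (len(nodes1), _subgraph_degree_signature(adj1))

        def compatible(c1, c2, sig1, p1):
            if interior_only and _touches_boundary(net2, c2):
                return None
            d = float(np.linalg.norm(p1 - net2.nodes[c2]["centroid"]))
            if d > d_max:
                return None
            if c2 not in sig2_cache:
                _, _, adj2 = cache2.get(c2)
                sig2_cache[c2] = (len(cache2.get(c2)[0]), _subgraph_degree_signature(adj2))
            if sig2_cache[c2] != sig1:
                return None
            return d

        def isomorphic(c1, c2):
            g1 = iso_graph(net1, cache1, iso_cache1, c1)
            g2 = iso_graph(net2, cache2, iso_cache2, c2)
            return nx.vf2pp_is_isomorphic(g1, g2, node_label="ctr")

        if order == 1:
            # first-order passes only run when no second-order structure
            # matched anywhere, so structure carries little information and
            # compatible pairs are tried nearest-first instead
            scored = []
            for c1 in sorted(net1):
                if interior_only and _touches_boundary(net1, c1):
                    continue
                sig1 = sig(c1)
                p1 = net1.nodes[c1]["centroid"]
                for c2 in deg2_index.get(net1.degree(c1), ()):
                    d = compatible(c1, c2, sig1, p1)
                    if d is not None:
                        scored.append((d, c1, c2))
            scored.sort()
            for _, c1, c2 in scored:
                if isomorphic(c1, c2):
                    yield (c1, c2)
            continue

        for c1 in sorted(net1):
            if interior_only and _touches_boundary(net1, c1):
                continue
            sig1 = sig(c1)
            p1 = net1.nodes[c1]["centroid"]
            matches = []
            for c2 in deg2_index.get(net1.degree(c1), ()):
                if compatible(c1, c2, sig1, p1) is None:
                    continue
                if isomorphic(c1, c2):
                    matches.append(c2)
                    if order == 2 and len(matches) > 1:
                        break
            if order == 2:
                # a second-order seed must be unambiguous: in homogeneous
                # regions several cells share a neighbourhood structure and
                # any of them could seed a coherent but shifted alignment
                if len(matches) == 1:
                    yield (c1, matches[0])
            else:
                yield from ((c1, c2) for c2 in matches)


# ---------------------------------------------------------------------------
# Iterative extension
# ---------------------------------------------------------------------------


def _displacement_coherent(
    a: int,
    b: int,
    pairs: dict[int, int],
    net1: nx.Graph,
    net2: nx.Graph,
    d_max: float,
    cfg: TrackerConfig,
) -> bool:
    """Is the displacement of pair (a, b) consistent with its tracked neighbours?"""
    disps = []
    for u in net1.adj[a]:
        v = pairs.get(u)
        if v is not None:
            disps.append(net2.nodes[v]["centroid"] - net1.nodes[u]["centroid"])
    if not disps:
        return True
    mean = np.mean(disps, axis=0)
    own = net2.nodes[b]["centroid"] - net1.nodes[a]["centroid"]
    cell_length = d_max / cfg.d_max_cell_lengths
    return float(np.linalg.norm(own - mean)) <= cfg.rel_disp_max_cell_lengths * cell_length


class _ExtensionState:
    def __init__(self, net1: nx.Graph, net2: nx.Graph, d_max: float, cfg: TrackerConfig):
        self.net1 = net1
        self.net2 = net2
        self.d_max = d_max
        self.cfg = cfg
        self.mapping = CellMapping()
        self.inv: dict[int, int] = {}
        self.cache1 = _NeighbourhoodIndex(net1, 2)
        self.cache2 = _NeighbourhoodIndex(net2, 2)
        # cell -> tracked-context size when it was last rejected; the cell
        # is re-inspected once more of its neighbourhood has been tracked
        self.blocked: dict[int, int] = {}
        self._pos1 = {
            c: (float(p[0]), float(p[1]))
            for c, p in ((c, net1.nodes[c]["centroid"]) for c in net1)
        }
        self._pos2 = {
            c: (float(p[0]), float(p[1]))
            for c, p in ((c, net2.nodes[c]["centroid"]) for c in net2)
        }
        self.deg1 = dict(net1.degree)
        self.deg2 = dict(net2.degree)
        self.deg2_index: dict[int, list[int]] = {}
        for c in sorted(net2):
            self.deg2_index.setdefault(self.deg2[c], []).append(c)

    def add(self, c1: int, c2: int, source: str) -> None:
        self.mapping.add(c1, c2, source)
        self.inv[c2] = c1

    def context_size(self, a: int) -> int:
        nodes, _, _ = self.cache1.get(a)
        return sum(1 for u in nodes if u != a and u in self.mapping.pairs)

    def is_blocked(self, a: int) -> bool:
        stored = self.blocked.get(a)
        if stored is None:
            return False
        if self.context_size(a) > stored:
            del self.blocked[a]
            return False
        return True

    def block(self, a: int) -> None:
        self.blocked[a] = self.context_size(a)

    def dist(self, c1: int, c2: int) -> float:
        p = self._pos1[c1]
        q = self._pos2[c2]
        return math.hypot(p[0] - q[0], p[1] - q[1])

    def displacement_coherent(self, a: int, b: int) -> bool:
        return _displacement_coherent(
            a, b, self.mapping.pairs, self.net1, self.net2, self.d_max, self.cfg
        )

    # -- candidate partners -------------------------------------------

    def candidates(self, a: int) -> list[int]:
        """Frame-2 cells with a's neighbour count that preserve all tracked
        connections of ``a`` in both directions, within the distance cutoff.

        For boundary cells the in-frame neighbour count is an artefact of
        where the field of view (or tissue) ends, so the count comparison is
        waived when either cell lies on its frame's boundary.
        """
        net1, net2, m = self.net1, self.net2, self.mapping.pairs
        tracked_nbrs = [u for u in net1.adj[a] if u in m]
        deg = self.deg1[a]
        a_boundary = net1.nodes[a].get("is_boundary", False)
        if tracked_nbrs:
            base = sorted(net2.adj[m[tracked_nbrs[0]]])
        else:
            base = self.deg2_index.get(deg, [])
        exact: list[int] = []
        relaxed: list[int] = []
        for b in base:
            if b in self.inv:
                continue
            same_degree = self.deg2[b] == deg
            if not same_degree and not (
                a_boundary or net2.nodes[b].get("is_boundary", False)
            ):
                continue
            if self.dist(a, b) > self.d_max:
                continue
            if any(m[u] not in net2.adj[b] for u in tracked_nbrs):
                continue
            ok = True
            for v in net2.adj[b]:
                u = self.inv.get(v)
                if u is not None and u not in net1.adj[a]:
                    ok = False
                    break
            if ok:
                (exact if same_degree else relaxed).append(b)
        # a degree-preserving candidate always outranks boundary-relaxed ones
        return exact if exact else relaxed

    # -- local-MCS scoring --------------------------------------------

    def _score(self, a: int, b: int, force: bool, target: int | None = None) -> int:
        nodes1, idx1, adj1 = self.cache1.get(a)
        nodes2, idx2, adj2 = self.cache2.get(b)
        in2 = set(nodes2)
        seed = []
        for u in nodes1:
            v = self.mapping.pairs.get(u)
            if v is not None and v in in2:
                seed.append((idx1[u], idx2[v]))
        if force:
            seed.append((idx1[a], idx2[b]))
            return (
                _mcs_size(
                    adj1,
                    adj2,
                    seed,
                    budget=self.cfg.mcs_node_budget,
                    target=len(nodes1),
                ),
                len(nodes1),
            )
        # exclusion score: same neighbourhoods with a and b removed
        keep1 = [n for n in nodes1 if n != a]
        keep2 = [n for n in nodes2 if n != b]
        r1 = {n: i for i, n in enumerate(keep1)}
        r2 = {n: i for i, n in enumerate(keep2)}
        adj1x = [0] * len(keep1)
        adj2x = [0] * len(keep2)
        for n in keep1:
            for k in _iter_bits(adj1[idx1[n]]):
                nb = nodes1[k]
                if nb in r1:
                    adj1x[r1[n]] |= 1 << r1[nb]
        for n in keep2:
            for k in _iter_bits(adj2[idx2[n]]):
                nb = nodes2[k]
                if nb in r2:
                    adj2x[r2[n]] |= 1 << r2[nb]
        seedx = [
            (r1[u], r2[v])
            for u, v in (
                (u, self.mapping.pairs.get(u)) for u in keep1
            )
            if v is not None and v in r2
        ]
        return _mcs_size(
            adj1x, adj2x, seedx, budget=self.cfg.mcs_node_budget, target=target
        )

    def try_add(self, a: int, cands: list[int], source: str) -> bool:
        cands = [b for b in cands if self.displacement_coherent(a, b)]
        if not cands:
            self.block(a)
            return False
        scored = []
        full = None
        for b in cands:
            s, full = self._score(a, b, force=True)
            scored.append((-s, self.dist(a, b), b))
        scored.sort()
        s_best = -scored[0][0]
        b_best = scored[0][2]
        if s_best < full:
            # an imperfect local match is only trustworthy once enough of
            # the surrounding cells are themselves tracked; early in the
            # extension the local MCS of two disordered patches cannot
            # discriminate, so defer the cell until context has grown
            nodes1, _, _ = self.cache1.get(a)
            n_anchors = sum(1 for u in nodes1 if u != a and u in self.mapping.pairs)
            if n_anchors < self.cfg.min_mcs_connections:
                self.block(a)
                return False
            s_excl = self._score(a, b_best, force=False, target=s_best)
            if s_excl >= s_best:
                self.block(a)
                return False
        self.add(a, b_best, source)
        return True


def extend_mcs(
    seed: tuple[int, int],
    net1: nx.Graph,
    net2: nx.Graph,
    d_max: float,
    cfg: TrackerConfig | None = None,
) -> CellMapping:
    """Grow the MCS from a seed pair by repeated local-MCS matching.

    At each step the untracked frame-1 cell adjacent to the MCS with the
    fewest candidate partners is matched to the candidate maximising the
    local MCS of their neighbourhood graphs — unless excluding the cell
    gives a local MCS at least as large, in which case it is skipped (it
    may be re-inspected after the MCS has grown).  When no adjacent cell
    extends the MCS, non-adjacent untracked cells are tried once, then the
    adjacency-restricted search resumes; the procedure halts at a fixpoint.
    """
    cfg = cfg or TrackerConfig()
    st = _ExtensionState(net1, net2, d_max, cfg)
    st.add(seed[0], seed[1], "seed")

    def adjacent_pass() -> bool:
        m = st.mapping.pairs
        progressed = False
        while True:
            frontier = sorted(
                {
                    a
                    for u in m
                    for a in net1.adj[u]
                    if a not in m and not st.is_blocked(a)
                }
            )
            cand_map = [(a, st.candidates(a)) for a in frontier]
            cand_map = [(a, c) for a, c in cand_map if c]
            if not cand_map:
                return progressed
            cand_map.sort(key=lambda ac: (len(ac[1]), ac[0]))
            step = False
            for a, cands in cand_map:
                if st.try_add(a, cands, "mcs"):
                    step = True
                    progressed = True
                    break
            if not step:
                return progressed

    def nonadjacent_step() -> bool:
        # a cell with no tracked neighbour carries no connection constraints,
        # so re-seeding away from the MCS demands the full seed criterion:
        # isomorphic second-order neighbourhoods with matching degrees
        m = st.mapping.pairs
        adjacent = {a for u in m for a in net1.adj[u] if a not in m}
        rest = [
            a
            for a in sorted(net1)
            if a not in m and a not in adjacent and not st.is_blocked(a)
        ]
        for a in rest:
            nodes1, idx1, adj1 = st.cache1.get(a)
            labels1 = [st.deg1[n] for n in nodes1]
            matches = []
            for b in st.candidates(a):
                nodes2, idx2, adj2 = st.cache2.get(b)
                if len(nodes2) != len(nodes1):
                    continue
                labels2 = [st.deg2[n] for n in nodes2]
                if sorted(labels1) != sorted(labels2):
                    continue
                size = _mcs_size(
                    adj1,
                    adj2,
                    [(idx1[a], idx2[b])],
                    labels1,
                    labels2,
                    budget=cfg.mcs_node_budget,
                    target=len(nodes1),
                )
                if size == len(nodes1):
                    matches.append(b)
                    if len(matches) > 1:
                        break
            # like the initial seed, a re-seed away from the MCS must be
            # unambiguous: several structurally identical partners mean a
            # homogeneous region where any choice may start a shifted island
            if len(matches) == 1:
                st.add(a, matches[0], "mcs")
                return True
            # an unmatched or ambiguous re-seed will not change until more
            # of this cell's surroundings have been tracked
            st.block(a)
        return False

    while True:
        adjacent_pass()
        if not nonadjacent_step():
            break
    st.mapping.validate_injective()
    return st.mapping


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def _preserved_neighbours(pairs: dict[int, int], net1: nx.Graph, net2: nx.Graph,
                          u: int) -> int:
    v = pairs[u]
    return sum(
        1 for w in net1.adj[u] if w in pairs and pairs[w] in net2.adj[v]
    )


def clean_mcs(
    mapping: CellMapping,
    net1: nx.Graph,
    net2: nx.Graph,
    cfg: TrackerConfig | None = None,
) -> CellMapping:
    """Remove weakly connected pairs and small clusters from the MCS.

    A pair survives only if at least ``min_mcs_connections`` of its tracked
    neighbours keep their adjacency to it in both frames (evaluated
    simultaneously on the incoming mapping), and only if it belongs to a
    connected cluster of preserved-adjacency pairs of at least
    ``min_cluster_size`` cells.
    """
    cfg = cfg or TrackerConfig()
    pairs = dict(mapping.pairs)
    # one simultaneous pass: iterating to a fixpoint would erode thin but
    # perfectly valid tracked regions (e.g. narrow overlap bands) from the
    # outside in, whereas mismatched pairs sit in weakly connected patches
    # that a single pass plus the cluster filter below removes
    keep = {
        u
        for u in pairs
        if _preserved_neighbours(pairs, net1, net2, u) >= cfg.min_mcs_connections
    }
    pairs = {u: v for u, v in pairs.items() if u in keep}

    cluster_graph = nx.Graph()
    cluster_graph.add_nodes_from(pairs)
    for u in pairs:
        for w in net1.adj[u]:
            if w in pairs and pairs[w] in net2.adj[pairs[u]]:
                cluster_graph.add_edge(u, w)
    out = CellMapping()
    for comp in nx.connected_components(cluster_graph):
        if len(comp) >= cfg.min_cluster_size:
            for u in sorted(comp):
                out.add(u, pairs[u], mapping.provenance.get(u, "mcs"))
    out.validate_injective()
    return out
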