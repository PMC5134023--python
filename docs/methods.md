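# Methods

## Problem and representation

Tracking cells between consecutive segmented frames of an epithelial sheet
means finding, for each cell of the first frame, the cell of the second
frame that is the same physical cell, while recognising cells that divided,
were removed (by delamination, extrusion or death) or entered/left the
field of view.  `epitrack` operates almost entirely on the *topology* of
the tissue.  Each frame is a polygonal tessellation (`Mesh`): vertices at
junctions where three or more cells meet, one counter-clockwise polygon per
cell.  Its dual is the cell network: one node per cell, an edge whenever
two cells share a polygon edge.  Because neighbour relations change slowly
— even when the tissue deforms substantially or frames are far apart in
time — the largest sub-network common to two consecutive frames (a maximum
common subgraph, MCS) pairs most cells correctly without relying on precise
positions.

Exact MCS detection is NP-hard, but epithelial networks are planar and
locally heterogeneous, which makes a seed-and-extend construction
practical: every decision is made by an *exact* search on neighbourhood
graphs of ~20 nodes, never on the full network.

## Pipeline

`track(mesh1, mesh2)` runs six stages.

1. **Seeding.**  Scan frame-1 cells in id order for a cell whose induced
   second-order neighbourhood graph (the cell, its neighbours and their
   neighbours) is isomorphic — with the centres corresponding — to that of
   exactly one frame-2 cell within the distance cutoff.  Requiring
   uniqueness matters: in homogeneous regions several cells share a
   neighbourhood structure, and committing to an arbitrary one can seed a
   self-consistent but shifted alignment.  If no second-order seed exists,
   first-order neighbourhoods not touching the tissue boundary are tried,
   and as a last resort first-order neighbourhoods anywhere; the
   first-order passes only run when structure has failed to discriminate,
   so their compatible pairs are tried nearest-first.  Seeds are consumed
   lazily: each candidate seed is extended and cleaned, and the search
   stops once an alignment covers two thirds of the smaller frame (or
   after three surviving alignments, or six disagreeing attempts beyond
   the first survivor, keeping the largest; seeds contained in the current
   best alignment are skipped).  Searching several seeds is routine — a
   seed's extension can die in cleaning when the seed was spurious — and
   a few hundred failed attempts without any survivor end the search with
   a tracking failure rather than a guess.

2. **Iterative extension.**  Maintain a partial injective mapping.  At each
   step, consider untracked frame-1 cells adjacent to the mapped set and,
   among them, the one with the fewest candidate partners.  A candidate
   partner must have the same neighbour count (waived when either cell lies
   on its frame's boundary, where the count is an artefact of the field of
   view — and then only if no count-preserving candidate exists), must
   preserve every connection to already-tracked cells in both directions,
   must lie within the distance cutoff, and must move coherently with its
   tracked neighbours (below).  Candidates are ranked by the size of the
   exact local MCS of the two cells' second-order neighbourhood graphs,
   anchored at the already-tracked pairs and at the candidate pair; ties
   break by centroid distance, then id.  If the winning score is imperfect,
   the pairing is accepted only when at least three neighbourhood cells are
   already tracked (otherwise the comparison has no power and the cell is
   deferred) and when forcing the pair beats excluding the cell from its
   local MCS altogether — the exclusion branch is how removed cells avoid
   being mapped.  Deferred cells are re-inspected once more of their
   neighbourhood has been tracked.  When no adjacent cell extends the
   mapping, untracked cells away from the mapped set are tried under the
   full seed criterion (unique degree-labelled isomorphism), after which
   adjacency-restricted extension resumes; the procedure halts at a
   fixpoint.

3. **Cleaning.**  In one simultaneous pass, remove every pair with fewer
   than `min_mcs_connections = 3` tracked neighbours whose adjacency is
   preserved in both frames; then remove connected components of the
   preserved-adjacency graph with fewer than `min_cluster_size = 11` cells.
   A single pass (rather than iterating to a fixpoint) is deliberate:
   mismatches sit in weakly connected patches that one pass plus the
   cluster filter removes, whereas iterated removal eats thin but perfectly
   valid tracked regions — e.g. the narrow overlap band of two shifted
   fields of view — from the perimeter inwards.

4. **Post-processing.**  Grow the cleaned mapping by repeatedly adding the
   untracked pair with the most preserved connections to tracked cells,
   subject to: at least `post_min_tracked_neighbours = 2` preserved
   connections; no cell may gain more tracked neighbours than it preserves;
   the distance cutoff; and displacement coherence.  Pairs are only added,
   never removed.  This stage tracks the cells the MCS deliberately left
   out: cells bordering a neighbour exchange, a removal or a division.

5. **Division resolution.**  Untracked frame-2 cells are grouped into
   connected clusters.  For a cluster, candidate triples (mother, daughter,
   daughter) are enumerated: the daughters are adjacent, each untracked or
   currently mapped from the mother; every tracked neighbour of the mother
   must map next to a daughter and vice versa; all three cells must be
   interior (cells truncated by the image border also gain interfaces and
   would otherwise fake the signature); and at least one tracked common
   neighbour of both daughters must have gained an interface while
   bordering the mother — the tell-tale cells flanking the new interface.
   If several triples qualify (which happens when a daughter is three- or
   four-sided, so the network evidence is ambiguous), the triple whose
   daughters' centroids lie closest to the mother's is chosen, the mother's
   provisional mapping (usually onto one daughter) is retracted, and the
   division is recorded.  Clusters with gain evidence but no consistent
   triple produce a warning and stay untracked — adjacent simultaneous
   divisions are a known failure mode.

6. **Death detection.**  A frame-1 cell is reported dead when it is
   untracked, not a division mother, not on the tissue boundary, all of its
   neighbours are tracked, and at least half of those tracked neighbours
   show a net loss of interfaces — a removal takes one interface away from
   each surrounding cell, and without this corroboration an untracked hole
   near a field-of-view edge would be misread as a death.

`track_sequence` chains pairwise results, propagating persistent track ids
along mappings, spawning fresh ids for daughters (with the mother's id
recorded as lineage) and for cells entering the field of view.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `d_max_cell_lengths` | 10 | absolute centroid-distance cutoff for any pairing, in frame-1 average cell lengths (`sqrt(mean cell area)`); far larger than plausible inter-frame movement, so it only excludes absurd matches |
| `min_mcs_connections` | 3 | preserved-adjacency tracked neighbours a pair needs to survive cleaning |
| `min_cluster_size` | 11 | smallest tracked cluster kept by cleaning (clusters of 10 or fewer are discarded) |
| `post_min_tracked_neighbours` | 2 | preserved connections required to add a pair in post-processing |
| `rel_disp_max_cell_lengths` | 0.75 | bound on a cell's displacement relative to the mean displacement of its tracked neighbours |
| `mcs_node_budget` | 100 000 | deterministic cap on branch-and-bound expansions per local search |

The relative-displacement bound deserves comment, since the design intent
is to lean on topology and keep geometric input minimal.  Cells of a
cohesive sheet move with their neighbours: rearrangement events displace a
centroid by at most about half a cell diameter (a T1 interface flip, a
rosette collapse, a daughter centroid after division), while the
characteristic failure modes of purely topological matching — a cell
stealing its neighbour's partner, or a locally isomorphic patch matched one
position over — displace it by at least one inter-centroid spacing
(~1 cell length).  0.75 cell lengths separates the two regimes with margin
on both sides.  The bound is *relative* to the local displacement field, so
uniform tissue motion of any magnitude (up to `d_max`) is unaffected.  Like
`d_max` it is deliberately loose and tissue-agnostic, not tuned per
dataset.

## Local exact MCS

Neighbourhood graphs are encoded as per-node adjacency bitmasks.  The
search for a maximum common connected induced subgraph is a depth-first
branch and bound: pick the frontier node with the fewest feasible partners,
branch over partners and over excluding the node, prune with the trivial
remaining-capacity bound, and stop early when a caller-supplied target size
is reached (callers only ever need threshold decisions: "is the match
perfect?" / "does exclusion reach the forced score?").  Anchored seeds are
taken as given and never revised.  The expansion budget makes worst-case
behaviour deterministic; on matched neighbourhoods the search is
effectively greedy.  Isomorphism tests during seeding use VF2++ on the
induced neighbourhood subgraphs with the centre labelled.

## Synthetic tissues

In-silico frames are Voronoi tessellations relaxed by Lloyd's algorithm,
which reproduces the side-number and area statistics of many proliferating
epithelia.  For an `m x n` tissue, `(m+g) x (n+g)` seeds are drawn
uniformly in a padded domain (`g = 8`), surrounded by two rows of evenly
spaced guard seeds (spacing 1.0, at distances 0.5 and 1.5, the outer row
shifted by 0.5) that keep every interior Voronoi region bounded.  Each of
the `n_L = 4` relaxation steps replaces interior seeds by their region
area-centroids and re-adds the guard rows.  Finally only polygons whose
centroids fall in the central `m x n` rectangle are kept, giving
approximately `m x n` cells of mean area 1.  More relaxation steps give
more homogeneous packings; the benchmarks pass for `n_L` from 4 to 14,
beyond which neighbourhood ambiguity (as in a perfect hexagonal lattice)
becomes the limiting factor for any purely topological method.

Perturbation operators implement the elementary rearrangements: T1
(interface replaced by a perpendicular interface of length 0.2, junction
cells reconnected according to which side cell owns the adjoining polygon
edge), T2 (interior cell collapsed onto its centroid; neighbours' runs of
its vertices are contracted to the new rosette vertex), and division
(chord through the centroid at a random angle; crossings within 1e-6 of an
existing vertex snap to it, which is how three- and four-sided daughters
arise).  Applicability is checked structurally (interior interface,
three-way end junctions, side cells keeping at least three vertices, the
gaining cells not already adjacent) and inapplicable draws are rejected.

The benchmark cases mirror the validation protocol: id permutation;
horizontal translation (two width-7 full-height windows of a 15 x 8 tissue
offset by two cell lengths, each re-anchored to x = 0); a single central
T1; a central T2 removal; a central division at a random orientation.  The
second frame's ids are always shuffled and the ground-truth correspondence
recorded.

What the generator does *not* emulate: segmentation errors (over- and
under-segmentation), curved interfaces, gradual vertex motion between
frames (perturbations are applied instantaneously with otherwise identical
geometry), correlated event clusters such as adjacent divisions, and
boundary influx/outflux other than the translation windows.  Passing these
benchmarks therefore demonstrates correct event resolution and robustness
to topological rearrangement and movement, not robustness to segmentation
noise — on real data the quality of the upstream segmentation is the
limiting factor.

## Label-image extraction

Segmented frames are 16-bit label images (one positive integer per cell;
configurable background label, covering both ilastik- and
SeedWaterSegmenter-style exports).  Junctions are detected with a 2x2
window scan — a vertex is emitted wherever a window contains three or more
distinct labels, the background counting as a label — at the window centre,
so vertex coordinates are half-integer pixels (x = column, y = row, origin
top left).  Vertices are assigned to cells and ordered by angle about the
cell's pixel centroid, which can misorder highly non-convex cells; polygon
edges shorter than `min_edge_px = 2` are contracted to their midpoint
(union-find over short-edge chains), merging duplicate detections of one
junction and collapsing near-degenerate junctions into higher-order
vertices.  Cells adjacent to the background or the image border are
removed, since their outlines are not closed polygons.  A frame with fewer
than three interior cells is rejected.  The inverse operation
(`rasterize_mesh`) labels every pixel whose centre lies inside a cell
polygon; round-tripping a synthetic tissue through rasterisation and
extraction reproduces its interior adjacency network exactly, provided the
shortest cell-cell interface spans more than `min_edge_px` at the chosen
resolution — shorter interfaces are (correctly, by design) absorbed into
higher-order junctions, which removes that adjacency from the polygonal
approximation.

## Numerical and tie-breaking choices

* Polygon orientation is normalised counter-clockwise on construction;
  areas and centroids use the shoelace formulas.
* All scans iterate in sorted id order; score ties break by centroid
  distance, then smallest id.  Tracking is deterministic: identical inputs
  and configuration give identical output.
* Lloyd centroids are polygon area centroids, not vertex means.
* Division-chord crossings within 1e-6 of an existing vertex snap to it.
* Coincident Voronoi seeds (never observed with continuous random input)
  would be jittered by 1e-6 with a warning.
* The "closest position" rule for ambiguous divisions minimises the sum of
  distances from the mother centroid to the two daughter centroids.

## Problem sizes used in the shipped benchmarks

The test suite runs the permutation and perturbation benchmarks at 100
seeded realizations each on 9 x 9 tissues, the homogeneity scan at 10
realizations per relaxation count, the neighbour-exchange sweep on 20 x 20
tissues at 10 repetitions per interface fraction (the shipped tests sweep
the four fractions with published reference values; `scripts/acceptance.py`
sweeps all of 1-10%), and the scaling check on square tissues of 10 to 30
cell lengths with a log-log regression of runtime against cell count.

## Known limitations

* Fully homogeneous tissues (perfect hexagonal lattices) admit no
  unambiguous seed; tracking fails loudly rather than guessing.
* Adjacent simultaneous divisions, and divisions whose flanking cells
  rearrange in the same interval, may not be resolved; these produce
  warnings.
* Isolated boundary cells with one neighbour, or symmetric boundary pairs
  sharing a single neighbour, are unresolvable from topology and remain
  untracked (at most a few cells per frame pair).
* Deaths and delaminations are not distinguished.
* The mapping between two frames showing *unrelated* tissues of similar
  statistics is not guaranteed to be empty; the tracker assumes its inputs
  are consecutive frames of one tissue.
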