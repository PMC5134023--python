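"""Voronoi/Lloyd tissue generator and vertex-model perturbation operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epitrack import (
    GenerationConfig,
    NotApplicableError,
    apply_division,
    apply_t1,
    apply_t2,
    boundary_cells,
    build_network,
    generate_tissue,
    hexagonal_mesh,
    permute_ids,
    t1_edges,
    translation_pair,
)
from epitrack.synthetic import relabel_cells


def adjacency(mesh):
    net = build_network(mesh)
    return {c: frozenset(net.adj[c]) for c in net}


class TestGenerateTissue:
    def test_cell_count_and_mean_area(self):
        # roughly m*n polygons of average area 1.0
        for seed in range(5):
            mesh = generate_tissue(GenerationConfig(9, 9, rng_seed=seed))
            assert 65 <= len(mesh.cells) <= 100
            mean_area = np.mean([mesh.area(c) for c in mesh.cells])
            assert 0.85 <= mean_area <= 1.15

    def test_centroids_inside_central_rectangle(self):
        mesh = generate_tissue(GenerationConfig(9, 9, rng_seed=3))
        for c in mesh.cells:
            x, y = mesh.centroid(c)
            assert -1e-9 <= x <= 9 + 1e-9
            assert -1e-9 <= y <= 9 + 1e-9

    def test_bit_reproducible(self):
        a = generate_tissue(GenerationConfig(9, 9, rng_seed=7))
        b = generate_tissue(GenerationConfig(9, 9, rng_seed=7))
        assert a.cells == b.cells
        assert all(np.array_equal(a.vertices[v], b.vertices[v]) for v in a.vertices)

    def test_meshes_satisfy_invariants(self):
        for seed in range(5):
            generate_tissue(GenerationConfig(9, 9, rng_seed=seed)).validate()

    def test_lloyd_relaxation_homogenises(self):
        # side-number variance decreases with relaxation; hexagon fraction
        # at n_L=4 sits between the unrelaxed value and a perfect lattice
        var0, var4, hex0, hex4 = [], [], [], []
        for seed in range(20):
            for n_l, var_acc, hex_acc in ((0, var0, hex0), (4, var4, hex4)):
                mesh = generate_tissue(GenerationConfig(9, 9, n_lloyd=n_l, rng_seed=seed))
                sides = [mesh.num_sides(c) for c in mesh.cells]
                var_acc.append(np.var(sides))
                hex_acc.append(np.mean([s == 6 for s in sides]))
        assert np.mean(var4) < np.mean(var0)
        assert np.mean(hex0) < np.mean(hex4) < 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GenerationConfig(2, 9)
        with pytest.raises(ValueError):
            GenerationConfig(9, 9, g=-1)


class TestPermuteIds:
    def test_applying_map_recovers_original(self, tissue9, rng):
        shuffled, truth = permute_ids(tissue9, rng)
        restored = relabel_cells(shuffled, {v: k for k, v in truth.map.items()})
        assert restored.cells == tissue9.cells

    def test_composition_of_shuffles(self, tissue9):
        rng = np.random.default_rng(5)
        m1, t1 = permute_ids(tissue9, rng)
        m2, t2 = permute_ids(m1, rng)
        composed = {c: t2.map[t1.map[c]] for c in t1.map}
        direct = relabel_cells(tissue9, composed)
        assert direct.cells == m2.cells

    def test_geometry_unchanged(self, tissue9, rng):
        shuffled, truth = permute_ids(tissue9, rng)
        for c, v in truth.map.items():
            assert shuffled.cells[v] == tissue9.cells[c]


class TestTranslationPair:
    def test_overlap_and_anchoring(self, rng):
        mesh1, mesh2, truth = translation_pair(rng)
        # overlap of two width-7 windows offset by 2 covers about 5x8 cells
        assert 25 <= len(truth.map) <= 55
        assert len(set(truth.map.values())) == len(truth.map)  # injective
        for mesh in (mesh1, mesh2):
            assert min(p[0] for p in mesh.vertices.values()) == pytest.approx(0.0)

    def test_zero_offset_covers_everything(self, rng):
        mesh1, mesh2, truth = translation_pair(rng, offset=0.0)
        assert len(truth.map) == len(mesh1.cells) == len(mesh2.cells)


class TestT1:
    def test_hexagonal_bookkeeping(self, hex5):
        net0 = build_network(hex5)
        edges = t1_edges(hex5)
        assert edges
        edge = edges[len(edges) // 2]
        out = apply_t1(hex5, edge)
        out.validate()
        net1 = build_network(out)
        # total number of adjacencies is unchanged: one lost, one gained
        assert net1.number_of_edges() == net0.number_of_edges()
        sides0 = {c: hex5.num_sides(c) for c in hex5.cells}
        sides1 = {c: out.num_sides(c) for c in out.cells}
        changed = {c for c in sides0 if sides0[c] != sides1[c]}
        assert len(changed) == 4
        assert sorted(sides1[c] - sides0[c] for c in changed) == [-1, -1, 1, 1]

    def test_changes_neighbour_relations_of_four_cells(self, tissue9):
        edge = t1_edges(tissue9)[0]
        out = apply_t1(tissue9, edge)
        before, after = adjacency(tissue9), adjacency(out)
        assert sum(1 for c in before if before[c] != after[c]) == 4

    def test_new_edge_has_requested_length(self, tissue9):
        edge = t1_edges(tissue9)[0]
        out = apply_t1(tissue9, edge, l_t1=0.2)
        new_vids = set(out.vertices) - set(tissue9.vertices)
        a, b = sorted(new_vids)
        assert np.linalg.norm(out.vertices[a] - out.vertices[b]) == pytest.approx(0.2)

    def test_boundary_edge_rejected(self, tissue9):
        owners = tissue9.edge_owners()
        boundary_edge = next(e for e, cs in owners.items() if len(cs) == 1)
        with pytest.raises(NotApplicableError):
            apply_t1(tissue9, tuple(sorted(boundary_edge)))


class TestT2:
    def test_removes_exactly_one_cell(self, tissue9):
        cell = next(c for c in sorted(tissue9.cells) if c not in boundary_cells(tissue9))
        out = apply_t2(tissue9, cell)
        out.validate()
        assert len(out.cells) == len(tissue9.cells) - 1
        assert cell not in out.cells

    def test_neighbours_share_rosette_vertex(self, tissue9):
        net = build_network(tissue9)
        cell = next(
            c
            for c in sorted(tissue9.cells)
            if c not in boundary_cells(tissue9) and tissue9.num_sides(c) == 6
        )
        nbrs = set(net.adj[cell])
        out = apply_t2(tissue9, cell)
        new_vertex = (set(out.vertices) - set(tissue9.vertices)).pop()
        for n in nbrs:
            assert new_vertex in out.cells[n]
        assert out.vertices[new_vertex] == pytest.approx(tissue9.centroid(cell))
        # consecutive neighbours around the rosette remain adjacent
        after = adjacency(out)
        net_after = build_network(out)
        ring = [n for n in nbrs]
        assert all(
            sum(1 for m in ring if m in net_after.adj[n]) >= 2 for n in ring
        )

    def test_boundary_cell_rejected(self, tissue9):
        cell = next(iter(sorted(boundary_cells(tissue9))))
        with pytest.raises(NotApplicableError):
            apply_t2(tissue9, cell)


class TestDivision:
    def test_daughter_areas_sum_to_mother(self, tissue9, rng):
        cell = next(c for c in sorted(tissue9.cells) if c not in boundary_cells(tissue9))
        out, (mother, d1, d2) = apply_division(tissue9, cell, rng=rng)
        out.validate()
        assert mother == cell
        assert out.area(d1) + out.area(d2) == pytest.approx(tissue9.area(cell))
        assert len(out.cells) == len(tissue9.cells) + 1

    def test_two_cut_neighbours_gain_a_side(self, tissue9):
        interior = [c for c in sorted(tissue9.cells) if c not in boundary_cells(tissue9)]
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(20):
            cell = interior[int(rng.integers(len(interior)))]
            try:
                out, (mother, d1, d2) = apply_division(tissue9, cell, rng=rng)
            except NotApplicableError:
                continue
            gained = [
                c
                for c in tissue9.cells
                if c != cell and out.num_sides(c) > tissue9.num_sides(c)
            ]
            if min(out.num_sides(d1), out.num_sides(d2)) >= 4:
                assert len(gained) == 2
            else:
                assert len(gained) <= 2
            checked += 1
        assert checked >= 15

    def test_snap_to_vertex_makes_small_daughter(self, tissue9):
        cell = next(c for c in sorted(tissue9.cells) if c not in boundary_cells(tissue9))
        centre = tissue9.centroid(cell)
        target = tissue9.vertices[tissue9.cells[cell][0]]
        angle = float(np.arctan2(*(target - centre)[::-1]))
        out, (mother, d1, d2) = apply_division(tissue9, cell, angle=angle, snap_tol=1e-6)
        # the snapped end re-uses the existing junction: no new vertex there
        new_vertices = set(out.vertices) - set(tissue9.vertices)
        assert len(new_vertices) == 1


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_perturbed_meshes_keep_invariants(seed):
    """Any applicable perturbation yields a valid tessellation."""
    rng = np.random.default_rng(seed)
    mesh = generate_tissue(GenerationConfig(6, 6, rng_seed=seed))
    edges = t1_edges(mesh)
    if edges:
        apply_t1(mesh, edges[int(rng.integers(len(edges)))]).validate()
    interior = sorted(set(mesh.cells) - boundary_cells(mesh))
    if interior:
        cell = interior[int(rng.integers(len(interior)))]
        try:
            apply_t2(mesh, cell).validate()
        except NotApplicableError:
            pass
        try:
            out, _ = apply_division(mesh, cell, rng=rng)
            out.validate()
        except NotApplicableError:
            pass
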