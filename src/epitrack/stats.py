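"""Tracking quality scores and tissue-homeostasis summaries.

Synthetic test cases come with a known cell correspondence, so tracking
output can be scored cell by cell (correct / incorrect / untracked).  The
neighbour-exchange sweep quantifies how tracking quality degrades as T1
transitions are applied to a growing share of the tissue's inner
interfaces.  Frame statistics summarise sequences the way a tissue
biologist would read them: cell counts, rearrangement counts, area trends
and per-track area excursions (mitotic rounding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matching import TrackerConfig
from .mesh import Mesh, build_network
from .synthetic import (
    GenerationConfig,
    GroundTruth,
    apply_t1,
    generate_tissue,
    permute_ids,
    t1_edges,
)
from .tracking import SequenceResult, TrackingError, TrackingResult, track

__all__ = [
    "SuccessReport",
    "score_against_truth",
    "apply_random_t1s",
    "t1_sweep",
    "frame_stats",
    "track_area_ratios",
]


@dataclass(frozen=True)
class SuccessReport:
    """Per-cell classification of a tracking result against ground truth."""

    n_cells: int
    n_correct: int
    n_incorrect: int
    n_untracked: int

    @property
    def fraction_correct(self) -> float:
        return self.n_correct / self.n_cells if self.n_cells else 0.0

    @property
    def fraction_incorrect(self) -> float:
        return self.n_incorrect / self.n_cells if self.n_cells else 0.0

    @property
    def fraction_untracked(self) -> float:
        return self.n_untracked / self.n_cells if self.n_cells else 0.0


def score_against_truth(result: TrackingResult, truth: GroundTruth) -> SuccessReport:
    """Classify each ground-truth cell as correct, incorrect or untracked."""
    n_correct = n_incorrect = n_untracked = 0
    for c, true_partner in truth.map.items():
        found = result.mapping.pairs.get(c)
        if found is None:
            n_untracked += 1
        elif found == true_partner:
            n_correct += 1
        else:
            n_incorrect += 1
    return SuccessReport(
        n_cells=len(truth.map),
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        n_untracked=n_untracked,
    )


def apply_random_t1s(
    mesh: Mesh, n_swaps: int, rng: np.random.Generator
) -> tuple[Mesh, int]:
    """Apply T1 transitions to ``n_swaps`` randomly chosen inner interfaces.

    The candidate interfaces are those applicable in the unperturbed
    tissue, identified by the two cells they separate; interfaces that
    become inapplicable after earlier swaps are rejected and the draw
    continues down the shuffled list.  Returns the perturbed mesh and the
    number of swaps actually applied.
    """
    owners = mesh.edge_owners()
    pairs = [tuple(sorted(owners[frozenset(e)])) for e in t1_edges(mesh)]
    order = rng.permutation(len(pairs))
    applied = 0
    current = mesh
    from .synthetic import NotApplicableError

    for idx in order:
        if applied >= n_swaps:
            break
        a, b = pairs[idx]
        if a not in current.cells or b not in current.cells:
            continue
        shared = set(current.edges_of(a)) & set(current.edges_of(b))
        if len(shared) != 1:
            continue
        edge = tuple(sorted(next(iter(shared))))
        try:
            current = apply_t1(current, edge)
        except NotApplicableError:
            continue
        applied += 1
    return current, applied


def _adjacency_sets(mesh: Mesh) -> dict[int, frozenset[int]]:
    net = build_network(mesh)
    return {c: frozenset(net.adj[c]) for c in net}


def t1_sweep(
    fractions=tuple(f / 100 for f in range(1, 11)),
    m: int = 20,
    n: int = 20,
    reps: int = 10,
    cfg: TrackerConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Tracking success versus the share of inner interfaces undergoing T1s.

    For each fraction and repetition a fresh tissue is generated, T1
    transitions are applied to that fraction of its inner interfaces, ids
    are shuffled, and the tracker is scored against the ground truth.
    Returns one row per (fraction, rep) with affected-cell and
    correct/incorrect/untracked percentages.
    """
    cfg = cfg or TrackerConfig()
    rows = []
    for rep in range(reps):
        tissue_rng = np.random.default_rng([seed, 9000, rep])
        mesh1 = generate_tissue(GenerationConfig(m=m, n=n), rng=tissue_rng)
        n_inner = len(t1_edges(mesh1))
        adj1 = _adjacency_sets(mesh1)
        for fi, fraction in enumerate(fractions):
            rng = np.random.default_rng([seed, fi, rep])
            n_swaps = int(round(fraction * n_inner))
            mesh2, applied = apply_random_t1s(mesh1, n_swaps, rng)
            adj2 = _adjacency_sets(mesh2)
            affected = sum(1 for c in adj1 if adj1[c] != adj2[c])
            mesh2p, perm = permute_ids(mesh2, rng)
            truth = GroundTruth(map=dict(perm.map))
            try:
                result = track(mesh1, mesh2p, cfg)
                report = score_against_truth(result, truth)
            except TrackingError:
                report = SuccessReport(len(truth.map), 0, 0, len(truth.map))
            rows.append(
                {
                    "fraction": fraction,
                    "rep": rep,
                    "n_cells": len(mesh1),
                    "n_inner_edges": n_inner,
                    "n_swaps": applied,
                    "affected_pct": 100.0 * affected / len(mesh1),
                    "correct_pct": 100.0 * report.fraction_correct,
                    "incorrect_pct": 100.0 * report.fraction_incorrect,
                    "untracked_pct": 100.0 * report.fraction_untracked,
                }
            )
    return pd.DataFrame(rows)


def frame_stats(seq: SequenceResult, meshes: list[Mesh]) -> pd.DataFrame:
    """Per-frame summary of a tracked sequence.

    ``n_rearranging`` counts cells that gain or lose neighbours between a
    frame and the next (evaluated over mapped pairs); ``n_tracked`` is the
    number of cells mapped to the next frame.
    """
    nets = [build_network(mesh) for mesh in meshes]
    rows = []
    for i, mesh in enumerate(meshes):
        row = {
            "frame": i,
            "n_cells": len(mesh.cells),
            "mean_cell_area": float(np.mean([mesh.area(c) for c in mesh.cells])),
        }
        if i < len(seq.results):
            res = seq.results[i]
            rearranging = sum(
                1
                for u, v in res.mapping.pairs.items()
                if nets[i].degree(u) != nets[i + 1].degree(v)
            )
            row.update(
                n_tracked=len(res.mapping.pairs),
                n_rearranging=rearranging,
                n_divisions=len(res.divisions),
                n_deaths=len(res.deaths),
            )
        else:
            row.update(n_tracked=0, n_rearranging=0, n_divisions=0, n_deaths=0)
        rows.append(row)
    return pd.DataFrame(rows)


def track_area_ratios(seq: SequenceResult, meshes: list[Mesh]) -> pd.Series:
    """Max/min apical area ratio per track (mitotic-rounding metric).

    Only tracks observed in at least two frames contribute.
    """
    areas: dict[int, list[float]] = {}
    for frame, ids in enumerate(seq.track_ids):
        mesh = meshes[frame]
        for cell, tid in ids.items():
            areas.setdefault(tid, []).append(mesh.area(cell))
    ratios = {
        tid: max(vals) / min(vals)
        for tid, vals in sorted(areas.items())
        if len(vals) >= 2
    }
    return pd.Series(ratios, name="area_ratio", dtype=float)
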