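"""Cluster extraction from a trained map and cluster-quality scoring.

Clusters are read off the U-matrix landscape: occupied neurons whose U-height
is at or below a threshold theta form nodes, toroidally adjacent (Moore)
low-U neurons are joined, and connected components define clusters. Compounds
whose BMU sits above the threshold (on a ridge) are left unclustered. This is
a deterministic stand-in for the manual coloring of U-matrix basins used in
interactive ESOM work. On sparse emergent maps (many more neurons than
compounds) most separation comes from occupancy adjacency itself and the
threshold only needs to cut the steepest ridges, so the default theta is the
90th percentile of the U-matrix; a median theta — natural on dense maps —
strands basin-border compounds without improving purity.

Scoring conventions for a dual-target selectivity panel:

* purity of a cluster = round(100 * majority-set count / library members),
  decoys excluded from the denominator; half-up integer rounding.
* a *pure selectivity cluster* holds compounds of exactly one selectivity
  set and no decoys at all.
* global performance over a library of size N: coverage = clustered library
  compounds / N, correct = sum of majority-set counts over clusters / N,
  error = coverage - correct, each also reported as half-up integer percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .esom import SelfOrganizingMap
from .selectivity import SetLabel

SET_ORDER = (SetLabel.K_OVER_S, SetLabel.KS_NONSELECTIVE, SetLabel.S_OVER_K)


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (printed-table convention)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class ClusterTable:
    """Cluster membership: disjoint clusters plus the unclustered remainder."""

    clusters: dict[int, list[str]]
    unclustered: list[str] = field(default_factory=list)

    def all_members(self) -> list[str]:
        out = [cid for members in self.clusters.values() for cid in members]
        return out + list(self.unclustered)


@dataclass
class ClusterComposition:
    cluster_id: int
    counts: dict[str, int]
    decoy_count: int
    total: int
    purity_pct: int
    is_pure_selectivity: bool


@dataclass
class PerformanceSummary:
    n_clusters: int
    coverage_pct: int
    correct_pct: int
    error_pct: int
    coverage_exact: float
    correct_exact: float
    error_exact: float


def extract_clusters(
    model: SelfOrganizingMap,
    projection: Mapping[str, tuple[int, int]],
    umat: np.ndarray | None = None,
    theta: float | None = None,
) -> ClusterTable:
    """U-threshold connected-component clustering of projected compounds.

    ``projection`` maps compound_id -> BMU (row, col). Neurons occupied by at
    least one compound and with U-height <= theta are nodes; edges join
    Moore-adjacent nodes (wrapping on a toroid); connected components are
    clusters. Default theta is the 90th percentile of the whole U-matrix.
    """
    if not projection:
        raise ValueError("projection is empty")
    if umat is None:
        umat = model.umatrix()
    if theta is None:
        theta = float(np.percentile(umat, 90))
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must be in [0, 1], got {theta}")

    occupied: dict[int, list[str]] = {}
    for cid, (r, c) in projection.items():
        occupied.setdefault(int(r) * model.cols + int(c), []).append(cid)

    flat_u = umat.reshape(-1)
    low = [idx for idx in occupied if flat_u[idx] <= theta]
    graph = nx.Graph()
    graph.add_nodes_from(low)
    low_set = set(low)
    for idx in low:
        for nbr in model.neighbor_indices(idx):
            if nbr in low_set:
                graph.add_edge(idx, nbr)

    # deterministic cluster ids: components ordered by size desc, then by
    # smallest member compound_id
    components = [
        sorted(cid for idx in comp for cid in occupied[idx])
        for comp in nx.connected_components(graph)
    ]
    components.sort(key=lambda members: (-len(members), members[0]))
    clusters = {i + 1: members for i, members in enumerate(components)}
    unclustered = sorted(
        cid for idx, cids in occupied.items() if idx not in low_set for cid in cids
    )
    return ClusterTable(clusters=clusters, unclustered=unclustered)


def composition(
    cluster_id: int,
    members: Sequence[str],
    set_labels: Mapping[str, SetLabel],
    decoy_flags: Mapping[str, bool] | None = None,
) -> ClusterComposition:
    """Per-set counts, decoy count, purity and pure-selectivity flag."""
    decoy_flags = decoy_flags or {}
    counts = {label.value: 0 for label in SET_ORDER}
    decoys = 0
    for cid in members:
        if decoy_flags.get(cid, False):
            decoys += 1
        elif cid in set_labels:
            label = set_labels[cid]
            counts[label.value] = counts.get(label.value, 0) + 1
        else:
            raise KeyError(f"member {cid!r} has neither a set label nor a decoy flag")
    library_n = sum(counts.values())
    purity = round_half_up(100.0 * max(counts.values()) / library_n) if library_n else 0
    pure = decoys == 0 and sum(1 for v in counts.values() if v > 0) == 1
    return ClusterComposition(
        cluster_id=cluster_id,
        counts=counts,
        decoy_count=decoys,
        total=library_n + decoys,
        purity_pct=purity,
        is_pure_selectivity=pure,
    )


def compositions_for_table(
    table: ClusterTable,
    set_labels: Mapping[str, SetLabel],
    decoy_flags: Mapping[str, bool] | None = None,
) -> list[ClusterComposition]:
    return [
        composition(cid, members, set_labels, decoy_flags)
        for cid, members in table.clusters.items()
    ]


def performance(
    compositions: Sequence[ClusterComposition], n_library: int
) -> PerformanceSummary:
    """Coverage / correct / error rates over a library of ``n_library`` compounds.

    Only library members count; decoys are ignored. Exact (unrounded) values
    satisfy coverage == correct + error; the integer percents are rounded
    per-term, which can make the printed identity off by one.
    """
    if n_library <= 0:
        raise ValueError("library size must be positive")
    clustered = sum(sum(c.counts.values()) for c in compositions)
    majority = sum(max(c.counts.values(), default=0) for c in compositions)
    coverage = 100.0 * clustered / n_library
    correct = 100.0 * majority / n_library
    error = 100.0 * (clustered - majority) / n_library
    return PerformanceSummary(
        n_clusters=len(compositions),
        coverage_pct=round_half_up(coverage),
        correct_pct=round_half_up(correct),
        error_pct=round_half_up(error),
        coverage_exact=coverage,
        correct_exact=correct,
        error_exact=error,
    )


def pure_cluster_report(
    compositions: Sequence[ClusterComposition],
) -> dict[str, object]:
    """Pure selectivity clusters (single set, decoy-free) and per-set tallies."""
    pure = [c for c in compositions if c.is_pure_selectivity]
    per_set = {label.value: 0 for label in SET_ORDER}
    for comp in pure:
        winner = max(comp.counts, key=lambda k: comp.counts[k])
        per_set[winner] += 1
    return {
        "pure_clusters": pure,
        "n_pure": len(pure),
        "pure_per_set": per_set,
    }
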