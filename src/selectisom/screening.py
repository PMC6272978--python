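"""Decoy merging and nearest-neighbor hit picking from mixed clusters.

The validation protocol merges a decoy pool (ZINC-like) with the selectivity
library, reclusters everything, and then mines *mixed* clusters — those that
contain at least one decoy alongside library compounds of exactly one
selectivity set. Each such decoy inherits the cluster's set label as its
predicted selectivity, scored by its maximum Tanimoto similarity to the
cluster's library members; the top-k decoys overall are the hit list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .clustering import ClusterComposition, ClusterTable
from .fingerprints import tanimoto_arrays
from .records import ActivityRecord, CompoundRecord, Source
from .selectivity import SelectivityThresholds, SetLabel, Target, assign


def merge_and_flag(
    library: Sequence[CompoundRecord],
    decoys: Sequence[CompoundRecord],
    collision_prefix: str = "decoy_",
) -> list[CompoundRecord]:
    """Concatenate library then decoys, flagging sources and de-colliding ids."""
    library_ids = {rec.compound_id for rec in library}
    out = [
        CompoundRecord(rec.compound_id, rec.smiles, Source.SELECTIVITY_DB, rec.name)
        for rec in library
    ]
    for rec in decoys:
        cid = rec.compound_id
        if cid in library_ids:
            cid = collision_prefix + cid
        out.append(CompoundRecord(cid, rec.smiles, Source.DECOY, rec.name))
    return out


@dataclass
class Hit:
    rank: int
    compound_id: str
    cluster_id: int
    predicted_set: SetLabel
    similarity: float
    sr: float | None = None
    favored_target: Target | None = None
    true_set: SetLabel | None = None


def select_hits(
    table: ClusterTable,
    compositions: Sequence[ClusterComposition],
    fps: Mapping[str, np.ndarray],
    decoy_flags: Mapping[str, bool],
    k: int = 5,
) -> list[Hit]:
    """Top-k decoys from single-set mixed clusters, by max similarity to members.

    A cluster qualifies when it holds >= 1 decoy and >= 1 library compound,
    and all its library compounds belong to one selectivity set. Ties in
    similarity break by compound_id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    comp_by_id = {c.cluster_id: c for c in compositions}
    candidates: list[Hit] = []
    for cluster_id, members in table.clusters.items():
        comp = comp_by_id.get(cluster_id)
        if comp is None or comp.decoy_count < 1:
            continue
        nonzero = [name for name, n in comp.counts.items() if n > 0]
        if len(nonzero) != 1:
            continue
        predicted = SetLabel(nonzero[0])
        library_members = [m for m in members if not decoy_flags.get(m, False)]
        cluster_decoys = [m for m in members if decoy_flags.get(m, False)]
        lib_fps = [np.asarray(fps[m]) for m in library_members]
        for decoy_id in cluster_decoys:
            sim = max(tanimoto_arrays(fps[decoy_id], lf) for lf in lib_fps)
            candidates.append(
                Hit(
                    rank=0,
                    compound_id=decoy_id,
                    cluster_id=cluster_id,
                    predicted_set=predicted,
                    similarity=sim,
                )
            )
    candidates.sort(key=lambda h: (-h.similarity, h.compound_id))
    hits = candidates[:k]
    for rank, hit in enumerate(hits, start=1):
        hit.rank = rank
    return hits


def annotate_hits(
    hits: Sequence[Hit],
    activities: Mapping[str, ActivityRecord],
    thresholds: SelectivityThresholds = SelectivityThresholds(),
) -> list[Hit]:
    """Attach measured SR / favored target / true set label to each hit.

    Raises ``KeyError`` when a hit has no activity record.
    """
    annotated = []
    for hit in hits:
        if hit.compound_id not in activities:
            raise KeyError(f"no activity record for hit {hit.compound_id!r}")
        assignment = assign(activities[hit.compound_id], thresholds)
        annotated.append(
            Hit(
                rank=hit.rank,
                compound_id=hit.compound_id,
                cluster_id=hit.cluster_id,
                predicted_set=hit.predicted_set,
                similarity=hit.similarity,
                sr=assignment.sr,
                favored_target=assignment.favored_target,
                true_set=assignment.set_label,
            )
        )
    return annotated
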