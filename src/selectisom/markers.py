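"""Differential bit-frequency analysis: selectivity markers and atom mapping.

A selectivity marker of a cluster is a fingerprint bit that is frequent
inside the cluster (freq_in >= min_in, default 0.5) AND enriched against the
rest of the library (freq_in - freq_rest >= min_diff, default 0.5 as a
fraction, i.e. 50 percentage points). Both thresholds are configurable:
min_diff=0 recovers the laxer "occurs in at least 50% of the cluster"
reading. "Rest of the database" means all library compounds outside the
cluster, decoys excluded. Marker bits map back onto member molecules through
the substructure query behind each key, giving atom-level highlights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .fingerprints import (
    BAPSKeyTable,
    Scheme,
    key_description,
    marker_query,
    as_mol,
)


@dataclass(frozen=True)
class Marker:
    bit: int
    pattern: str
    description: str
    freq_in_cluster: float
    freq_rest: float


@dataclass
class MarkerSet:
    cluster_id: int
    markers: list[Marker]

    @property
    def n_features(self) -> int:
        return len(self.markers)


def bit_frequencies(fps: np.ndarray) -> np.ndarray:
    """Per-bit fraction of rows with the bit ON; rows are fingerprints."""
    fps = np.asarray(fps)
    if fps.ndim != 2 or fps.shape[0] == 0:
        raise ValueError("need a non-empty (n, bits) fingerprint matrix")
    return fps.mean(axis=0)


def selectivity_markers(
    cluster_fps: np.ndarray,
    rest_fps: np.ndarray,
    scheme: Scheme,
    min_in: float = 0.5,
    min_diff: float = 0.5,
    cluster_id: int = 0,
    table: BAPSKeyTable | None = None,
) -> MarkerSet:
    """Markers of a cluster against the rest of the library.

    Sorted by descending (freq_in - freq_rest), ties by bit index.
    """
    cluster_fps = np.asarray(cluster_fps)
    rest_fps = np.asarray(rest_fps)
    if cluster_fps.shape[1] != rest_fps.shape[1]:
        raise ValueError("fingerprint schemes differ between cluster and rest")
    freq_in = bit_frequencies(cluster_fps)
    freq_rest = bit_frequencies(rest_fps)
    diff = freq_in - freq_rest
    hits = np.flatnonzero((freq_in >= min_in) & (diff >= min_diff))
    order = sorted(hits.tolist(), key=lambda b: (-diff[b], b))
    markers = []
    for bit in order:
        pattern, description = key_description(scheme, bit, table)
        markers.append(
            Marker(
                bit=bit,
                pattern=pattern,
                description=description,
                freq_in_cluster=float(freq_in[bit]),
                freq_rest=float(freq_rest[bit]),
            )
        )
    return MarkerSet(cluster_id=cluster_id, markers=markers)


def map_marker_to_atoms(
    molecule: str | Chem.Mol,
    query: str | Chem.Mol,
) -> list[tuple[int, ...]]:
    """All substructure matches of a key query, as 0-based atom-index tuples."""
    mol = as_mol(molecule)
    if isinstance(query, str):
        compiled = Chem.MolFromSmarts(query)
        if compiled is None:
            raise ValueError(f"query does not compile: {query!r}")
    else:
        compiled = query
    return [tuple(match) for match in mol.GetSubstructMatches(compiled)]


def map_bit_to_atoms(
    molecule: str | Chem.Mol,
    scheme: Scheme,
    bit: int,
    table: BAPSKeyTable | None = None,
) -> list[tuple[int, ...]]:
    """Atom matches for a fingerprint bit; empty when the key has no query."""
    compiled = marker_query(scheme, bit, table)
    if compiled is None:
        return []
    return map_marker_to_atoms(molecule, compiled)


@dataclass
class SSRReport:
    """Structure-selectivity relationship summary across clusters."""

    per_cluster: dict[int, MarkerSet]
    per_set: dict[str, list[Marker]]
    highlights: dict[str, list[list[int]]] = field(default_factory=dict)


def ssr_report(
    marker_sets: Sequence[MarkerSet],
    cluster_majority_set: Mapping[int, str],
    molecules: Mapping[str, str | Chem.Mol] | None = None,
    cluster_members: Mapping[int, Sequence[str]] | None = None,
    scheme: Scheme = Scheme.COMBINED283,
    table: BAPSKeyTable | None = None,
) -> SSRReport:
    """Aggregate markers per selectivity set and build highlight annotations.

    ``cluster_majority_set`` names the selectivity set each cluster stands
    for; markers of clusters sharing a set are pooled (deduplicated by bit,
    keeping the first occurrence). When ``molecules`` and ``cluster_members``
    are given, per-compound atom highlights are computed for that cluster's
    marker bits, ready for annotated SDF export.
    """
    per_cluster = {ms.cluster_id: ms for ms in marker_sets}
    per_set: dict[str, list[Marker]] = {}
    for ms in marker_sets:
        set_name = cluster_majority_set.get(ms.cluster_id)
        if set_name is None:
            continue
        seen = {m.bit for m in per_set.get(set_name, [])}
        per_set.setdefault(set_name, []).extend(
            m for m in ms.markers if m.bit not in seen
        )
    highlights: dict[str, list[list[int]]] = {}
    if molecules is not None and cluster_members is not None:
        for ms in marker_sets:
            for cid in cluster_members.get(ms.cluster_id, ()):  # compounds
                if cid not in molecules:
                    continue
                mol = as_mol(molecules[cid])
                atom_sets: list[list[int]] = []
                for marker in ms.markers:
                    for match in map_bit_to_atoms(mol, scheme, marker.bit, table):
                        atom_sets.append(sorted(match))
                if atom_sets:
                    highlights[cid] = atom_sets
    return SSRReport(per_cluster=per_cluster, per_set=per_set, highlights=highlights)
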