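"""End-to-end orchestration: fingerprint -> map -> clusters -> markers -> hits.

`run_scheme` executes the full protocol for one fingerprint scheme and is the
unit both the CLI and reproduction scripts build on; `run_pipeline` loops over
schemes, writes the report files and records seeds/settings in ``run.json``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    ClusterComposition,
    ClusterTable,
    PerformanceSummary,
    compositions_for_table,
    extract_clusters,
    performance,
    pure_cluster_report,
)
from .esom import SelfOrganizingMap, stratified_split
from .fingerprints import Scheme, fingerprinter_for
from .markers import MarkerSet, SSRReport, selectivity_markers, ssr_report
from .records import ActivityRecord, CompoundRecord, Source
from .screening import Hit, annotate_hits, select_hits
from .selectivity import SelectivityThresholds, SetLabel, assign_all


@dataclass
class SchemeResult:
    """Everything the protocol produces for one fingerprint scheme."""

    scheme: Scheme
    model: SelfOrganizingMap
    projection: dict[str, tuple[int, int]]
    table: ClusterTable
    compositions: list[ClusterComposition]
    performance: PerformanceSummary
    pure_report: dict
    marker_sets: list[MarkerSet]
    ssr: SSRReport
    hits: list[Hit]
    fps: dict[str, np.ndarray]
    umatrix: np.ndarray


def run_scheme(
    records: Sequence[CompoundRecord],
    activities: Sequence[ActivityRecord],
    scheme: Scheme,
    som_params: Mapping | None = None,
    thresholds: SelectivityThresholds = SelectivityThresholds(),
    theta: float | None = None,
    min_in: float = 0.5,
    min_diff: float = 0.5,
    k_hits: int = 5,
    train_fraction: float | None = None,
    seed: int = 0,
) -> SchemeResult:
    """Run the full selectivity-profiling protocol for one scheme.

    The map is trained on all compounds (or a seeded stratified fraction when
    ``train_fraction`` is given) and every compound is projected back onto it.
    Library compounds drive cluster scoring and markers; decoys feed the
    purity exclusion and the hit list.
    """
    ids = [r.compound_id for r in records]
    decoy_flags = {r.compound_id: r.source is Source.DECOY for r in records}
    library_ids = [cid for cid in ids if not decoy_flags[cid]]

    assignments = assign_all(
        [a for a in activities if not decoy_flags.get(a.compound_id, False)], thresholds
    )
    set_labels: dict[str, SetLabel] = {a.compound_id: a.set_label for a in assignments}

    transformer = fingerprinter_for(scheme)
    X = transformer.transform([r.smiles for r in records]).astype(np.float64)
    fps = {cid: X[i] for i, cid in enumerate(ids)}

    params = dict(som_params or {})
    params.setdefault("random_state", seed)
    model = SelfOrganizingMap(**params)

    if train_fraction is not None:
        strata = [
            set_labels[cid].value if cid in set_labels else "decoy" for cid in ids
        ]
        train_idx, _ = stratified_split(strata, train_fraction, random_state=seed)
        model.fit(X[train_idx])
    else:
        model.fit(X)

    coords = model.project(X)
    projection = {cid: (int(r), int(c)) for cid, (r, c) in zip(ids, coords)}

    umat = model.umatrix()
    table = extract_clusters(model, projection, umat, theta)
    comps = compositions_for_table(table, set_labels, decoy_flags)
    perf = performance(comps, n_library=len(library_ids))
    pure = pure_cluster_report(comps)

    # markers: per cluster, library members vs the rest of the library
    lib_in_cluster = {
        cid: [m for m in members if not decoy_flags[m]]
        for cid, members in table.clusters.items()
    }
    marker_sets = []
    majority: dict[int, str] = {}
    for cluster_id, members in lib_in_cluster.items():
        rest = [cid for cid in library_ids if cid not in set(members)]
        if not members or not rest:
            continue
        marker_sets.append(
            selectivity_markers(
                np.stack([fps[m] for m in members]),
                np.stack([fps[m] for m in rest]),
                scheme,
                min_in=min_in,
                min_diff=min_diff,
                cluster_id=cluster_id,
            )
        )
        comp = next(c for c in comps if c.cluster_id == cluster_id)
        majority[cluster_id] = max(comp.counts, key=lambda kk: comp.counts[kk])

    smiles_by_id = {r.compound_id: r.smiles for r in records}
    ssr = ssr_report(
        marker_sets,
        {cid: majority[cid] for cid in majority},
        molecules=smiles_by_id,
        cluster_members=lib_in_cluster,
        scheme=scheme,
    )

    hits = select_hits(table, comps, fps, decoy_flags, k=k_hits)
    by_id = {a.compound_id: a for a in activities}
    if all(h.compound_id in by_id for h in hits):
        hits = annotate_hits(hits, by_id, thresholds)

    return SchemeResult(
        scheme=scheme,
        model=model,
        projection=projection,
        table=table,
        compositions=comps,
        performance=perf,
        pure_report=pure,
        marker_sets=marker_sets,
        ssr=ssr,
        hits=hits,
        fps=fps,
        umatrix=umat,
    )


def pooled_set_markers(
    result: SchemeResult,
    library_ids: Sequence[str],
    min_in: float = 0.5,
    min_diff: float = 0.5,
) -> dict[str, set[int]]:
    """Markers per selectivity set, pooling each set's 100%-purity clusters.

    Library members of all single-set (100% purity; decoys allowed, since
    purity ignores decoys) clusters of a set are merged and the marker rule is
    applied to the pooled members against the rest of the library — the
    per-set view of the structure-selectivity relationship.
    """
    single_set = {
        c.cluster_id
        for c in result.compositions
        if c.purity_pct == 100 and sum(c.counts.values()) > 0
    }
    pooled: dict[str, list[str]] = {}
    for comp in result.compositions:
        if comp.cluster_id not in single_set:
            continue
        winner = max(comp.counts, key=lambda kk: comp.counts[kk])
        members = [
            m
            for m in result.table.clusters[comp.cluster_id]
            if m in set(library_ids)
        ]
        pooled.setdefault(winner, []).extend(members)
    out: dict[str, set[int]] = {}
    lib_set = list(library_ids)
    for set_name, members in pooled.items():
        rest = [cid for cid in lib_set if cid not in set(members)]
        if not members or not rest:
            out[set_name] = set()
            continue
        ms = selectivity_markers(
            np.stack([result.fps[m] for m in members]),
            np.stack([result.fps[m] for m in rest]),
            result.scheme,
            min_in=min_in,
            min_diff=min_diff,
        )
        out[set_name] = {m.bit for m in ms.markers}
    return out


def _write_reports(result: SchemeResult, out_dir: Path, write_images: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"cluster_id": cid, "compound_id": m}
        for cid, members in result.table.clusters.items()
        for m in members
    ]
    pd.DataFrame(rows, columns=["cluster_id", "compound_id"]).to_csv(
        out_dir / "clusters.csv", index=False
    )
    n_feat = {ms.cluster_id: ms.n_features for ms in result.marker_sets}
    comp_rows = [
        {
            "cluster_id": c.cluster_id,
            "total": c.total,
            "K/S": c.counts.get("K/S", 0),
            "KS": c.counts.get("KS", 0),
            "S/K": c.counts.get("S/K", 0),
            "decoys": c.decoy_count,
            "purity": c.purity_pct,
            "n_features": n_feat.get(c.cluster_id, 0),
        }
        for c in result.compositions
    ]
    pd.DataFrame(comp_rows).to_csv(out_dir / "compositions.csv", index=False)
    perf = result.performance
    (out_dir / "performance.json").write_text(
        json.dumps(
            {
                "n_clusters": perf.n_clusters,
                "coverage_pct": perf.coverage_pct,
                "correct_pct": perf.correct_pct,
                "error_pct": perf.error_pct,
                "coverage_exact": perf.coverage_exact,
                "correct_exact": perf.correct_exact,
                "error_exact": perf.error_exact,
                "n_pure_clusters": result.pure_report["n_pure"],
                "pure_per_set": result.pure_report["pure_per_set"],
            },
            indent=2,
        )
    )
    markers_payload = {
        str(ms.cluster_id): [
            {
                "bit": m.bit,
                "pattern": m.pattern,
                "description": m.description,
                "freq_in_cluster": m.freq_in_cluster,
                "freq_rest": m.freq_rest,
            }
            for m in ms.markers
        ]
        for ms in result.marker_sets
    }
    (out_dir / "markers.json").write_text(json.dumps(markers_payload, indent=2))
    hit_rows = [
        {
            "rank": h.rank,
            "compound_id": h.compound_id,
            "cluster_id": h.cluster_id,
            "predicted_set": h.predicted_set.value,
            "similarity": round(h.similarity, 6),
            "sr": None if h.sr is None else round(h.sr, 4),
            "true_set": None if h.true_set is None else h.true_set.value,
        }
        for h in result.hits
    ]
    pd.DataFrame(
        hit_rows,
        columns=["rank", "compound_id", "cluster_id", "predicted_set", "similarity", "sr", "true_set"],
    ).to_csv(out_dir / "hits.csv", index=False)
    np.savetxt(out_dir / "umatrix.tsv", result.umatrix, delimiter="\t", fmt="%.6f")
    if write_images:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(result.umatrix, cmap="viridis")
        ax.set_title(f"U-matrix ({result.scheme.value})")
        fig.colorbar(im, ax=ax, label="normalized U-height")
        fig.savefig(out_dir / "umatrix.png", dpi=120)
        plt.close(fig)


def run_pipeline(
    records: Sequence[CompoundRecord],
    activities: Sequence[ActivityRecord],
    out_dir: str | Path,
    schemes: Sequence[Scheme] = (Scheme.BAPS117, Scheme.MACCS166, Scheme.COMBINED283),
    som_params: Mapping | None = None,
    thresholds: SelectivityThresholds = SelectivityThresholds(),
    theta: float | None = None,
    min_in: float = 0.5,
    min_diff: float = 0.5,
    k_hits: int = 5,
    train_fraction: float | None = None,
    seed: int = 0,
    write_images: bool = True,
) -> dict[Scheme, SchemeResult]:
    """Run every scheme, write per-scheme report directories and a run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[Scheme, SchemeResult] = {}
    log: dict = {
        "version": __version__,
        "seed": seed,
        "thresholds": {
            "selective_min": thresholds.selective_min,
            "nonselective_max": thresholds.nonselective_max,
        },
        "som_params": dict(som_params or {}),
        "stages": [],
    }
    for scheme in schemes:
        start = time.time()
        try:
            result = run_scheme(
                records,
                activities,
                scheme,
                som_params=som_params,
                thresholds=thresholds,
                theta=theta,
                min_in=min_in,
                min_diff=min_diff,
                k_hits=k_hits,
                train_fraction=train_fraction,
                seed=seed,
            )
        except Exception as exc:  # keep partial outputs, name the stage
            log["stages"].append({"scheme": scheme.value, "error": str(exc)})
            (out_dir / "run.json").write_text(json.dumps(log, indent=2))
            raise RuntimeError(f"stage {scheme.value!r} failed: {exc}") from exc
        _write_reports(result, out_dir / scheme.value, write_images)
        results[scheme] = result
        log["stages"].append(
            {"scheme": scheme.value, "seconds": round(time.time() - start, 2)}
        )
    (out_dir / "run.json").write_text(json.dumps(log, indent=2))
    return results
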