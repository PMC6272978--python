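"""Readers and writers for compound libraries (SMILES, SDF V2000, CSV).

Every reader returns a :class:`~selectisom.records.LibraryReadResult` so that
``len(input rows) == len(records) + len(failures)`` — parse failures are
reported, never dropped silently. The CSV dialect is fixed: header row with
columns ``compound_id,smiles,ic50_K_nM,ic50_S_nM`` (activity columns optional),
comma-separated, UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .records import (
    ActivityRecord,
    CompoundRecord,
    LibraryReadResult,
    ParseFailure,
    Source,
)

RDLogger.DisableLog("rdApp.*")

CSV_ID, CSV_SMILES, CSV_K, CSV_S = "compound_id", "smiles", "ic50_K_nM", "ic50_S_nM"

HIGHLIGHT_FIELD = "highlight_atoms"


def _check_unique_ids(records: Sequence[CompoundRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.compound_id in seen:
            raise ValueError(f"duplicate compound_id: {rec.compound_id!r}")
        seen.add(rec.compound_id)


def read_library(
    path: str | Path,
    format: str,
    source: Source = Source.SELECTIVITY_DB,
) -> LibraryReadResult:
    """Read a compound library from ``path`` in ``format`` (smiles|sdf|csv).

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` when no
    record parses or when compound ids collide.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "smiles":
        result = _read_smiles(path, source)
    elif format == "sdf":
        result = _read_sdf(path, source)
    elif format == "csv":
        result = _read_csv(path, source)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if not result.records:
        raise ValueError(f"no parsable records in {path}")
    _check_unique_ids(result.records)
    return result


def _read_smiles(path: Path, source: Source) -> LibraryReadResult:
    records, failures = [], []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol_{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                failures.append(ParseFailure(lineno, line, "unparsable SMILES"))
                continue
            records.append(CompoundRecord(cid, smiles, source))
    return LibraryReadResult(records=records, failures=failures)


def _read_sdf(path: Path, source: Source) -> LibraryReadResult:
    records, failures = [], []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            failures.append(ParseFailure(i + 1, f"molblock #{i + 1}", "unparsable molblock"))
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i + 1}"
        records.append(CompoundRecord(cid, Chem.MolToSmiles(mol), source))
    return LibraryReadResult(records=records, failures=failures)


def _read_csv(path: Path, source: Source) -> LibraryReadResult:
    frame = pd.read_csv(path, dtype={CSV_ID: str})
    missing = {CSV_ID, CSV_SMILES} - set(frame.columns)
    if missing:
        raise ValueError(f"CSV missing required columns: {sorted(missing)}")
    has_activity = CSV_K in frame.columns and CSV_S in frame.columns
    records, activities, failures = [], [], []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        smiles = str(row[CSV_SMILES])
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            failures.append(ParseFailure(row_number, smiles, "unparsable SMILES"))
            continue
        cid = str(row[CSV_ID])
        records.append(CompoundRecord(cid, smiles, source))
        if has_activity and pd.notna(row[CSV_K]) and pd.notna(row[CSV_S]):
            try:
                activities.append(
                    ActivityRecord(cid, float(row[CSV_K]), float(row[CSV_S]))
                )
            except ValueError as exc:
                failures.append(ParseFailure(row_number, smiles, str(exc)))
                records.pop()
    return LibraryReadResult(records=records, activities=activities, failures=failures)


def write_library(
    records: Sequence[CompoundRecord],
    path: str | Path,
    format: str,
    activities: Sequence[ActivityRecord] = (),
) -> None:
    """Write records (and optional activities, CSV only) to ``path``."""
    path = Path(path)
    if format == "smiles":
        with open(path, "w", encoding="utf-8") as handle:
            for rec in records:
                handle.write(f"{rec.smiles}\t{rec.compound_id}\n")
    elif format == "sdf":
        write_annotated_sdf(records, {}, path)
    elif format == "csv":
        by_id = {a.compound_id: a for a in activities}
        rows = []
        for rec in records:
            act = by_id.get(rec.compound_id)
            rows.append(
                {
                    CSV_ID: rec.compound_id,
                    CSV_SMILES: rec.smiles,
                    CSV_K: act.ic50_K if act else None,
                    CSV_S: act.ic50_S if act else None,
                }
            )
        frame = pd.DataFrame(rows, columns=[CSV_ID, CSV_SMILES, CSV_K, CSV_S])
        if not by_id:
            frame = frame[[CSV_ID, CSV_SMILES]]
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format: {format!r}")


def write_annotated_sdf(
    records: Sequence[CompoundRecord],
    annotations: Mapping[str, Mapping[str, object]],
    path: str | Path,
) -> None:
    """Write an SDF V2000 with one data field per annotation key.

    ``annotations`` maps compound_id -> {field name -> value}. The special
    field ``highlight_atoms`` is a list of 0-based atom-index lists; it is
    serialized as JSON with indices shifted to 1-based, the SDF convention.
    An empty record list yields an empty (zero-block) but valid file.
    """
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.MolFromSmiles(rec.smiles)
            if mol is None:
                raise ValueError(f"unparsable SMILES for {rec.compound_id}")
            mol.SetProp("_Name", rec.compound_id)
            for key, value in annotations.get(rec.compound_id, {}).items():
                if key == HIGHLIGHT_FIELD:
                    value = json.dumps(
                        [[i + 1 for i in match] for match in value]
                    )
                mol.SetProp(str(key), str(value))
            writer.write(mol)
    finally:
        writer.close()


def read_highlight_annotations(path: str | Path) -> dict[str, list[list[int]]]:
    """Read back ``highlight_atoms`` fields from an SDF, as 0-based indices."""
    out: dict[str, list[list[int]]] = {}
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None or not mol.HasProp(HIGHLIGHT_FIELD):
            continue
        raw = json.loads(mol.GetProp(HIGHLIGHT_FIELD))
        out[mol.GetProp("_Name")] = [[i - 1 for i in match] for match in raw]
    return out


def read_activities_csv(path: str | Path) -> list[ActivityRecord]:
    """Read an activity table (compound_id, ic50_K_nM, ic50_S_nM columns)."""
    frame = pd.read_csv(path, dtype={CSV_ID: str})
    return [
        ActivityRecord(str(r[CSV_ID]), float(r[CSV_K]), float(r[CSV_S]))
        for _, r in frame.iterrows()
        if pd.notna(r[CSV_K]) and pd.notna(r[CSV_S])
    ]
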