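"""Manifest reading/writing: CSV with a JSONL twin, validated on load.

Schema (CSV header order and JSONL keys):
``path,sheep_id,age_months,x,y,w,h,split,origin``.  Paths are relative to the
manifest's directory.  Reading re-validates every dataset invariant (age
range, split rules for the declared protocol) and preserves row order.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .synthetic_faces import DatasetManifest, ManifestRecord

COLUMNS = ["path", "sheep_id", "age_months", "x", "y", "w", "h", "split", "origin"]


class ManifestError(ValueError):
    pass


class MissingColumnError(ManifestError):
    pass


class AgeRangeError(ManifestError):
    pass


class SplitViolationError(ManifestError):
    pass


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write CSV and a JSONL twin next to it; deterministic field order."""
    path = Path(path)
    rows = []
    for r in manifest.records:
        x, y, w, h = r.box
        rows.append({"path": r.path, "sheep_id": r.sheep_id,
                     "age_months": r.age_months, "x": x, "y": y, "w": w, "h": h,
                     "split": r.split, "origin": r.origin})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    meta = {"protocol": manifest.protocol}
    with open(path.with_suffix(".jsonl"), "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_meta": meta}, sort_keys=True) + "\n")
        for row in rows:
            fh.write(json.dumps(row, sort_keys=True) + "\n")
    with open(path.with_suffix(".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, sort_keys=True)
        fh.write("\n")


def _record_from_row(row: dict, where: str) -> ManifestRecord:
    missing = [c for c in COLUMNS if c not in row or row[c] is None]
    if missing:
        raise MissingColumnError(f"{where}: missing column(s) {missing}")
    try:
        age = int(row["age_months"])
        box = tuple(int(row[k]) for k in ("x", "y", "w", "h"))
    except (TypeError, ValueError) as exc:
        raise ManifestError(f"{where}: malformed numeric field: {exc}") from None
    if not 1 <= age <= 12:
        raise AgeRangeError(f"{where}: age out of range: {age}")
    return ManifestRecord(path=str(row["path"]), sheep_id=str(row["sheep_id"]),
                          age_months=age, box=box, split=str(row["split"]),
                          origin=str(row.get("origin", "original")))


def read_manifest(path: str | Path, protocol: str | None = None) -> DatasetManifest:
    """Read a CSV or JSONL manifest and validate all invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    if path.suffix == ".jsonl":
        meta = {}
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                row = json.loads(line)
                if "_meta" in row:
                    meta = row["_meta"]
                    continue
                records.append(_record_from_row(row, f"{path}:{i + 1}"))
        protocol = protocol or meta.get("protocol")
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise MissingColumnError(f"{path}: empty file, no header")
            missing = [c for c in COLUMNS if c not in reader.fieldnames]
            if missing:
                raise MissingColumnError(f"{path}: missing column(s) {missing}")
            for i, row in enumerate(reader):
                records.append(_record_from_row(row, f"{path}:{i + 2}"))
        if protocol is None:
            meta_path = path.with_suffix(".meta.json")
            if meta_path.exists():
                protocol = json.loads(meta_path.read_text()).get("protocol")
    protocol = protocol or "age_based"
    try:
        return DatasetManifest(records=records, protocol=protocol)
    except ValueError as exc:
        msg = str(exc)
        if "split violation" in msg:
            raise SplitViolationError(f"{path}: {msg}") from None
        raise ManifestError(f"{path}: {msg}") from None
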