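"""Readers and writers for every on-disk format the pipeline touches.

Formats are deliberately simple and lossless:

* curve-csv — one row per landmark/curve point, columns
  ``specimen_id, curve, index, x, y, z`` (mm).  If every curve of a specimen
  has exactly 20 rows they are taken as the landmarks themselves; otherwise
  the rows form a digitized centerline polyline and 20 evenly spaced
  landmarks are projected onto it.
* TPS dialect — ``LM3=60`` coordinate blocks followed by ``ID=`` lines;
  accepted for interoperability with landmark-digitizing software.
* Newick trees (via dendropy), and plain CSV metadata / occurrence /
  hearing-reference tables.

All writers emit full floating-point precision so write-then-read is
bit-identical.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from otomorph.curves import landmarks_from_curves
from otomorph.types import (
    CANAL_NAMES,
    LANDMARKS_PER_CANAL,
    CanalCurve,
    LabyrinthConfiguration,
    OccurrenceRecord,
    ParseError,
    SpecimenRecord,
    ValidationError,
)

_FLOAT = "%.17g"


def _placeholder_record(specimen_id: str) -> SpecimenRecord:
    # Ecology is unknown at parse time; metadata is attached downstream.
    return SpecimenRecord(
        specimen_id=specimen_id, taxon=specimen_id, group_role="projection"
    )


def read_landmarks(path, dialect: str = "curve-csv") -> List[LabyrinthConfiguration]:
    """Read labyrinth configurations from curve-csv or the TPS dialect."""
    if dialect == "curve-csv":
        return _read_curve_csv(path)
    if dialect == "tps":
        return _read_tps(path)
    raise ValidationError(f"unknown landmark dialect {dialect!r}")


def write_landmarks(configs: Sequence[LabyrinthConfiguration], path, dialect: str = "curve-csv") -> None:
    if dialect == "curve-csv":
        _write_curve_csv(configs, path)
    elif dialect == "tps":
        _write_tps(configs, path)
    else:
        raise ValidationError(f"unknown landmark dialect {dialect!r}")


def _read_curve_csv(path) -> List[LabyrinthConfiguration]:
    rows: Dict[str, Dict[str, list]] = {}
    order: List[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:6]] != [
            "specimen_id", "curve", "index", "x", "y", "z",
        ]:
            raise ParseError(f"{path}:1: expected header specimen_id,curve,index,x,y,z")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                sid, curve, idx = row[0].strip(), row[1].strip(), int(row[2])
                xyz = [float(row[c]) for c in (3, 4, 5)]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row {row!r}") from exc
            if curve not in CANAL_NAMES:
                raise ParseError(f"{path}:{lineno}: unknown curve {curve!r}")
            spec = rows.setdefault(sid, {c: [] for c in CANAL_NAMES})
            if sid not in order:
                order.append(sid)
            spec[curve].append((idx, xyz))
    configs = []
    for sid in order:
        curves = []
        counts = set()
        for name in CANAL_NAMES:
            pts = rows[sid][name]
            if len(pts) < 2:
                raise ValidationError(
                    f"specimen {sid!r}: curve {name!r} has {len(pts)} points (need >= 2)"
                )
            pts.sort(key=lambda t: t[0])
            counts.add(len(pts))
            curves.append(CanalCurve(canal=name, points=np.array([p for _, p in pts])))
        record = _placeholder_record(sid)
        if counts == {LANDMARKS_PER_CANAL}:
            configs.append(
                LabyrinthConfiguration(
                    specimen=record,
                    landmarks=np.vstack([c.points for c in curves]),
                    curves=tuple(curves),
                )
            )
        else:
            configs.append(landmarks_from_curves(record, curves))
    return configs


def _write_curve_csv(configs: Sequence[LabyrinthConfiguration], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "curve", "index", "x", "y", "z"])
        for cfg in configs:
            for c, name in enumerate(CANAL_NAMES):
                block = cfg.landmarks[cfg.canal_slice(name)]
                for i, pt in enumerate(block):
                    writer.writerow(
                        [cfg.specimen.specimen_id, name, i] + [_FLOAT % v for v in pt]
                    )


def _read_tps(path) -> List[LabyrinthConfiguration]:
    configs = []
    lines = Path(path).read_text().splitlines()
    i, n_spec = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise ParseError(f"{path}:{i+1}: expected 'LM3=' block, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{i+1}: malformed count {line!r}") from exc
        coords = []
        i += 1
        for _ in range(k):
            try:
                coords.append([float(v) for v in lines[i].split()])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{i+1}: malformed coordinate row") from exc
            if len(coords[-1]) != 3:
                raise ParseError(f"{path}:{i+1}: expected 3 coordinates")
            i += 1
        sid = f"specimen{n_spec + 1}"
        if i < len(lines) and lines[i].strip().upper().startswith("ID="):
            sid = lines[i].strip().split("=", 1)[1]
            i += 1
        n_spec += 1
        lm = np.asarray(coords)
        if lm.shape[0] != 3 * LANDMARKS_PER_CANAL:
            raise ValidationError(
                f"specimen {sid!r}: expected {3 * LANDMARKS_PER_CANAL} landmarks, got {lm.shape[0]}"
            )
        configs.append(LabyrinthConfiguration(specimen=_placeholder_record(sid), landmarks=lm))
    return configs


def _write_tps(configs: Sequence[LabyrinthConfiguration], path) -> None:
    out = []
    for cfg in configs:
        out.append(f"LM3={len(cfg.landmarks)}")
        out.extend(" ".join(_FLOAT % v for v in pt) for pt in cfg.landmarks)
        out.append(f"ID={cfg.specimen.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


def read_newick(path) -> dendropy.Tree:
    """Rooted topology from a Newick file; branch lengths are optional."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon" in str(exc):
            raise ValidationError(f"{path}: duplicate tip labels: {exc}") from exc
        raise ParseError(f"{path}: {exc}") from exc
    labels = [l.taxon.label.strip() for l in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate tip labels {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    )


def read_metadata(path) -> List[SpecimenRecord]:
    """Specimen metadata CSV: specimen_id, taxon, side, ecology, group_role."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"specimen_id", "taxon"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    records = []
    seen = set()
    for _, row in df.iterrows():
        sid = row["specimen_id"].strip()
        if sid in seen:
            raise ValidationError(f"{path}: duplicate specimen_id {sid!r}")
        seen.add(sid)
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                taxon=row["taxon"].strip(),
                side=(row.get("side", "") or "left").strip(),
                ecology=(row.get("ecology", "").strip() or None),
                group_role=(row.get("group_role", "") or "training").strip(),
            )
        )
    return records


def write_metadata(records: Sequence[SpecimenRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "taxon": r.taxon,
                "side": r.side,
                "ecology": r.ecology or "",
                "group_role": r.group_role,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def attach_metadata(
    configs: Sequence[LabyrinthConfiguration], records: Sequence[SpecimenRecord]
) -> List[LabyrinthConfiguration]:
    """Replace parse-time placeholder records with metadata-table records."""
    by_id = {r.specimen_id: r for r in records}
    out = []
    for cfg in configs:
        sid = cfg.specimen.specimen_id
        if sid not in by_id:
            raise ValidationError(f"no metadata row for specimen {sid!r}")
        out.append(cfg.with_specimen(by_id[sid]))
    return out


def read_occurrences(path) -> List[OccurrenceRecord]:
    """Occurrence CSV: taxon, first_appearance, last_appearance (Ma)."""
    df = pd.read_csv(path)
    needed = {"taxon", "first_appearance", "last_appearance"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(needed)}")
    return [
        OccurrenceRecord(
            taxon=str(row["taxon"]).strip(),
            first_appearance=float(row["first_appearance"]),
            last_appearance=float(row["last_appearance"]),
        )
        for _, row in df.iterrows()
    ]


def write_occurrences(occurrences: Sequence[OccurrenceRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "taxon": o.taxon,
                "first_appearance": o.first_appearance,
                "last_appearance": o.last_appearance,
            }
            for o in occurrences
        ]
    ).to_csv(path, index=False, float_format=_FLOAT)


def read_hearing_table(path) -> pd.DataFrame:
    """Hearing reference CSV: taxon, duct_length, basicranium, best_frequency,
    best_range.  Missing duct lengths are allowed (NaN) and are dropped by the
    model fit."""
    df = pd.read_csv(path)
    needed = {"taxon", "duct_length", "basicranium", "best_frequency", "best_range"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(needed)}")
    return df


def write_hearing_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT)
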