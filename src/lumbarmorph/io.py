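"""Readers and writers for measurement tables and landmark files.

Supported formats:

* measurement CSV — one row per specimen-level, schema::

      specimen_id, taxon, group, sex, lumbar_count, level,
      ventral_height, dorsal_height, sup_dv_diameter, inf_dv_diameter,
      max_inter_IAF, max_inter_SAF

  Parenthesized cells, e.g. ``(28.0)``, mark estimated measurements;
  blank cells or a bare dash mark missing values. En-dash minus signs
  (as printed in comparative tables) are accepted.

* landmark XYZ — whitespace-delimited three-column text, one landmark
  per row in a fixed order, one file per specimen, joined to specimen
  metadata via a manifest CSV (``specimen_id, file, taxon, group, sex,
  lumbar_count``).

* TPS — the morphometrics interchange dialect restricted to ``LM3=``,
  ``ID=`` and ``SCALE=`` keys.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import (
    FacetWidths,
    LandmarkConfiguration,
    LandmarkSet,
    LumbarSeries,
    Measurement,
    MissingDataError,
    SpecimenInfo,
    ValidationError,
    VertebralBodyGeometry,
    default_landmark_labels,
)

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_landmarks_xyz",
    "write_landmarks_xyz",
    "read_landmarks_tps",
    "write_landmarks_tps",
]

MEASUREMENT_COLUMNS = [
    "specimen_id",
    "taxon",
    "group",
    "sex",
    "lumbar_count",
    "level",
    "ventral_height",
    "dorsal_height",
    "sup_dv_diameter",
    "inf_dv_diameter",
    "max_inter_IAF",
    "max_inter_SAF",
]

_NUMERIC_FIELDS = MEASUREMENT_COLUMNS[6:]

# dashes that mean "missing" when they are the whole cell, and
# dash variants accepted as a minus sign in front of a number
_DASH_CHARS = "–—−-"
_MISSING_RE = re.compile(rf"^[{_DASH_CHARS}]$")


class ParseError(ValueError):
    """A cell could not be interpreted; the message names row and column."""


def _parse_cell(
    raw: str, *, row: int, column: str
) -> Optional[Measurement]:
    """Parse one measurement cell into a Measurement or None (missing)."""
    text = raw.strip()
    if not text or _MISSING_RE.match(text):
        return None
    estimated = False
    if text.startswith("(") and text.endswith(")"):
        estimated = True
        text = text[1:-1].strip()
    # normalize en-dash / minus-sign variants to ASCII hyphen
    text = re.sub(rf"^[{_DASH_CHARS}]", "-", text)
    try:
        value = float(text)
    except ValueError:
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {raw!r} as a number"
        ) from None
    try:
        return Measurement(value, estimated=estimated)
    except ValidationError as exc:
        raise ParseError(f"row {row}, column {column!r}: {exc}") from None


def read_measurements(path: Union[str, Path]) -> list[LumbarSeries]:
    """Read a measurement CSV into one :class:`LumbarSeries` per specimen.

    Raises
    ------
    ParseError
        On a malformed numeric cell (names the offending row and column).
    ValidationError
        On a missing/invalid header or a duplicate specimen+level row.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in MEASUREMENT_COLUMNS if c not in header]
        if missing:
            raise ValidationError(
                f"{path.name}: header lacks required columns {missing}"
            )
        per_specimen: dict[str, dict] = {}
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            sid = (row["specimen_id"] or "").strip()
            if not sid:
                raise ParseError(f"row {i}: empty specimen_id")
            level = (row["level"] or "").strip()
            cells = {
                name: _parse_cell(row[name] or "", row=i, column=name)
                for name in _NUMERIC_FIELDS
            }
            try:
                lumbar_count = int(row["lumbar_count"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"row {i}, column 'lumbar_count': cannot parse "
                    f"{row['lumbar_count']!r} as an integer"
                ) from None
            entry = per_specimen.setdefault(
                sid,
                {
                    "info": SpecimenInfo(
                        specimen_id=sid,
                        taxon=(row["taxon"] or "").strip(),
                        group=(row["group"] or "").strip(),
                        sex=(row["sex"] or "").strip() or None,
                        lumbar_count=lumbar_count,
                        is_fossil=_is_fossil_group((row["group"] or "").strip()),
                    ),
                    "levels": {},
                },
            )
            if level in entry["levels"]:
                raise ValidationError(
                    f"row {i}: duplicate entry for specimen {sid!r} level "
                    f"{level!r}"
                )
            entry["levels"][level] = (
                VertebralBodyGeometry(
                    ventral_height=cells["ventral_height"],
                    dorsal_height=cells["dorsal_height"],
                    sup_dv_diameter=cells["sup_dv_diameter"],
                    inf_dv_diameter=cells["inf_dv_diameter"],
                ),
                FacetWidths(
                    max_inter_IAF=cells["max_inter_IAF"],
                    max_inter_SAF=cells["max_inter_SAF"],
                ),
            )
    return [
        LumbarSeries(specimen=entry["info"], levels=entry["levels"])
        for entry in per_specimen.values()
    ]


_FOSSIL_GROUPS = {
    "fossil",
    "australopithecus",
    "a. sediba",
    "a. africanus",
    "a. afarensis",
    "neandertal",
    "neanderthal",
    "h. erectus",
    "h. naledi",
}


def _is_fossil_group(group: str) -> bool:
    return group.lower() in _FOSSIL_GROUPS


def _format_cell(m: Optional[Measurement]) -> str:
    if m is None:
        return ""
    text = format(m.value, "g")
    return f"({text})" if m.estimated else text


def write_measurements(
    series: Sequence[LumbarSeries], path: Union[str, Path]
) -> None:
    """Write LumbarSeries back to the measurement CSV schema."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for s in series:
            info = s.specimen
            for level in s.present_levels:
                geom, fac = s.levels[level]
                writer.writerow(
                    [
                        info.specimen_id,
                        info.taxon,
                        info.group,
                        info.sex or "",
                        info.lumbar_count,
                        level,
                        _format_cell(geom.ventral_height),
                        _format_cell(geom.dorsal_height),
                        _format_cell(geom.sup_dv_diameter),
                        _format_cell(geom.inf_dv_diameter),
                        _format_cell(fac.max_inter_IAF),
                        _format_cell(fac.max_inter_SAF),
                    ]
                )


MANIFEST_COLUMNS = ["specimen_id", "file", "taxon", "group", "sex", "lumbar_count"]


def read_landmarks_xyz(
    manifest: Union[str, Path], root: Optional[Union[str, Path]] = None
) -> LandmarkSet:
    """Read per-specimen XYZ landmark files listed in a manifest CSV.

    Parameters
    ----------
    manifest : path
        CSV with columns ``specimen_id, file, taxon, group, sex,
        lumbar_count``; ``file`` paths are resolved relative to ``root``
        (default: the manifest's directory).
    """
    manifest = Path(manifest)
    base = Path(root) if root is not None else manifest.parent
    table = pd.read_csv(manifest, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(
            f"{manifest.name}: manifest lacks columns {missing}"
        )
    configs: list[LandmarkConfiguration] = []
    counts: dict[str, int] = {}
    for row in table.itertuples(index=False):
        fpath = base / row.file
        if not fpath.exists():
            raise ValidationError(
                f"specimen {row.specimen_id!r}: landmark file {fpath} not found"
            )
        coords = np.loadtxt(fpath, ndmin=2)
        if coords.shape[1] != 3:
            raise ParseError(
                f"{fpath.name}: expected 3 columns, got {coords.shape[1]}"
            )
        counts[fpath.name] = coords.shape[0]
        sex = row.sex if isinstance(row.sex, str) and row.sex else None
        info = SpecimenInfo(
            specimen_id=row.specimen_id,
            taxon=row.taxon,
            group=row.group,
            sex=sex,
            lumbar_count=int(row.lumbar_count),
            is_fossil=_is_fossil_group(str(row.group)),
        )
        configs.append(
            LandmarkConfiguration(
                specimen=info,
                coordinates=coords,
                landmark_labels=default_landmark_labels(coords.shape[0]),
            )
        )
    if not configs:
        raise ValidationError(f"{manifest.name}: empty manifest")
    k_values = set(counts.values())
    if len(k_values) > 1:
        common = max(k_values, key=lambda k: sum(v == k for v in counts.values()))
        offenders = sorted(f for f, k in counts.items() if k != common)
        raise ValidationError(
            f"inconsistent landmark counts {sorted(k_values)}; offending "
            f"files: {offenders}"
        )
    return LandmarkSet(
        configurations=configs, landmark_labels=configs[0].landmark_labels
    )


def write_landmarks_xyz(
    lms: LandmarkSet, out_dir: Union[str, Path], manifest_name: str = "manifest.csv"
) -> Path:
    """Write one XYZ file per configuration plus a manifest CSV.

    Coordinates are serialized with ``repr``-level precision so a
    write→read round trip reproduces them bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cfg in lms:
        fname = f"{cfg.specimen.specimen_id}.xyz"
        with (out_dir / fname).open("w") as fh:
            for x, y, z in cfg.coordinates:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
        info = cfg.specimen
        rows.append(
            [
                info.specimen_id,
                fname,
                info.taxon,
                info.group,
                info.sex or "",
                info.lumbar_count,
            ]
        )
    mpath = out_dir / manifest_name
    with mpath.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)
    return mpath


def read_landmarks_tps(path: Union[str, Path]) -> LandmarkSet:
    """Read a 3D TPS file (``LM3=``, ``ID=``, ``SCALE=`` keys).

    SCALE, when present, multiplies the record's coordinates.
    """
    path = Path(path)
    records: list[tuple[str, np.ndarray]] = []
    current_coords: list[list[float]] = []
    current_k: Optional[int] = None
    current_id: Optional[str] = None
    current_scale = 1.0

    def flush() -> None:
        nonlocal current_coords, current_k, current_id, current_scale
        if current_k is None:
            return
        if len(current_coords) != current_k:
            raise ParseError(
                f"{path.name}: record {current_id or len(records) + 1!r} "
                f"declares LM3={current_k} but has {len(current_coords)} "
                "coordinate lines"
            )
        rid = current_id if current_id is not None else f"tps{len(records) + 1}"
        records.append(
            (rid, np.asarray(current_coords, dtype=float) * current_scale)
        )
        current_coords, current_k, current_id, current_scale = [], None, None, 1.0

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.strip()
        if not text:
            continue
        upper = text.upper()
        if upper.startswith("LM3="):
            flush()
            try:
                current_k = int(text.split("=", 1)[1])
            except ValueError:
                raise ParseError(
                    f"{path.name} line {lineno}: bad LM3 count {text!r}"
                ) from None
        elif upper.startswith("ID="):
            current_id = text.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            try:
                current_scale = float(text.split("=", 1)[1])
            except ValueError:
                raise ParseError(
                    f"{path.name} line {lineno}: bad SCALE {text!r}"
                ) from None
        else:
            if current_k is None:
                raise ParseError(
                    f"{path.name} line {lineno}: coordinate line outside an "
                    "LM3 record"
                )
            fields = text.split()
            if len(fields) != 3:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 3 coordinates, got "
                    f"{len(fields)}"
                )
            try:
                current_coords.append([float(f) for f in fields])
            except ValueError:
                raise ParseError(
                    f"{path.name} line {lineno}: non-numeric coordinate in "
                    f"{text!r}"
                ) from None
    flush()
    if not records:
        raise ValidationError(f"{path.name}: no TPS records found")
    cardinalities = {coords.shape[0] for _, coords in records}
    if len(cardinalities) > 1:
        raise ValidationError(
            f"{path.name}: mixed landmark cardinalities {sorted(cardinalities)}"
        )
    k = records[0][1].shape[0]
    labels = default_landmark_labels(k)
    configs = [
        LandmarkConfiguration(
            specimen=SpecimenInfo(specimen_id=rid, taxon="", group=""),
            coordinates=coords,
            landmark_labels=labels,
        )
        for rid, coords in records
    ]
    return LandmarkSet(configurations=configs, landmark_labels=labels)


def write_landmarks_tps(lms: LandmarkSet, path: Union[str, Path]) -> None:
    """Write a LandmarkSet as a 3D TPS file (one LM3 record per specimen)."""
    path = Path(path)
    with path.open("w") as fh:
        for cfg in lms:
            fh.write(f"LM3={cfg.n_landmarks}\n")
            for x, y, z in cfg.coordinates:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
            fh.write(f"ID={cfg.specimen.specimen_id}\n")
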