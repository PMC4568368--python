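"""Readers and writers for the pipeline's tabular formats.

Units are fixed per column and named in headers (mm², mm, µm); there is no
unit autodetection. Field-count CSV schema (one row per microscopic field)::

    animal_id, group, p_collagen, p_vessel, p_hair, p_dermis, q_minus,
    frame_area_mm2, height_mm, vessel_transects, diameters_um

``diameters_um`` is a semicolon-joined list (empty string when no profile was
measured). Wound series CSV: ``animal_id, group, day, area_mm2``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import FieldCounts, StereologyError
from .timecourse import WoundSeries

__all__ = [
    "FIELD_COLUMNS",
    "read_field_counts",
    "write_field_counts",
    "read_wound_series",
    "write_wound_series",
    "read_mask",
    "load_config_file",
]

FIELD_COLUMNS = [
    "animal_id", "group", "p_collagen", "p_vessel", "p_hair", "p_dermis",
    "q_minus", "frame_area_mm2", "height_mm", "vessel_transects", "diameters_um",
]

_COUNT_COLUMNS = ["p_collagen", "p_vessel", "p_hair", "p_dermis", "q_minus",
                  "vessel_transects"]


def _comment_offset(path: str | Path) -> int:
    """Number of leading '#' comment lines (e.g. the seed/config header)."""
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
    return n


def read_field_counts(path: str | Path) -> list[FieldCounts]:
    """Read and validate a field-count CSV; malformed rows are reported with
    their (1-based, header-inclusive) line numbers. Leading '#' comment lines
    (the run's seed/config header) are skipped."""
    offset = _comment_offset(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str},
                     keep_default_na=False, float_precision="round_trip",
                     comment="#")
    missing = [c for c in FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise StereologyError(f"{path}: missing required columns {missing}")
    records: list[FieldCounts] = []
    for idx, row in df.iterrows():
        line = idx + 2 + offset
        for col in _COUNT_COLUMNS:
            v = row[col]
            if float(v) < 0 or float(v) != int(float(v)):
                raise StereologyError(
                    f"{path}, line {line}: {col} must be a non-negative integer, got {v!r}")
        raw = str(row["diameters_um"]).strip()
        diameters = [float(tok) for tok in raw.split(";") if tok.strip()] if raw else []
        try:
            records.append(FieldCounts(
                p_collagen=int(row["p_collagen"]),
                p_vessel=int(row["p_vessel"]),
                p_hair=int(row["p_hair"]),
                p_dermis=int(row["p_dermis"]),
                q_minus=int(row["q_minus"]),
                frame_area_mm2=float(row["frame_area_mm2"]),
                height_mm=float(row["height_mm"]),
                vessel_transects=int(row["vessel_transects"]),
                vessel_profile_diameters=diameters,
                animal_id=row["animal_id"] or None,
                group=row["group"] or None,
            ))
        except StereologyError as exc:
            raise StereologyError(f"{path}, line {line}: {exc}") from exc
    return records


def write_field_counts(fields: list[FieldCounts], path: str | Path,
                       header_comment: str | None = None) -> None:
    rows = []
    for f in fields:
        rows.append({
            "animal_id": f.animal_id or "",
            "group": f.group or "",
            "p_collagen": f.p_collagen,
            "p_vessel": f.p_vessel,
            "p_hair": f.p_hair,
            "p_dermis": f.p_dermis,
            "q_minus": f.q_minus,
            "frame_area_mm2": repr(f.frame_area_mm2),
            "height_mm": repr(f.height_mm),
            "vessel_transects": f.vessel_transects,
            "diameters_um": ";".join(repr(d) for d in f.vessel_profile_diameters),
        })
    _write_csv(pd.DataFrame(rows, columns=FIELD_COLUMNS), path, header_comment)


def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=index)


def read_wound_series(path: str | Path) -> list[WoundSeries]:
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str},
                     float_precision="round_trip", comment="#")
    needed = ["animal_id", "group", "day", "area_mm2"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise StereologyError(f"{path}: missing required columns {missing}")
    out = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=False):
        sub = sub.sort_values("day")
        out.append(WoundSeries(animal_id=animal, group=group,
                               days=[int(d) for d in sub["day"]],
                               areas=[float(a) for a in sub["area_mm2"]]))
    return out


def write_wound_series(series: list[WoundSeries], path: str | Path,
                       header_comment: str | None = None) -> None:
    rows = [{"animal_id": s.animal_id, "group": s.group, "day": d, "area_mm2": repr(a)}
            for s in series for d, a in zip(s.days, s.areas)]
    _write_csv(pd.DataFrame(rows, columns=["animal_id", "group", "day", "area_mm2"]),
               path, header_comment)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a wound mask image (PNG/TIFF) as a boolean array; any nonzero
    pixel (first channel if multi-channel) counts as wound."""
    import imageio.v3 as iio
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise StereologyError(f"{path}: config must be a mapping")
    return data
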