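"""File formats: item tables, covariance tables, response matrices, reports.

Schemas (CSV, comma-separated, header row required):

* item table: ``item_id,a,b,c``
* covariance table: ``item_id,var_a,var_b,var_c,cov_ab,cov_ac,cov_bc``
* response matrix: ``person_id`` followed by one column per item, entries 0/1
  (blank or -1 for missing)
* link object: JSON ``{"u": ..., "v": ..., "direction": ...}``
* link report: JSON with ``methods``, ``per_item``, ``provenance`` and
  ``warnings`` blocks
* study design: YAML mapping of :class:`irtlink.study.StudyDesign` fields

Numeric values are written with 17 significant digits so that write/read
round trips are lossless for double precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from .linking import LinearLink
from .model import ResponseMatrix
from .study import StudyDesign

__all__ = [
    "SchemaError",
    "read_item_table",
    "write_item_table",
    "read_cov_table",
    "write_cov_table",
    "read_responses",
    "write_responses",
    "read_link",
    "write_link",
    "write_report",
    "read_design",
    "write_design",
]

ITEM_COLUMNS = ["item_id", "a", "b", "c"]
COV_TABLE_COLUMNS = ["item_id", "var_a", "var_b", "var_c",
                     "cov_ab", "cov_ac", "cov_bc"]
FLOAT_FORMAT = "%.17g"

#: The orientation every link object and report in this package uses.
DIRECTION_NOTE = (
    "links map source-calibration (calibration 1) parameters onto the "
    "target-calibration (calibration 2) scale: theta* = u*theta + v, "
    "a* = a/u, b* = u*b + v, c* = c"
)


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _check_schema(frame: pd.DataFrame, expected: list[str], path) -> None:
    found = list(frame.columns)
    missing = [c for c in expected if c not in found]
    extra = [c for c in found if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: header mismatch; missing columns {missing}, "
            f"unexpected columns {extra}; expected exactly {expected}"
        )


def _check_numeric(frame: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based counting
            raise SchemaError(
                f"{path}: non-numeric value in column '{col}' at line "
                f"{int(bad[0]) + 2}"
            )
        frame[col] = coerced
    return frame


def read_item_table(path) -> pd.DataFrame:
    """Read an item table; validates the header and numeric cells."""
    frame = pd.read_csv(path)
    _check_schema(frame, ITEM_COLUMNS, path)
    return _check_numeric(frame, ["a", "b", "c"], path)


def write_item_table(items: pd.DataFrame, path) -> None:
    items[ITEM_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cov_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_schema(frame, COV_TABLE_COLUMNS, path)
    return _check_numeric(frame, COV_TABLE_COLUMNS[1:], path)


def write_cov_table(cov: pd.DataFrame, path) -> None:
    cov[COV_TABLE_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_responses(path) -> ResponseMatrix:
    frame = pd.read_csv(path)
    if "person_id" not in frame.columns:
        raise SchemaError(f"{path}: responses need a leading 'person_id' column")
    return ResponseMatrix.from_frame(frame)


def write_responses(responses: ResponseMatrix, path) -> None:
    responses.to_frame().to_csv(path, index=False)


def read_link(path) -> LinearLink:
    with open(path) as fh:
        obj = json.load(fh)
    if "u" not in obj or "v" not in obj:
        raise SchemaError(f"{path}: link JSON must contain 'u' and 'v'")
    return LinearLink(obj["u"], obj["v"],
                      direction=obj.get("direction", "source_to_target"))


def write_link(link: LinearLink, path) -> None:
    with open(path, "w") as fh:
        json.dump(link.to_dict(), fh, indent=2)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(methods: dict, per_item: pd.DataFrame | None, path,
                 provenance: dict | None = None,
                 warnings_list: list | None = None) -> None:
    """Write a link report: a methods block (method -> u, se_u, v, se_v),
    a per-item block, and provenance (inputs, seed, version, timestamp,
    direction convention)."""
    from . import __version__

    method_block = {}
    warning_out = list(warnings_list or [])
    for name, pooled in methods.items():
        entry = pooled.to_dict() if hasattr(pooled, "to_dict") else dict(pooled)
        for key in ("se_u", "se_v"):
            if entry.get(key) is None:
                warning_out.append(
                    f"method {name}: no {key} available (covariances not supplied)"
                )
        method_block[name] = entry
    report = {
        "methods": method_block,
        "per_item": None if per_item is None else per_item,
        "provenance": {
            "package": "irtlink",
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "direction": DIRECTION_NOTE,
            **(provenance or {}),
        },
        "warnings": warning_out,
    }
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
        fh.write("\n")


def read_design(path) -> StudyDesign:
    """Read a study design from YAML; unknown keys raise SchemaError."""
    with open(path) as fh:
        obj = yaml.safe_load(fh) or {}
    valid = set(StudyDesign.__dataclass_fields__)
    unknown = sorted(set(obj) - valid)
    if unknown:
        raise SchemaError(f"{path}: unknown design fields {unknown}")
    for key in ("common_b_grid", "common_a_levels", "unique_a_range",
                "ability_mean", "ability_scale"):
        if key in obj and isinstance(obj[key], list):
            obj[key] = tuple(obj[key])
    return StudyDesign(**obj)


def write_design(design: StudyDesign, path) -> None:
    obj = asdict(design)
    for key, value in obj.items():
        if isinstance(value, tuple):
            obj[key] = list(value)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
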