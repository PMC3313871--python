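"""Delimited-text readers and writers for measurement tables and rules.

The canonical on-disk format is long: one row per (subject, variable) with
columns ``subject_id, center_id, variable, value, download_index`` (see
docs/schema.md).  A wide-format convenience reader melts one-column-per-
variable files into the long form.  Comma is the default delimiter, tab is
accepted (``.tsv`` infers it); decimal points only.
"""

from __future__ import annotations

import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from .diagnostics import CorrectionRule
from .exceptions import NoDataError, ValidationError

__all__ = [
    "REQUIRED_COLUMNS",
    "read_measurements",
    "write_measurements",
    "read_measurements_wide",
    "validate_measurements",
    "load_arm_assignment",
    "load_correction_rules",
    "save_correction_rules",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "center_id", "variable", "value")
ID_COLUMNS = ("subject_id", "center_id", "variable")


def _delimiter(path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if pathlib.Path(path).suffix.lower() == ".tsv" else ","


def read_measurements(
    path, delimiter: str | None = None, validate: bool = True
) -> pd.DataFrame:
    """Read a long-format measurement table from delimited text.

    Malformed numeric cells become missing values (with a logged count);
    a missing ``download_index`` column is filled with 0.  Round-trips with
    :func:`write_measurements`.
    """
    sep = _delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise NoDataError("no data") from None
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing required column: {col}")
    if len(df) == 0:
        raise NoDataError("no data")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = int((values.isna() & df["value"].notna()).sum())
    if bad:
        logger.warning("%d malformed value cell(s) treated as missing", bad)
    df["value"] = values
    if "download_index" in df.columns:
        downloads = pd.to_numeric(df["download_index"], errors="coerce")
        if downloads.isna().any() or (downloads < 0).any():
            raise ValidationError(
                "download_index must be a non-negative integer"
            )
        df["download_index"] = downloads.astype(int)
    else:
        logger.warning("no download_index column; assuming a single snapshot 0")
        df["download_index"] = 0
    if validate:
        validate_measurements(df)
    return df


def validate_measurements(df: pd.DataFrame) -> None:
    """Enforce table invariants: non-missing center, unique (subject, variable)."""
    if df["center_id"].isna().any():
        raise ValidationError("rows with missing center_id")
    dup = df.duplicated(subset=["subject_id", "variable"])
    if dup.any():
        raise ValidationError(
            f"{int(dup.sum())} duplicate (subject_id, variable) row(s)"
        )


def write_measurements(df: pd.DataFrame, path, delimiter: str | None = None):
    """Write a measurement table; float repr is round-trip exact."""
    sep = _delimiter(path, delimiter)
    df.to_csv(path, sep=sep, index=False)


def read_measurements_wide(
    path,
    delimiter: str | None = None,
    id_columns: tuple[str, ...] = ("subject_id", "center_id", "download_index"),
) -> pd.DataFrame:
    """Read a wide table (one column per variable) and normalise to long."""
    sep = _delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise NoDataError("no data") from None
    for col in ("subject_id", "center_id"):
        if col not in df.columns:
            raise ValidationError(f"missing required column: {col}")
    present_ids = [c for c in id_columns if c in df.columns]
    value_vars = [c for c in df.columns if c not in present_ids]
    if not value_vars:
        raise NoDataError("no data")
    long = df.melt(
        id_vars=present_ids, value_vars=value_vars,
        var_name="variable", value_name="value",
    )
    long["value"] = pd.to_numeric(long["value"], errors="coerce")
    if "download_index" not in long.columns:
        long["download_index"] = 0
    long["subject_id"] = long["subject_id"].astype(str)
    long["center_id"] = long["center_id"].astype(str)
    validate_measurements(long)
    return long[
        ["subject_id", "center_id", "variable", "value", "download_index"]
    ]


def load_arm_assignment(path, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column (center_id, arm) file into a mapping."""
    sep = _delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("center_id", "arm"):
        if col not in df.columns:
            raise ValidationError(f"missing required column: {col}")
    return dict(zip(df["center_id"], df["arm"]))


def _rule_to_dict(rule: CorrectionRule) -> dict:
    return {
        "center_id": rule.center_id,
        "variable": rule.variable,
        "offset": rule.offset,
        "download_min": rule.download_min,
        "download_max": rule.download_max,
        "subject_ids": list(rule.subject_ids) if rule.subject_ids else None,
        "reason": rule.reason,
    }


def _rule_from_dict(d: dict) -> CorrectionRule:
    return CorrectionRule(
        center_id=str(d["center_id"]),
        variable=str(d["variable"]),
        offset=float(d["offset"]),
        download_min=d.get("download_min"),
        download_max=d.get("download_max"),
        subject_ids=(
            tuple(d["subject_ids"]) if d.get("subject_ids") else None
        ),
        reason=str(d.get("reason", "")),
    )


def load_correction_rules(path) -> list[CorrectionRule]:
    """Read correction rules from a JSON or YAML list of mappings."""
    path = pathlib.Path(path)
    text = path.read_text()
    data = (
        yaml.safe_load(text)
        if path.suffix in (".yaml", ".yml")
        else json.loads(text)
    )
    if not isinstance(data, list):
        raise ValidationError("correction rules file must hold a list")
    return [_rule_from_dict(d) for d in data]


def save_correction_rules(rules: list[CorrectionRule], path) -> None:
    path = pathlib.Path(path)
    data = [_rule_to_dict(r) for r in rules]
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, sort_keys=True, indent=2))
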