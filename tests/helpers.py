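"""Shared test utilities: deterministic seeds and table builders."""

from __future__ import annotations

import zlib

import pandas as pd

#: Package-wide base seed; per-test streams are derived from it by tag.
BASE_SEED = 20080901


def seed_for(tag: str) -> int:
    """Deterministic per-test seed derived from a stable convention."""
    return (BASE_SEED + zlib.crc32(tag.encode())) % (2**31)


def make_table(
    groups: dict[str, list[float]],
    variable: str = "y",
    download_index: int = 1,
) -> pd.DataFrame:
    """Long-format measurement table from {center: [values]}."""
    rows = []
    for center, values in groups.items():
        for j, v in enumerate(values):
            rows.append(
                {
                    "subject_id": f"{center}-{j}",
                    "center_id": center,
                    "variable": variable,
                    "value": v,
                    "download_index": download_index,
                }
            )
    return pd.DataFrame(rows)
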