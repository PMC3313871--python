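"""Typed QA findings shared by the diagnostics and monitoring modules."""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

import pandas as pd


class FlagType(str, enum.Enum):
    HIGH_ICC = "HIGH_ICC"
    ICC_JUMP = "ICC_JUMP"
    SHIFTED_CENTER = "SHIFTED_CENTER"
    IMPLAUSIBLE_VALUE = "IMPLAUSIBLE_VALUE"


@dataclass(frozen=True)
class Flag:
    """One advisory finding; never an automatic correction."""

    flag_type: FlagType
    variable: str
    download_index: int
    details: dict[str, Any] = field(default_factory=dict)


def _details_repr(details: dict[str, Any]) -> str:
    parts = []
    for key in sorted(details):
        val = details[key]
        if dataclasses.is_dataclass(val) and not isinstance(val, type):
            val = dataclasses.asdict(val)
        parts.append(f"{key}={val}")
    return "; ".join(parts)


@dataclass
class FlagReport:
    """An ordered collection of flags for a monitoring run."""

    entries: list[Flag] = field(default_factory=list)

    def add(self, flag: Flag) -> None:
        self.entries.append(flag)

    def extend(self, flags: Iterable[Flag]) -> None:
        self.entries.extend(flags)

    def __iter__(self) -> Iterator[Flag]:
        return iter(self.sorted_entries())

    def __len__(self) -> int:
        return len(self.entries)

    def sorted_entries(self) -> list[Flag]:
        """Entries sorted by (download_index, variable, flag type)."""
        return sorted(
            self.entries,
            key=lambda f: (f.download_index, f.variable, f.flag_type.value,
                           _details_repr(f.details)),
        )

    def filter(
        self,
        flag_type: FlagType | None = None,
        variable: str | None = None,
        download_index: int | None = None,
    ) -> list[Flag]:
        out = []
        for f in self.sorted_entries():
            if flag_type is not None and f.flag_type != flag_type:
                continue
            if variable is not None and f.variable != variable:
                continue
            if download_index is not None and f.download_index != download_index:
                continue
            out.append(f)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "download_index": f.download_index,
                "variable": f.variable,
                "flag_type": f.flag_type.value,
                "details": _details_repr(f.details),
            }
            for f in self.sorted_entries()
        ]
        return pd.DataFrame(
            rows, columns=["download_index", "variable", "flag_type", "details"]
        )
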