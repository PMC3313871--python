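"""The sequential download → compute → flag → report engine.

A multicenter study's database is extracted periodically; each extract is a
cumulative *snapshot* carrying every record entered so far, tagged with a
``download_index``.  At each download the engine recomputes the ICC (with
confidence interval) of every configured variable on the cumulative data,
compares it to the flag thresholds, runs shifted-center detection and the
implausible-value scan, and appends everything to a monitoring history from
which tabular reports are rendered.

Flags are advisory: a correction is only ever applied when an explicit
:class:`~iccwatch.diagnostics.CorrectionRule` is supplied (mirroring field
practice, where an anomaly is confirmed with the measuring staff before any
value is touched).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .core import ICCEstimate, icc_with_ci
from .diagnostics import (
    CorrectionRule,
    PlausibleRange,
    apply_correction,
    center_boxplot_stats,
    detect_shifted_centers,
    implausible_value_scan,
)
from .exceptions import (
    InsufficientClustersError,
    SnapshotRegressionError,
    ValidationError,
)
from .flags import Flag, FlagReport, FlagType

__all__ = [
    "MonitoringConfig",
    "MonitoringHistory",
    "monitor_download",
    "run_monitoring",
    "render_report",
    "format_report",
    "write_report",
]


@dataclass(frozen=True)
class MonitoringConfig:
    """Thresholds and per-variable settings for a monitoring run.

    ``icc_flag_threshold`` (default 0.05) marks an ICC as higher than
    expected for a population without strong regional differences;
    ``icc_jump_threshold`` flags an absolute increase between consecutive
    downloads.  Variables listed in ``reference_variables`` (automated
    instruments) have their ICC reported but are exempt from HIGH_ICC.
    """

    variables: tuple[str, ...]
    icc_flag_threshold: float = 0.05
    icc_jump_threshold: float = 0.05
    alpha: float = 0.05
    plausible_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    min_offset: Mapping[str, float] = field(default_factory=dict)
    robust_z: float = 3.0
    reference_variables: tuple[str, ...] = ()
    ci_method: str = "smith"

    def __post_init__(self):
        if not self.variables:
            raise ValidationError("config requires at least one variable")
        for name, value in (
            ("icc_flag_threshold", self.icc_flag_threshold),
            ("icc_jump_threshold", self.icc_jump_threshold),
            ("alpha", self.alpha),
        ):
            if not 0.0 < value < 1.0:
                raise ValidationError(f"{name} must be in (0, 1)")
        for var, (low, high) in self.plausible_ranges.items():
            if not low < high:
                raise ValidationError(f"plausible range for {var!r}: low < high")

    def ranges(self) -> list[PlausibleRange]:
        return [
            PlausibleRange(variable=v, low=lo, high=hi)
            for v, (lo, hi) in self.plausible_ranges.items()
        ]

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "icc_flag_threshold": self.icc_flag_threshold,
            "icc_jump_threshold": self.icc_jump_threshold,
            "alpha": self.alpha,
            "plausible_ranges": {
                k: [v[0], v[1]] for k, v in self.plausible_ranges.items()
            },
            "min_offset": dict(self.min_offset),
            "robust_z": self.robust_z,
            "reference_variables": list(self.reference_variables),
            "ci_method": self.ci_method,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MonitoringConfig":
        d = dict(d)
        return cls(
            variables=tuple(d["variables"]),
            icc_flag_threshold=float(d.get("icc_flag_threshold", 0.05)),
            icc_jump_threshold=float(d.get("icc_jump_threshold", 0.05)),
            alpha=float(d.get("alpha", 0.05)),
            plausible_ranges={
                k: (float(v[0]), float(v[1]))
                for k, v in d.get("plausible_ranges", {}).items()
            },
            min_offset={
                k: float(v) for k, v in d.get("min_offset", {}).items()
            },
            robust_z=float(d.get("robust_z", 3.0)),
            reference_variables=tuple(d.get("reference_variables", ())),
            ci_method=str(d.get("ci_method", "smith")),
        )

    def to_file(self, path) -> None:
        path = pathlib.Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), sort_keys=True, indent=2))

    @classmethod
    def from_file(cls, path) -> "MonitoringConfig":
        path = pathlib.Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


class MonitoringHistory:
    """Ordered ICC trajectories per variable, plus gap bookkeeping.

    Within a variable, download indices are strictly increasing and the
    total n is non-decreasing (snapshots are cumulative).
    """

    def __init__(self):
        self._series: dict[str, list[ICCEstimate]] = {}
        self._gaps: dict[str, list[int]] = {}

    def append(self, estimate: ICCEstimate) -> None:
        series = self._series.setdefault(estimate.variable, [])
        if series:
            last = series[-1]
            if estimate.download_index <= last.download_index:
                raise ValidationError(
                    "download_index must be strictly increasing per variable"
                )
            if estimate.N < last.N:
                raise SnapshotRegressionError("snapshot regression")
        series.append(estimate)

    def record_gap(self, variable: str, download_index: int) -> None:
        self._gaps.setdefault(variable, []).append(download_index)

    @property
    def variables(self) -> list[str]:
        return sorted(set(self._series) | set(self._gaps))

    def estimates(self, variable: str) -> list[ICCEstimate]:
        return list(self._series.get(variable, []))

    def gaps(self, variable: str) -> list[int]:
        return list(self._gaps.get(variable, []))

    def last(self, variable: str) -> ICCEstimate | None:
        series = self._series.get(variable)
        return series[-1] if series else None

    def downloads(self) -> list[int]:
        out: set[int] = set()
        for series in self._series.values():
            out.update(e.download_index for e in series)
        for gaps in self._gaps.values():
            out.update(gaps)
        return sorted(out)


def _count_nonmissing(snapshot: pd.DataFrame, variable: str) -> int:
    if "variable" in snapshot.columns:
        sub = snapshot[snapshot["variable"] == variable]
    else:
        sub = snapshot
    return int(sub["value"].notna().sum())


def monitor_download(
    snapshot: pd.DataFrame,
    history: MonitoringHistory,
    config: MonitoringConfig,
) -> tuple[MonitoringHistory, FlagReport]:
    """Process one cumulative snapshot: estimate, compare, flag.

    For every configured variable present in the snapshot the ICC and its
    confidence interval are computed on the cumulative data and appended to
    the history; HIGH_ICC fires when rho exceeds the flag threshold (unless
    the variable is a reference instrument), ICC_JUMP when rho rose by more
    than the jump threshold since the previous download (the jump is judged
    on the point estimates; CI overlap is reported in the details but does
    not gate the flag).  Shifted-center detection runs on the per-center
    box-plot statistics, and the implausible-value scan covers the rows that
    arrived at this download.  Deterministic throughout.
    """
    if len(snapshot) == 0:
        raise SnapshotRegressionError("snapshot regression")
    d = int(snapshot["download_index"].max()) if "download_index" in snapshot.columns else 0
    report = FlagReport()
    ranges = {r.variable: r for r in config.ranges()}
    if "download_index" in snapshot.columns:
        new_rows = snapshot[snapshot["download_index"] == d]
    else:
        new_rows = snapshot
    for var in config.variables:
        n_var = _count_nonmissing(snapshot, var)
        last = history.last(var)
        if n_var == 0:
            history.record_gap(var, d)
            continue
        if last is not None and n_var < last.N:
            raise SnapshotRegressionError("snapshot regression")
        est = icc_with_ci(
            snapshot, variable=var, alpha=config.alpha, method=config.ci_method
        )
        est = dataclasses.replace(est, download_index=d)
        history.append(est)
        if (
            est.rho > config.icc_flag_threshold
            and var not in config.reference_variables
        ):
            report.add(
                Flag(FlagType.HIGH_ICC, var, d, details={"estimate": est})
            )
        if last is not None:
            delta = est.rho - last.rho
            if delta > config.icc_jump_threshold:
                ci_overlap = (
                    last.ci_low is not None
                    and est.ci_low is not None
                    and est.ci_low <= last.ci_high
                    and last.ci_low <= est.ci_high
                )
                report.add(
                    Flag(
                        FlagType.ICC_JUMP,
                        var,
                        d,
                        details={
                            "previous_rho": last.rho,
                            "rho": est.rho,
                            "delta": delta,
                            "ci_overlap": bool(ci_overlap),
                        },
                    )
                )
        summaries = center_boxplot_stats(snapshot, var)
        if len(summaries) >= 3:
            try:
                findings = detect_shifted_centers(
                    summaries,
                    min_offset=config.min_offset.get(var),
                    robust_z=config.robust_z,
                )
            except InsufficientClustersError:
                findings = []
            for f in findings:
                report.add(
                    Flag(
                        FlagType.SHIFTED_CENTER,
                        var,
                        d,
                        details={
                            "center_id": f.center_id,
                            "estimated_offset": f.estimated_offset,
                            "robust_z": f.robust_z,
                        },
                    )
                )
        if var in ranges:
            var_new = (
                new_rows[new_rows["variable"] == var]
                if "variable" in new_rows.columns
                else new_rows
            )
            scan = implausible_value_scan(var_new, [ranges[var]])
            for fl in scan:
                report.add(dataclasses.replace(fl, download_index=d))
    return history, report


def run_monitoring(
    snapshots: Sequence[pd.DataFrame],
    config: MonitoringConfig,
    corrections: Mapping[int, Sequence[CorrectionRule]] | None = None,
) -> tuple[MonitoringHistory, FlagReport, pd.DataFrame]:
    """Run the engine over an ordered sequence of cumulative snapshots.

    ``corrections`` maps a download index to the rules *discovered after*
    that download: when processing a later snapshot, every rule discovered
    at a strictly earlier download is applied first (each snapshot is a
    fresh extract, so the full set of known rules is re-applied each time).
    """
    corrections = corrections or {}
    history = MonitoringHistory()
    flags = FlagReport()
    for snapshot in snapshots:
        d = (
            int(snapshot["download_index"].max())
            if "download_index" in snapshot.columns and len(snapshot)
            else 0
        )
        current = snapshot
        for disc in sorted(corrections):
            if disc >= d:
                continue
            for rule in corrections[disc]:
                current, _ = apply_correction(current, rule)
        history, report = monitor_download(current, history, config)
        flags.extend(report.entries)
    return history, flags, render_report(history, flags)


def render_report(
    history: MonitoringHistory, flags: FlagReport
) -> pd.DataFrame:
    """One row per (variable, download): rho, CI, n, k, triggered flags.

    Downloads at which a variable had no data appear as gap rows with
    missing statistics.  Numbers are full precision; rounding belongs to the
    human rendering (:func:`format_report`).
    """
    flag_cells: dict[tuple[str, int], list[str]] = {}
    for f in flags:
        flag_cells.setdefault((f.variable, f.download_index), []).append(
            f.flag_type.value
        )
    rows = []
    for var in history.variables:
        have = {e.download_index: e for e in history.estimates(var)}
        gap_ds = set(history.gaps(var))
        for d in sorted(set(have) | gap_ds):
            est = have.get(d)
            cell = flag_cells.get((var, d), [])
            uniq = sorted(set(cell))
            flag_str = ";".join(
                f"{t}x{cell.count(t)}" if cell.count(t) > 1 else t
                for t in uniq
            )
            rows.append(
                {
                    "variable": var,
                    "download_index": d,
                    "rho": est.rho if est else None,
                    "ci_low": est.ci_low if est else None,
                    "ci_high": est.ci_high if est else None,
                    "se": est.se if est else None,
                    "n": est.N if est else None,
                    "k": est.k if est else None,
                    "flags": flag_str,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variable", "download_index", "rho", "ci_low", "ci_high",
            "se", "n", "k", "flags",
        ],
    )


def format_report(report: pd.DataFrame, decimals: int = 3) -> str:
    """Human-readable rendering; rounding happens only here."""
    shown = report.copy()
    for col in ("rho", "ci_low", "ci_high", "se"):
        shown[col] = shown[col].map(
            lambda v: "" if pd.isna(v) else f"{v:.{decimals}f}"
        )
    for col in ("n", "k"):
        shown[col] = shown[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    return shown.to_string(index=False)


def _estimate_dict(est: ICCEstimate) -> dict:
    return dataclasses.asdict(est)


def write_report(
    report: pd.DataFrame,
    history: MonitoringHistory,
    flags: FlagReport,
    out_dir,
) -> dict[str, pathlib.Path]:
    """Write the TSV report, flag table, and a structured JSON document.

    Machine-readable outputs carry full precision; serialization is
    deterministic (sorted keys, stable row order) so identical runs produce
    identical bytes.
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out_dir / "report.tsv",
        "flags": out_dir / "flags.tsv",
        "json": out_dir / "report.json",
    }
    report.to_csv(paths["report"], sep="\t", index=False)
    flags.to_frame().to_csv(paths["flags"], sep="\t", index=False)
    doc = {
        "history": {
            var: [_estimate_dict(e) for e in history.estimates(var)]
            for var in history.variables
        },
        "gaps": {var: history.gaps(var) for var in history.variables},
        "flags": [
            {
                "flag_type": f.flag_type.value,
                "variable": f.variable,
                "download_index": f.download_index,
                "details": {
                    k: (_estimate_dict(v) if isinstance(v, ICCEstimate) else v)
                    for k, v in f.details.items()
                },
            }
            for f in flags
        ],
    }
    paths["json"].write_text(json.dumps(doc, sort_keys=True, indent=2))
    return paths
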