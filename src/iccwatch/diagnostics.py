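"""Per-center diagnostics: box-plot summaries, shifted-center detection,
offset corrections, and implausible-value scanning.

This is the numerical form of the visual workflow used to chase equipment
errors in multicenter anthropometry: draw side-by-side box plots by center,
spot the center whose whole distribution sits a constant above or below the
others (wrong ruler, wrong stool), confirm the cause with the field staff,
then apply a documented additive correction and recompute the ICC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientClustersError,
    NoMatchingRowsError,
    RuleAlreadyAppliedError,
    ValidationError,
    VariableNotFoundError,
)
from .flags import Flag, FlagType

__all__ = [
    "CenterSummary",
    "CorrectionRule",
    "PlausibleRange",
    "ShiftFinding",
    "center_boxplot_stats",
    "detect_shifted_centers",
    "apply_correction",
    "revert_correction",
    "implausible_value_scan",
    "plot_center_boxplots",
]

logger = logging.getLogger(__name__)

#: Consistency factor turning a median absolute deviation into a normal SD.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class CenterSummary:
    """Tukey box-plot statistics for one center.

    Quartiles use linear-interpolation quantiles (numpy's default), whiskers
    extend to the most extreme data points within 1.5 IQR of the quartiles,
    and everything outside the whisker fences is listed in
    ``outlier_values``.
    """

    center_id: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outlier_values: tuple[float, ...] = ()


@dataclass(frozen=True)
class CorrectionRule:
    """A documented additive correction to one center's values.

    ``offset`` is added to the value of every matching row.  The optional
    ``download_min``/``download_max`` window and ``subject_ids`` restriction
    let a rule target late-entered stale records (measurements taken before a
    technique was fixed but keyed into the database afterwards) without
    touching clean rows.
    """

    center_id: str
    variable: str
    offset: float
    download_min: int | None = None
    download_max: int | None = None
    subject_ids: tuple[str, ...] | None = None
    reason: str = ""

    def __post_init__(self):
        if not np.isfinite(self.offset) or self.offset == 0:
            raise ValidationError("correction offset must be finite and nonzero")

    @property
    def key(self) -> str:
        """Stable identity used to refuse double application."""
        subj = "" if self.subject_ids is None else ",".join(self.subject_ids)
        return (
            f"{self.center_id}|{self.variable}|{self.offset!r}"
            f"|{self.download_min}|{self.download_max}|{subj}"
        )

    def inverse(self) -> "CorrectionRule":
        return CorrectionRule(
            center_id=self.center_id,
            variable=self.variable,
            offset=-self.offset,
            download_min=self.download_min,
            download_max=self.download_max,
            subject_ids=self.subject_ids,
            reason=f"inverse of: {self.reason}" if self.reason else "inverse",
        )


@dataclass(frozen=True)
class PlausibleRange:
    """Closed plausibility interval for one variable, in measurement units."""

    variable: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValidationError("plausible range requires low < high")


@dataclass(frozen=True)
class ShiftFinding:
    """A center whose distribution sits a constant off the others."""

    center_id: str
    estimated_offset: float
    robust_z: float


def center_boxplot_stats(
    table: pd.DataFrame, variable: str
) -> list[CenterSummary]:
    """Five-number box-plot summaries per center, ordered by center_id.

    Centers with no non-missing rows for the variable are omitted (a center
    that has not yet entered records simply has no box).
    """
    if "variable" in table.columns:
        sub = table[table["variable"] == variable]
    else:
        sub = table
    if len(sub) == 0:
        raise VariableNotFoundError(f"variable not found: {variable}")
    sub = sub[sub["value"].notna()]
    out: list[CenterSummary] = []
    for center_id, grp in sub.groupby("center_id", sort=True):
        v = grp["value"].to_numpy(dtype=float)
        if v.size == 0:
            continue
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
        out.append(
            CenterSummary(
                center_id=str(center_id),
                n=int(v.size),
                mean=float(v.mean()),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                iqr=float(iqr),
                whisker_low=float(inside.min()),
                whisker_high=float(inside.max()),
                outlier_values=tuple(float(x) for x in outliers),
            )
        )
    return out


def detect_shifted_centers(
    summaries: list[CenterSummary],
    min_offset: float | None = None,
    robust_z: float = 3.0,
) -> list[ShiftFinding]:
    """Detect centers offset by a roughly constant amount from the rest.

    Each center's offset is estimated as its median minus the median of all
    centers' medians; the overall median is robust to fewer than half the
    centers being shifted, so a grossly wrong center (or two) cannot mask
    itself.  A center is flagged when |offset| >= ``min_offset`` (if given)
    or when the offset exceeds ``robust_z`` scaled MADs of the medians.

    Medians and MADs — not means and SDs — so the shifted centers themselves
    do not inflate the spread they are judged against.
    """
    if len(summaries) < 3:
        raise InsufficientClustersError("insufficient centers for shift detection")
    medians = np.array([s.median for s in summaries], dtype=float)
    ref = float(np.median(medians))
    mad = float(np.median(np.abs(medians - ref))) * MAD_SCALE
    findings: list[ShiftFinding] = []
    for s, med in zip(summaries, medians):
        offset = float(med - ref)
        if mad > 0:
            z = abs(offset) / mad
        else:
            z = np.inf if offset != 0 else 0.0
        hit = (min_offset is not None and abs(offset) >= min_offset) or z >= robust_z
        if hit:
            findings.append(
                ShiftFinding(center_id=s.center_id, estimated_offset=offset,
                             robust_z=float(z))
            )
    return findings


def _applied_set(table: pd.DataFrame) -> frozenset:
    return frozenset(table.attrs.get("applied_corrections", ()))


def _rule_mask(table: pd.DataFrame, rule: CorrectionRule) -> pd.Series:
    mask = (table["center_id"] == rule.center_id) & table["value"].notna()
    if "variable" in table.columns:
        mask &= table["variable"] == rule.variable
    if rule.download_min is not None:
        mask &= table["download_index"] >= rule.download_min
    if rule.download_max is not None:
        mask &= table["download_index"] <= rule.download_max
    if rule.subject_ids is not None:
        mask &= table["subject_id"].isin(rule.subject_ids)
    return mask


def apply_correction(
    table: pd.DataFrame, rule: CorrectionRule
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply one correction rule; return (corrected table, change log).

    The change log has one row per modified value with the old and new
    values.  The rule's identity is recorded on the returned table so that
    re-applying the same rule raises instead of double-shifting.
    """
    applied = _applied_set(table)
    if rule.key in applied:
        raise RuleAlreadyAppliedError("rule already applied")
    mask = _rule_mask(table, rule)
    if not bool(mask.any()):
        raise NoMatchingRowsError("no matching rows")
    corrected = table.copy()
    corrected.loc[mask, "value"] = corrected.loc[mask, "value"] + rule.offset
    log = table.loc[mask, [c for c in
                           ("subject_id", "center_id", "variable",
                            "download_index") if c in table.columns]].copy()
    log["old_value"] = table.loc[mask, "value"]
    log["new_value"] = corrected.loc[mask, "value"]
    log["offset"] = rule.offset
    log["reason"] = rule.reason
    log = log.reset_index(drop=True)
    corrected.attrs = dict(table.attrs)
    corrected.attrs["applied_corrections"] = applied | {rule.key}
    return corrected, log


def revert_correction(
    table: pd.DataFrame, log: pd.DataFrame
) -> pd.DataFrame:
    """Restore the logged old values bit-exactly (the change log is the undo)."""
    restored = table.copy()
    key_cols = [c for c in ("subject_id", "variable") if c in log.columns]
    idx = restored.set_index(key_cols).index
    log_idx = log.set_index(key_cols).index
    positions = idx.get_indexer(log_idx)
    if (positions < 0).any():
        raise NoMatchingRowsError("no matching rows")
    col = restored.columns.get_loc("value")
    restored.iloc[positions, col] = log["old_value"].to_numpy()
    restored.attrs = dict(table.attrs)
    return restored


def implausible_value_scan(
    table: pd.DataFrame, ranges: list[PlausibleRange]
) -> list[Flag]:
    """Flag every row whose value falls strictly outside its plausible range.

    Values exactly at a bound are plausible (closed interval).  Variables
    present in the table but without a configured range are skipped with a
    logged warning; missing values are never flagged.
    """
    by_var = {r.variable: r for r in ranges}
    flags: list[Flag] = []
    if len(table) == 0:
        return flags
    present = (
        table["variable"].unique() if "variable" in table.columns else []
    )
    for var in present:
        if var not in by_var:
            logger.warning("no plausible range configured for %r; skipped", var)
    sub = table[table["value"].notna()]
    for _, row in sub.iterrows():
        var = row.get("variable", "")
        rng = by_var.get(var)
        if rng is None:
            continue
        val = float(row["value"])
        if val < rng.low or val > rng.high:
            flags.append(
                Flag(
                    flag_type=FlagType.IMPLAUSIBLE_VALUE,
                    variable=str(var),
                    download_index=int(row.get("download_index", 0)),
                    details={
                        "subject_id": str(row.get("subject_id", "")),
                        "center_id": str(row.get("center_id", "")),
                        "value": val,
                        "low": rng.low,
                        "high": rng.high,
                    },
                )
            )
    return flags


def plot_center_boxplots(summaries: list[CenterSummary], ax=None, **kwargs):
    """Convenience rendering of precomputed box-plot statistics (matplotlib).

    Not part of the tested numerical contract; requires the ``plots`` extra.
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots()
    stats = [
        {
            "label": s.center_id,
            "med": s.median,
            "q1": s.q1,
            "q3": s.q3,
            "whislo": s.whisker_low,
            "whishi": s.whisker_high,
            "fliers": list(s.outlier_values),
            "mean": s.mean,
        }
        for s in summaries
    ]
    ax.bxp(stats, **kwargs)
    return ax
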