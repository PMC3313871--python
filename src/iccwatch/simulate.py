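"""Synthetic multicenter measurement data with known variance components.

The generator draws from the same random-intercept model the estimator
assumes::

    y_ij = mu + arm_effect * 1[arm_i = intervention] + b_i + delta_i + e_ij

with ``b_i ~ N(0, sigma_b^2)``, ``e_ij ~ N(0, sigma_w^2)`` and ``delta_i`` a
constant per-center equipment offset (a wrong ruler adds the same 50 cm to
every record it produces).  Offset-free and effect-free, the true ICC is
sigma_b^2 / (sigma_b^2 + sigma_w^2).

Records are assigned to sequential downloads by per-center entry fractions,
so late-entering centers (zero early fractions) and stale records (measured
under an old faulty technique, entered later) can be scripted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import CorrectionRule
from .exceptions import ValidationError
from .monitoring import MonitoringConfig

__all__ = [
    "SimulationConfig",
    "simulate_multicenter",
    "center_labels",
    "snapshot",
    "ReplayScenario",
    "probit_replay_scenario",
]


def center_labels(k: int) -> list[str]:
    """Spreadsheet-style center labels A, B, ..., Z, AA, AB, ..."""
    labels = []
    for i in range(k):
        name = ""
        j = i
        while True:
            name = chr(ord("A") + j % 26) + name
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(name)
    return labels


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated variable.

    ``center_sizes`` is a common per-center size or one size per center;
    ``downloads`` are the entry fractions per sequential download (must sum
    to 1), optionally overridden per center via ``center_schedules`` (a
    center entering late simply has zero early fractions).
    """

    k: int = 31
    center_sizes: int | Sequence[int] = 300
    mu: float = 70.0
    sigma_b: float = 0.5
    sigma_w: float = 4.0
    variable: str = "sitting_height"
    offsets: Mapping[str, float] = field(default_factory=dict)
    arm_assignment: Mapping[str, str] | None = None
    arm_effect: float = 0.0
    downloads: Sequence[float] = (1.0,)
    center_schedules: Mapping[str, Sequence[float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.sigma_b < 0 or self.sigma_w < 0 or (
            self.sigma_b == 0 and self.sigma_w == 0
        ):
            raise ValidationError("sigma_b, sigma_w >= 0 and not both zero")
        self._check_schedule(self.downloads)
        if self.center_schedules:
            for sched in self.center_schedules.values():
                self._check_schedule(sched, len(self.downloads))

    @staticmethod
    def _check_schedule(fractions, expected_len: int | None = None):
        fr = np.asarray(fractions, dtype=float)
        if (
            fr.ndim != 1
            or len(fr) == 0
            or (fr < 0).any()
            or abs(fr.sum() - 1.0) > 1e-9
            or (expected_len is not None and len(fr) != expected_len)
        ):
            raise ValidationError("download schedule invalid")

    def sizes(self) -> np.ndarray:
        if np.isscalar(self.center_sizes):
            return np.full(self.k, int(self.center_sizes))
        sizes = np.asarray(self.center_sizes, dtype=int)
        if sizes.size != self.k:
            raise ValidationError("center_sizes must have length k")
        return sizes

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["center_sizes"] = (
            int(self.center_sizes)
            if np.isscalar(self.center_sizes)
            else [int(v) for v in self.center_sizes]
        )
        d["downloads"] = [float(f) for f in self.downloads]
        d["offsets"] = dict(self.offsets)
        d["arm_assignment"] = (
            dict(self.arm_assignment) if self.arm_assignment else None
        )
        d["center_schedules"] = (
            {c: [float(f) for f in s] for c, s in self.center_schedules.items()}
            if self.center_schedules
            else None
        )
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = {k: v for k, v in dict(d).items() if v is not None}
        return cls(**d)


def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of n across downloads, preserving the total."""
    quota = n * fractions
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_multicenter(config: SimulationConfig) -> pd.DataFrame:
    """Generate one variable's long-format measurement table.

    Reproducible given ``config.seed``: the same config yields a
    bit-identical table.
    """
    rng = np.random.default_rng(config.seed)
    labels = center_labels(config.k)
    sizes = config.sizes()
    n_downloads = len(config.downloads)
    global_sched = np.asarray(config.downloads, dtype=float)
    b = rng.normal(0.0, config.sigma_b, size=config.k)
    frames = []
    for i, (label, n_i) in enumerate(zip(labels, sizes)):
        e = rng.normal(0.0, config.sigma_w, size=n_i)
        arm = (
            config.arm_assignment.get(label) if config.arm_assignment else None
        )
        effect = config.arm_effect if arm == "intervention" else 0.0
        offset = float(config.offsets.get(label, 0.0))
        values = config.mu + effect + b[i] + offset + e
        sched = global_sched
        if config.center_schedules and label in config.center_schedules:
            sched = np.asarray(config.center_schedules[label], dtype=float)
        counts = _largest_remainder(int(n_i), sched)
        download = np.repeat(np.arange(1, n_downloads + 1), counts)
        width = max(4, len(str(max(int(n_i) - 1, 0))))
        subjects = [f"{label}-{j:0{width}d}" for j in range(int(n_i))]
        frame = pd.DataFrame(
            {
                "subject_id": subjects,
                "center_id": label,
                "variable": config.variable,
                "value": values,
                "download_index": download,
            }
        )
        if arm is not None:
            frame["arm"] = arm
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def snapshot(table: pd.DataFrame, download_index: int) -> pd.DataFrame:
    """Cumulative snapshot: all rows entered at or before a download."""
    out = table[table["download_index"] <= download_index].reset_index(drop=True)
    out = out.copy()
    out.attrs = dict(table.attrs)
    return out


@dataclass
class ReplayScenario:
    """A scripted four-download QA exercise with known injected errors.

    ``snapshots`` are the raw cumulative extracts; ``corrections`` maps a
    download index to the rules *discovered after* reviewing it, ready to
    feed to :func:`iccwatch.monitoring.run_monitoring`.
    """

    snapshots: list[pd.DataFrame]
    corrections: dict[int, list[CorrectionRule]]
    config: MonitoringConfig
    flagged_variable: str
    control_variable: str
    seed: int


def probit_replay_scenario(seed: int = 20080901) -> ReplayScenario:
    """A canned multicenter scenario with a wrong-ruler and wrong-stool error.

    31 centers entering the study across four downloads (15, then 27, then
    all 31).  Sitting height is contaminated: centers B and AB measure with
    the wrong ruler (+50 cm) until the first download review; stale
    wrong-ruler records from B and N are entered late at download 2; and AB
    additionally uses a 10 cm-short stool for its download-2 records
    (−10 cm).  Weight is a clean control variable.  Running the monitoring
    engine with the bundled corrections produces a HIGH_ICC flag at download
    1 and a strictly decreasing sitting-height ICC across downloads 1→3.
    """
    k = 31
    labels = center_labels(k)
    early = [
        "A", "B", "C", "D", "E", "F", "G", "H", "I", "J", "K", "L", "M",
        "O", "AB",
    ]
    late_d3 = ["AA", "AC", "AD", "AE"]
    schedules: dict[str, list[float]] = {}
    for lab in labels:
        if lab in early:
            schedules[lab] = [0.3, 0.3, 0.2, 0.2]
        elif lab in late_d3:
            schedules[lab] = [0.0, 0.0, 0.5, 0.5]
        else:
            schedules[lab] = [0.0, 0.4, 0.3, 0.3]
    common = dict(
        k=k,
        center_sizes=400,
        downloads=(0.25, 0.25, 0.25, 0.25),
        center_schedules=schedules,
    )
    sitting = simulate_multicenter(
        SimulationConfig(
            mu=70.0, sigma_b=0.5, sigma_w=4.0, variable="sitting_height",
            seed=seed, **common,
        )
    )
    weight = simulate_multicenter(
        SimulationConfig(
            mu=38.0, sigma_b=0.7, sigma_w=6.0, variable="weight",
            seed=seed + 1, **common,
        )
    )

    sh = sitting
    ruler = 50.0
    stool = -10.0
    # wrong ruler at B and AB for everything measured before the d1 review
    for center in ("B", "AB"):
        mask = (sh["center_id"] == center) & (sh["download_index"] == 1)
        sh.loc[mask, "value"] += ruler
    # stale wrong-ruler records keyed in late at download 2 (B and N)
    stale: dict[str, tuple[str, ...]] = {}
    for center, n_stale in (("B", 36), ("N", 50)):
        batch = sh[(sh["center_id"] == center) & (sh["download_index"] == 2)]
        ids = tuple(sorted(batch["subject_id"]))[:n_stale]
        sh.loc[sh["subject_id"].isin(ids), "value"] += ruler
        stale[center] = ids
    # AB swaps in a 10 cm-short stool for its download-2 measurements
    mask = (sh["center_id"] == "AB") & (sh["download_index"] == 2)
    sh.loc[mask, "value"] += stool

    table = pd.concat([sh, weight], ignore_index=True)
    snapshots = [snapshot(table, d) for d in (1, 2, 3, 4)]

    corrections = {
        1: [
            CorrectionRule(
                center_id="B", variable="sitting_height", offset=-ruler,
                download_max=1, reason="wrong sitting-height ruler (+50 cm)",
            ),
            CorrectionRule(
                center_id="AB", variable="sitting_height", offset=-ruler,
                download_max=1, reason="wrong sitting-height ruler (+50 cm)",
            ),
        ],
        2: [
            CorrectionRule(
                center_id="B", variable="sitting_height", offset=-ruler,
                download_min=2, download_max=2, subject_ids=stale["B"],
                reason="stale wrong-ruler records entered late",
            ),
            CorrectionRule(
                center_id="N", variable="sitting_height", offset=-ruler,
                download_min=2, download_max=2, subject_ids=stale["N"],
                reason="stale wrong-ruler records entered late",
            ),
            CorrectionRule(
                center_id="AB", variable="sitting_height", offset=-stool,
                download_min=2, download_max=2,
                reason="40 cm stool instead of the 50 cm study stool",
            ),
        ],
    }
    config = MonitoringConfig(
        variables=("sitting_height", "weight"),
        plausible_ranges={
            "sitting_height": (40.0, 110.0),
            "weight": (10.0, 90.0),
        },
        min_offset={"sitting_height": 20.0, "weight": 20.0},
        # with 31 centers and real between-center variance, a 3-MAD rule
        # false-positives too often for a clean demonstration
        robust_z=6.0,
    )
    return ReplayScenario(
        snapshots=snapshots,
        corrections=corrections,
        config=config,
        flagged_variable="sitting_height",
        control_variable="weight",
        seed=seed,
    )
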