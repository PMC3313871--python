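"""One-way random-effects ANOVA and intraclass correlation estimation.

The model is the random-intercept decomposition of a continuous measurement
``y_ij`` on subject *j* at center *i*::

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_b^2),   e_ij ~ N(0, sigma_w^2)

The intraclass correlation coefficient (ICC)

    rho = sigma_b^2 / (sigma_b^2 + sigma_w^2)

is the fraction of total variance attributable to systematic differences
between centers: 0 means measurements are exchangeable across centers, 1 means
all variation is between centers.  In a multicenter study an unexpectedly high
ICC on a physical measurement is a data-quality signal — e.g. one center using
the wrong instrument shifts every one of its values by a constant and inflates
the between-center variance.

Estimation is the classical method-of-moments ANOVA estimator for unbalanced
designs.  With ``k`` centers of sizes ``n_i`` (``N = sum n_i``)::

    MSB = sum_i n_i (ybar_i - ybar)^2 / (k - 1)
    MSW = sum_ij (y_ij - ybar_i)^2 / (N - k)
    n0  = (N - sum_i n_i^2 / N) / (k - 1)       # effective cluster size
    sigma_w^2 = MSW,   sigma_b^2 = (MSB - MSW) / n0
    rho_hat = (MSB - MSW) / (MSB + (n0 - 1) MSW)

Large-sample standard errors use a Smith-type delta-method variance for the
unbalanced estimator (see :func:`smith_variance`); a parametric bootstrap is
available as an alternative and serves as an independent cross-check in the
test suite.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateVarianceError,
    InsufficientClustersError,
    NoDataError,
    ValidationError,
    VariableNotFoundError,
    WithinVarianceUndefinedError,
)

__all__ = [
    "VarianceComponents",
    "ICCEstimate",
    "anova_components",
    "icc_from_components",
    "icc_estimate",
    "icc_confidence_interval",
    "icc_with_ci",
    "smith_variance",
    "balanced_icc_variance",
    "parametric_bootstrap_se",
]

#: Relative tolerance below which a mean square is treated as exactly zero,
#: scaled by the grand mean square of the data (units^2).
ZERO_VARIANCE_RTOL = 1e-12


@dataclass(frozen=True)
class VarianceComponents:
    """ANOVA mean squares and method-of-moments variance components.

    All variance-like fields are in squared measurement units.  ``sigma_b2``
    is the raw moment estimate and may be negative; truncation is the ICC
    estimator's concern, not this container's.
    """

    msb: float
    msw: float
    sigma_b2: float
    sigma_w2: float
    n0: float
    k: int
    N: int
    per_center_n: Mapping[str, int]


@dataclass(frozen=True)
class ICCEstimate:
    """Point and interval estimate of the ICC for one variable/snapshot.

    ``rho`` is the reported estimate (truncated to [0, 1] under the default
    policy); ``rho_raw`` preserves the untruncated moment estimator for
    diagnostics.  ``se``/``ci_low``/``ci_high`` are ``None`` until a
    confidence interval has been attached.
    """

    variable: str
    download_index: int
    rho: float
    rho_raw: float
    k: int
    N: int
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    alpha: float | None = None


def _prepare(table: pd.DataFrame, variable: str | None):
    """Extract (values, center codes, labels) for one variable's rows."""
    df = table
    if "variable" in df.columns:
        if variable is not None:
            df = df[df["variable"] == variable]
            if len(df) == 0:
                raise VariableNotFoundError(f"variable not found: {variable}")
        else:
            uniq = df["variable"].unique()
            if len(uniq) > 1:
                raise ValidationError(
                    "table holds multiple variables; pass `variable=`"
                )
            variable = str(uniq[0]) if len(uniq) else ""
    mask = df["value"].notna() & df["center_id"].notna()
    df = df[mask]
    if len(df) == 0:
        raise NoDataError("no data")
    values = df["value"].to_numpy(dtype=float)
    codes, labels = pd.factorize(df["center_id"], sort=True)
    download = 0
    if "download_index" in df.columns and len(df):
        download = int(df["download_index"].max())
    return values, codes, [str(c) for c in labels], variable or "", download


def _anova_kernel(values: np.ndarray, codes: np.ndarray):
    """Mean squares and design constants from raw arrays.

    ``codes`` must be 0..k-1 with every code present.  Returns
    (msb, msw, n0, counts, grand_mean_square).
    """
    N = values.size
    counts = np.bincount(codes).astype(float)
    k = counts.size
    if k < 2:
        raise InsufficientClustersError("insufficient clusters")
    if N == k:
        raise WithinVarianceUndefinedError("within variance undefined")
    sums = np.bincount(codes, weights=values)
    means = sums / counts
    grand = values.sum() / N
    msb = float(np.sum(counts * (means - grand) ** 2)) / (k - 1)
    msw = float(np.sum((values - means[codes]) ** 2)) / (N - k)
    n0 = (N - float(np.sum(counts**2)) / N) / (k - 1)
    gms = float(np.mean(values**2))
    return msb, msw, n0, counts, gms


def anova_components(
    table: pd.DataFrame, variable: str | None = None
) -> VarianceComponents:
    """One-way random-effects ANOVA decomposition of one variable.

    The table must be restricted to (or ``variable`` must select) a single
    measurement.  Rows with missing values are dropped.  Singleton centers
    contribute to MSB and to N but add no within-center degrees of freedom.

    Deterministic, and invariant to row order and center relabeling.
    """
    values, codes, labels, _, _ = _prepare(table, variable)
    msb, msw, n0, counts, _ = _anova_kernel(values, codes)
    k = counts.size
    return VarianceComponents(
        msb=msb,
        msw=msw,
        sigma_b2=(msb - msw) / n0,
        sigma_w2=msw,
        n0=n0,
        k=k,
        N=values.size,
        per_center_n={lab: int(c) for lab, c in zip(labels, counts)},
    )


def icc_from_components(sigma_b2: float, sigma_w2: float) -> float:
    """ICC from known (non-negative) variance components.

    rho = sigma_b2 / (sigma_b2 + sigma_w2).  Scale-invariant; equals 1 when
    all variation is between centers and 0 when all is within.
    """
    if sigma_b2 < 0 or sigma_w2 < 0:
        raise ValidationError("variance components must be non-negative")
    total = sigma_b2 + sigma_w2
    if total == 0:
        raise DegenerateVarianceError("degenerate: no variance")
    return sigma_b2 / total


def icc_estimate(
    table: pd.DataFrame,
    variable: str | None = None,
    truncate: bool = True,
) -> ICCEstimate:
    """ANOVA (method-of-moments) ICC point estimate for one variable.

    ``rho_raw`` is (MSB − MSW) / (MSB + (n0 − 1) MSW); under the default
    truncation policy ``rho = max(rho_raw, 0)`` so the reported estimate
    respects the [0, 1] parameter space while the raw value stays available
    for diagnostics.
    """
    values, codes, _, varname, download = _prepare(table, variable)
    msb, msw, n0, counts, gms = _anova_kernel(values, codes)
    denom = msb + (n0 - 1.0) * msw
    if denom <= ZERO_VARIANCE_RTOL * max(gms, 1.0):
        raise DegenerateVarianceError("degenerate: no variance")
    rho_raw = (msb - msw) / denom
    rho = min(max(rho_raw, 0.0), 1.0) if truncate else rho_raw
    return ICCEstimate(
        variable=varname,
        download_index=download,
        rho=rho,
        rho_raw=rho_raw,
        k=counts.size,
        N=values.size,
    )


def balanced_icc_variance(rho: float, n: float, k: int) -> float:
    """Fisher large-sample variance of the ANOVA ICC, balanced design.

    Var(rho_hat) ~= 2 (1 - rho)^2 [1 + (n - 1) rho]^2 / [n (n - 1) (k - 1)].
    """
    return (
        2.0
        * (1.0 - rho) ** 2
        * (1.0 + (n - 1.0) * rho) ** 2
        / (n * (n - 1.0) * (k - 1.0))
    )


def smith_variance(rho: float, components: VarianceComponents) -> float:
    """Delta-method large-sample variance of the ANOVA ICC, unbalanced design.

    Smith's expansion in the cluster sizes, normalised by N/(N−1) so that the
    balanced case reduces algebraically to :func:`balanced_icc_variance`
    (the two classical expressions differ by exactly that factor).
    """
    counts = np.array(list(components.per_center_n.values()), dtype=float)
    N = float(components.N)
    k = float(components.k)
    n0 = components.n0
    if N - k <= 0:
        raise WithinVarianceUndefinedError("within variance undefined")
    s2 = float(np.sum(counts**2))
    s3 = float(np.sum(counts**3))
    size_term = s2 - 2.0 * s3 / N + (s2 / N) ** 2
    v = (2.0 * (1.0 - rho) ** 2 / n0**2) * (
        (1.0 + (n0 - 1.0) * rho) ** 2 / (N - k)
        + ((k - 1.0) * (1.0 - rho) * (1.0 + (2.0 * n0 - 1.0) * rho)
           + rho**2 * size_term) / (k - 1.0) ** 2
    )
    v *= N / (N - 1.0)
    return max(v, 0.0)


def parametric_bootstrap_se(
    components: VarianceComponents,
    n_boot: int = 1000,
    random_state: int | np.random.Generator | None = None,
) -> float:
    """Bootstrap SE of the ICC under the fitted Gaussian random-effects model.

    Simulates ``n_boot`` datasets with the estimated components (sigma_b2
    truncated at 0) on the observed cluster-size design and returns the SD of
    the truncated ICC estimates.
    """
    rng = np.random.default_rng(random_state)
    counts = np.array(list(components.per_center_n.values()), dtype=int)
    k = counts.size
    sb = float(np.sqrt(max(components.sigma_b2, 0.0)))
    sw = float(np.sqrt(max(components.sigma_w2, 0.0)))
    codes = np.repeat(np.arange(k), counts)
    N = int(counts.sum())
    rhos = np.empty(n_boot)
    for r in range(n_boot):
        b = rng.normal(0.0, sb, size=k)
        y = b[codes] + rng.normal(0.0, sw, size=N)
        msb, msw, n0, _, _ = _anova_kernel(y, codes)
        denom = msb + (n0 - 1.0) * msw
        rhos[r] = 0.0 if denom <= 0 else max((msb - msw) / denom, 0.0)
    return float(np.std(rhos, ddof=1))


def icc_confidence_interval(
    estimate: ICCEstimate,
    components: VarianceComponents,
    alpha: float = 0.05,
    method: str = "smith",
    n_boot: int = 1000,
    random_state: int | np.random.Generator | None = None,
) -> ICCEstimate:
    """Attach a symmetric Wald interval, clipped to [0, 1], to an estimate.

    The interval is centred on the truncated estimate; with ``method="smith"``
    the SE is the Smith delta-method SE evaluated at that value, with
    ``method="bootstrap"`` it is a parametric-bootstrap SD.  With fewer than
    three clusters a warning is emitted — the large-sample variance is then
    little more than a guess.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if components.k < 3:
        warnings.warn("interval unstable with <3 clusters", stacklevel=2)
    rho = min(max(estimate.rho, 0.0), 1.0)
    if method == "smith":
        se = float(np.sqrt(smith_variance(rho, components)))
    elif method == "bootstrap":
        se = parametric_bootstrap_se(components, n_boot, random_state)
    else:
        raise ValidationError(f"unknown CI method: {method!r}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo = min(max(rho - z * se, 0.0), 1.0)
    hi = min(max(rho + z * se, 0.0), 1.0)
    return dataclasses.replace(
        estimate, se=se, ci_low=lo, ci_high=hi, alpha=alpha
    )


def icc_with_ci(
    table: pd.DataFrame,
    variable: str | None = None,
    alpha: float = 0.05,
    truncate: bool = True,
    method: str = "smith",
    n_boot: int = 1000,
    random_state: int | np.random.Generator | None = None,
) -> ICCEstimate:
    """One-shot ICC point estimate plus confidence interval."""
    est = icc_estimate(table, variable=variable, truncate=truncate)
    comps = anova_components(table, variable=variable)
    return icc_confidence_interval(
        est, comps, alpha=alpha, method=method, n_boot=n_boot,
        random_state=random_state,
    )
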