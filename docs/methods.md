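# Methods

## The statistical model

Every operation in this package assumes the one-way random-effects
decomposition of a continuous measurement taken on subject *j* at center
*i*:

    y_ij = mu + b_i + e_ij,    b_i ~ N(0, sigma_b^2),   e_ij ~ N(0, sigma_w^2)

The intraclass correlation coefficient (ICC)

    rho = sigma_b^2 / (sigma_b^2 + sigma_w^2)

is the fraction of total variance attributable to systematic between-center
differences. Two boundary identities anchor its interpretation: if all
variation is between centers (sigma_w^2 = 0) the ICC is 1; if all variation
is within centers (sigma_b^2 = 0) the ICC is 0. In a quality-assurance
setting the ICC of a physical measurement in a reasonably homogeneous
population should be small; a constant equipment offset at even one center
(a wrong ruler adds the same 50 cm to every record it produces) inflates
sigma_b^2 and is visible as an ICC far above its expected range, long before
an analyst would think to look at that particular variable.

## Estimation

Point estimates are the classical method-of-moments (ANOVA) estimator for
unbalanced designs. With k centers of sizes n_i (N = sum n_i):

    MSB = sum_i n_i (ybar_i - ybar)^2 / (k - 1)
    MSW = sum_ij (y_ij - ybar_i)^2 / (N - k)
    n0  = (N - sum_i n_i^2 / N) / (k - 1)
    sigma_w^2 = MSW,  sigma_b^2 = (MSB - MSW) / n0
    rho_hat   = (MSB - MSW) / (MSB + (n0 - 1) MSW)

n0 is the effective cluster size; it equals the common size in a balanced
design and never exceeds the largest cluster. Singleton centers contribute
to MSB and N but add no within-center degrees of freedom. Missing values
are dropped per variable, never listwise.

**Truncation.** The moment estimator can be negative when MSB < MSW. The
reported `rho` is truncated at 0 by default — the parameter space is
[0, 1] and a monitoring report full of small negative ICCs would invite
over-interpretation — while `rho_raw` always preserves the untruncated
value for diagnostics. Degenerate data (total variance numerically zero,
i.e. below 1e-12 times the grand mean square) raise an error rather than
return 0/0.

## Standard errors and confidence intervals

The interval is a symmetric Wald interval, `rho_hat ± z_{1-alpha/2} * se`,
clipped to [0, 1]. The default SE is Smith's large-sample (delta-method)
variance for the unbalanced ANOVA estimator, evaluated at the truncated
point estimate:

    Var(rho_hat) = N/(N-1) * 2(1-rho)^2/n0^2 * [
        (1+(n0-1)rho)^2/(N-k)
        + ((k-1)(1-rho)(1+(2n0-1)rho) + rho^2 * S) / (k-1)^2 ]
    S = sum n_i^2 - 2 sum n_i^3 / N + (sum n_i^2)^2 / N^2

The leading N/(N−1) factor is an asymptotically null normalisation chosen
so that the balanced case reduces *algebraically* to the Fisher closed form
2(1−rho)²[1+(n−1)rho]² / [n(n−1)(k−1)]; without it the two classical
expressions differ by exactly (N−1)/N, which would leave the balanced-case
cross-check hostage to an arbitrary convention. The test suite verifies the
balanced reduction to floating-point precision and checks the SE against a
10,000-replicate parametric bootstrap (an independent simulation oracle) to
within Monte-Carlo and higher-order error.

A parametric bootstrap SE (`ci_method="bootstrap"`) is available as an
alternative: it simulates the fitted Gaussian model on the observed
cluster-size design and reports the SD of the truncated estimates.

Interval behaviour worth knowing: the estimator's sampling distribution is
right-skewed and the plug-in SE shrinks exactly when `rho_hat`
underestimates, so symmetric Wald intervals tend to be slightly
anti-conservative at a few dozen clusters; the suite checks the operating
coverage band at 31 clusters of 300. With fewer than three clusters the
interval is computed but a warning is emitted. When MSW = 0 the SE is
exactly 0 and the interval collapses to [1, 1]; when the estimate is
truncated at 0 the lower bound clips to 0.

## Per-center diagnostics

**Box-plot statistics** use linear-interpolation quantiles (numpy's
default) rather than Tukey hinges — the ubiquitous convention, documented
so rendered plots are reproducible. Whiskers extend to the most extreme
points within 1.5 IQR of the quartiles; everything outside is listed as an
outlier value.

**Shifted-center detection** estimates each center's offset as its median
minus the median of *all* centers' medians, and flags a center when the
absolute offset exceeds a per-variable `min_offset` (units are
variable-specific, so there is no defensible universal default) or exceeds
`robust_z` scaled MADs of the medians. Medians and MADs are used
throughout so that the faulty centers do not inflate the spread they are
judged against. The reference is the overall median rather than a
leave-one-out median: the overall median tolerates just under half the
centers being shifted, whereas a leave-self-out reference reaches 50%
contamination as soon as two of five centers share a gross error and then
flags the clean centers instead. A gross center still cannot mask itself
for k ≥ 3. Note the familywise behaviour of the z-rule: with ~30 centers
and genuine between-center variance, a 3-MAD threshold will advisorily
flag a clean center at roughly the rate tail probability dictates; the
bundled replay scenario raises it to 6 for a clean demonstration, and
gross-offset decisions should rest on `min_offset`.

**Corrections** are explicit, additive, and logged. A rule names the
center, variable, offset, and optionally a download-index window or a
subject list (stale records — measured under an old faulty technique but
keyed in late — are targeted this way). Applying a rule returns a new
table plus a change log of every modified value; re-applying the same rule
raises. The change log is the undo: `revert_correction` restores the old
values bit-exactly, which plain float subtraction cannot guarantee.

**Implausible-value scanning** flags values strictly outside a per-variable
closed plausibility interval; values exactly at a bound are plausible.

## The monitoring engine

ICCs are computed on *cumulative* snapshots, matching how study databases
grow; a snapshot with fewer rows per variable than its predecessor is a
hard error. Per variable and download: HIGH_ICC fires when `rho` exceeds
the flag threshold (default 0.05 — appropriate for a population without
strong regional differences; raise it where real geographic heterogeneity
is expected); ICC_JUMP fires on an absolute rise above the jump threshold
(default 0.05) between consecutive downloads, judged on point estimates
with CI overlap reported alongside; shifted-center detection runs on the
cumulative data; the implausible-value scan covers only the rows that
arrived at the current download (rescanning history would re-flag rows
already handled). Variables measured by automated instruments can be
listed as `reference_variables`: their ICC is reported but exempt from
HIGH_ICC. A variable with no data at a download is recorded as a gap, not
flagged. Flags never trigger corrections; the engine applies only the
correction rules it is explicitly given, re-applying all rules discovered
at earlier downloads to each fresh cumulative extract.

## Two-arm contrasts

The unadjusted contrast is a Welch two-sample t interval on subject values,
treating observations as independent — deliberately naive, since its
interval is too narrow by roughly the design effect 1 + (n̄−1)rho under
clustering. The adjusted contrast collapses each center to its mean and
runs the same Welch machinery on center means between arms (unweighted by
default; a size-weighted variant is available). Cluster-level means are
exactly valid under balanced clusters and a transparent, dependency-free
approximation to a mixed-model fit otherwise; REML mixed models, GEE and
small-sample df corrections are out of scope. When both arms' cluster
means are constant the interval degenerates to a point at the difference.

## The simulator

`simulate_multicenter` draws from exactly the model above plus an optional
constant per-center offset and an optional constant arm effect, and
assigns records to downloads by per-center entry fractions (largest-
remainder rounding, so center totals are preserved; a late-entering center
has zero early fractions). Gaussian components only: the anthropometric
measurements this emulates are well approximated by normal within-center
variation, and the equipment errors of interest are exactly constant
offsets, not slopes or inflations. What it does *not* emulate — heavy
tails, missing-not-at-random entry, observer nesting within center (a
single clustering level only), drift over calendar time — bounds what
passing tests show: calibration and detection results here demonstrate
correctness of the machinery under the stated model, not robustness to
every failure mode of real field data.

`probit_replay_scenario` scripts a four-download exercise on 31 centers
(15 entering at download 1, 12 more at download 2, 4 at download 3; 400
subjects per center): sitting height (mu 70 cm, sigma_b 0.5, sigma_w 4) is
contaminated with a +50 cm wrong-ruler error at centers B and AB, stale
wrong-ruler records entered late at B and N, and a −10 cm wrong-stool
error at AB's download-2 records; weight (mu 38 kg, sigma_b 0.7, sigma_w
6) is a clean control. The bundled correction rules mirror the narrative:
each is discovered after the download that reveals it. Monitoring the
scenario yields a HIGH_ICC flag at download 1 and a strictly decreasing
contaminated-variable ICC across downloads 1→3, ending near the clean
value sigma_b²/(sigma_b²+sigma_w²) ≈ 0.015.

## Problem sizes and numerical choices

The statistical test suites use 31 centers of 300 subjects (estimator
recovery across true ICC 0.01–0.92, and interval coverage at ICC 0.10,
200–1,000 replicates), 15 centers of 300 with two +50 offsets for the
detection workflow (100 replicates), and 30 centers of 50 split 15/15 for
the contrast-calibration study (1,000 replicates) — sizes chosen to mirror
a realistic multicenter follow-up while keeping a full run around a
minute. Recovery is asserted on the mean estimate (bias): at 31 clusters
the estimator's sampling SD near ICC 0.3 is ~0.055, so no implementation
could promise small *absolute* error per replicate. All randomness flows
through `numpy.random.default_rng` seeds; identical seeds give
bit-identical tables, reports, and serialized output.

Known limitations: no binary-outcome ICCs; no exact F-based intervals; no
REML/ML estimation; single clustering level; Wald intervals are
approximate at small k and near the parameter boundary.
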