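"""Concurrent-validity and reproducibility statistics.

Implements the agreement toolkit used to validate a continuous trunk
measurement against a scoliometer and to quantify intra-/interrater
reproducibility:

* two-way ANOVA intraclass correlation, absolute-agreement form
  (McGraw & Wong ICC(A,k), with the consistency form available),
  with F-based 95% confidence interval and significance test;
* SEM = SD * sqrt(1 - ICC) and MDC = z * SD * sqrt(2 (1 - ICC));
* Spearman rank correlation with clinical classification bands;
* RMSE and Bland-Altman limits of agreement;
* Walter-Eliasziw-Donner sample-size calculation for an ICC design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RatingTable",
    "AgreementEstimate",
    "SpearmanResult",
    "BlandAltmanResult",
    "ValidityReport",
    "SampleSizeSpec",
    "anova_mean_squares",
    "icc_absolute_agreement",
    "sem_from_icc",
    "mdc_from_icc",
    "spearman",
    "rmse",
    "bland_altman",
    "validity_report",
    "sample_size_icc",
    "classify_correlation",
    "classify_icc",
]

DEFAULT_Z = 1.96  # two-sided normal critical value for alpha = 0.05


@dataclass(frozen=True)
class RatingTable:
    """Complete subjects x measurements matrix (degrees), no missing values.

    Columns are repeated measurements of the same quantity: either k raters
    (interrater design) or k consecutive sessions of one rater (intrarater
    design).
    """

    values: np.ndarray
    subject_ids: tuple = ()
    columns: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("rating table must be 2-D (subjects x measurements)")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError("rating table needs >= 2 subjects and >= 2 measurements")
        if not np.all(np.isfinite(v)):
            raise ValueError("rating table entries must be finite")
        if not self.subject_ids:
            object.__setattr__(self, "subject_ids", tuple(f"S{i+1:03d}" for i in range(n)))
        if not self.columns:
            object.__setattr__(self, "columns", tuple(f"M{j+1}" for j in range(k)))
        if len(self.subject_ids) != n or len(self.columns) != k:
            raise ValueError("label lengths must match the matrix shape")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_measurements(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AgreementEstimate:
    """ICC-based reproducibility summary for one rating table."""

    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    sd: float
    sem: float
    mdc: float
    z: float
    label: str | None
    n: int
    k: int
    form: str
    degenerate: bool = False


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    label: str | None
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement of paired differences x - y."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    z: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class ValidityReport:
    """Concurrent-validity summary of a method against a reference."""

    rho: float
    rho_p: float
    rho_label: str | None
    rmse: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design parameters for an ICC reliability study sample-size calculation."""

    rho1: float
    rho0: float = 0.0
    k: int = 2
    power: float = 0.80
    alpha: float = 0.05
    two_sided: bool = False
    inflation: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho0 < self.rho1 < 1.0):
            raise ValueError("require 0 <= rho0 < rho1 < 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 <= self.inflation < 1.0):
            raise ValueError("inflation must be in [0, 1)")


def classify_icc(icc: float) -> str | None:
    """Reliability band: poor (<0.4), moderate (0.4-<0.75), excellent (>=0.75)."""
    if not np.isfinite(icc):
        return None
    if icc < 0.4:
        return "poor"
    if icc < 0.75:
        return "moderate"
    return "excellent"


def classify_correlation(rho: float) -> str | None:
    """Correlation band on |rho|: insignificant (<0.3), low (0.3-<0.5),
    moderate (0.5-<0.7), high (0.7-<0.9), very_high (>=0.9).

    The band edge 0.9 is assigned to very_high so that the bands tile
    [0, 1] without a gap.
    """
    if not np.isfinite(rho):
        return None
    a = abs(rho)
    if a < 0.3:
        return "insignificant"
    if a < 0.5:
        return "low"
    if a < 0.7:
        return "moderate"
    if a < 0.9:
        return "high"
    return "very_high"


def anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows, columns, residual) of an n x k table."""
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * float(np.sum((row_means - grand) ** 2)) / (n - 1)
    msc = n * float(np.sum((col_means - grand) ** 2)) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = float(np.sum(resid**2)) / ((n - 1) * (k - 1))
    return msr, msc, mse


def _sb_up(r1: float, k: int) -> float:
    """Spearman-Brown step-up from a single-measure to a k-average ICC."""
    if not np.isfinite(r1):
        return float("nan")
    denom = 1.0 + (k - 1) * r1
    return float("nan") if denom == 0 else k * r1 / denom


def _icc_a1_ci(msr: float, msc: float, mse: float, n: int, k: int, alpha: float) -> tuple[float, float]:
    """F-based CI for the single-measure absolute-agreement ICC(A,1)."""
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan"), float("nan")
    r = (msr - mse) / denom
    if r >= 1.0 or (mse == 0 and msc == 0):
        return 1.0, 1.0
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    if den_v == 0:
        return 1.0, 1.0
    v = num_v / den_v
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    if not (np.isfinite(f_l) and np.isfinite(f_u)):
        return float("nan"), float("nan")
    low_den = f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    hi_den = k * msc + (k * n - k - n) * mse + n * f_u * msr
    low = n * (msr - f_l * mse) / low_den if low_den != 0 else float("nan")
    high = n * (f_u * msr - mse) / hi_den if hi_den != 0 else float("nan")
    return low, high


def icc_absolute_agreement(
    table: RatingTable,
    average_measures: bool = True,
    consistency: bool = False,
    alpha: float = 0.05,
    z: float = DEFAULT_Z,
) -> AgreementEstimate:
    """Two-way ANOVA intraclass correlation with CI, test, SEM and MDC.

    The primary form is absolute agreement over the average of the k
    measurements, ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n); set
    ``consistency=True`` for the consistency form ICC(C,k) = 1 - MSE/MSR,
    or ``average_measures=False`` for the single-measure variants.  The
    confidence interval for the absolute-agreement forms follows the
    McGraw-Wong F approximation (single-measure bounds stepped up by
    Spearman-Brown for the average form); the p-value comes from the
    one-sided F test of MSR against MSE with (n-1, (n-1)(k-1)) degrees of
    freedom.  The SD entering SEM/MDC is the pooled sample SD of all
    observations across columns.

    A table with no between-subject signal and no residual error (or a
    non-positive ICC denominator) has no defined ICC; the estimate is NaN
    and flagged degenerate.
    """
    values = table.values
    n, k = values.shape
    msr, msc, mse = anova_mean_squares(values)
    sd = float(np.std(values, ddof=1))

    degenerate = False
    if consistency:
        if msr == 0:
            icc = float("nan")
            degenerate = True
        else:
            icc = 1.0 - mse / msr if average_measures else (msr - mse) / (msr + (k - 1) * mse)
        # CI from the exact F pivot for the consistency forms
        if degenerate or mse == 0:
            ci_low = ci_high = 1.0 if not degenerate else float("nan")
        else:
            fobs = msr / mse
            f_l = fobs / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            f_u = fobs * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            if average_measures:
                ci_low, ci_high = 1.0 - 1.0 / f_l, 1.0 - 1.0 / f_u
            else:
                ci_low = (f_l - 1) / (f_l + k - 1)
                ci_high = (f_u - 1) / (f_u + k - 1)
        form = "C,k" if average_measures else "C,1"
    else:
        denom_k = msr + (msc - mse) / n
        denom_1 = msr + (k - 1) * mse + k * (msc - mse) / n
        denom = denom_k if average_measures else denom_1
        # non-positive denominators (no usable agreement signal) leave the
        # estimator undefined; the threshold is relative so that exact
        # real-arithmetic boundaries are classified consistently
        if denom <= 1e-12 * max(abs(msr), abs(msc), abs(mse), 1e-300):
            icc = float("nan")
            degenerate = True
        else:
            icc = (msr - mse) / denom
        low1, high1 = _icc_a1_ci(msr, msc, mse, n, k, alpha)
        if average_measures:
            ci_low, ci_high = _sb_up(low1, k), _sb_up(high1, k)
        else:
            ci_low, ci_high = low1, high1
        form = "A,k" if average_measures else "A,1"

    if not degenerate:
        icc = float(np.clip(icc, -1.0, 1.0))

    if mse == 0:
        p_value = 0.0 if msr > 0 else float("nan")
    else:
        p_value = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))

    if degenerate:
        sem = mdc = float("nan")
    else:
        sem = sem_from_icc(icc, sd)
        mdc = mdc_from_icc(icc, sd, z)

    return AgreementEstimate(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p_value,
        sd=sd,
        sem=float(sem),
        mdc=float(mdc),
        z=z,
        label=classify_icc(icc),
        n=n,
        k=k,
        form=form,
        degenerate=degenerate,
    )


def sem_from_icc(icc: float, sd: float) -> float:
    """Standard error of measurement, SEM = SD * sqrt(1 - ICC)."""
    if icc > 1:
        raise ValueError("icc must be <= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return sd * math.sqrt(1.0 - icc)


def mdc_from_icc(icc: float, sd: float, z: float = DEFAULT_Z) -> float:
    """Minimal detectable change, MDC = z * SD * sqrt(2 (1 - ICC)).

    Satisfies MDC = z * sqrt(2) * SEM exactly.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    return z * math.sqrt(2.0) * sem_from_icc(icc, sd)


def spearman(
    x,
    y,
    method: str = "t",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> SpearmanResult:
    """Spearman rank correlation with a clinical classification band.

    Ranks use midranks on ties.  ``method="t"`` gives the large-sample
    t approximation with n - 2 degrees of freedom; ``method="permutation"``
    gives a seeded two-sided permutation p-value for small samples.
    Constant input leaves rho undefined (NaN, flagged degenerate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), None, len(x), degenerate=True)

    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if method == "t":
        p = float(res.pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(ry)
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError("method must be 't' or 'permutation'")
    return SpearmanResult(rho, p, classify_correlation(rho), len(x))


def rmse(x, y) -> float:
    """Root mean square error between paired sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be 1-D sequences of equal length >= 1")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def bland_altman(x, y, z: float = DEFAULT_Z) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of paired measurements.

    Differences are taken as d = x - y; the bias is mean(d) and the limits
    of agreement bias +/- z * SD(d) with the sample SD (n - 1).  The
    returned (mean, difference) pairs are plot-ready.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be 1-D sequences of equal length >= 2")
    d = x - y
    bias = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - z * sd_d,
        loa_high=bias + z * sd_d,
        sd_diff=sd_d,
        z=z,
        means=(x + y) / 2.0,
        diffs=d,
    )


def validity_report(x, y, z: float = DEFAULT_Z, method: str = "t") -> ValidityReport:
    """Concurrent validity of method x against reference y.

    Bundles Spearman correlation (with band label), RMSE, and Bland-Altman
    bias / limits of agreement into one report.
    """
    sp = spearman(x, y, method=method)
    ba = bland_altman(x, y, z=z)
    return ValidityReport(
        rho=sp.rho,
        rho_p=sp.p_value,
        rho_label=sp.label,
        rmse=rmse(x, y),
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        n=len(np.asarray(x)),
    )


def sample_size_icc(spec: SampleSizeSpec | None = None, **kwargs) -> tuple[int, int]:
    """Subjects required to detect ICC rho1 against rho0 with k measurements.

    Walter-Eliasziw-Donner approximation:

        n = 1 + 2 k (z_{1-a} + z_{1-b})^2 / [(k - 1) (ln C0)^2],
        C0 = (1 + k rho0 / (1 - rho0)) / (1 + k rho1 / (1 - rho1)),

    rounded up.  Returns ``(n_required, n_inflated)`` where the second
    value inflates for an anticipated loss fraction,
    n_inflated = ceil(n / (1 - inflation)).
    """
    if spec is None:
        spec = SampleSizeSpec(**kwargs)
    alpha = spec.alpha / 2 if spec.two_sided else spec.alpha
    za = stats.norm.ppf(1 - alpha)
    zb = stats.norm.ppf(spec.power)
    c0 = (1 + spec.k * spec.rho0 / (1 - spec.rho0)) / (
        1 + spec.k * spec.rho1 / (1 - spec.rho1)
    )
    n = 1 + 2 * spec.k * (za + zb) ** 2 / ((spec.k - 1) * math.log(c0) ** 2)
    n_required = int(math.ceil(n - 1e-12))
    n_inflated = int(math.ceil(n_required / (1 - spec.inflation) - 1e-12))
    return n_required, n_inflated
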