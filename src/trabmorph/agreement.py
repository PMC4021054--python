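"""Method-agreement and reliability statistics for paired BV/TV measurements.

Covers the full statistical toolkit of a two-modality validation study:
Spearman rank correlation with a Fisher-z confidence interval, per-side
subgroup correlations, Bland-Altman bias and limits of agreement, the
two-way mixed consistency intraclass correlation ICC(3,1) for test-retest
reads, the root-mean-square coefficient of variation (RMS %CV) precision
error, and the Fisher-z minimum sample size for detecting a correlation.

Conventions (stated in every report):

* Bland-Altman differences are *test minus reference* — here MR minus
  microCT, so the conservative-threshold underestimation by MR shows up as
  a negative bias.
* Printed-value comparisons round half-up to two decimals.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "ReliabilityReport",
    "BlandAltman",
    "spearman_rho",
    "spearman_ci_fisher",
    "subgroup_correlations",
    "bland_altman",
    "icc_3_1",
    "rms_percent_cv",
    "sample_size_for_correlation",
    "compute_agreement",
    "compute_reliability",
    "round_half_up",
]

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("id", "side", "microct_bvtv_percent", "mr_bvtv_percent")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how printed tables are rounded."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class PairedMeasurements:
    """Per-specimen paired BV/TV percents from the two modalities."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"paired table is missing columns {missing}")
        if len(self.table) < 3:
            raise ValueError("need at least 3 paired measurements")
        if (self.table[["microct_bvtv_percent", "mr_bvtv_percent"]] < 0).any().any():
            raise ValueError("BV/TV percentages must be non-negative")
        keys = self.table[["id", "side"]].apply(tuple, axis=1)
        if keys.duplicated().any():
            raise ValueError("specimen (id, side) pairs must be unique")

    @classmethod
    def from_csv(cls, path) -> "PairedMeasurements":
        return cls(pd.read_csv(path))

    @property
    def microct(self) -> np.ndarray:
        return self.table["microct_bvtv_percent"].to_numpy(float)

    @property
    def mr(self) -> np.ndarray:
        return self.table["mr_bvtv_percent"].to_numpy(float)


@dataclass
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray
    convention: str = "test - reference (MR - microCT)"


@dataclass
class AgreementReport:
    n: int
    spearman_rho: float
    ci_level: float
    ci_low: float
    ci_high: float
    by_side: dict[str, float]
    bland_altman: BlandAltman
    notes: str = ""

    def to_dict(self) -> dict:
        ba = self.bland_altman
        return {
            "n": self.n,
            "spearman_rho": self.spearman_rho,
            "ci_level": self.ci_level,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "by_side": dict(self.by_side),
            "bland_altman": {
                "bias": ba.bias,
                "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "convention": ba.convention,
            },
            "notes": self.notes,
        }


@dataclass
class ReliabilityReport:
    icc_3_1: float
    diff_min: float
    diff_max: float
    rms_percent_cv: float

    def to_dict(self) -> dict:
        return {
            "icc_3_1": self.icc_3_1,
            "paired_difference_min": self.diff_min,
            "paired_difference_max": self.diff_max,
            "rms_percent_cv": self.rms_percent_cv,
        }


def _as_vec(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.isnan(v).any():
        raise ValueError(f"{name} contains missing values")
    return v


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks; for tie-free data this equals the classic
    ``1 - 6 * sum(d^2) / (n * (n^2 - 1))``.
    """
    xv, yv = _as_vec(x, "x"), _as_vec(y, "y")
    if len(xv) != len(yv):
        raise ValueError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if len(xv) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("rank correlation is undefined for a constant vector")
    rx = stats.rankdata(xv)  # mid-ranks
    ry = stats.rankdata(yv)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_ci_fisher(
    rho: float, n: int, level: float = 0.95, method: str = "fisher"
) -> tuple[float, float]:
    """Confidence interval for a correlation via the Fisher z-transform.

    ``z = atanh(rho)`` is treated as normal with standard error
    ``1 / sqrt(n - 3)`` (``method="fisher"``) or the Bonett-Wright variant
    ``sqrt((1 + rho^2 / 2) / (n - 3))`` (``method="bonett_wright"``), and
    the interval is mapped back through ``tanh``.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if abs(rho) >= 1:
        raise ValueError("interval is degenerate at |rho| = 1")
    z = math.atanh(rho)
    if method == "fisher":
        se = 1.0 / math.sqrt(n - 3)
    elif method == "bonett_wright":
        se = math.sqrt((1.0 + rho**2 / 2.0) / (n - 3))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    half = stats.norm.ppf((1.0 + level) / 2.0) * se
    return math.tanh(z - half), math.tanh(z + half)


def subgroup_correlations(data: PairedMeasurements) -> dict[str, float]:
    """Spearman correlation within each side label; sides with < 3 pairs are skipped."""
    out: dict[str, float] = {}
    for side, grp in data.table.groupby("side"):
        if len(grp) < 3:
            warnings.warn(f"side {side!r} has only {len(grp)} pairs; skipped", stacklevel=2)
            continue
        out[str(side)] = spearman_rho(
            grp["microct_bvtv_percent"].to_numpy(float), grp["mr_bvtv_percent"].to_numpy(float)
        )
    return out


def bland_altman(reference, test) -> BlandAltman:
    """Bland-Altman agreement: per-pair differences ``test - reference``.

    Bias is the mean difference, the limits of agreement are
    ``bias +/- 1.96 * sd`` with the sample (n-1) standard deviation.
    """
    ref, tst = _as_vec(reference, "reference"), _as_vec(test, "test")
    if len(ref) != len(tst):
        raise ValueError(f"length mismatch: {len(ref)} vs {len(tst)}")
    if len(ref) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = tst - ref
    means = (tst + ref) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=means,
        diffs=diffs,
    )


def icc_3_1(ratings) -> float:
    """ICC(3,1): two-way mixed effects, single measurement, consistency.

    ``ratings`` is an n-targets x k-raters matrix with no missing cells.
    From the two-way ANOVA decomposition, ``(BMS - EMS) / (BMS + (k-1)*EMS)``
    where BMS is the between-targets mean square and EMS the residual mean
    square.  Consistency ICC ignores fixed rater offsets: adding a constant
    to one column leaves it unchanged.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2D matrix (targets x raters)")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must be complete")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return float((bms - ems) / (bms + (k - 1) * ems))


def rms_percent_cv(first, second, divisor: str = "n-1") -> float:
    """Root-mean-square coefficient of variation for duplicate measurements.

    For each pair the standard deviation is ``|d| / sqrt(2)`` (two
    replicates, n-1 divisor; ``divisor="n"`` uses ``|d| / 2``), the CV is
    sd over the pair mean, and the result is ``100 * sqrt(mean(cv^2))``.
    Scale-invariant; requires strictly positive pair means.
    """
    a, b = _as_vec(first, "first"), _as_vec(second, "second")
    if len(a) != len(b) or len(a) < 1:
        raise ValueError("need equal-length, non-empty duplicate vectors")
    means = (a + b) / 2.0
    if (means <= 0).any():
        raise ValueError("CV undefined for non-positive pair means")
    denom = math.sqrt(2.0) if divisor == "n-1" else 2.0
    sds = np.abs(a - b) / denom
    cvs = sds / means
    return float(100.0 * math.sqrt(np.mean(cvs**2)))


def sample_size_for_correlation(
    rho_alt: float,
    alpha: float = 0.05,
    power: float = 0.80,
    rho_null: float = 0.0,
) -> int:
    """Fisher-z minimum n to detect ``rho_alt`` against ``rho_null`` (two-sided).

    ``n = ceil(((z_{1-alpha/2} + z_power) / (atanh(rho_alt) - atanh(rho_null)))^2 + 3)``.
    """
    if not 0 < rho_alt < 1:
        raise ValueError("rho_alt must be in (0, 1)")
    if rho_alt <= rho_null:
        raise ValueError("rho_alt must exceed rho_null")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    delta = math.atanh(rho_alt) - math.atanh(rho_null)
    return math.ceil((za + zb) ** 2 / delta**2 + 3)


def compute_agreement(
    data: PairedMeasurements,
    ci_level: float = 0.95,
    ci_method: str = "fisher",
) -> AgreementReport:
    """Full cross-modality agreement report for a paired BV/TV table."""
    rho = spearman_rho(data.microct, data.mr)
    ci_low, ci_high = spearman_ci_fisher(rho, len(data.table), level=ci_level, method=ci_method)
    by_side = subgroup_correlations(data)
    ba = bland_altman(reference=data.microct, test=data.mr)
    return AgreementReport(
        n=len(data.table),
        spearman_rho=rho,
        ci_level=ci_level,
        ci_low=ci_low,
        ci_high=ci_high,
        by_side=by_side,
        bland_altman=ba,
        notes="differences are MR - microCT",
    )


def compute_reliability(first, second, divisor: str = "n-1") -> ReliabilityReport:
    """Test-retest reliability of duplicate reads: ICC(3,1), range of paired
    differences, and RMS %CV."""
    a, b = _as_vec(first, "first"), _as_vec(second, "second")
    diffs = b - a
    return ReliabilityReport(
        icc_3_1=icc_3_1(np.column_stack([a, b])),
        diff_min=float(diffs.min()),
        diff_max=float(diffs.max()),
        rms_percent_cv=rms_percent_cv(a, b, divisor=divisor),
    )
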