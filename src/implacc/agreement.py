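"""Descriptive statistics and inter-observer agreement.

Accuracy studies report each deviation metric as mean ± SD over the
cohort, and quantify how reproducible the measurement procedure itself
is by having two observers repeat it on a subsample and computing the
intraclass correlation coefficient.  The coefficient implemented here is
ICC(A,1) in McGraw & Wong's nomenclature: two-way model, absolute
agreement, single measures — the form appropriate when each observer
rates every subject and the observers' systematic offsets should count
against agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .geometry import DeviationRecord

__all__ = [
    "AgreementError",
    "RatingsMatrix",
    "SummaryRow",
    "describe",
    "icc_absolute_single",
    "mean_absolute_difference",
    "summarise_cohort",
]


class AgreementError(ValueError):
    """Invalid input for an agreement/summary computation."""


@dataclass(frozen=True)
class RatingsMatrix:
    """n subjects × k observers measurements of one metric, no missing cells.

    Subjects with any missing rating must be dropped listwise before
    construction.
    """

    values: np.ndarray
    subject_ids: Optional[Sequence[str]] = None
    observer_ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise AgreementError(f"ratings must be 2D (subjects x observers), got {v.shape}")
        n, k = v.shape
        if n < 2 or k < 2:
            raise AgreementError(f"need >= 2 subjects and >= 2 observers, got {n} x {k}")
        if not np.all(np.isfinite(v)):
            raise AgreementError("ratings contain missing or non-finite cells")
        object.__setattr__(self, "values", v)
        if self.subject_ids is not None and len(self.subject_ids) != n:
            raise AgreementError("subject_ids length mismatch")
        if self.observer_ids is not None and len(self.observer_ids) != k:
            raise AgreementError("observer_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_observers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SummaryRow:
    metric: str
    n: int
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self):
        if self.sd < 0:
            raise AgreementError("sd must be >= 0")
        if not (self.min - 1e-12 <= self.mean <= self.max + 1e-12):
            raise AgreementError("mean must lie within [min, max]")


def describe(values: Sequence[float], divisor: str = "population", metric: str = "") -> SummaryRow:
    """Mean, SD, min, max of a metric column.

    ``divisor`` selects the SD denominator: ``"population"`` (n, the
    default, matching how the reference table's footer reproduces from
    its printed per-implant values) or ``"sample"`` (n−1).  Missing
    values must be filtered out by the caller.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise AgreementError("cannot summarise an empty list")
    if not np.all(np.isfinite(v)):
        raise AgreementError("values contain NaN/inf; filter missing entries first")
    if divisor == "population":
        ddof = 0
    elif divisor == "sample":
        if v.size < 2:
            raise AgreementError("sample SD needs n >= 2")
        ddof = 1
    else:
        raise AgreementError(f"divisor must be 'population' or 'sample', got {divisor!r}")
    return SummaryRow(
        metric=metric,
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=ddof)),
        min=float(v.min()),
        max=float(v.max()),
    )


def icc_absolute_single(
    ratings: RatingsMatrix, confidence: float = 0.95
) -> tuple[float, float, float]:
    """ICC(A,1): two-way, absolute agreement, single measures, with CI.

    From the two-way ANOVA decomposition into subject (rows), observer
    (columns) and residual mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1)·MSE + (k/n)·(MSC - MSE))

    The confidence interval follows the McGraw–Wong F-quantile
    construction with Satterthwaite degrees of freedom.  The absolute-
    agreement single-measures point estimate is identical under the
    two-way random and two-way mixed models.
    """
    if not 0.0 < confidence < 1.0:
        raise AgreementError("confidence must be in (0, 1)")
    x = ratings.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_tot = float(np.sum((x - grand) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if ss_tot <= 1e-300 or denom <= 0:
        raise AgreementError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 1e-300 and msc <= 1e-300:
        # perfect agreement: the F construction degenerates
        return float(icc), float(icc), float(icc)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
    else:
        v = (n - 1) * (k - 1)
    f_u = sstats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_l = sstats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return float(icc), float(lo), float(hi)


def mean_absolute_difference(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean of |aᵢ − bᵢ| over paired measurements."""
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if av.size != bv.size:
        raise AgreementError(f"length mismatch: {av.size} vs {bv.size}")
    if av.size == 0:
        raise AgreementError("need at least one pair")
    return float(np.mean(np.abs(av - bv)))


_METRIC_FIELDS = (
    ("angular_deg", "angular_deg"),
    ("global_mm", "global_mm"),
    ("lateral_mm", "lateral_mm"),
    ("depth_mm", "depth_mm"),
)


def summarise_cohort(
    records: Sequence[DeviationRecord], divisor: str = "population"
) -> list[SummaryRow]:
    """Four summary rows (angular, global, lateral, depth) for a cohort.

    Implants with no measurements at all are excluded from every row;
    records whose lateral deviation is undefined are excluded from the
    lateral row only.  Each row's ``n`` reflects its own exclusions.
    """
    if not records:
        raise AgreementError("no deviation records supplied")
    usable = [r for r in records if not r.is_missing]
    if not usable:
        raise AgreementError("all deviation records are missing")
    rows = []
    for metric, attr in _METRIC_FIELDS:
        vals = [getattr(r, attr) for r in usable if getattr(r, attr) is not None]
        if not vals:
            raise AgreementError(f"no measurable values for metric {metric}")
        rows.append(describe(vals, divisor=divisor, metric=metric))
    return rows
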