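"""Reproducibility statistics: coefficients of variation and the two-way
random-effects, absolute-agreement, single-measure intraclass correlation
ICC(2,1).

The ICC is computed from the mean squares of the two-way ANOVA decomposition
(subjects × replicate measurements), with the standard F-based 95% confidence
interval (McGraw & Wong). Absolute agreement is the conservative form for the
design here — the same sections measured across slides — because a constant
offset between slides counts against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicateTable",
    "ICCResult",
    "ReproducibilityReport",
    "coefficient_of_variation",
    "icc",
    "icc_consistency",
    "reproducibility_report",
]


@dataclass
class ReplicateTable:
    """Measurements with rows = subjects/blocks and columns = replicates.

    Rows with missing cells are removed listwise with a warning.
    """

    values: np.ndarray
    grouping: str = "intraslide"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.grouping not in ("intraslide", "interslide"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        bad = np.isnan(self.values).any(axis=1)
        if bad.any():
            warnings.warn(
                f"removing {int(bad.sum())} subject rows with missing cells",
                stacklevel=2,
            )
            self.values = self.values[~bad]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCResult:
    """ICC(2,1) point estimate with its 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float

    @property
    def half_width(self) -> float:
        """Symmetric half-width, for the conventional 'estimate ± hw' notation."""
        return 0.5 * (self.ci_high - self.ci_low)


def coefficient_of_variation(values: np.ndarray) -> float:
    """CV in percent: 100 × sample SD (n−1 denominator) / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * values.std(ddof=1) / mean)


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Row (subject), column (rater) and error mean squares of a two-way table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(table: ReplicateTable, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Estimate (n subjects, k replicates):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    with the F-based confidence interval of McGraw & Wong (Satterthwaite
    degrees of freedom for the column/error mixture).
    """
    x = table.values
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 subjects and 2 replicates")
    if np.allclose(x, x.flat[0]):
        raise ValueError("ICC undefined: zero total variance")
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    est = (msr - mse) / denom

    alpha = 1.0 - confidence
    a = (k * est) / (n * (1.0 - est)) if est < 1.0 else np.inf
    b = 1.0 + (k * est * (n - 1)) / (n * (1.0 - est)) if est < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lower = n * (msr - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
    else:  # perfect agreement: interval degenerates at 1
        lower = upper = 1.0
    lower = min(lower, est)
    upper = max(upper, est)
    return ICCResult(estimate=float(est), ci_low=float(lower), ci_high=float(upper))


def icc_consistency(table: ReplicateTable) -> float:
    """ICC(3,1) consistency form, insensitive to constant column offsets.

    Provided for diagnostics: a gap between this and the absolute-agreement
    ICC(2,1) localizes systematic inter-replicate shifts.
    """
    x = table.values
    n, k = x.shape
    msr, _, mse = _anova_mean_squares(x)
    return float((msr - mse) / (msr + (k - 1) * mse))


@dataclass
class ReproducibilityReport:
    """Intra-/inter-slide variability summary for a replicate experiment."""

    intraslide_cvs: np.ndarray
    mean_intraslide_cv: float
    interslide_cv: float | None
    icc: ICCResult | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"intraslide_cv_subject_{i + 1}", "value": cv, "unit": "%"}
            for i, cv in enumerate(self.intraslide_cvs)
        ]
        rows.append(
            {"metric": "mean_intraslide_cv", "value": self.mean_intraslide_cv, "unit": "%"}
        )
        if self.interslide_cv is not None:
            rows.append({"metric": "interslide_cv", "value": self.interslide_cv, "unit": "%"})
        if self.icc is not None:
            rows += [
                {"metric": "icc_2_1", "value": self.icc.estimate, "unit": ""},
                {"metric": "icc_ci_low", "value": self.icc.ci_low, "unit": ""},
                {"metric": "icc_ci_high", "value": self.icc.ci_high, "unit": ""},
                {"metric": "icc_ci_half_width", "value": self.icc.half_width, "unit": ""},
            ]
        return pd.DataFrame(rows)


def reproducibility_report(
    intraslide: ReplicateTable,
    interslide: ReplicateTable | None = None,
) -> ReproducibilityReport:
    """Per-subject intraslide CVs, their mean, the interslide CV across subject
    means, and the ICC with its confidence interval.

    The ICC is refused (reported as None) when fewer than 2 subjects are
    available; CVs are still reported.
    """
    x = intraslide.values
    cvs = np.array([coefficient_of_variation(row) for row in x])
    inter_cv = None
    source = interslide.values if interslide is not None else x
    if source.shape[0] >= 2:
        inter_cv = coefficient_of_variation(source.mean(axis=1))
    icc_result = None
    if x.shape[0] >= 2 and x.shape[1] >= 2:
        try:
            icc_result = icc(intraslide)
        except ValueError:
            icc_result = None
    return ReproducibilityReport(
        intraslide_cvs=cvs,
        mean_intraslide_cv=float(cvs.mean()),
        interslide_cv=inter_cv,
        icc=icc_result,
    )
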