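"""Human-vs-automated agreement via the intraclass correlation coefficient.

The comparison is between two specific raters (a trained examiner and the
automated counter) scoring the same units (nuclei, or patients after
aggregation), and their absolute counts must match — not merely co-vary.
The default ICC is therefore the two-way, single-measure, absolute-
agreement form ICC(A,1); the consistency form ICC(C,1) is available as an
option.  Both are computed from the two-way ANOVA mean squares with rows
= units and columns = raters, with confidence intervals from the
F-distribution.  Reliability is labeled "good" at ICC >= 0.75 (boundary
inclusive), "moderate" in [0.5, 0.75) and "poor" below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

__all__ = ["IccResult", "icc_agreement", "band_label", "anova_mean_squares"]


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n_units: int
    model_label: str
    band: str


def band_label(icc: float) -> str:
    """Reliability band: >= 0.75 good, 0.5-0.75 moderate, below poor."""
    if not np.isfinite(icc):
        raise ValueError("icc must be finite")
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way mean squares (rows = units, columns = raters): MSR, MSC, MSE."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_agreement(
    rater_a,
    rater_b,
    alpha: float = 0.05,
    model: str = "A1",
) -> IccResult:
    """ICC between two raters' values on the same units.

    ``model="A1"`` (default): two-way, absolute agreement, single measures
    — ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)) with k = 2,
    CI by the Satterthwaite/F method.  ``model="C1"``: consistency,
    insensitive to a constant offset between raters.
    """
    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("raters must be 1-D arrays of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 units")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    data = np.column_stack([a, b])
    n, k = data.shape
    msr, msc, mse = anova_mean_squares(data)
    if msr <= 0 and mse <= 0:
        raise ValueError("constant data: ICC undefined (no between-unit variance)")

    if model == "A1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        icc = (msr - mse) / denom
        # Satterthwaite df for the (aMSC + bMSE) pseudo mean square
        a_c = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b_c = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a_c):
            num_v = (a_c * msc + b_c * mse) ** 2
            den_v = (a_c * msc) ** 2 / (k - 1) + (b_c * mse) ** 2 / ((n - 1) * (k - 1))
            v = num_v / den_v if den_v > 0 else 1.0
            fl = f_dist.ppf(1 - alpha / 2, n - 1, v)
            fu = f_dist.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - fl * mse) / (
                fl * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (fu * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * fu * msr
            )
        else:
            lo = hi = 1.0
        label = "ICC(A,1) two-way absolute agreement, single measures"
    elif model == "C1":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse > 0:
            fobs = msr / mse
            df2 = (n - 1) * (k - 1)
            fl = fobs / f_dist.ppf(1 - alpha / 2, n - 1, df2)
            fu = fobs * f_dist.ppf(1 - alpha / 2, df2, n - 1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            lo = hi = 1.0
        label = "ICC(C,1) two-way consistency, single measures"
    else:
        raise ValueError(f"unknown model {model!r} (use 'A1' or 'C1')")
    lo, hi = min(lo, icc), max(hi, icc)
    return IccResult(float(icc), float(lo), float(hi), n, label, band_label(icc))
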