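"""Diagnostic accuracy of the mean AgNOR count as a screening marker.

Patients with higher mean AgNORs/nucleus are "more suspicious", so a test
is positive when the patient mean is at or above a threshold.  The module
provides the ROC curve over all achievable thresholds, the Mann-Whitney
AUC, the optimal cut-point (the ROC point closest to perfect sensitivity
and specificity, i.e. minimizing (1−sens)² + (1−spec)²), the 2×2 table
metrics at a cut-off, and the two-sample-means sample-size formula used
to size such a study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "RocCurve",
    "DiagnosticResult",
    "roc_curve",
    "auc",
    "optimal_cutpoint",
    "confusion_metrics",
    "evaluate_contrast",
    "sample_size_two_means",
    "CONTRASTS",
]

#: the six pairwise group contrasts, reference first, in reporting order
CONTRASTS = [
    ("CG", "EG"),
    ("CG", "OPMDG"),
    ("CG", "OSCCG"),
    ("EG", "OPMDG"),
    ("EG", "OSCCG"),
    ("OPMDG", "OSCCG"),
]


@dataclass(frozen=True)
class RocCurve:
    """Sensitivity/specificity over ascending thresholds (positive: value >= t)."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray


@dataclass(frozen=True)
class DiagnosticResult:
    reference_group: str
    case_group: str
    auc: float
    cutoff: float
    sens: float
    spec: float
    ppv: float
    npv: float
    accuracy: float


def _check_two_class(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D and the same length")
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("need at least one case (1) and one control (0)")
    return values, labels


def roc_curve(values, labels) -> RocCurve:
    """ROC over midpoint thresholds between consecutive distinct values.

    ±∞ sentinels guarantee the degenerate corners (sens, spec) = (1, 0)
    and (0, 1) are always present.
    """
    values, labels = _check_two_class(values, labels)
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    cases = values[labels == 1]
    controls = values[labels == 0]
    sens = np.array([(cases >= t).mean() for t in thresholds])
    spec = np.array([(controls < t).mean() for t in thresholds])
    return RocCurve(thresholds, sens, spec)


def auc(values, labels) -> float:
    """Mann-Whitney AUC: P(case > control) + ½·P(case = control).

    Computed via the rank-sum identity (average ranks give ties the half
    credit), which is exactly the mean over all case/control pairs and
    the trapezoidal area under the midpoint-threshold ROC.
    """
    from scipy.stats import rankdata

    values, labels = _check_two_class(values, labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(values)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def optimal_cutpoint(roc: RocCurve) -> tuple[float, float, float]:
    """Threshold whose ROC point is closest to perfect sensitivity/specificity.

    Minimizes squared Euclidean distance to (sens, spec) = (1, 1); ties go
    to higher sensitivity, then to the lower threshold.  Returns
    ``(cutoff, sens, spec)``.
    """
    d2 = (1.0 - roc.sens) ** 2 + (1.0 - roc.spec) ** 2
    order = np.lexsort((roc.thresholds, -roc.sens, d2))
    best = order[0]
    return float(roc.thresholds[best]), float(roc.sens[best]), float(roc.spec[best])


def confusion_metrics(values, labels, cutoff: float) -> dict[str, float]:
    """2×2 metrics at a cut-off (positive ⇔ value >= cutoff).

    Ratios with zero denominators are returned as NaN (missing), not 0.
    """
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    values, labels = _check_two_class(values, labels)
    pos = values >= cutoff
    tp = int(np.sum(pos & (labels == 1)))
    fp = int(np.sum(pos & (labels == 0)))
    fn = int(np.sum(~pos & (labels == 1)))
    tn = int(np.sum(~pos & (labels == 0)))

    def ratio(a: int, b: int) -> float:
        return a / b if b else float("nan")

    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sens": ratio(tp, tp + fn),
        "spec": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
    }


def evaluate_contrast(
    ref_values, case_values, reference_group: str = "ref", case_group: str = "case"
) -> DiagnosticResult:
    """AUC, optimal cut-off and 2×2 metrics for one reference/case contrast."""
    values = np.concatenate([np.asarray(ref_values, float), np.asarray(case_values, float)])
    labels = np.concatenate([np.zeros(len(ref_values), int), np.ones(len(case_values), int)])
    roc = roc_curve(values, labels)
    cutoff, _, _ = optimal_cutpoint(roc)
    if not math.isfinite(cutoff):  # degenerate (all values tied): report the tie value
        cutoff = float(values[0])
    m = confusion_metrics(values, labels, cutoff)
    return DiagnosticResult(
        reference_group, case_group, auc(values, labels), cutoff,
        m["sens"], m["spec"], m["ppv"], m["npv"], m["accuracy"],
    )


def sample_size_two_means(
    delta: float,
    sd1: float,
    sd2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    dropout: float = 0.0,
) -> tuple[int, int]:
    """Per-group n for detecting a difference in means (two-sided z-formula).

    n = ceil[(z_{1−α/2} + z_{power})² (sd1² + sd2²) / Δ²]; the recruited
    count inflates for the expected drop-out: ceil[n / (1 − dropout)].
    """
    if delta == 0:
        raise ValueError("delta must be non-zero")
    if not (0 < alpha < 1 and 0 < power < 1 and 0 <= dropout < 1):
        raise ValueError("alpha/power in (0,1), dropout in [0,1)")
    z = norm.ppf(1 - alpha / 2) + norm.ppf(power)
    n = math.ceil(z**2 * (sd1**2 + sd2**2) / delta**2)
    n_recruited = math.ceil(n / (1 - dropout))
    return n, n_recruited
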