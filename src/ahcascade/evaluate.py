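"""Evaluation metrics: confusion metrics, severity report, AHI agreement.

Segment metrics treat AH as the positive class.  The severity report works on
a 4×4 matrix (rows = estimated class, columns = reference class, in
NON/MILD/MODERATE/SEVERE order): it binarizes at each standard AHI cutoff
(5, 15, 30 events/h), reports SEN/SPE/PPV/ACC per cutoff plus their means,
and unweighted Cohen's kappa on the full matrix.  Percentages are rounded
half-up to one decimal — the convention of published tables — and the
cross-cutoff means average those displayed one-decimal values; kappa is
rounded to two decimals.  AHI agreement combines Pearson correlation with
Bland–Altman limits (mean difference ± 1.96 SD).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .event_detector import SEVERITY_ORDER, SubjectResult, severity_of
from .preprocess import AH, N

__all__ = [
    "ConfusionCounts",
    "SeverityMatrix",
    "UndefinedMetricError",
    "round_half_up",
    "segment_metrics",
    "binarize_severity",
    "severity_report",
    "cohen_kappa",
    "ahi_agreement",
    "confusion_from_labels",
    "severity_matrix_from_results",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the message names the metric."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as printed tables do (not banker's)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 counts with AH as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SeverityMatrix:
    """4×4 severity counts, rows = estimated, columns = reference."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.counts, dtype=int)
        if m.shape != (4, 4) or (m < 0).any():
            raise ValueError("severity matrix must be 4x4 nonnegative")
        object.__setattr__(self, "counts", m)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} is undefined: zero denominator")
    return 100.0 * num / den


def segment_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity in percent at one-decimal rounding."""
    if c.total == 0:
        raise UndefinedMetricError("all metrics undefined: empty confusion matrix")
    return {
        "acc": round_half_up(_ratio(c.tp + c.tn, c.total, "accuracy")),
        "sen": round_half_up(_ratio(c.tp, c.tp + c.fn, "sensitivity")),
        "spe": round_half_up(_ratio(c.tn, c.tn + c.fp, "specificity")),
    }


def binarize_severity(m: SeverityMatrix, cutoff: float) -> ConfusionCounts:
    """Pool the 4×4 matrix into 2×2 counts at an AHI cutoff (5, 15 or 30).

    Classes whose AHI range lies at or above the cutoff are positive:
    cutoff 5 → MILD+, cutoff 15 → MODERATE+, cutoff 30 → SEVERE.
    """
    try:
        k = 1 + SEVERITY_CUTOFFS_INDEX[float(cutoff)]
    except KeyError:
        raise ValueError(f"cutoff must be one of 5, 15, 30; got {cutoff}") from None
    c = m.counts
    return ConfusionCounts(
        tp=int(c[k:, k:].sum()),
        fp=int(c[k:, :k].sum()),
        fn=int(c[:k, k:].sum()),
        tn=int(c[:k, :k].sum()),
    )


SEVERITY_CUTOFFS_INDEX = {5.0: 0, 15.0: 1, 30.0: 2}


def cohen_kappa(m: SeverityMatrix) -> float:
    """Unweighted Cohen's kappa of a square contingency matrix (full precision)."""
    c = m.counts.astype(float)
    n = c.sum()
    if n == 0:
        raise ValueError("empty severity matrix")
    po = np.trace(c) / n
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def severity_report(m: SeverityMatrix) -> dict:
    """Per-cutoff SEN/SPE/PPV/ACC, their cross-cutoff means, and kappa.

    Per-cutoff values are one-decimal percentages; the means average those
    displayed values (and are themselves rounded to one decimal); kappa is
    rounded to two decimals.
    """
    if m.total == 0:
        raise ValueError("empty severity matrix")

    def _cell(num: int, den: int) -> float | None:
        # a cohort may lack a reference class entirely; report None rather
        # than fail, and exclude the cell from the cross-cutoff mean
        return round_half_up(100.0 * num / den) if den else None

    per_cutoff: dict[float, dict[str, float | None]] = {}
    for cutoff in (5.0, 15.0, 30.0):
        c = binarize_severity(m, cutoff)
        per_cutoff[cutoff] = {
            "sen": _cell(c.tp, c.tp + c.fn),
            "spe": _cell(c.tn, c.tn + c.fp),
            "ppv": _cell(c.tp, c.tp + c.fp),
            "acc": _cell(c.tp + c.tn, c.total),
        }
    means = {}
    for k in ("sen", "spe", "ppv", "acc"):
        vals = [per_cutoff[c][k] for c in per_cutoff if per_cutoff[c][k] is not None]
        means[k] = round_half_up(float(np.mean(vals))) if vals else None
    return {
        "per_cutoff": per_cutoff,
        "mean": means,
        "kappa": round_half_up(cohen_kappa(m), 2),
    }


def ahi_agreement(pairs: list[tuple[float, float]]) -> dict[str, float]:
    """Pearson correlation and Bland–Altman statistics of (AHI_est, AHI_ref) pairs.

    ``mean_diff`` and the limits of agreement are on estimated − reference;
    limits are mean ± 1.96 × sample SD (ddof=1).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (ahi_est, ahi_ref) pairs")
    est, ref = arr[:, 0], arr[:, 1]
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        raise UndefinedMetricError("Pearson correlation undefined for a constant column")
    r = float(stats.pearsonr(est, ref).statistic)
    diff = est - ref
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    return {
        "pearson_r": r,
        "mean_diff": mean_diff,
        "loa_low": mean_diff - 1.96 * sd,
        "loa_high": mean_diff + 1.96 * sd,
    }


def confusion_from_labels(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Pool per-segment predicted vs reference AH/N labels (UNKNOWN excluded)."""
    pred = np.asarray(pred, dtype=object)
    ref = np.asarray(ref, dtype=object)
    known = np.isin(pred, [AH, N]) & np.isin(ref, [AH, N])
    pred, ref = pred[known], ref[known]
    return ConfusionCounts(
        tp=int(np.sum((pred == AH) & (ref == AH))),
        fp=int(np.sum((pred == AH) & (ref == N))),
        fn=int(np.sum((pred == N) & (ref == AH))),
        tn=int(np.sum((pred == N) & (ref == N))),
    )


def severity_matrix_from_results(results: list[SubjectResult]) -> SeverityMatrix:
    """Tally per-subject estimated vs reference severity into the 4×4 matrix."""
    m = np.zeros((4, 4), dtype=int)
    for r in results:
        i = SEVERITY_ORDER.index(r.severity_est or severity_of(r.ahi_est))
        j = SEVERITY_ORDER.index(r.severity_ref or severity_of(r.ahi_ref))
        m[i, j] += 1
    return SeverityMatrix(m)
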