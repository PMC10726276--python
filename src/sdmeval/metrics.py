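"""Discrimination metrics for presence-absence predictions.

Four metrics are provided, all comparing a binary occurrence vector ``y``
against predicted occurrence probabilities ``p``:

* **AUC** — probability that a randomly chosen occupied entity receives a
  higher predicted probability than a randomly chosen empty one; computed via
  rank statistics in O(n log n). Range [0, 1], chance level 0.5.
* **Tjur's R²** — mean predicted probability among occupied entities minus the
  mean among empty ones. Range [-1, 1], chance level 0.
* **max-Kappa** — Cohen's chance-corrected accuracy, maximized over all
  probability thresholds. Range [-1, 1].
* **max-TSS** — sensitivity + specificity - 1, maximized over thresholds.
  Range [-1, 1].

Thresholding predicts a presence when ``p >= t`` (boundary included). A metric
that is undefined — e.g. a single-class ``y`` — is reported as NaN, never
raised; callers exclude NaNs from averages and count the exclusions.

For cross-metric comparability two reporting transforms are used:
``2*AUC - 1`` (so chance maps to 0) and the signed square root of Tjur's R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PredictionSet",
    "ConfusionCounts",
    "MetricSet",
    "confusion_counts",
    "accuracy_sensitivity_specificity",
    "tss",
    "kappa",
    "auc",
    "tjur_r2",
    "maximize_over_thresholds",
    "transform_auc",
    "transform_tjur",
    "evaluate_all",
    "METRIC_NAMES",
]

METRIC_NAMES = ("auc", "tjur_r2", "max_kappa", "max_tss")


@dataclass(frozen=True)
class PredictionSet:
    """Paired observed occurrences and predicted probabilities at one level."""

    y: np.ndarray
    p: np.ndarray
    level: str = "unit"

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        p = np.asarray(self.p, dtype=float)
        if y.shape != p.shape or y.ndim != 1:
            raise ValueError("y and p must be 1-D vectors of equal length")
        if y.size == 0:
            raise ValueError("empty prediction set")
        if not np.isin(np.unique(y), (0, 1)).all():
            raise ValueError("y entries must be 0 or 1")
        if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise ValueError("p entries must lie in [0, 1]")
        object.__setattr__(self, "y", y.astype(np.int64))
        object.__setattr__(self, "p", p)

    @property
    def n_presences(self) -> int:
        return int(self.y.sum())

    @property
    def n_absences(self) -> int:
        return int(self.y.size - self.y.sum())

    @property
    def single_class(self) -> bool:
        return self.n_presences == 0 or self.n_absences == 0


@dataclass(frozen=True)
class ConfusionCounts:
    """Cells of the 2x2 confusion matrix at one threshold.

    ``a`` true positives, ``b`` false positives, ``c`` false negatives,
    ``d`` true negatives.
    """

    a: int
    b: int
    c: int
    d: int
    threshold: float

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def confusion_counts(ps: PredictionSet, threshold: float) -> ConfusionCounts:
    """Tabulate the confusion matrix for thresholded predictions t_i = 1[p_i >= t]."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    t = ps.p >= threshold
    y = ps.y.astype(bool)
    return ConfusionCounts(
        a=int(np.sum(t & y)),
        b=int(np.sum(t & ~y)),
        c=int(np.sum(~t & y)),
        d=int(np.sum(~t & ~y)),
        threshold=float(threshold),
    )


def accuracy_sensitivity_specificity(cc: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); an undefined ratio is NaN."""
    accuracy = (cc.a + cc.d) / cc.n
    sensitivity = cc.a / (cc.a + cc.c) if cc.a + cc.c > 0 else math.nan
    specificity = cc.d / (cc.b + cc.d) if cc.b + cc.d > 0 else math.nan
    return accuracy, sensitivity, specificity


def tss(cc: ConfusionCounts) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    _, sens, spec = accuracy_sensitivity_specificity(cc)
    return sens + spec - 1.0


def kappa(cc: ConfusionCounts) -> float:
    """Cohen's Kappa: (Ao - Ae) / (1 - Ae) with marginal-product chance accuracy Ae."""
    n = cc.n
    ao = (cc.a + cc.d) / n
    ae = ((cc.a + cc.b) * (cc.a + cc.c) + (cc.c + cc.d) * (cc.b + cc.d)) / n**2
    if ae == 1.0:
        return math.nan
    return (ao - ae) / (1.0 - ae)


def auc(ps: PredictionSet, tie_policy: str = "half") -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    ``tie_policy='half'`` counts tied presence-absence pairs as 1/2 (the
    Mann-Whitney convention, giving 0.5 for a constant predictor);
    ``'strict'`` counts only strictly higher pairs.
    """
    if tie_policy not in ("half", "strict"):
        raise ValueError("tie_policy must be 'half' or 'strict'")
    n1, n0 = ps.n_presences, ps.n_absences
    if n1 == 0 or n0 == 0:
        return math.nan
    ranks = rankdata(ps.p)  # average ranks -> half-tie convention
    u = ranks[ps.y == 1].sum() - n1 * (n1 + 1) / 2.0
    if tie_policy == "strict":
        # subtract the half-credit that average ranks gave to tied pairs
        vals, inv = np.unique(ps.p, return_inverse=True)
        pos = np.bincount(inv[ps.y == 1], minlength=len(vals))
        neg = np.bincount(inv[ps.y == 0], minlength=len(vals))
        u -= 0.5 * float(pos @ neg)
    return float(u / (n1 * n0))


def tjur_r2(ps: PredictionSet) -> float:
    """Tjur's coefficient of discrimination: mean(p | y=1) - mean(p | y=0)."""
    if ps.single_class:
        return math.nan
    return float(ps.p[ps.y == 1].mean() - ps.p[ps.y == 0].mean())


def _threshold_sweep(ps: PredictionSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Confusion counts at every threshold where the matrix can change.

    Candidates are 0, each distinct predicted probability, and — when
    max(p) < 1 — a value just above max(p) realizing the all-absent
    prediction. Returns ``(thresholds, a, b, c, d)`` sorted by threshold.
    """
    n1, n0 = ps.n_presences, ps.n_absences
    vals, inv = np.unique(ps.p, return_inverse=True)
    pos = np.bincount(inv[ps.y == 1], minlength=len(vals)).astype(np.int64)
    neg = np.bincount(inv[ps.y == 0], minlength=len(vals)).astype(np.int64)
    # at t = vals[k]: predicted present iff p >= vals[k]
    a = pos[::-1].cumsum()[::-1]
    b = neg[::-1].cumsum()[::-1]
    thresholds = vals.copy()
    if thresholds[0] > 0.0:  # t = 0 predicts everything present, same matrix as t = min(p)
        thresholds = np.concatenate(([0.0], thresholds))
        a = np.concatenate(([n1], a))
        b = np.concatenate(([n0], b))
    if vals[-1] < 1.0:  # all-absent matrix, reached just above the largest p
        thresholds = np.concatenate((thresholds, [np.nextafter(vals[-1], 1.0)]))
        a = np.concatenate((a, [0]))
        b = np.concatenate((b, [0]))
    return thresholds, a, b, n1 - a, n0 - b


def maximize_over_thresholds(ps: PredictionSet, statistic: str = "tss") -> tuple[float, float]:
    """Maximize TSS or Kappa over all probability thresholds.

    The statistic is a step function of the threshold, changing only where a
    predicted probability sits, so sweeping the distinct values of ``p``
    (plus the boundary cases) is exact. Returns ``(max value, threshold)``;
    value ties resolve to the smallest threshold.
    """
    if statistic not in ("tss", "kappa"):
        raise ValueError("statistic must be 'tss' or 'kappa'")
    if ps.single_class:
        return math.nan, math.nan
    thr, a, b, c, d = _threshold_sweep(ps)
    n = ps.y.size
    with np.errstate(divide="ignore", invalid="ignore"):
        if statistic == "tss":
            stat = a / (a + c) + d / (b + d) - 1.0
        else:
            ao = (a + d) / n
            ae = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
            stat = np.where(ae == 1.0, np.nan, (ao - ae) / (1.0 - ae))
    best = np.nanmax(stat)
    idx = int(np.flatnonzero(stat == best)[0])  # thresholds ascend -> smallest wins
    return float(best), float(thr[idx])


def transform_auc(value: float) -> float:
    """Map AUC from [0, 1] onto [-1, 1] via 2*AUC - 1 (chance -> 0)."""
    return 2.0 * value - 1.0


def transform_tjur(value: float) -> float:
    """Signed square root of Tjur's R² (negative values keep their sign)."""
    if math.isnan(value):
        return math.nan
    return math.copysign(math.sqrt(abs(value)), value)


@dataclass(frozen=True)
class MetricSet:
    """All four discrimination metrics plus thresholds and reporting transforms."""

    auc: float
    tjur_r2: float
    max_kappa: float
    max_tss: float
    kappa_threshold: float
    tss_threshold: float
    transformed_auc: float = field(default=math.nan)
    transformed_tjur: float = field(default=math.nan)
    n_presences: int = 0
    n_absences: int = 0
    tie_policy: str = "half"

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "tjur_r2": self.tjur_r2,
            "max_kappa": self.max_kappa,
            "max_tss": self.max_tss,
            "kappa_threshold": self.kappa_threshold,
            "tss_threshold": self.tss_threshold,
            "transformed_auc": self.transformed_auc,
            "transformed_tjur": self.transformed_tjur,
            "n_presences": self.n_presences,
            "n_absences": self.n_absences,
            "tie_policy": self.tie_policy,
        }


def evaluate_all(ps: PredictionSet, tie_policy: str = "half") -> MetricSet:
    """Compute the four metrics, the maximizing thresholds and the transforms."""
    a = auc(ps, tie_policy=tie_policy)
    r2 = tjur_r2(ps)
    mk, kt = maximize_over_thresholds(ps, "kappa")
    mt, tt = maximize_over_thresholds(ps, "tss")
    return MetricSet(
        auc=a,
        tjur_r2=r2,
        max_kappa=mk,
        max_tss=mt,
        kappa_threshold=kt,
        tss_threshold=tt,
        transformed_auc=transform_auc(a),
        transformed_tjur=transform_tjur(r2),
        n_presences=ps.n_presences,
        n_absences=ps.n_absences,
        tie_policy=tie_policy,
    )
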