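"""Classification metrics, the repeated-run protocol and the Friedman test.

Binary confusion-matrix metrics (accuracy, precision, sensitivity,
F-measure, Matthews correlation coefficient) with the 0/0 -> 0 convention
for degenerate denominators; best/mean/worst summaries over repeated
stochastic runs; box-plot quartiles; and the nonparametric Friedman rank
test with average ranks on ties and the standard tie-corrected chi-square
statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import chi2, rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "metrics",
    "ExperimentTable",
    "run_experiment",
    "quartiles",
    "chi2_critical_value",
    "FriedmanResult",
    "friedman",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the positive class is label 1 (depressive)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    sensitivity: float
    f_measure: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
        }


def _ratio(num: float, den: float) -> float:
    """0/0 -> 0 convention for degenerate confusion matrices."""
    return num / den if den != 0 else 0.0


def metrics(cm: ConfusionMatrix) -> MetricSet:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    accuracy = (tp + tn) / cm.total
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    f_measure = _ratio(2 * precision * sensitivity, precision + sensitivity)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den)
    return MetricSet(accuracy, precision, sensitivity, f_measure, mcc)


@dataclass
class ExperimentTable:
    """Per-run values of one algorithm plus best/mean/worst summaries."""

    values: list[float]
    best: float
    mean: float
    worst: float
    n_features_best: int | None = None
    records: list[dict] = field(default_factory=list)


def run_experiment(
    run_fn: Callable[[int], dict],
    seeds: Sequence[int],
) -> ExperimentTable:
    """Run ``run_fn`` once per seed and summarize.

    ``run_fn(seed)`` must return a mapping with at least ``value`` (the
    tracked figure of merit, larger is better) and may include
    ``n_features``; the feature count reported is the one from the best run.
    """
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    records = []
    for seed in seeds:
        rec = dict(run_fn(seed))
        rec["seed"] = seed
        records.append(rec)
    values = [float(r["value"]) for r in records]
    best_rec = max(records, key=lambda r: r["value"])
    return ExperimentTable(
        values=values,
        best=max(values),
        mean=float(np.mean(values)),
        worst=min(values),
        n_features_best=best_rec.get("n_features"),
        records=records,
    )


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation — the box-plot summary."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("quartiles of an empty sequence")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def chi2_critical_value(alpha: float, df: int) -> float:
    """Upper-tail chi-square critical value: the (1 - alpha) quantile."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.ppf(1.0 - alpha, df))


@dataclass
class FriedmanResult:
    sum_ranks: np.ndarray
    mean_ranks: np.ndarray
    chi2: float
    df: int
    p_value: float
    critical_value: float
    reject_h0: bool
    alpha: float


def friedman(
    results: np.ndarray,
    alpha: float = 0.05,
    larger_is_better: bool = True,
) -> FriedmanResult:
    """Friedman rank test over an (n blocks) x (k algorithms) matrix.

    Within each block values are ranked with average ranks on ties; with
    ``larger_is_better`` the best value in a block receives rank k.  The
    statistic is the standard tie-corrected chi-square

        chi2 = [12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / C,
        C    = 1 - sum(t^3 - t) / (n k (k^2 - 1)),

    with R_j the rank sums and t the tie-group sizes.  H0 (no difference
    among algorithms) is rejected when the statistic exceeds the (1 - alpha)
    chi-square quantile at k - 1 degrees of freedom.
    """
    results = np.asarray(results, dtype=float)
    if results.ndim != 2:
        raise ValueError("results must be a 2-D (blocks x algorithms) matrix")
    n, k = results.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 algorithms")

    data = results if larger_is_better else -results
    ranks = np.vstack([rankdata(row, method="average") for row in data])
    sum_ranks = ranks.sum(axis=0)
    mean_ranks = sum_ranks / n

    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(sum_ranks**2)) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        stat = 0.0  # every block fully tied: no rank variation at all
    else:
        stat = stat / correction
    stat = max(stat, 0.0)

    df = k - 1
    crit = chi2_critical_value(alpha, df)
    p = float(chi2.sf(stat, df))
    return FriedmanResult(
        sum_ranks=sum_ranks,
        mean_ranks=mean_ranks,
        chi2=float(stat),
        df=df,
        p_value=p,
        critical_value=crit,
        reject_h0=bool(stat > crit),
        alpha=alpha,
    )
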