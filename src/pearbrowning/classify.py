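"""Bayesian classification of slices from Weibull shape factors.

The classifier follows the Parzen / probabilistic-neural-network construction:
each class gets a Gaussian-kernel density estimate over the chosen feature
subspace (per-feature Silverman bandwidth by default) and a prior equal to its
empirical frequency; prediction is the argmax of prior × density.  A Gaussian
naive-Bayes mode is available as an alternative.  Per-class correct-
classification rates are estimated by jackknife (leave-one-out) cross-
validation.  Confusion-matrix metrics use exact rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "SliceRecord",
    "ConfusionMatrix",
    "ClassMetrics",
    "ClassifierModel",
    "FEATURES",
    "bayes_fit",
    "jackknife_rate",
    "confusion_metrics",
    "two_class_report",
    "improvement_over_singles",
    "lsd_compare",
    "read_records",
    "write_records",
]

#: canonical feature columns on a slice record.
FEATURES = ("beta_bi", "beta_yi")

_ALIASES = {"bi": "beta_bi", "yi": "beta_yi", "beta_bi": "beta_bi", "beta_yi": "beta_yi"}


@dataclass(frozen=True)
class SliceRecord:
    """One analysed slice: identity, treatment group, and fitted shape factors."""

    slice_id: str
    group: str  # "control" | "treated"
    time_min: float
    beta_bi: float
    beta_yi: float

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("exposure time must be non-negative")
        if not (self.beta_bi > 0 and self.beta_yi > 0):
            raise ValueError("shape factors must be strictly positive")


def _feature_matrix(records: list[SliceRecord], features: tuple[str, ...]) -> np.ndarray:
    cols = [_ALIASES[f] for f in features]
    return np.array([[getattr(r, c) for c in cols] for r in records], dtype=float)


@dataclass
class ClassifierModel:
    """Fitted kernel-density (or Gaussian) Bayes classifier."""

    classes: list[str]
    features: tuple[str, ...]
    priors: dict[str, float]
    train: dict[str, np.ndarray]          # per-class n_c × d feature matrix
    bandwidths: dict[str, np.ndarray]     # per-class per-feature kernel widths
    mode: str = "kde"                     # "kde" | "gaussian"

    def log_score(self, X: np.ndarray) -> np.ndarray:
        """log(prior × density) for each row of X, per class (n × k)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(self.classes)))
        for j, c in enumerate(self.classes):
            T, h = self.train[c], self.bandwidths[c]
            if self.mode == "gaussian":
                mu, sd = T.mean(axis=0), h
                logf = stats.norm.logpdf(X, mu, sd).sum(axis=1)
            else:
                # product Gaussian kernel, averaged over training points
                z = (X[:, None, :] - T[None, :, :]) / h
                logk = (
                    -0.5 * (z**2).sum(axis=2)
                    - np.log(h).sum()
                    - 0.5 * T.shape[1] * np.log(2 * np.pi)
                )
                logf = logsumexp(logk, axis=1) - np.log(T.shape[0])
            out[:, j] = np.log(self.priors[c]) + logf
        return out

    def predict(self, X: np.ndarray) -> list[str]:
        """Argmax of prior × density; ties go to the first class alphabetically."""
        scores = self.log_score(X)
        # classes are stored sorted, so argmax's first-hit rule is the tie-break
        return [self.classes[j] for j in np.argmax(scores, axis=1)]


def _silverman(T: np.ndarray) -> np.ndarray:
    n, d = T.shape
    sd = T.std(axis=0, ddof=1)
    return sd * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))


def bayes_fit(
    records: list[SliceRecord],
    features: tuple[str, ...] = FEATURES,
    bandwidth: float | None = None,
    *,
    mode: str = "kde",
) -> ClassifierModel:
    """Fit the kernel-density Bayes classifier on the chosen feature subset.

    ``bandwidth=None`` uses Silverman's rule per class and feature; a float
    forces that width everywhere.  ``mode="gaussian"`` switches to Gaussian
    naive Bayes.
    """
    if not features:
        raise ValueError("at least one feature is required")
    features = tuple(_ALIASES[f] for f in features)
    classes = sorted({r.group for r in records})
    if len(classes) < 2:
        raise ValueError("need records from at least two classes")
    train: dict[str, np.ndarray] = {}
    bandwidths: dict[str, np.ndarray] = {}
    priors: dict[str, float] = {}
    for c in classes:
        sub = [r for r in records if r.group == c]
        if len(sub) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 records")
        T = _feature_matrix(sub, features)
        if bandwidth is not None:
            h = np.full(T.shape[1], float(bandwidth))
        else:
            h = _silverman(T)
            if np.any(h <= 0):
                bad = features[int(np.argmin(h))]
                raise ValueError(
                    f"feature {bad!r} is constant within class {c!r}; "
                    "pass an explicit bandwidth"
                )
        train[c] = T
        bandwidths[c] = h
        priors[c] = len(sub) / len(records)
    return ClassifierModel(
        classes=classes, features=features, priors=priors,
        train=train, bandwidths=bandwidths, mode=mode,
    )


def jackknife_rate(
    records: list[SliceRecord],
    features: tuple[str, ...] = FEATURES,
    bandwidth: float | None = None,
    *,
    mode: str = "kde",
) -> dict[str, float]:
    """Leave-one-out per-class correct-classification rate, in percent.

    Each record is predicted by a classifier fitted on all other records;
    deterministic and invariant to record order.
    """
    n = len(records)
    correct: dict[str, int] = {}
    total: dict[str, int] = {}
    for i in range(n):
        rest = records[:i] + records[i + 1:]
        model = bayes_fit(rest, features, bandwidth, mode=mode)
        X = _feature_matrix([records[i]], model.features)
        pred = model.predict(X)[0]
        g = records[i].group
        total[g] = total.get(g, 0) + 1
        correct[g] = correct.get(g, 0) + (pred == g)
    return {c: 100.0 * correct.get(c, 0) / total[c] for c in sorted(total)}


def improvement_over_singles(
    single_rates: tuple[float, ...] | list[float], combined_rate: float
) -> float:
    """Percentage-point gain of the combined-feature rate over the average
    of the single-feature rates, for one class."""
    return combined_rate - float(np.mean(single_rates))


# ---------------------------------------------------------------------------
# confusion-matrix arithmetic


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (positive class first)."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one prediction")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions with the positive/negative roles exchanged."""
        return ConfusionMatrix(TP=self.TN, FP=self.FN, FN=self.FP, TN=self.TP)


@dataclass(frozen=True)
class ClassMetrics:
    """Accuracy, precision, recall and F1 as exact fractions (None = undefined)."""

    accuracy: Fraction | None
    precision: Fraction | None
    recall: Fraction | None
    f1: Fraction | None

    def as_percent(self) -> dict[str, float | None]:
        """accuracy/precision/recall as % (2 dp), F1 as a ratio (3 dp)."""
        pct = lambda v: None if v is None else round(float(v) * 100, 2)
        return {
            "accuracy": pct(self.accuracy),
            "precision": pct(self.precision),
            "recall": pct(self.recall),
            "f1": None if self.f1 is None else round(float(self.f1), 3),
        }


def confusion_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Accuracy, precision, recall (sensitivity) and F1 from binary counts.

    Computed in exact rational arithmetic; a metric with a zero denominator is
    reported as None (undefined), never coerced to 0.
    """
    acc = Fraction(cm.TP + cm.TN, cm.total)
    prec = Fraction(cm.TP, cm.TP + cm.FP) if cm.TP + cm.FP else None
    rec = Fraction(cm.TP, cm.TP + cm.FN) if cm.TP + cm.FN else None
    if prec is None or rec is None or prec + rec == 0:
        f1 = None
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return ClassMetrics(accuracy=acc, precision=prec, recall=rec, f1=f1)


def two_class_report(
    cm: ConfusionMatrix, positive: str = "brown", negative: str = "good"
) -> dict:
    """Per-class precision/recall/F1 plus overall accuracy, Table-style.

    The positive class uses the counts as given; the negative class sees the
    same predictions with the roles exchanged.
    """
    pos = confusion_metrics(cm).as_percent()
    neg = confusion_metrics(cm.swapped()).as_percent()
    return {
        "total": cm.total,
        "accuracy_percent": pos["accuracy"],
        positive: {k: pos[k] for k in ("precision", "recall", "f1")},
        negative: {k: neg[k] for k in ("precision", "recall", "f1")},
    }


# ---------------------------------------------------------------------------
# Fisher's LSD


def lsd_compare(
    records: list[SliceRecord],
    feature: str,
    *,
    by: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's Least Significant Difference comparison of group means.

    One-way ANOVA supplies the pooled error variance; a pair of groups is
    flagged significant when |mean difference| exceeds
    t(1−α/2, N−k)·sqrt(MSE·(1/n_i + 1/n_j)).
    """
    col = _ALIASES.get(feature, feature)
    labels = sorted({getattr(r, by) for r in records})
    groups = {
        g: np.array([getattr(r, col) for r in records if getattr(r, by) == g])
        for g in labels
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs at least two records")
    N = sum(len(v) for v in groups.values())
    k = len(groups)
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_err = N - k
    mse = sse / df_err
    tcrit = stats.t.ppf(1 - alpha / 2, df_err)
    rows = []
    for g1, g2 in combinations(labels, 2):
        v1, v2 = groups[g1], groups[g2]
        diff = v1.mean() - v2.mean()
        se = np.sqrt(mse * (1 / len(v1) + 1 / len(v2)))
        lsd = tcrit * se
        tval = diff / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tval), df_err)
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "mean_diff": diff,
                "lsd": lsd,
                "p_value": p,
                "significant": bool(abs(diff) > lsd),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# records I/O


def write_records(path: str | Path, records: list[SliceRecord]) -> None:
    pd.DataFrame(
        {
            "slice_id": [r.slice_id for r in records],
            "group": [r.group for r in records],
            "time_min": [r.time_min for r in records],
            "beta_bi": [r.beta_bi for r in records],
            "beta_yi": [r.beta_yi for r in records],
        }
    ).to_csv(path, index=False)


def read_records(path: str | Path) -> list[SliceRecord]:
    df = pd.read_csv(path)
    return [
        SliceRecord(
            slice_id=str(row.slice_id),
            group=str(row.group),
            time_min=float(row.time_min),
            beta_bi=float(row.beta_bi),
            beta_yi=float(row.beta_yi),
        )
        for row in df.itertuples()
    ]
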