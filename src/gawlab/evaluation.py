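"""Evaluation surface: classification metrics, ROC/AUC, severity correlation,
paired-change analysis, and percentile-bootstrap confidence intervals.

Sensitivity is defined on the positive class (moderate/severe hoarseness,
H >= 2).  Correlations that are undefined because one side has zero variance
are reported as flagged NaNs, never silently dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "EvaluationReport",
    "classification_metrics",
    "roc_auc",
    "severity_correlation",
    "make_pairs",
    "delta_analysis",
    "bootstrap_ci",
    "evaluate_predictions",
]


@dataclass
class EvaluationReport:
    """Point metrics, their bootstrap CIs, and the severity correlations."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    spearman_rho_yhat_h: float
    spearman_rho_delta: float
    confusion: dict
    n: int
    ci: dict = field(default_factory=dict)
    bootstrap_settings: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_json(self, path) -> None:
        def _clean(v):
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        payload = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "spearman_rho_yhat_H": _clean(self.spearman_rho_yhat_h),
            "spearman_rho_delta": _clean(self.spearman_rho_delta),
            "confusion": self.confusion,
            "n": self.n,
            "ci": self.ci,
            "bootstrap_settings": self.bootstrap_settings,
            "flags": self.flags,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def classification_metrics(
    y_true: np.ndarray, y_hat: np.ndarray, threshold: float = 0.5
) -> dict:
    """Accuracy, sensitivity, specificity and the confusion counts.

    ``y_hat`` may be probabilities (thresholded at 0.5, ties positive) or
    already-binary predictions.
    """
    y_true = np.asarray(y_true).astype(int)
    pred = (np.asarray(y_hat, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((y_true == 1) & (pred == 1)))
    fn = int(np.sum((y_true == 1) & (pred == 0)))
    tn = int(np.sum((y_true == 0) & (pred == 0)))
    fp = int(np.sum((y_true == 0) & (pred == 1)))
    n = len(y_true)
    return {
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "confusion": {"TP": tp, "FN": fn, "TN": tn, "FP": fp},
        "n": n,
    }


def roc_auc(y_true: np.ndarray, y_hat: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC via the rank (Mann-Whitney) formulation with ties.

    AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos n_neg) where R_pos is the sum
    of average ranks of the positive-class scores.  The returned curve holds
    one (fpr, tpr, threshold) row per distinct score, descending.
    """
    y_true = np.asarray(y_true).astype(int)
    y_hat = np.asarray(y_hat, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC analysis")
    ranks = _stats.rankdata(y_hat, method="average")
    auc = (float(ranks[y_true == 1].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.unique(y_hat)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = y_hat >= t
        tpr.append(np.sum(pred & (y_true == 1)) / n_pos)
        fpr.append(np.sum(pred & (y_true == 0)) / n_neg)
    curve = pd.DataFrame(
        {
            "threshold": np.concatenate([[np.inf], thresholds]),
            "fpr": fpr,
            "tpr": tpr,
        }
    )
    return curve, float(auc)


def severity_correlation(y_hat: np.ndarray, h: np.ndarray) -> float:
    """Spearman rho (average-rank ties) between severity scores and H.

    Returns NaN when either side has zero variance (degenerate input).
    """
    y_hat = np.asarray(y_hat, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.ptp(y_hat) == 0 or np.ptp(h) == 0:
        return float("nan")
    rho, _ = _stats.spearmanr(y_hat, h)
    return float(rho)


def make_pairs(visits: pd.DataFrame, y_hat: np.ndarray) -> pd.DataFrame:
    """Per-subject (pre, post) deltas of H and the severity score.

    ``visits`` must carry subject_id, visit_order, and H; consecutive visits
    of each multi-visit subject, ordered by visit_order, form the pairs.
    """
    df = visits.copy()
    df["y_hat"] = np.asarray(y_hat, dtype=float)
    rows = []
    for subj, grp in df.groupby("subject_id"):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("visit_order")
        h = grp["H"].to_numpy()
        y = grp["y_hat"].to_numpy()
        for i in range(len(grp) - 1):
            rows.append(
                {
                    "subject_id": subj,
                    "delta_H": int(h[i + 1] - h[i]),
                    "delta_y_hat": float(y[i + 1] - y[i]),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "delta_H", "delta_y_hat"])


def delta_analysis(pairs: pd.DataFrame) -> tuple[float, list]:
    """Spearman rho between predicted and observed severity change.

    Requires >= 3 pairs; zero-variance deltas yield a flagged NaN.
    """
    if len(pairs) < 3:
        raise ValueError("paired-change analysis requires at least 3 pairs")
    flags: list[str] = []
    rho = severity_correlation(pairs["delta_y_hat"].to_numpy(), pairs["delta_H"].to_numpy())
    if math.isnan(rho):
        flags.append("delta correlation undefined: zero variance in deltas")
    return rho, flags


def bootstrap_ci(
    metric_fn,
    y_true: np.ndarray,
    y_hat: np.ndarray,
    n_resamples: int = 10000,
    level: float = 0.95,
    seed: int = 0,
    require_both_classes: bool = True,
) -> tuple[float, float]:
    """Percentile bootstrap CI over visit-level resamples with replacement.

    Resamples missing one of the two classes are redrawn (the count is
    implicit in determinism: redraws consume the same seeded stream).
    """
    y_true = np.asarray(y_true).astype(int)
    y_hat = np.asarray(y_hat, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y_true)
    stats = np.empty(n_resamples)
    for i in range(n_resamples):
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            if not require_both_classes or len(np.unique(y_true[idx])) == 2:
                break
        else:
            raise ValueError("could not draw a resample containing both classes")
        stats[i] = metric_fn(y_true[idx], y_hat[idx])
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(stats, alpha)), float(np.quantile(stats, 1.0 - alpha))


def evaluate_predictions(
    y_true: np.ndarray,
    y_hat: np.ndarray,
    h: np.ndarray,
    pairs: pd.DataFrame | None = None,
    n_resamples: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> EvaluationReport:
    """Assemble the full evaluation report for one model's test predictions."""
    m = classification_metrics(y_true, y_hat)
    _, auc = roc_auc(y_true, y_hat)
    rho = severity_correlation(y_hat, h)
    flags: list[str] = []
    if math.isnan(rho):
        flags.append("severity correlation undefined: zero variance")
    rho_delta = float("nan")
    if pairs is not None and len(pairs) >= 3:
        rho_delta, dflags = delta_analysis(pairs)
        flags.extend(dflags)

    ci = {}
    for name in ("accuracy", "sensitivity", "specificity"):
        fn = lambda yt, yh, _k=name: classification_metrics(yt, yh)[_k]
        ci[name] = bootstrap_ci(fn, y_true, y_hat, n_resamples, level, seed)
    return EvaluationReport(
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        auc=auc,
        spearman_rho_yhat_h=rho,
        spearman_rho_delta=rho_delta,
        confusion=m["confusion"],
        n=m["n"],
        ci=ci,
        bootstrap_settings={"n_resamples": n_resamples, "level": level, "seed": seed},
        flags=flags,
    )
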