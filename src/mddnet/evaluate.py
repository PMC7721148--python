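"""Imbalance-aware classifier evaluation and the printed hypothesis tests.

Covers the confusion-matrix metric panel (accuracy, sensitivity,
specificity, PPV, NPV, MCC), rank-based ROC AUC, the label-permutation
significance test for the whole marker, per-site bootstrap confidence
intervals, the pooled two-proportion z-test, and the exact two-sided
binomial test against chance used for cross-disorder generalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .classify import train_ensemble
from .synth import MultiSiteDataset

__all__ = [
    "MetricsReport",
    "confusion_metrics",
    "roc_auc",
    "permutation_test_marker",
    "bootstrap_site_ci",
    "two_proportion_ztest",
    "binomial_generalization_test",
]


@dataclass
class MetricsReport:
    """Confusion counts plus derived metrics; undefined ratios are NaN."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mcc: float
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "tn", "fn", "accuracy", "sensitivity",
                 "specificity", "ppv", "npv", "mcc", "auc")}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Metric panel from raw confusion counts (patients = positive class)."""
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn,
                         accuracy=(tp + tn) / n,
                         sensitivity=_ratio(tp, tp + fn),
                         specificity=_ratio(tn, tn + fp),
                         ppv=_ratio(tp, tp + fp),
                         npv=_ratio(tn, tn + fn),
                         mcc=float(mcc))


def confusion_metrics(labels: np.ndarray, probabilities: np.ndarray,
                      threshold: float = 0.5) -> MetricsReport:
    """Threshold the diagnostic probabilities (> threshold = patient) and score."""
    y = np.asarray(labels).astype(int).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.size != p.size:
        raise ValueError("labels and probabilities must have equal lengths")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    pred = p > threshold
    report = metrics_from_counts(tp=int(np.sum(pred & (y == 1))),
                                 fp=int(np.sum(pred & (y == 0))),
                                 tn=int(np.sum(~pred & (y == 0))),
                                 fn=int(np.sum(~pred & (y == 1))))
    if len(set(y)) == 2:
        report.auc = roc_auc(y, p)
    return report


def roc_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 1/2."""
    y = np.asarray(labels).astype(int).ravel()
    if len(set(y)) != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float).ravel()))


def permutation_test_marker(data: MultiSiteDataset, n_perm: int = 100, seed: int = 0,
                            **train_kwargs) -> dict[str, float | np.ndarray]:
    """Label-permutation significance of the whole training procedure.

    Per permutation the diagnosis labels are shuffled and the full
    nested-CV ensemble is retrained; held-out AUC and MCC are recorded.
    One-sided p-values use the plus-one convention
    p = (1 + #{perm >= observed}) / (n_perm + 1), so they are never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ens = train_ensemble(data, seed=int(rng.integers(2 ** 31)), **train_kwargs)
    obs = confusion_metrics(data.y, ens.cv_probabilities)
    null_auc = np.empty(n_perm)
    null_mcc = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(data.y)
        ens_b = train_ensemble(data, seed=int(rng.integers(2 ** 31)),
                               labels=perm, **train_kwargs)
        rep = confusion_metrics(perm, ens_b.cv_probabilities)
        null_auc[b] = rep.auc
        null_mcc[b] = rep.mcc if np.isfinite(rep.mcc) else 0.0
    obs_mcc = obs.mcc if np.isfinite(obs.mcc) else 0.0
    return {
        "observed_auc": obs.auc,
        "observed_mcc": obs_mcc,
        "p_auc": (1 + int(np.sum(null_auc >= obs.auc))) / (n_perm + 1),
        "p_mcc": (1 + int(np.sum(null_mcc >= obs_mcc))) / (n_perm + 1),
        "null_auc": null_auc,
        "null_mcc": null_mcc,
    }


def bootstrap_site_ci(labels: np.ndarray, probabilities: np.ndarray, site: np.ndarray,
                      n_boot: int = 1000, seed: int = 0, alpha: float = 0.05,
                      threshold: float = 0.5) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-site percentile CIs for AUC/accuracy/sensitivity/specificity.

    Participants are resampled with replacement within site; replicates
    whose resample lacks a class contribute nothing to the class-dependent
    metrics (they are recorded as NaN and dropped from the percentiles).
    """
    y = np.asarray(labels).astype(int).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    site = np.asarray(site).ravel()
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for s in sorted(set(site)):
        mask = site == s
        if mask.sum() < 2:
            raise ValueError(f"site {s!r} has fewer than 2 participants")
        ys, ps = y[mask], p[mask]
        reps = {k: np.full(n_boot, np.nan) for k in ("auc", "accuracy", "sensitivity", "specificity")}
        for b in range(n_boot):
            idx = rng.integers(ys.size, size=ys.size)
            yb, pb = ys[idx], ps[idx]
            rep = confusion_metrics(yb, pb, threshold)
            reps["accuracy"][b] = rep.accuracy
            if len(set(yb)) == 2:
                reps["auc"][b] = rep.auc
            reps["sensitivity"][b] = rep.sensitivity
            reps["specificity"][b] = rep.specificity
        out[str(s)] = {
            k: (float(np.nanpercentile(v, 100 * alpha / 2)),
                float(np.nanpercentile(v, 100 * (1 - alpha / 2))))
            if np.isfinite(v).any() else (float("nan"), float("nan"))
            for k, v in reps.items()
        }
    return out


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, no continuity correction.

    Returns (z, two-sided normal p).  The sign of z follows p1 - p2.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not (0 <= k <= n):
            raise ValueError("successes must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def binomial_generalization_test(n_correct: int, n_total: int) -> tuple[float, float]:
    """Accuracy and exact two-sided binomial p against chance (0.5)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_correct <= n_total):
        raise ValueError("n_correct must lie in [0, n_total]")
    res = stats.binomtest(n_correct, n_total, 0.5, alternative="two-sided")
    return n_correct / n_total, float(res.pvalue)
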