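"""Important-connection identification and cross-dataset reproducibility.

A connection is "diagnostically important" when the LASSO members of the
ensemble select it (give it nonzero weight) more often than a max-statistic
permutation null allows: per permutation the diagnosis labels are shuffled,
the full nested-CV ensemble is retrained, and the *maximum* selection count
over all connections is recorded.  Thresholding the observed counts at the
(1 - alpha) quantile of this max distribution controls the family-wise
error over all connections at level alpha.

Univariate reproducibility is quantified by correlating per-connection
two-sample t statistics (patients minus controls; negative t =
under-connectivity) between two independent cohorts, with a permutation
null built by recomputing both t vectors under within-cohort label
shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifierEnsemble, train_ensemble
from .fc import index_to_pair
from .synth import MultiSiteDataset

__all__ = [
    "SelectionCountResult",
    "EffectSizeVector",
    "selection_counts",
    "importance_threshold_null",
    "effect_size_t",
    "reproducibility_correlation",
    "describe_important_fcs",
]


@dataclass
class SelectionCountResult:
    counts: np.ndarray
    threshold: int
    null_max: np.ndarray

    @property
    def important_indices(self) -> np.ndarray:
        return np.flatnonzero(self.counts >= self.threshold)


@dataclass
class EffectSizeVector:
    t_values: np.ndarray
    df: int


def selection_counts(ensemble: ClassifierEnsemble) -> np.ndarray:
    """Per-connection number of member models with nonzero weight."""
    members = ensemble.flat_models()
    if not members:
        raise ValueError("ensemble has no members")
    counts = np.zeros(members[0].w.size, dtype=int)
    for m in members:
        counts[m.selected_indices] += 1
    return counts


def importance_threshold_null(data: MultiSiteDataset, n_perm: int = 100, seed: int = 0,
                              alpha: float = 0.05, **train_kwargs) -> SelectionCountResult:
    """Observed counts plus the max-count permutation threshold.

    The threshold is the smallest integer c whose permutation p-value
    (plus-one convention) is at or below alpha:
    (1 + #{null max >= c}) / (n_perm + 1) <= alpha.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ens = train_ensemble(data, seed=int(rng.integers(2 ** 31)), **train_kwargs)
    counts = selection_counts(ens)
    null_max = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(data.y)
        ens_b = train_ensemble(data, seed=int(rng.integers(2 ** 31)),
                               labels=perm, **train_kwargs)
        null_max[b] = selection_counts(ens_b).max()
    n_members = ens.n_models
    threshold = n_members + 1  # unattainable unless some c qualifies
    for c in range(0, n_members + 1):
        p = (1 + int(np.sum(null_max >= c))) / (n_perm + 1)
        if p <= alpha:
            threshold = c
            break
    threshold = max(threshold, 1)  # count 0 is never evidence of importance
    return SelectionCountResult(counts=counts, threshold=int(threshold), null_max=null_max)


def effect_size_t(data: MultiSiteDataset, labels: np.ndarray | None = None) -> EffectSizeVector:
    """Pooled-variance two-sample t per connection, signed patients minus controls."""
    y = data.y if labels is None else np.asarray(labels).astype(int).ravel()
    x_mdd = data.connectivity[y == 1]
    x_hc = data.connectivity[y == 0]
    n1, n0 = x_mdd.shape[0], x_hc.shape[0]
    if n1 < 2 or n0 < 2:
        raise ValueError("both groups need at least 2 members")
    v1 = x_mdd.var(axis=0, ddof=1)
    v0 = x_hc.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x_mdd.mean(axis=0) - x_hc.mean(axis=0)) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    degenerate = sp2 == 0
    if degenerate.any():
        import warnings
        warnings.warn(f"{int(degenerate.sum())} connection(s) with zero pooled variance; t set to NaN")
        t = np.where(degenerate, np.nan, t)
    return EffectSizeVector(t_values=t, df=n1 + n0 - 2)


def reproducibility_correlation(data_a: MultiSiteDataset, data_b: MultiSiteDataset,
                                n_perm: int = 1000, seed: int = 0) -> dict[str, float]:
    """Pearson correlation of the two cohorts' t vectors with a permutation p.

    Returns r, its Fisher-z 95% CI, and a one-sided p from a null in which
    diagnosis labels are shuffled independently within each cohort and both
    t vectors recomputed.
    """
    t_a = effect_size_t(data_a).t_values
    t_b = effect_size_t(data_b).t_values
    if t_a.size != t_b.size:
        raise ValueError("cohorts have different connection counts")
    r = float(stats.pearsonr(t_a, t_b).statistic)
    n = t_a.size
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        ta = effect_size_t(data_a, labels=rng.permutation(data_a.y)).t_values
        tb = effect_size_t(data_b, labels=rng.permutation(data_b.y)).t_values
        null[b] = stats.pearsonr(ta, tb).statistic
    p = (1 + int(np.sum(null >= r))) / (n_perm + 1)
    return {"r": r, "ci_low": ci[0], "ci_high": ci[1], "p": p, "n_perm": n_perm}


def describe_important_fcs(important_indices: np.ndarray, t_values: np.ndarray,
                           region_labels: list[str] | None = None,
                           counts: np.ndarray | None = None) -> pd.DataFrame:
    """Annotated table of the flagged connections.

    One row per important connection: pair index, region pair (labels if
    provided), selection count, effect size, and under/over-connectivity
    direction from the sign of t.
    """
    rows = []
    for k in np.asarray(important_indices, dtype=int):
        if k < 0 or k >= t_values.size:
            raise ValueError(f"connection index {k} out of range")
        i, j = index_to_pair(int(k))
        if region_labels is not None:
            if i >= len(region_labels) or j >= len(region_labels):
                raise ValueError(f"region labels do not cover pair ({i}, {j})")
            ri, rj = region_labels[i], region_labels[j]
        else:
            ri, rj = f"region{i}", f"region{j}"
        t = float(t_values[k])
        rows.append({
            "pair_index": int(k),
            "region_a": ri,
            "region_b": rj,
            "t_value": t,
            "direction": "under" if t < 0 else "over",
            "selection_count": int(counts[k]) if counts is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=["pair_index", "region_a", "region_b",
                                       "t_value", "direction", "selection_count"])
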