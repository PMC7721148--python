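"""Diagnostic-stability simulation: rater noise, kappa, variance components.

The simulation asks how stable a dichotomous MDD diagnosis is when the
underlying continuous "probability of depression" is read through noisy
raters.  Each of 2 raters observes true_p + N(0, sigma) (sigma in squared
probability units, i.e. a variance) and diagnoses MDD when the noisy value
is at or above 0.5.  Cohen's kappa between the raters, averaged over Monte
Carlo replicates, maps sigma to an agreement level; bisection inverts that
map so a target kappa (e.g. the 0.28 reported for clinician DSM diagnoses)
yields the implied rater variance.

For the scanner-as-rater comparison, classifier outputs of repeatedly
scanned travelers are decomposed per participant into whole variance
(across all scans), between-site variance (across per-site mean outputs)
and within-site variance (across repeated scans at one designated site),
then averaged across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KappaSimResult",
    "VarianceDecomposition",
    "cohen_kappa",
    "simulate_rater_agreement",
    "invert_kappa_to_variance",
    "variance_decomposition",
]

#: Diagnosis rule in this simulation: MDD when the noisy probability is >= 0.5.
DIAGNOSIS_THRESHOLD = 0.5


@dataclass
class KappaSimResult:
    sigma: float
    kappa_mean: float
    n_rep: int
    seed: int


@dataclass
class VarianceDecomposition:
    whole: float
    between_site: float
    within_site: float
    per_participant: pd.DataFrame


def cohen_kappa(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) for binary raters.

    Expected agreement p_e is the marginal product.  When p_e = 1 (both
    raters constant), kappa is 1 for identical labelings and NaN otherwise.
    """
    a = np.asarray(labels_a).astype(int).ravel()
    b = np.asarray(labels_b).astype(int).ravel()
    if a.size != b.size or a.size == 0:
        raise ValueError("label vectors must be non-empty and of equal length")
    po = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return 1.0 if po == 1.0 else float("nan")
    return float((po - pe) / (1 - pe))


def simulate_rater_agreement(true_p: np.ndarray, sigma: float, n_rep: int = 200,
                             seed: int = 0) -> KappaSimResult:
    """Mean kappa between two raters reading true_p through N(0, sigma) noise."""
    p = np.asarray(true_p, dtype=float).ravel()
    if p.size == 0 or np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("true probabilities must lie strictly in (0, 1)")
    if sigma < 0:
        raise ValueError("sigma (a variance) must be >= 0")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(sigma)
    kappas = np.empty(n_rep)
    for r in range(n_rep):
        diag_a = (p + rng.normal(0.0, sd, size=p.size) >= DIAGNOSIS_THRESHOLD) if sd > 0 \
            else (p >= DIAGNOSIS_THRESHOLD)
        diag_b = (p + rng.normal(0.0, sd, size=p.size) >= DIAGNOSIS_THRESHOLD) if sd > 0 \
            else (p >= DIAGNOSIS_THRESHOLD)
        kappas[r] = cohen_kappa(diag_a.astype(int), diag_b.astype(int))
    return KappaSimResult(sigma=float(sigma), kappa_mean=float(np.nanmean(kappas)),
                          n_rep=n_rep, seed=seed)


def invert_kappa_to_variance(true_p: np.ndarray, target_kappa: float, n_rep: int = 500,
                             seed: int = 0, tolerance: float = 0.005,
                             sigma_hi: float = 4.0, max_iter: int = 60) -> KappaSimResult:
    """Bisection on sigma until the simulated mean kappa hits the target.

    Kappa decreases (stochastically) in sigma from ~1 at sigma = 0 toward 0
    for huge noise; an unreachable target raises with the attainable range.
    """
    lo, hi = 0.0, float(sigma_hi)
    k_lo = simulate_rater_agreement(true_p, lo, n_rep, seed).kappa_mean
    k_hi = simulate_rater_agreement(true_p, hi, n_rep, seed + 1).kappa_mean
    if not (k_hi - tolerance <= target_kappa <= k_lo + tolerance):
        raise ValueError(
            f"target kappa {target_kappa} outside attainable range [{k_hi:.3f}, {k_lo:.3f}]"
        )
    result = KappaSimResult(sigma=lo, kappa_mean=k_lo, n_rep=n_rep, seed=seed)
    for it in range(max_iter):
        mid = 0.5 * (lo + hi)
        result = simulate_rater_agreement(true_p, mid, n_rep, seed + 2 + it)
        if abs(result.kappa_mean - target_kappa) <= tolerance:
            return result
        if result.kappa_mean > target_kappa:
            lo = mid  # agreement still too high -> need more noise
        else:
            hi = mid
    return result


def variance_decomposition(outputs: pd.DataFrame, within_site: str,
                           value_col: str = "probability") -> VarianceDecomposition:
    """Whole / between-site / within-site variance of per-scan outputs.

    ``outputs`` needs columns participant, site and ``value_col``.  Per
    participant: whole = sample variance over all scans; between = sample
    variance over per-site mean outputs; within = sample variance over the
    scans at ``within_site``.  Components are then averaged across
    participants.  Participants without >= 2 scans at the designated site
    are skipped with a warning.
    """
    required = {"participant", "site", value_col}
    if not required.issubset(outputs.columns):
        raise ValueError(f"outputs needs columns {sorted(required)}")
    rows = []
    for pid, grp in outputs.groupby("participant"):
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"participant {pid!r} has < 2 scans; skipped")
            continue
        site_means = grp.groupby("site")[value_col].mean().to_numpy()
        within_vals = grp.loc[grp["site"] == within_site, value_col].to_numpy(dtype=float)
        if within_vals.size < 2:
            warnings.warn(f"participant {pid!r} lacks >= 2 scans at site {within_site!r}; skipped")
            continue
        rows.append({
            "participant": pid,
            "whole": float(np.var(vals, ddof=1)),
            "between_site": float(np.var(site_means, ddof=1)) if site_means.size > 1 else 0.0,
            "within_site": float(np.var(within_vals, ddof=1)),
        })
    if not rows:
        raise ValueError("no participant had enough scans for the decomposition")
    table = pd.DataFrame(rows)
    return VarianceDecomposition(whole=float(table["whole"].mean()),
                                 between_site=float(table["between_site"].mean()),
                                 within_site=float(table["within_site"].mean()),
                                 per_participant=table)
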