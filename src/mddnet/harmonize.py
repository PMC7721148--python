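"""Site-difference control: traveling-subject regression and ComBat.

Two harmonization routes are provided.

*Traveling-subject regression* (the primary method) fits, independently for
every connection, the linear model

    y = const + m[site] + s_hc[site]*1{HC} + s_mdd[site]*1{MDD}
        + d*1{MDD} + p[traveler] + e

jointly over the study cohort (which carries measurement bias, sampling
bias and the disorder term) and the traveling-subject scans (which carry
measurement bias and the participant factor only).  Identifiability comes
from sum-to-zero constraints on ``m``, ``s_hc``, ``s_mdd`` and ``p`` and
from fixing the healthy-control level of the disorder factor at zero.
Harmonization then subtracts *only* the estimated measurement bias
``m_hat[site]``, leaving population (sampling) differences and the disorder
effect untouched.

*ComBat* (fallback when no travelers exist) is the parametric
empirical-Bayes location/scale batch-adjustment: per connection, site
effects are standardized against a covariate-preserving linear fit, shrunk
toward their empirical priors (normal prior for the additive effect,
inverse-gamma for the multiplicative), removed, and the covariate effects
restored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import MultiSiteDataset, TravelingSubjectDataset

__all__ = [
    "BiasModelEstimates",
    "CombatParams",
    "fit_traveling_subject_model",
    "subtract_measurement_bias",
    "combat_fit_transform",
]


@dataclass
class BiasModelEstimates:
    """Per-connection estimates of the traveling-subject bias model."""

    sites: list[str]
    travelers: list[str]
    m_hat: np.ndarray            # sites x n_fc
    s_hc_hat: np.ndarray         # sites x n_fc (0 where site has no HC)
    s_mdd_hat: np.ndarray        # sites x n_fc (0 where site has no MDD)
    d_hat: np.ndarray            # n_fc (MDD level; HC level fixed at 0)
    p_hat: np.ndarray            # travelers x n_fc
    const_hat: np.ndarray        # n_fc
    residual_variance: np.ndarray  # n_fc

    def site_index(self, site: str) -> int:
        return self.sites.index(site)


def _sum_to_zero_contrast(n_levels: int) -> np.ndarray:
    """n_levels x (n_levels-1) coding matrix C with columns spanning {v: sum v = 0}.

    Level k < n-1 maps to unit vector e_k; the last level maps to -1s, so
    for reduced coefficients b the full effect is C @ b and sums to zero.
    """
    c = np.eye(n_levels, n_levels - 1)
    c[-1, :] = -1.0
    return c


def fit_traveling_subject_model(study: MultiSiteDataset,
                                travelers: TravelingSubjectDataset) -> BiasModelEstimates:
    """Constrained least-squares fit of the bias model, all connections at once.

    The sum-to-zero constraints are imposed by re-parameterising each
    categorical factor with a sum-to-zero contrast basis; the reduced design
    is solved by a single rank-revealing ``lstsq`` shared across
    connections, and full-length effects are reconstructed from the reduced
    coefficients.
    """
    if study.n_fc != travelers.connectivity.shape[1]:
        raise ValueError("study and traveler data have different connection counts")
    sites = sorted(set(study.site))
    missing = set(sites) - set(travelers.site)
    if missing:
        raise ValueError(f"sites without traveler coverage: {sorted(missing)}")
    # include traveler-only sites too: m is estimable wherever travelers went
    sites = sorted(set(sites) | set(travelers.site))
    trav_ids = sorted(set(travelers.subject))
    n_sites, n_trav = len(sites), len(trav_ids)
    site_pos = {s: k for k, s in enumerate(sites)}
    trav_pos = {t: j for j, t in enumerate(trav_ids)}

    hc_sites = sorted(set(study.site[study.y == 0]))
    mdd_sites = sorted(set(study.site[study.y == 1]))

    n_study, n_scan = study.n_participants, travelers.connectivity.shape[0]
    n_rows = n_study + n_scan

    blocks: list[np.ndarray] = [np.ones((n_rows, 1))]  # const
    # measurement bias: all rows
    x_site = np.zeros((n_rows, n_sites))
    for r, s in enumerate(study.site):
        x_site[r, site_pos[s]] = 1.0
    for r, s in enumerate(travelers.site):
        x_site[n_study + r, site_pos[s]] = 1.0
    cm = _sum_to_zero_contrast(n_sites)
    blocks.append(x_site @ cm)
    # sampling biases: study rows only, per diagnosis group, over sites with that group
    def group_block(group_sites: list[str], mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ind = np.zeros((n_rows, len(group_sites)))
        pos = {s: k for k, s in enumerate(group_sites)}
        for r in np.flatnonzero(mask):
            ind[r, pos[study.site[r]]] = 1.0
        contrast = _sum_to_zero_contrast(len(group_sites))
        return ind @ contrast, contrast

    b_hc, c_hc = group_block(hc_sites, study.y == 0)
    b_mdd, c_mdd = group_block(mdd_sites, study.y == 1)
    blocks += [b_hc, b_mdd]
    # disorder factor, HC level fixed at 0
    x_d = np.zeros((n_rows, 1))
    x_d[:n_study, 0] = study.y
    blocks.append(x_d)
    # participant factors: traveler rows only
    x_p = np.zeros((n_rows, n_trav))
    for r, t in enumerate(travelers.subject):
        x_p[n_study + r, trav_pos[t]] = 1.0
    cp = _sum_to_zero_contrast(n_trav)
    blocks.append(x_p @ cp)

    design = np.hstack(blocks)
    y = np.vstack([study.connectivity, travelers.connectivity])
    rank_needed = design.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < rank_needed:
        raise ValueError(
            f"rank-deficient bias-model design (rank {rank} < {rank_needed}); "
            "check traveler coverage and group/site composition"
        )

    # unpack reduced coefficients back to constrained full-length effects
    idx = 0
    const_hat = beta[idx]; idx += 1
    m_hat = cm @ beta[idx:idx + n_sites - 1]; idx += n_sites - 1
    s_hc_full = np.zeros((n_sites, study.n_fc))
    s_red = c_hc @ beta[idx:idx + len(hc_sites) - 1]; idx += len(hc_sites) - 1
    for k, s in enumerate(hc_sites):
        s_hc_full[site_pos[s]] = s_red[k]
    s_mdd_full = np.zeros((n_sites, study.n_fc))
    s_red = c_mdd @ beta[idx:idx + len(mdd_sites) - 1]; idx += len(mdd_sites) - 1
    for k, s in enumerate(mdd_sites):
        s_mdd_full[site_pos[s]] = s_red[k]
    d_hat = beta[idx]; idx += 1
    p_hat = cp @ beta[idx:idx + n_trav - 1]; idx += n_trav - 1

    resid = y - design @ beta
    dof = max(n_rows - rank_needed, 1)
    residual_variance = (resid ** 2).sum(axis=0) / dof
    return BiasModelEstimates(sites=sites, travelers=trav_ids, m_hat=m_hat,
                              s_hc_hat=s_hc_full, s_mdd_hat=s_mdd_full,
                              d_hat=d_hat, p_hat=p_hat, const_hat=const_hat,
                              residual_variance=residual_variance)


def subtract_measurement_bias(data: MultiSiteDataset,
                              est: BiasModelEstimates) -> MultiSiteDataset:
    """Remove the estimated measurement bias: row -> row - m_hat[site].

    Only the site-specific measurement offset is subtracted; sampling bias
    and the disorder effect stay in the data.  Note the operation is not
    idempotent: applying it twice subtracts 2*m_hat.
    """
    unknown = set(data.site) - set(est.sites)
    if unknown:
        raise ValueError(f"sites missing from the bias estimates: {sorted(unknown)}")
    site_rows = np.array([est.site_index(s) for s in data.site])
    harmonized = data.connectivity - est.m_hat[site_rows]
    return replace(data, connectivity=harmonized, phenotypes=data.phenotypes.copy())


def subtract_measurement_bias_scans(travelers: TravelingSubjectDataset,
                                    est: BiasModelEstimates) -> TravelingSubjectDataset:
    """Measurement-bias removal for traveling-subject scans."""
    unknown = set(travelers.site) - set(est.sites)
    if unknown:
        raise ValueError(f"sites missing from the bias estimates: {sorted(unknown)}")
    site_rows = np.array([est.site_index(s) for s in travelers.site])
    return replace(travelers, connectivity=travelers.connectivity - est.m_hat[site_rows],
                   scans=travelers.scans.copy())


@dataclass
class CombatParams:
    """Fitted parametric empirical-Bayes ComBat parameters."""

    sites: list[str]
    gamma_star: np.ndarray       # sites x n_fc additive site effects (EB-shrunk)
    delta_star: np.ndarray       # sites x n_fc multiplicative site effects (EB-shrunk)
    gamma_bar: np.ndarray        # per-site prior means
    tau_sq: np.ndarray           # per-site prior variances
    alpha_hat: np.ndarray        # grand mean per connection
    beta_hat: np.ndarray         # covariate coefficients x n_fc
    var_pooled: np.ndarray       # n_fc
    covariate_names: list[str]
    kept: np.ndarray             # mask of non-constant connections actually adjusted


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_sol(sdat: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-8, max_iter: int = 5000) -> tuple[np.ndarray, np.ndarray]:
    """EB iteration for one site: alternate posterior gamma and delta updates."""
    n = np.full(g_hat.size, sdat.shape[0], dtype=float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                         np.max(np.abs(d_new - d_old) / np.abs(d_old)))
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _build_covariates(pheno: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Numeric covariate design; categoricals dummy-coded, missing numerics
    mean-imputed within site with a missing-indicator column."""
    cols, names = [], []
    for cov in covariates:
        col = pheno[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float)); names.append(c)
        else:
            vals = col.to_numpy(dtype=float)
            if np.isnan(vals).any():
                miss = np.isnan(vals).astype(float)
                filled = vals.copy()
                for s in pheno["site"].unique():
                    mask = (pheno["site"] == s).to_numpy()
                    site_vals = vals[mask]
                    fill = np.nanmean(site_vals) if np.isfinite(np.nanmean(site_vals)) else 0.0
                    filled[mask & np.isnan(vals)] = fill
                cols.append(filled); names.append(cov)
                cols.append(miss); names.append(cov + "_missing")
            else:
                cols.append(vals); names.append(cov)
    if not cols:
        return np.empty((len(pheno), 0)), []
    return np.column_stack(cols), names


def combat_fit_transform(data: MultiSiteDataset,
                         covariates: Sequence[str] = ("diagnosis", "bdi", "age", "sex"),
                         ) -> tuple[MultiSiteDataset, CombatParams]:
    """Parametric empirical-Bayes ComBat; covariate-associated variance preserved.

    Constant (zero-variance) connections are returned untouched with a
    warning recorded in ``CombatParams.kept``.
    """
    sites = sorted(set(data.site))
    if len(sites) < 2:
        raise ValueError("ComBat needs at least 2 sites")
    site_masks = {s: data.site == s for s in sites}
    for s, mask in site_masks.items():
        if mask.sum() < 2:
            raise ValueError(f"site {s!r} has fewer than 2 participants")

    x = data.connectivity.T.copy()  # n_fc x n
    n_fc, n = x.shape
    kept = x.var(axis=1) > 0
    work = x[kept]

    batch = np.column_stack([site_masks[s].astype(float) for s in sites])
    n_per_site = batch.sum(axis=0)
    covs, cov_names = _build_covariates(data.phenotypes, covariates)
    design = np.column_stack([batch, covs])

    b_hat, *_ = np.linalg.lstsq(design, work.T, rcond=None)
    grand_mean = (n_per_site / n) @ b_hat[:len(sites)]
    var_pooled = ((work - (design @ b_hat).T) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[:, None] + (covs @ b_hat[len(sites):]).T if covs.size \
        else np.tile(grand_mean[:, None], (1, n))
    s_data = (work - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.empty((len(sites), work.shape[0]))
    delta_hat = np.empty_like(gamma_hat)
    for k, s in enumerate(sites):
        sub = s_data[:, site_masks[s]]
        gamma_hat[k] = sub.mean(axis=1)
        delta_hat[k] = sub.var(axis=1, ddof=1)
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for k, s in enumerate(sites):
        a, b = _aprior(delta_hat[k]), _bprior(delta_hat[k])
        g, d = _it_sol(s_data[:, site_masks[s]].T, gamma_hat[k], delta_hat[k],
                       gamma_bar[k], tau_sq[k], a, b)
        gamma_star[k], delta_star[k] = g, d

    adjusted = s_data.copy()
    for k, s in enumerate(sites):
        mask = site_masks[s]
        adjusted[:, mask] = (s_data[:, mask] - gamma_star[k][:, None]) / np.sqrt(delta_star[k])[:, None]
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean

    out = x.copy()
    out[kept] = adjusted
    harmonized = replace(data, connectivity=out.T, phenotypes=data.phenotypes.copy())
    params = CombatParams(sites=sites, gamma_star=_expand(gamma_star, kept, n_fc),
                          delta_star=_expand(delta_star, kept, n_fc, fill=1.0),
                          gamma_bar=gamma_bar, tau_sq=tau_sq,
                          alpha_hat=_expand_vec(grand_mean, kept, n_fc),
                          beta_hat=b_hat[len(sites):],
                          var_pooled=_expand_vec(var_pooled, kept, n_fc),
                          covariate_names=cov_names, kept=kept)
    return harmonized, params


def _expand(arr: np.ndarray, kept: np.ndarray, n_fc: int, fill: float = 0.0) -> np.ndarray:
    out = np.full((arr.shape[0], n_fc), fill)
    out[:, kept] = arr
    return out


def _expand_vec(vec: np.ndarray, kept: np.ndarray, n_fc: int, fill: float = 0.0) -> np.ndarray:
    out = np.full(n_fc, fill)
    out[kept] = vec
    return out
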