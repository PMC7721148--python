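"""Synthetic multi-site connectivity data with known ground truth.

The generator emulates the generative structure assumed by the
traveling-subject harmonization model: every connection of every scan is

    const + m[site] + s_hc/s_mdd[site] + d * 1{MDD} + (p[traveler]) + noise

where ``m`` is an additive site-specific measurement bias, ``s_hc``/``s_mdd``
are site-specific sampling biases for the healthy-control and patient
populations, ``d`` is a sparse disorder effect supported on a small subset
of connections, ``p`` is a per-traveler offset (traveling-subject scans
only), and the noise is i.i.d. Gaussian.  All site-level effects are
centered across sites (and ``p`` across travelers) so the sum-to-zero
identifiability constraints of the estimator hold exactly in the truth.

Default effect scales encode the empirical ordering that measurement bias
dominates the disorder effect (bias SD twice the disorder-effect SD), and
the default disorder support is 25 connections with a 19 negative / 6
positive sign split — the under-/over-connectivity ratio reported for the
depression marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruthConfig",
    "SiteConfig",
    "GroundTruthEffects",
    "MultiSiteDataset",
    "TravelingSubjectDataset",
    "generate_ground_truth",
    "generate_multisite_dataset",
    "generate_traveling_dataset",
    "generate_true_probabilities",
    "default_site_configs",
]


@dataclass
class GroundTruthConfig:
    """Scales and shapes of the planted effects.

    ``disorder_sd`` sets the per-connection SD of the disorder effect on its
    support; measurement and sampling bias SDs default to 2x and 1x that
    scale.  ``noise_sd`` is the residual scan noise (gamma^-1/2 in the
    precision parameterisation).
    """

    n_fc: int = 200
    n_sites: int = 4
    n_travelers: int = 9
    disorder_support: int = 25
    n_negative: int | None = 19  # sign split on the support; None = random signs
    disorder_sd: float = 0.1
    measurement_sd: float = 0.2
    sampling_sd: float = 0.1
    participant_sd: float = 0.1
    noise_sd: float = 0.1
    const_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_fc < 1 or self.n_sites < 2 or self.n_travelers < 2:
            raise ValueError("need n_fc >= 1, n_sites >= 2, n_travelers >= 2")
        if not (0 <= self.disorder_support <= self.n_fc):
            raise ValueError("disorder support must lie in [0, n_fc]")
        if self.n_negative is not None:
            if self.n_negative < 0:
                raise ValueError("n_negative must be non-negative")
            self.n_negative = min(self.n_negative, self.disorder_support)
        if min(self.disorder_sd, self.measurement_sd, self.sampling_sd,
               self.participant_sd, self.noise_sd, self.const_sd) < 0:
            raise ValueError("scales must be non-negative")


@dataclass
class SiteConfig:
    """Per-site sample sizes and demographics."""

    n_hc: int
    n_mdd: int
    age_mean_hc: float = 45.0
    age_mean_mdd: float = 45.0
    age_sd: float = 12.0
    frac_female: float = 0.5

    def __post_init__(self) -> None:
        if self.n_hc < 0 or self.n_mdd < 0:
            raise ValueError("group sizes must be non-negative")
        if not (0.0 <= self.frac_female <= 1.0):
            raise ValueError("frac_female must be in [0, 1]")


def default_site_configs(n_sites: int, n_hc_per_site: int = 100, n_mdd_per_site: int = 30,
                         age_offset_mdd: float = 0.0) -> list[SiteConfig]:
    """Imbalanced HC-heavy sites with slightly staggered age distributions."""
    return [
        SiteConfig(n_hc=n_hc_per_site, n_mdd=n_mdd_per_site,
                   age_mean_hc=40.0 + 3.0 * k,
                   age_mean_mdd=40.0 + 3.0 * k + age_offset_mdd)
        for k in range(n_sites)
    ]


@dataclass
class GroundTruthEffects:
    """True effect parameters; all sum-to-zero constraints hold exactly."""

    m: np.ndarray            # sites x n_fc measurement bias
    s_hc: np.ndarray         # sites x n_fc HC sampling bias
    s_mdd: np.ndarray        # sites x n_fc MDD sampling bias
    d: np.ndarray            # n_fc disorder effect, sparse support
    p: np.ndarray            # travelers x n_fc participant factors
    const: np.ndarray        # n_fc baseline
    noise_sd: float
    support: np.ndarray      # indices where d may be nonzero

    @property
    def n_fc(self) -> int:
        return self.d.size

    @property
    def n_sites(self) -> int:
        return self.m.shape[0]


@dataclass
class MultiSiteDataset:
    """Participants x connections with per-participant phenotypes.

    ``connectivity`` is Fisher-z valued; ``phenotypes`` is a DataFrame with
    columns participant_id, site, diagnosis (HC/MDD), age, sex, bdi and
    medication flags, aligned row-for-row with ``connectivity``.
    """

    connectivity: np.ndarray
    phenotypes: pd.DataFrame
    n_regions: int | None = None

    def __post_init__(self) -> None:
        self.connectivity = np.asarray(self.connectivity, dtype=float)
        if self.connectivity.shape[0] != len(self.phenotypes):
            raise ValueError("connectivity rows must match phenotype rows")
        bad = set(self.phenotypes["diagnosis"].unique()) - {"HC", "MDD"}
        if bad:
            raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")

    @property
    def n_participants(self) -> int:
        return self.connectivity.shape[0]

    @property
    def n_fc(self) -> int:
        return self.connectivity.shape[1]

    @property
    def site(self) -> np.ndarray:
        return self.phenotypes["site"].to_numpy()

    @property
    def diagnosis(self) -> np.ndarray:
        return self.phenotypes["diagnosis"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        """Binary labels: MDD = 1, HC = 0."""
        return (self.diagnosis == "MDD").astype(int)

    @property
    def age(self) -> np.ndarray:
        return self.phenotypes["age"].to_numpy(dtype=float)


@dataclass
class TravelingSubjectDataset:
    """Repeated scans of the same travelers at every site."""

    connectivity: np.ndarray
    scans: pd.DataFrame  # columns: subject, site, scan_index
    n_regions: int | None = None

    def __post_init__(self) -> None:
        self.connectivity = np.asarray(self.connectivity, dtype=float)
        if self.connectivity.shape[0] != len(self.scans):
            raise ValueError("connectivity rows must match scan rows")
        per_subj_sites = self.scans.groupby("subject")["site"].nunique()
        if (per_subj_sites < 2).any():
            raise ValueError("every traveler must be scanned at >= 2 sites")

    @property
    def subject(self) -> np.ndarray:
        return self.scans["subject"].to_numpy()

    @property
    def site(self) -> np.ndarray:
        return self.scans["site"].to_numpy()


def _centered_normal(rng: np.ndarray, sd: float, shape: tuple[int, int]) -> np.ndarray:
    draws = rng.normal(0.0, sd, size=shape) if sd > 0 else np.zeros(shape)
    return draws - draws.mean(axis=0, keepdims=True)


def generate_ground_truth(config: GroundTruthConfig | None = None, seed: int = 0) -> GroundTruthEffects:
    """Draw all planted effects; centering enforces the constraints exactly."""
    cfg = config or GroundTruthConfig()
    rng = np.random.default_rng(seed)
    m = _centered_normal(rng, cfg.measurement_sd, (cfg.n_sites, cfg.n_fc))
    s_hc = _centered_normal(rng, cfg.sampling_sd, (cfg.n_sites, cfg.n_fc))
    s_mdd = _centered_normal(rng, cfg.sampling_sd, (cfg.n_sites, cfg.n_fc))
    p = _centered_normal(rng, cfg.participant_sd, (cfg.n_travelers, cfg.n_fc))
    const = rng.normal(0.0, cfg.const_sd, size=cfg.n_fc)

    d = np.zeros(cfg.n_fc)
    support = rng.choice(cfg.n_fc, size=cfg.disorder_support, replace=False)
    support.sort()
    if cfg.disorder_support:
        mag = np.abs(rng.normal(0.0, cfg.disorder_sd, size=cfg.disorder_support))
        mag = np.maximum(mag, 0.25 * cfg.disorder_sd)  # keep the support detectable
        if cfg.n_negative is None:
            signs = rng.choice([-1.0, 1.0], size=cfg.disorder_support)
        else:
            signs = np.ones(cfg.disorder_support)
            neg = rng.choice(cfg.disorder_support, size=cfg.n_negative, replace=False)
            signs[neg] = -1.0
        d[support] = signs * mag
    return GroundTruthEffects(m=m, s_hc=s_hc, s_mdd=s_mdd, d=d, p=p,
                              const=const, noise_sd=cfg.noise_sd, support=support)


def generate_multisite_dataset(gt: GroundTruthEffects,
                               site_configs: list[SiteConfig] | None = None,
                               seed: int = 0) -> MultiSiteDataset:
    """Simulate the study cohort forward from the ground-truth model.

    Each participant's connectivity row is const + m[site] + s[site, group]
    + d (patients only) + N(0, noise_sd).  Ages are drawn from per-site,
    per-group normals truncated to [18, 80]; BDI scores are generated so
    that patients score high (mean 25) and controls low (mean 5), with a
    small missingness rate, and medication flags are random in patients.
    """
    cfgs = site_configs or default_site_configs(gt.n_sites)
    if len(cfgs) != gt.n_sites:
        raise ValueError("one SiteConfig per ground-truth site required")
    rng = np.random.default_rng(seed)
    rows, pheno = [], []
    pid = 0
    for k, cfg in enumerate(cfgs):
        for diag, n, age_mean in (("HC", cfg.n_hc, cfg.age_mean_hc),
                                  ("MDD", cfg.n_mdd, cfg.age_mean_mdd)):
            s_term = gt.s_hc[k] if diag == "HC" else gt.s_mdd[k]
            d_term = gt.d if diag == "MDD" else 0.0
            base = gt.const + gt.m[k] + s_term + d_term
            for _ in range(n):
                noise = rng.normal(0.0, gt.noise_sd, size=gt.n_fc) if gt.noise_sd > 0 else 0.0
                rows.append(base + noise)
                age = float(np.clip(rng.normal(age_mean, cfg.age_sd), 18.0, 80.0))
                bdi_mean = 25.0 if diag == "MDD" else 5.0
                bdi = float(np.clip(rng.normal(bdi_mean, 7.0), 0, 63))
                if rng.random() < 0.05:
                    bdi = np.nan
                pheno.append({
                    "participant_id": f"sub-{pid:04d}",
                    "site": f"site{k}",
                    "diagnosis": diag,
                    "age": age,
                    "sex": "F" if rng.random() < cfg.frac_female else "M",
                    "bdi": bdi,
                    "antidepressant": int(diag == "MDD" and rng.random() < 0.7),
                    "anxiolytic": int(diag == "MDD" and rng.random() < 0.4),
                })
                pid += 1
    return MultiSiteDataset(connectivity=np.asarray(rows), phenotypes=pd.DataFrame(pheno))


def generate_traveling_dataset(gt: GroundTruthEffects, scans_per_site: int = 3,
                               seed: int = 0) -> TravelingSubjectDataset:
    """Simulate travelers scanned ``scans_per_site`` times at every site."""
    if gt.n_sites < 2:
        raise ValueError("traveling-subject design needs >= 2 sites")
    if scans_per_site < 1:
        raise ValueError("scans_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    for j in range(gt.p.shape[0]):
        for k in range(gt.n_sites):
            for rep in range(scans_per_site):
                noise = rng.normal(0.0, gt.noise_sd, size=gt.n_fc) if gt.noise_sd > 0 else 0.0
                rows.append(gt.const + gt.m[k] + gt.p[j] + noise)
                meta.append({"subject": f"trav-{j:02d}", "site": f"site{k}", "scan_index": rep})
    return TravelingSubjectDataset(connectivity=np.asarray(rows), scans=pd.DataFrame(meta))


def generate_true_probabilities(n: int = 1000, seed: int = 0,
                                weights: tuple[float, float] = (0.65, 0.35),
                                alpha: tuple[float, float] = (2.0, 6.0),
                                beta: tuple[float, float] = (6.0, 2.0),
                                point_mass: float | None = None) -> np.ndarray:
    """Surrogate "true" diagnostic probabilities in (0, 1).

    A two-component Beta mixture with one mode below 0.5 (control-like
    outputs) and one above (patient-like), standing in for the ensemble
    classifier's real outputs.  ``point_mass`` overrides the mixture with a
    degenerate distribution (useful for boundary checks).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if point_mass is not None:
        if not (0.0 < point_mass < 1.0):
            raise ValueError("point_mass must lie strictly in (0, 1)")
        return np.full(n, float(point_mass))
    w = np.asarray(weights, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise ValueError("mixture weights must be non-negative and not all zero")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < w[1]
    out = np.where(comp,
                   rng.beta(alpha[1], beta[1], size=n),
                   rng.beta(alpha[0], beta[0], size=n))
    return np.clip(out, 1e-9, 1.0 - 1e-9)
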