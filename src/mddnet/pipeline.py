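"""End-to-end pipeline driver and its configuration.

``run_pipeline`` wires the stages together on synthetic or loaded data:
harmonize (traveling-subject regression) -> train the nested-CV ensemble ->
score held-out discovery predictions -> apply to a validation cohort ->
selection-count importance.  Every artifact embeds the seed and a config
hash so a run is reproducible from the bundle alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify, evaluate, harmonize, importance, synth

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Numeric defaults mirror the study design: 10 outer folds, 10
    subsamples, 25 lambda values, 0.5 decision threshold, alpha 0.05,
    100 permutations, 1000 bootstrap replicates."""

    seed: int = 0
    outer_folds: int = 10
    subsamples: int = 10
    n_lambda: int = 25
    k_inner: int = 10
    threshold: float = 0.5
    alpha: float = 0.05
    n_perm: int = 100
    n_boot: int = 1000
    undersample_cap: int = 125
    age_tolerance: float = 1.0
    # synthetic-data settings (used when no input paths are given)
    n_fc: int = 200
    n_sites: int = 4
    n_hc_per_site: int = 100
    n_mdd_per_site: int = 30
    scans_per_site: int = 3
    run_importance: bool = True
    importance_n_perm: int = 0  # 0 = skip the permutation null (report counts only)

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 study: synth.MultiSiteDataset | None = None,
                 travelers: synth.TravelingSubjectDataset | None = None,
                 validation: synth.MultiSiteDataset | None = None) -> dict:
    """Run harmonize -> train -> evaluate -> (validate) -> importance.

    When no datasets are supplied, synthetic ones are generated from the
    config, so the pipeline is exercisable end-to-end without downloads.
    Returns the results bundle; writes ``metrics.json`` when ``out_dir``
    is given.
    """
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    bundle: dict = {"config": asdict(config), "config_hash": config.hash(),
                    "seed": config.seed, "stages": {}}

    if study is None:
        gt = synth.generate_ground_truth(
            synth.GroundTruthConfig(n_fc=config.n_fc, n_sites=config.n_sites),
            seed=int(rng.integers(2 ** 31)))
        sites = synth.default_site_configs(config.n_sites, config.n_hc_per_site,
                                           config.n_mdd_per_site)
        study = synth.generate_multisite_dataset(gt, sites, seed=int(rng.integers(2 ** 31)))
        travelers = synth.generate_traveling_dataset(gt, config.scans_per_site,
                                                     seed=int(rng.integers(2 ** 31)))
        validation = synth.generate_multisite_dataset(gt, sites, seed=int(rng.integers(2 ** 31)))
        bundle["stages"]["simulate"] = {"n_fc": study.n_fc,
                                        "n_participants": study.n_participants}

    if travelers is not None:
        est = harmonize.fit_traveling_subject_model(study, travelers)
        study = harmonize.subtract_measurement_bias(study, est)
        bundle["stages"]["harmonize"] = {"method": "traveling-subject",
                                         "sites": est.sites}

    ens = classify.train_ensemble(study, outer_folds=config.outer_folds,
                                  subsamples=config.subsamples, seed=int(rng.integers(2 ** 31)),
                                  n_lambda=config.n_lambda, k_inner=config.k_inner,
                                  undersample_cap=config.undersample_cap,
                                  age_tolerance=config.age_tolerance)
    disc = evaluate.confusion_metrics(study.y, ens.cv_probabilities, config.threshold)
    bundle["stages"]["train"] = {"n_models": ens.n_models}
    bundle["stages"]["discovery_cv"] = disc.as_dict()

    if validation is not None:
        prob = classify.predict_probability(ens, validation.connectivity)
        val = evaluate.confusion_metrics(validation.y, prob, config.threshold)
        bundle["stages"]["validation"] = val.as_dict()

    if config.run_importance:
        counts = importance.selection_counts(ens)
        t = importance.effect_size_t(study)
        imp: dict = {"max_count": int(counts.max()),
                     "n_selected_ge_1": int((counts >= 1).sum())}
        if config.importance_n_perm > 0:
            res = importance.importance_threshold_null(
                study, n_perm=config.importance_n_perm, seed=int(rng.integers(2 ** 31)),
                alpha=config.alpha, outer_folds=config.outer_folds,
                subsamples=config.subsamples, n_lambda=config.n_lambda,
                k_inner=config.k_inner, undersample_cap=config.undersample_cap,
                age_tolerance=config.age_tolerance)
            table = importance.describe_important_fcs(res.important_indices,
                                                      t.t_values, counts=res.counts)
            imp.update({"threshold": res.threshold,
                        "n_important": int(res.important_indices.size),
                        "important": table.to_dict(orient="records")})
        bundle["stages"]["importance"] = imp

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        # the written bundle is byte-reproducible under a fixed config/seed
        (out_dir / "metrics.json").write_text(json.dumps(bundle, indent=2, default=_jsonify))
    bundle["elapsed_s"] = round(time.time() - t0, 2)
    return bundle


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
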