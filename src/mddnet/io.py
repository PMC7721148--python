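"""Dataset readers/writers: TSV tables with a JSON sidecar.

A connectivity dataset is a TSV with the phenotype columns first
(participant_id, site, diagnosis, age, sex, bdi, ...) followed by one
``fc_<k>`` column per lower-triangle pair index, plus a ``<name>.json``
sidecar recording ``n_regions``, the pair-index convention and any
generation metadata.  Traveling-subject data use columns subject, site,
scan_index instead of phenotypes.  Missing BDI cells stay missing (NaN).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import PAIR_CONVENTION, lower_triangle_size
from .synth import MultiSiteDataset, TravelingSubjectDataset

__all__ = [
    "save_multisite_dataset",
    "load_multisite_dataset",
    "save_traveling_dataset",
    "load_traveling_dataset",
]

_PHENO_COLS = ["participant_id", "site", "diagnosis", "age", "sex", "bdi",
               "antidepressant", "anxiolytic"]


def _fc_columns(n_fc: int) -> list[str]:
    return [f"fc_{k}" for k in range(n_fc)]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _check_sidecar(meta: dict, n_fc: int) -> None:
    n_regions = meta.get("n_regions")
    if n_regions is not None and lower_triangle_size(n_regions) != n_fc:
        raise ValueError(
            f"sidecar n_regions={n_regions} requires {lower_triangle_size(n_regions)} "
            f"connectivity columns, found {n_fc}"
        )


def save_multisite_dataset(data: MultiSiteDataset, path: str | Path,
                           metadata: dict | None = None) -> None:
    path = Path(path)
    pheno_cols = [c for c in data.phenotypes.columns]
    table = data.phenotypes.copy()
    fc = pd.DataFrame(data.connectivity, columns=_fc_columns(data.n_fc), index=table.index)
    pd.concat([table, fc], axis=1).to_csv(path, sep="\t", index=False)
    meta = {"n_regions": data.n_regions, "n_fc": data.n_fc,
            "pair_index_convention": PAIR_CONVENTION,
            "phenotype_columns": pheno_cols}
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_multisite_dataset(path: str | Path) -> MultiSiteDataset:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    table = pd.read_csv(path, sep="\t")
    fc_cols = [c for c in table.columns if c.startswith("fc_")]
    _check_sidecar(meta, len(fc_cols))
    pheno = table[[c for c in table.columns if not c.startswith("fc_")]].copy()
    bad = set(pheno["diagnosis"].unique()) - {"HC", "MDD"}
    if bad:
        raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
    return MultiSiteDataset(connectivity=table[fc_cols].to_numpy(dtype=float),
                            phenotypes=pheno, n_regions=meta.get("n_regions"))


def save_traveling_dataset(data: TravelingSubjectDataset, path: str | Path,
                           metadata: dict | None = None) -> None:
    path = Path(path)
    fc = pd.DataFrame(data.connectivity, columns=_fc_columns(data.connectivity.shape[1]),
                      index=data.scans.index)
    pd.concat([data.scans, fc], axis=1).to_csv(path, sep="\t", index=False)
    meta = {"n_regions": data.n_regions, "n_fc": int(data.connectivity.shape[1]),
            "pair_index_convention": PAIR_CONVENTION}
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_traveling_dataset(path: str | Path) -> TravelingSubjectDataset:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    table = pd.read_csv(path, sep="\t")
    fc_cols = [c for c in table.columns if c.startswith("fc_")]
    _check_sidecar(meta, len(fc_cols))
    scans = table[[c for c in table.columns if not c.startswith("fc_")]].copy()
    return TravelingSubjectDataset(connectivity=table[fc_cols].to_numpy(dtype=float),
                                   scans=scans, n_regions=meta.get("n_regions"))
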