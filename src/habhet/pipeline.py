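"""End-to-end orchestration: case processing and cohort-level analysis.

Per case: normalize the resampled stack, derive the peritumoral bands,
encode each region into K habitats, extract the 428-feature table per
region, and reduce to the 1712-entry heterogeneity vector (plus the
428-entry whole-tumor "Rad" baseline). Per cohort: assemble matrices, run
the staged selection and the classifier suite on both feature subsets, and
produce the survival stratification report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import habitats as hab
from . import modeling, radiomics, survival
from .batch import extract_per_habitat_fast
from .heterogeneity import heterogeneity_vector, stability_analysis
from .io import VolumeStack, load_case, normalize_stack, read_manifest
from .regions import DEFAULT_DISTANCES, make_peritumoral_bands

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline constants; defaults follow the published workflow."""

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    band_distances: tuple[float, ...] = DEFAULT_DISTANCES
    K: int = hab.DEFAULT_K
    compactness: float = hab.DEFAULT_COMPACTNESS
    bin_width: float = radiomics.DEFAULT_BIN_WIDTH
    icc_threshold: float = modeling.ICC_THRESHOLD
    alpha: float = modeling.ALPHA
    top_k: int = modeling.TOP_K
    split_ratio: float = 0.7
    taus: tuple[float, ...] = survival.DEFAULT_TAUS
    algorithms: tuple[str, ...] = modeling.ALGORITHMS
    seed: int = hab.DEFAULT_SEED

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def process_case(
    stack: VolumeStack,
    tumor: np.ndarray,
    config: PipelineConfig | None = None,
    K: int | None = None,
    fast: bool = True,
) -> dict:
    """Run the per-case stages on an already-resampled stack.

    Returns habitat feature tables per region, the 1712-entry heterogeneity
    vector (``th``), and the 428-entry whole-tumor baseline (``rad``).
    ``fast`` selects the batched extraction path (identical output to the
    per-ROI reference path, which remains available for cross-checking).
    """
    cfg = config or PipelineConfig()
    K = K if K is not None else cfg.K
    norm = normalize_stack(stack)
    regions = make_peritumoral_bands(tumor, stack.spacing, cfg.band_distances)
    extract = extract_per_habitat_fast if fast else radiomics.extract_per_habitat
    tables: dict[str, pd.DataFrame] = {}
    maps: dict[str, hab.HabitatMap] = {}
    for name, mask in regions.regions().items():
        hm = hab.encode_habitats(norm, mask, K=K, compactness=cfg.compactness,
                                 seed=cfg.seed, region_name=name)
        maps[name] = hm
        tables[name] = extract(norm, hm, cfg.bin_width)
    th = heterogeneity_vector(tables)
    rad = radiomics.extract_whole_region(norm, regions.tumor, cfg.bin_width)
    return {"regions": regions, "habitat_maps": maps, "tables": tables,
            "th": th, "rad": rad}


def cohort_matrices(
    cases: list[dict],
    config: PipelineConfig | None = None,
    mask_key: str = "tumor_obs1",
    K: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TH (1712-col) and Rad (428-col) matrices for in-memory phantom cases."""
    th_rows, rad_rows, ids = [], [], []
    for case in cases:
        res = process_case(case["stack"], case["masks"][mask_key], config, K=K)
        th_rows.append(res["th"])
        rad_rows.append(res["rad"])
        ids.append(case["case_id"])
    th = pd.DataFrame(th_rows, index=pd.Index(ids, name="case_id"))
    rad = pd.DataFrame(rad_rows, index=pd.Index(ids, name="case_id"))
    return th, rad


def model_cohort(
    features: pd.DataFrame,
    labels: pd.Series,
    config: PipelineConfig | None = None,
    rating_sets: dict | None = None,
    seed: int = 0,
) -> dict:
    """Split, select, fit the suite, and evaluate both splits."""
    cfg = config or PipelineConfig()
    split = modeling.stratified_split(labels, cfg.split_ratio, seed)
    tr, te = split == "train", split == "test"
    report = modeling.select_features(
        features[tr], labels[tr], rating_sets=rating_sets,
        icc_threshold=cfg.icc_threshold, alpha=cfg.alpha, top_k=cfg.top_k, seed=seed)
    if not report.retained:
        raise ValueError("no features survived selection")
    suite = modeling.ModelSuite(report.retained, seed=seed,
                                algorithms=cfg.algorithms)
    suite.fit(features[tr], labels[tr])
    evals = {}
    for algo in cfg.algorithms:
        evals[algo] = {
            "train": modeling.evaluate(suite, algo, features[tr], labels[tr]),
            "test": modeling.evaluate(suite, algo, features[te], labels[te]),
        }
    return {"split": split, "selection": report, "suite": suite, "evaluations": evals}


def crossval_auc(
    features: pd.DataFrame,
    labels: pd.Series,
    algo: str = "DNN",
    n_splits: int = 5,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> float:
    """Pooled out-of-fold test AUC with selection redone inside each fold.

    Stratified K-fold; the staged feature selection, imputation and
    standardization are fitted on each training fold only, so the pooled
    predictions are leakage-free. Preferred over a single split for small
    simulated cohorts, where a 30% holdout holds only a couple of positives.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    cfg = config or PipelineConfig()
    y = pd.Series(labels).astype(int)
    oof = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        f_tr = features.iloc[tr_idx]
        report = modeling.select_features(
            f_tr, y.iloc[tr_idx], icc_threshold=cfg.icc_threshold,
            alpha=cfg.alpha, top_k=cfg.top_k, seed=seed)
        if not report.retained:
            oof[te_idx] = 0.5
            continue
        suite = modeling.ModelSuite(report.retained, seed=seed, algorithms=(algo,))
        suite.fit(f_tr, y.iloc[tr_idx])
        oof[te_idx] = suite.predict_proba(algo, features.iloc[te_idx])
    return float(roc_auc_score(y, oof))


def stability_report(
    cases: list[dict],
    K_list: tuple[int, ...] = (30, 40, 50, 60, 70),
    features: list[str] | None = None,
    config: PipelineConfig | None = None,
) -> pd.Series:
    """ICC(2,1) of heterogeneity features across habitat-count settings."""
    vectors = {}
    for K in K_list:
        th, _ = cohort_matrices(cases, config, K=K)
        vectors[K] = th
    return stability_analysis(vectors, features)


def run_pipeline_from_manifest(
    manifest_path: str | Path,
    cohort_csv: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """File-based end-to-end run: manifest + cohort table -> report directory."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = read_manifest(manifest_path)
    cohort = pd.read_csv(cohort_csv).set_index("case_id")

    th_rows, rad_rows, ids = [], [], []
    for entry in entries:
        stack, tumor = load_case(entry["sequences"],
                                 entry["masks"]["tumor_obs1"],
                                 case_id=entry["case_id"],
                                 target_spacing=cfg.target_spacing)
        res = process_case(stack, tumor, cfg)
        th_rows.append(res["th"])
        rad_rows.append(res["rad"])
        ids.append(entry["case_id"])
        logger.info("processed %s", entry["case_id"])
    th = pd.DataFrame(th_rows, index=pd.Index(ids, name="case_id"))
    rad = pd.DataFrame(rad_rows, index=pd.Index(ids, name="case_id"))
    th.to_csv(out / "heterogeneity_matrix.csv")
    rad.to_csv(out / "rad_matrix.csv")

    labels = cohort.loc[th.index, "label"]
    results = {}
    for name, feats in (("TH", th), ("Rad", rad)):
        res = model_cohort(feats, labels, cfg, seed=cfg.seed)
        results[name] = {
            "selection": res["selection"].to_dict(),
            "metrics": {a: {s: r.to_dict() for s, r in d.items()}
                        for a, d in res["evaluations"].items()},
        }
    report = {"n_cases": len(ids), "config": {"K": cfg.K}, "models": results}

    if {"time_rfs", "event_rfs"} <= set(cohort.columns):
        rec = cohort.loc[th.index].rename(
            columns={"time_rfs": "time", "event_rfs": "event"})
        report["survival_rfs"] = survival.survival_report(rec, "label", cfg.taus)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
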