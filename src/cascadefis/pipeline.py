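"""Validated run configuration and the end-to-end pipeline.

``RunConfig`` is the single document that pins every stage of a run:
synthetic dataset parameters, descriptor configuration, reducer, cascade
training, codec strategy and metrics.  All randomness funnels through one
run seed.  ``run_pipeline`` executes simulate -> extract -> reduce -> train
-> evaluate (optionally k-fold cross-validation) and returns the metrics
report plus the intermediate artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time

import numpy as np
from pydantic import BaseModel, Field

from . import imgfeat, metrics, synthgen
from .cascade import CascadeConfig, CascadedAnfis, train_cascade
from .dimreduce import GroupReducer
from .imgfeat import FeatureConfig
from .metrics import MetricsConfig, MetricsReport

__all__ = ["RunConfig", "run_pipeline", "crossval_pipeline"]

logger = logging.getLogger("cascadefis")


class SimulateSection(BaseModel):
    n_classes: int = Field(8, ge=2)
    per_class: int = Field(100, ge=4)
    train_fraction: float = Field(0.7, gt=0, lt=1)
    separability: float = Field(1.0, gt=0, le=1)


class FeatureSection(BaseModel):
    cs_bins: int = 64
    cs_window: int = Field(8, ge=2)
    eh_grid: int = Field(4, ge=1)
    eh_threshold: float = Field(11.0, ge=0)
    hog_cell: int = Field(10, ge=2)
    hog_block: int = Field(2, ge=1)
    hog_orientations: int = Field(9, ge=2)
    glcm_levels: int = Field(8, ge=2)
    glcm_distance: int = Field(1, ge=1)
    n_keypoints: int = Field(100, ge=10)
    color_layout_variant: str = "cld"

    def to_feature_config(self) -> FeatureConfig:
        return FeatureConfig(**self.model_dump())


class ReducerSection(BaseModel):
    method: str = Field("ICA", pattern="^(ICA|PCA)$")
    n_components: int = Field(9, ge=1)


class CascadeSection(BaseModel):
    mfs_per_input: int = Field(2, ge=2)
    epochs: int = Field(1, ge=1)
    premise_lr: float = Field(0.01, gt=0)
    lse_ridge: float = Field(1e-8, ge=0)
    strategy: str = Field("one-vs-rest",
                          pattern="^(index-regression|one-vs-rest)$")
    kary_groups: bool = False
    pair_selection: bool = False

    def to_cascade_config(self, seed: int) -> CascadeConfig:
        return CascadeConfig(seed=seed, **self.model_dump())


class MetricsSection(BaseModel):
    beta: float = Field(1.0, gt=0)
    zero_division_value: float = 0.0

    def to_metrics_config(self) -> MetricsConfig:
        return MetricsConfig(**self.model_dump())


class RunConfig(BaseModel):
    """Full pipeline configuration; validates before any computation."""

    simulate: SimulateSection = SimulateSection()
    features: FeatureSection = FeatureSection()
    reducer: ReducerSection = ReducerSection()
    cascade: CascadeSection = CascadeSection()
    metrics: MetricsSection = MetricsSection()
    cv_folds: int = Field(10, ge=2)
    log_level: str = "INFO"

    @classmethod
    def from_json_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-10s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: RunConfig, seed: int = 0,
                 return_artifacts: bool = False):
    """Simulate, extract, reduce, train and evaluate in one deterministic run.

    Returns the test-split :class:`MetricsReport`; with
    ``return_artifacts=True`` also a dict holding the dataset, raw and
    reduced feature tables, reducer and fitted cascade.
    """
    logger.info("run seed=%d config=%s", seed, config.config_hash())
    t0 = time.perf_counter()
    sim = config.simulate
    ds = synthgen.generate(sim.n_classes, sim.per_class,
                           train_fraction=sim.train_fraction, seed=seed,
                           separability=sim.separability)
    t0 = _stage("simulate", t0)

    fc = config.features.to_feature_config()
    train_imgs, y_train = ds.subset("train")
    test_imgs, y_test = ds.subset("test")
    raw_train = imgfeat.extract_tables(train_imgs, fc)
    raw_test = imgfeat.extract_tables(test_imgs, fc)
    t0 = _stage("extract", t0)

    reducer = GroupReducer(method=config.reducer.method,
                           n_components=config.reducer.n_components,
                           seed=seed).fit(raw_train)
    Z_train = reducer.transform(raw_train)
    Z_test = reducer.transform(raw_test)
    k = config.reducer.n_components
    grouped_train = [Z_train[:, g * k:(g + 1) * k]
                     for g in range(reducer.n_groups)]
    grouped_test = [Z_test[:, g * k:(g + 1) * k]
                    for g in range(reducer.n_groups)]
    t0 = _stage("reduce", t0)

    cascade_cfg = config.cascade.to_cascade_config(seed)
    results = CascadedAnfis(list(y_train), grouped_train).fit(cascade_cfg)
    t0 = _stage("train", t0)

    y_pred = results.predict(grouped_test)
    report = metrics.evaluate(list(y_test), y_pred,
                              classes=sorted(set(ds.labels.tolist())),
                              config=config.metrics.to_metrics_config())
    _stage("evaluate", t0)
    if not return_artifacts:
        return report
    return report, {
        "dataset": ds,
        "raw_train": raw_train, "raw_test": raw_test,
        "reducer": reducer,
        "grouped_train": grouped_train, "grouped_test": grouped_test,
        "y_train": y_train, "y_test": y_test,
        "cascade": results, "y_pred": y_pred,
    }


def crossval_pipeline(config: RunConfig, seed: int = 0,
                      artifacts: dict | None = None):
    """Stratified k-fold cross-validation of the cascade on the full
    (train + test) synthetic dataset.

    Features are extracted once; the reducer and cascade are re-fitted
    inside every fold on the fold's training portion only.  Returns
    ``(fold_accuracies, mean)``.
    """
    if artifacts is None:
        _, artifacts = run_pipeline(config, seed, return_artifacts=True)
    raw_all = [np.vstack([a, b]) for a, b in
               zip(artifacts["raw_train"], artifacts["raw_test"])]
    y_all = np.concatenate([artifacts["y_train"], artifacts["y_test"]])
    k = config.reducer.n_components
    cascade_cfg = config.cascade.to_cascade_config(seed)

    def trainer(train_idx):
        tables = [T[train_idx] for T in raw_all]
        reducer = GroupReducer(method=config.reducer.method,
                               n_components=k, seed=seed).fit(tables)
        Z = reducer.transform(tables)
        grouped = [Z[:, g * k:(g + 1) * k] for g in range(reducer.n_groups)]
        res, _, _ = train_cascade(grouped, list(y_all[train_idx]),
                                  cascade_cfg)
        return reducer, res

    def evaluator(model, test_idx):
        reducer, res = model
        Z = reducer.transform([T[test_idx] for T in raw_all])
        grouped = [Z[:, g * k:(g + 1) * k] for g in range(reducer.n_groups)]
        pred = res.predict(grouped)
        return float(np.mean([p == t for p, t in
                              zip(pred, y_all[test_idx])]))

    return metrics.kfold_cv(y_all, trainer, evaluator, k=config.cv_folds,
                            seed=seed)
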