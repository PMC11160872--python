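"""Bootstrapped classifier ensembles with per-sample uncertainty.

Each ensemble fits B base classifiers on independent bootstrap resamples
of the training rows. For a new sample the B predicted probabilities give
both the risk estimate (their mean) and its uncertainty (their sample
standard deviation) — the signal the staged deferral rule gates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from ._exceptions import ConfigError, DataError, SchemaError
from .preprocess import (
    FeaturePipeline,
    PipelineConfig,
    base_importances,
    make_base_learner,
)

__all__ = [
    "EnsembleConfig",
    "EnsembleModel",
    "PredictionDistribution",
    "fit_ensemble",
    "predict_distribution",
    "feature_importance",
]

_MAX_REDRAWS = 100


@dataclass
class EnsembleConfig:
    """Ensemble hyperparameters.

    ``sample_fraction`` is the fraction of training rows drawn *with
    replacement* for each base model; ``param_grid`` (optional) is tuned
    once by stratified inner CV on the training rows before the bootstrap
    models are fit.
    """

    n_base_models: int = 25
    sample_fraction: float = 0.8
    base_spec: str = "logistic"
    param_grid: dict | None = None
    inner_folds: int = 3
    bootstrap: bool = True
    stratified: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_base_models < 1:
            raise ConfigError("n_base_models must be >= 1")
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ConfigError("sample_fraction must lie in (0, 1]")
        if self.inner_folds < 2:
            raise ConfigError("inner_folds must be >= 2")


@dataclass
class PredictionDistribution:
    """Per-sample ensemble prediction distribution: the B base-model
    probabilities, their mean ``mu`` and sample standard deviation ``sd``
    (defined as 0 when B = 1)."""

    probs: np.ndarray  # (n_samples, B)
    mu: np.ndarray
    sd: np.ndarray

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "PredictionDistribution":
        probs = np.atleast_2d(np.asarray(probs, dtype=float))
        mu = probs.mean(axis=1)
        if probs.shape[1] > 1:
            sd = probs.std(axis=1, ddof=1)
        else:
            sd = np.zeros(probs.shape[0])
        return cls(probs=probs, mu=mu, sd=sd)

    def __len__(self) -> int:
        return self.probs.shape[0]

    def to_frame(self, ids=None) -> pd.DataFrame:
        frame = pd.DataFrame({"mu": self.mu, "sd": self.sd})
        frame["B"] = self.probs.shape[1]
        if ids is not None:
            frame.insert(0, "id", np.asarray(ids))
        return frame


@dataclass
class EnsembleModel:
    """B fitted base models plus the bound feature pipeline and the
    bootstrap index sets they were trained on."""

    base_models: list
    bootstrap_indices: list[np.ndarray]
    pipeline: FeaturePipeline
    config: EnsembleConfig
    best_params: dict | None = None
    n_features_in: int = 0
    prediction_calls: int = 0  # cumulative base-model predict invocations

    @property
    def n_base_models(self) -> int:
        return len(self.base_models)

    def save(self, path) -> None:
        """Serialize the whole bundle (config, pipeline, base models) to a
        single archive."""
        import joblib

        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        import joblib

        model = joblib.load(path)
        if not isinstance(model, cls):
            raise DataError(f"{path} does not contain an EnsembleModel")
        return model


def _bootstrap_draw(rng, y, size, stratified, max_redraws=_MAX_REDRAWS):
    n = len(y)
    if stratified:
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        k_pos = max(1, int(round(size * len(pos) / n)))
        idx = np.concatenate(
            [rng.choice(pos, size=k_pos, replace=True),
             rng.choice(neg, size=size - k_pos, replace=True)]
        )
        return idx
    for _ in range(max_redraws):
        idx = rng.integers(0, n, size=size)
        if len(np.unique(y[idx])) == 2:
            return idx
    raise DataError(
        "could not draw a bootstrap sample containing both classes "
        f"after {max_redraws} attempts"
    )


def fit_ensemble(
    X,
    y,
    config: EnsembleConfig,
    pipeline_config: PipelineConfig | None = None,
) -> EnsembleModel:
    """Fit the feature pipeline once on the training rows, tune base-learner
    hyperparameters by stratified inner CV if a grid is given, then fit B
    base models on independent bootstrap draws of round(f*n) rows."""
    config.validate()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("training labels contain a single class")

    pipeline = FeaturePipeline(pipeline_config)
    Z = pipeline.fit_transform(X, y)
    n = Z.shape[0]

    template = make_base_learner(config.base_spec)
    best_params = None
    if config.param_grid:
        search = GridSearchCV(
            clone(template),
            config.param_grid,
            cv=StratifiedKFold(
                n_splits=config.inner_folds, shuffle=True,
                random_state=config.seed,
            ),
            scoring="roc_auc",
        )
        search.fit(Z, y)
        best_params = search.best_params_
        template.set_params(**best_params)

    rng = np.random.default_rng(config.seed)
    size = int(round(config.sample_fraction * n))
    size = max(2, size)
    models, index_sets = [], []
    for b in range(config.n_base_models):
        if config.bootstrap:
            idx = _bootstrap_draw(rng, y, size, config.stratified)
        else:
            idx = np.arange(n)
        model = clone(template)
        if "random_state" in model.get_params():
            model.set_params(random_state=int(rng.integers(0, 2**31 - 1)))
        model.fit(Z[idx], y[idx])
        models.append(model)
        index_sets.append(idx)

    n_in = X.shape[1] if hasattr(X, "shape") else np.asarray(X).shape[1]
    return EnsembleModel(
        base_models=models,
        bootstrap_indices=index_sets,
        pipeline=pipeline,
        config=config,
        best_params=best_params,
        n_features_in=n_in,
    )


def predict_distribution(model: EnsembleModel, X) -> PredictionDistribution:
    """Per-sample B-vector of base-model probabilities with mean and sd.

    The bound pipeline is applied internally, so ``X`` lives in the
    original (pre-selection) feature space.
    """
    arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    if arr.ndim != 2 or arr.shape[1] != model.n_features_in:
        raise SchemaError(
            f"expected {model.n_features_in} feature columns, got "
            f"{arr.shape[1] if arr.ndim == 2 else 'non-2D input'}"
        )
    Z = model.pipeline.transform(X)
    probs = np.column_stack([m.predict_proba(Z)[:, 1] for m in model.base_models])
    model.prediction_calls += len(model.base_models) * Z.shape[0]
    return PredictionDistribution.from_probs(probs)


def feature_importance(model: EnsembleModel) -> pd.Series:
    """Ensemble-averaged absolute feature importance in the original
    feature space; features removed by selection score 0."""
    mask = model.pipeline.mask_
    kept_cols = model.pipeline.output_columns
    stacked = np.stack([base_importances(m) for m in model.base_models])
    mean_imp = np.abs(stacked).mean(axis=0)
    scores = pd.Series(0.0, index=mask.columns)
    scores[kept_cols] = mean_imp
    return scores
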