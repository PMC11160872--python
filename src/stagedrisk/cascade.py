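"""The uncertainty-gated staged (cascade) classifier.

A subject is first scored by the cheap Stage-1 ensemble. The prediction is
*retained* when it is both stable and decisive:

    retain at Stage 1  iff  sd <= sigma_thr  and  |mu - 0.5| > halfway_thr

Otherwise the subject cascades to the Stage-2 ensemble, which additionally
uses the expensive feature block. Stage-2 predictions are computed only
for cascaded rows — the whole point of the cascade is that the expensive
modality is acquired only when needed.

The two gate thresholds are tuned on a validation set by exhaustive grid
search over a *scaled weighted AUC*: the size-weighted mean of the AUC
among retained rows and the AUC among cascaded rows (a single-class subset
contributes its size with AUC 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from ._exceptions import ConfigError, DataError, SchemaError
from .ensemble import (
    EnsembleConfig,
    EnsembleModel,
    PredictionDistribution,
    fit_ensemble,
    predict_distribution,
)
from .preprocess import PipelineConfig

__all__ = [
    "STAGE1",
    "STAGE2",
    "StagedThresholds",
    "RoutingResult",
    "route",
    "staged_predict",
    "scaled_weighted_auc",
    "tune_thresholds",
    "dxa_requirement_rate",
    "default_sigma_grid",
    "default_halfway_grid",
    "StagedCascadeModel",
    "StagedCascadeResults",
]

STAGE1 = "STAGE1"
STAGE2 = "STAGE2"


@dataclass(frozen=True)
class StagedThresholds:
    """The deferral rule's two thresholds."""

    sigma_thr: float
    halfway_thr: float

    def __post_init__(self) -> None:
        if self.sigma_thr < 0:
            raise ConfigError("sigma_thr must be >= 0")
        if not (0.0 <= self.halfway_thr <= 0.5):
            raise ConfigError("halfway_thr must lie in [0, 0.5]")


@dataclass
class RoutingResult:
    """Per-sample route and final probability of a staged prediction."""

    routes: np.ndarray  # STAGE1 / STAGE2 per sample
    p_final: np.ndarray
    thresholds: StagedThresholds
    mu1: np.ndarray
    sd1: np.ndarray

    @property
    def stage2_rate(self) -> float:
        return float(np.mean(self.routes == STAGE2))

    @property
    def stage1_retention(self) -> float:
        return 1.0 - self.stage2_rate

    def to_frame(self, ids=None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "route": self.routes,
                "mu1": self.mu1,
                "s1": self.sd1,
                "p_final": self.p_final,
            }
        )
        if ids is not None:
            frame.insert(0, "id", np.asarray(ids))
        return frame


def route(dist1: PredictionDistribution, thresholds: StagedThresholds) -> np.ndarray:
    """Apply the deferral rule to a Stage-1 prediction distribution."""
    if len(dist1) == 0:
        raise DataError("empty prediction distribution")
    retain = (dist1.sd <= thresholds.sigma_thr) & (
        np.abs(dist1.mu - 0.5) > thresholds.halfway_thr
    )
    return np.where(retain, STAGE1, STAGE2)


def staged_predict(
    ens1: EnsembleModel,
    ens2: EnsembleModel,
    X1,
    X2,
    thresholds: StagedThresholds,
    dist1: PredictionDistribution | None = None,
) -> RoutingResult:
    """Route every row and produce its final probability.

    ``X2`` is the *combined* Stage-2 design (clinical + expensive block) on
    which ``ens2`` was trained. Stage-2 predictions are computed only for
    cascaded rows; retained rows keep their Stage-1 mean.
    """
    if len(X1) != len(X2):
        raise SchemaError("X1 and X2 must be row-aligned")
    if dist1 is None:
        dist1 = predict_distribution(ens1, X1)
    routes = route(dist1, thresholds)
    p_final = dist1.mu.copy()
    cascaded = routes == STAGE2
    if cascaded.any():
        X2_sub = X2.iloc[cascaded] if isinstance(X2, pd.DataFrame) else X2[cascaded]
        p_final[cascaded] = predict_distribution(ens2, X2_sub).mu
    return RoutingResult(
        routes=routes,
        p_final=p_final,
        thresholds=thresholds,
        mu1=dist1.mu,
        sd1=dist1.sd,
    )


def _subset_auc(y: np.ndarray, p: np.ndarray) -> float:
    """AUC with a 0.5 fallback when the subset has a single class."""
    if len(np.unique(y)) < 2:
        return 0.5
    return float(roc_auc_score(y, p))


def scaled_weighted_auc(y, p_final, routes) -> float:
    """Size-weighted mean of the retained-subset and cascaded-subset AUCs.

    J = (n_r * AUC_r + n_c * AUC_c) / (n_r + n_c); an empty subset
    contributes zero weight, a single-class subset its size with AUC 0.5.
    """
    y = np.asarray(y)
    p_final = np.asarray(p_final)
    routes = np.asarray(routes)
    if len(y) == 0:
        raise DataError("empty input")
    total, weight = 0.0, 0
    for tag in (STAGE1, STAGE2):
        m = routes == tag
        k = int(m.sum())
        if k:
            total += k * _subset_auc(y[m], p_final[m])
            weight += k
    return total / weight


def default_sigma_grid(sd: np.ndarray, n_points: int = 11) -> np.ndarray:
    """Percentile grid over observed Stage-1 uncertainties, spanning the
    fully blocking (0) to fully permissive (max sd) ends."""
    qs = np.linspace(0, 100, n_points)
    grid = np.percentile(sd, qs)
    return np.unique(np.concatenate([[0.0], grid]))


def default_halfway_grid(n_points: int = 11) -> np.ndarray:
    return np.linspace(0.0, 0.5, n_points)


def tune_thresholds(
    ens1: EnsembleModel,
    ens2: EnsembleModel,
    X1_val,
    X2_val,
    y_val,
    sigma_grid=None,
    halfway_grid=None,
    return_trace: bool = False,
):
    """Exhaustive grid search for the gate thresholds on a validation set.

    Maximizes the scaled weighted AUC; ties broken by larger Stage-1
    retention, then smaller sigma threshold, then grid order.
    """
    y_val = np.asarray(y_val)
    if len(np.unique(y_val)) < 2:
        raise DataError("validation labels contain a single class")
    dist1 = predict_distribution(ens1, X1_val)
    mu2 = predict_distribution(ens2, X2_val).mu  # tuning evaluates the full grid

    if sigma_grid is None:
        sigma_grid = default_sigma_grid(dist1.sd)
    if halfway_grid is None:
        halfway_grid = default_halfway_grid()
    sigma_grid = np.atleast_1d(np.asarray(sigma_grid, dtype=float))
    halfway_grid = np.atleast_1d(np.asarray(halfway_grid, dtype=float))
    if sigma_grid.size == 0 or halfway_grid.size == 0:
        raise ConfigError("threshold grids must be nonempty")

    best, best_key, trace = None, None, []
    for sig in sigma_grid:
        for half in halfway_grid:
            thr = StagedThresholds(sigma_thr=float(sig), halfway_thr=float(half))
            routes = route(dist1, thr)
            p_final = np.where(routes == STAGE1, dist1.mu, mu2)
            j = scaled_weighted_auc(y_val, p_final, routes)
            n_retained = int((routes == STAGE1).sum())
            key = (j, n_retained, -thr.sigma_thr)
            trace.append(
                {
                    "sigma_thr": thr.sigma_thr,
                    "halfway_thr": thr.halfway_thr,
                    "objective": j,
                    "stage1_retained": n_retained,
                }
            )
            if best_key is None or key > best_key:
                best, best_key = thr, key
    if return_trace:
        return best, trace
    return best


def dxa_requirement_rate(routes_per_fold) -> dict:
    """Per-fold Stage-2 rates and the across-fold summary of the Stage-1
    retention rate (the fraction of subjects spared the expensive scan)."""
    folds = [np.asarray(r) for r in routes_per_fold]
    if not folds:
        raise DataError("at least one fold of routes is required")
    stage2_rates = np.array([float(np.mean(r == STAGE2)) for r in folds])
    retention = 1.0 - stage2_rates
    return {
        "stage2_rate_per_fold": stage2_rates.tolist(),
        "stage1_retention_per_fold": retention.tolist(),
        "mean_stage1_retention": float(retention.mean()),
        "retention_p25": float(np.percentile(retention, 25)),
        "retention_p50": float(np.percentile(retention, 50)),
        "retention_p75": float(np.percentile(retention, 75)),
    }


# ---------------------------------------------------------------------------
# model / results objects


class StagedCascadeModel:
    """Two-modality staged classifier, statsmodels-style.

    Construct from a Stage-1 design ``X1``, the expensive block ``X2`` and
    binary outcome ``y``; ``fit`` trains both ensembles (Stage 2 on the
    concatenated blocks), tunes the gate thresholds on an internal
    stratified validation split and returns a :class:`StagedCascadeResults`.
    """

    def __init__(
        self,
        X1,
        X2,
        y,
        ens1_config: EnsembleConfig | None = None,
        ens2_config: EnsembleConfig | None = None,
        pipeline_config: PipelineConfig | None = None,
        validation_size: float | int = 0.2,
        sigma_grid=None,
        halfway_grid=None,
    ):
        if len(X1) != len(X2) or len(X1) != len(y):
            raise SchemaError("X1, X2 and y must be row-aligned")
        self.X1 = X1 if isinstance(X1, pd.DataFrame) else pd.DataFrame(np.asarray(X1))
        self.X2 = X2 if isinstance(X2, pd.DataFrame) else pd.DataFrame(np.asarray(X2))
        self.y = np.asarray(y)
        self.ens1_config = ens1_config or EnsembleConfig()
        self.ens2_config = ens2_config or EnsembleConfig()
        self.pipeline_config = pipeline_config
        self.validation_size = validation_size
        self.sigma_grid = sigma_grid
        self.halfway_grid = halfway_grid

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "StagedCascadeModel":
        return cls(cohort.X1, cohort.X2, cohort.y, **kwargs)

    def fit(self, seed: int | None = None) -> "StagedCascadeResults":
        seed = self.ens1_config.seed if seed is None else seed
        idx = np.arange(len(self.y))
        train_idx, val_idx = train_test_split(
            idx,
            test_size=self.validation_size,
            stratify=self.y,
            random_state=seed,
        )
        combined = pd.concat(
            [self.X1.reset_index(drop=True), self.X2.reset_index(drop=True)], axis=1
        )
        ens1 = fit_ensemble(
            self.X1.iloc[train_idx], self.y[train_idx],
            self.ens1_config, self.pipeline_config,
        )
        ens2 = fit_ensemble(
            combined.iloc[train_idx], self.y[train_idx],
            self.ens2_config, self.pipeline_config,
        )
        thresholds, trace = tune_thresholds(
            ens1,
            ens2,
            self.X1.iloc[val_idx],
            combined.iloc[val_idx],
            self.y[val_idx],
            sigma_grid=self.sigma_grid,
            halfway_grid=self.halfway_grid,
            return_trace=True,
        )
        return StagedCascadeResults(
            model=self,
            ensemble1=ens1,
            ensemble2=ens2,
            thresholds=thresholds,
            tuning_trace=trace,
            train_idx=train_idx,
            val_idx=val_idx,
        )


@dataclass
class StagedCascadeResults:
    """Fitted cascade: both ensembles, the tuned gate, and the tuning trace."""

    model: StagedCascadeModel
    ensemble1: EnsembleModel
    ensemble2: EnsembleModel
    thresholds: StagedThresholds
    tuning_trace: list[dict]
    train_idx: np.ndarray
    val_idx: np.ndarray

    def predict(self, X1, X2) -> RoutingResult:
        combined = pd.concat(
            [
                pd.DataFrame(np.asarray(X1)).reset_index(drop=True)
                if not isinstance(X1, pd.DataFrame)
                else X1.reset_index(drop=True),
                pd.DataFrame(np.asarray(X2)).reset_index(drop=True)
                if not isinstance(X2, pd.DataFrame)
                else X2.reset_index(drop=True),
            ],
            axis=1,
        )
        return staged_predict(
            self.ensemble1, self.ensemble2, X1, combined, self.thresholds
        )

    @property
    def validation_objective(self) -> float:
        best = max(self.tuning_trace, key=lambda t: t["objective"])
        return best["objective"]

    def summary(self) -> str:
        lines = [
            "Staged cascade results",
            "=" * 54,
            f"training rows                 {len(self.train_idx):>8d}",
            f"validation rows               {len(self.val_idx):>8d}",
            f"Stage-1 base models (B1)      {self.ensemble1.n_base_models:>8d}",
            f"Stage-2 base models (B2)      {self.ensemble2.n_base_models:>8d}",
            f"sigma threshold               {self.thresholds.sigma_thr:>8.4f}",
            f"halfway threshold             {self.thresholds.halfway_thr:>8.4f}",
            f"validation scaled wAUC        {self.validation_objective:>8.4f}",
            "=" * 54,
        ]
        return "\n".join(lines)
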