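"""Preprocessing and feature selection for the staged pipeline.

Chain (fixed order, each stage clearing the next one's preconditions):

1. near-zero-variance (NZV) filter — drops constant columns and columns
   dominated by a single value, caret-style;
2. correlation filter — greedy removal until no retained pair exceeds the
   correlation threshold;
3. centering/scaling, optionally followed by the spatial-sign transform
   (row-wise projection onto the unit sphere, which blunts outliers);
4. optional recursive feature elimination (RFE) on the transformed data.

All statistics are learned on training rows only; `FeaturePipeline`
packages the chain so an ensemble can bind one fitted pipeline and apply
it identically across its base models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression

from ._exceptions import CapabilityError, ConfigError, DataError, SchemaError

__all__ = [
    "PreprocessModel",
    "SelectionMask",
    "fit_preprocessor",
    "apply_preprocessor",
    "nzv_filter",
    "correlation_filter",
    "rfe",
    "PipelineConfig",
    "FeaturePipeline",
    "make_base_learner",
    "base_importances",
]

# ---------------------------------------------------------------------------
# base-learner registry (shared with the ensemble module)

_REGISTRY = {
    "logistic": lambda: LogisticRegression(max_iter=2000, solver="lbfgs"),
    "gbt": lambda: GradientBoostingClassifier(n_estimators=50, max_depth=2),
}


def make_base_learner(spec: str):
    """Instantiate a registered base learner by identifier."""
    try:
        return _REGISTRY[spec]()
    except KeyError:
        raise ConfigError(
            f"unknown base learner {spec!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def base_importances(estimator) -> np.ndarray:
    """Nonnegative per-feature importances: |coef| for linear models,
    impurity gain for trees."""
    if hasattr(estimator, "coef_"):
        return np.abs(np.asarray(estimator.coef_)).ravel()
    if hasattr(estimator, "feature_importances_"):
        return np.asarray(estimator.feature_importances_)
    raise CapabilityError(
        f"{type(estimator).__name__} exposes neither coef_ nor feature_importances_"
    )


# ---------------------------------------------------------------------------
# helpers


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise DataError("expected a 2-D feature matrix")
    return arr, [f"x{i}" for i in range(arr.shape[1])]


# ---------------------------------------------------------------------------
# centering / scaling / spatial sign


@dataclass
class PreprocessModel:
    """Per-column center/scale learned on training rows, plus the
    spatial-sign flag. Zero-variance columns are flagged rather than
    scaled (they belong to the NZV filter)."""

    center: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray
    apply_spatial_sign: bool
    columns: list[str]


def fit_preprocessor(X_train, apply_spatial_sign: bool = True) -> PreprocessModel:
    arr, cols = _as_matrix(X_train)
    if arr.shape[0] < 2:
        raise DataError("need at least 2 training rows to estimate scales")
    if np.isnan(arr).any():
        raise DataError("training matrix contains missing values")
    center = arr.mean(axis=0)
    scale = arr.std(axis=0, ddof=1)
    zero = scale == 0.0
    return PreprocessModel(
        center=center,
        scale=np.where(zero, 1.0, scale),
        zero_variance=zero,
        apply_spatial_sign=apply_spatial_sign,
        columns=cols,
    )


def apply_preprocessor(model: PreprocessModel, X) -> np.ndarray:
    """Standardize columns and, if configured, project each row onto the
    unit sphere. All-zero rows are left unchanged (no direction exists)."""
    arr, cols = _as_matrix(X)
    if cols != model.columns and arr.shape[1] != len(model.columns):
        raise SchemaError(
            f"expected {len(model.columns)} columns {model.columns[:5]}..., "
            f"got {arr.shape[1]}"
        )
    if isinstance(X, pd.DataFrame) and cols != model.columns:
        raise SchemaError("column names do not match the fitted preprocessor")
    z = (arr - model.center) / model.scale
    if model.apply_spatial_sign:
        norms = np.linalg.norm(z, axis=1)
        nz = norms > 0
        z[nz] = z[nz] / norms[nz, None]
    return z


# ---------------------------------------------------------------------------
# selection mask


@dataclass
class SelectionMask:
    """Boolean keep-mask over feature columns with a removal-provenance tag
    per column (one of ``none``, ``nzv``, ``correlation``, ``rfe``)."""

    keep: np.ndarray
    removed_by: np.ndarray
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.removed_by = np.asarray(self.removed_by, dtype=object)
        if not ((self.removed_by == "none") == self.keep).all():
            raise ConfigError("keep[i] must be true exactly when removed_by[i] == 'none'")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "keep": self.keep.tolist(),
            "removed_by": self.removed_by.tolist(),
        }


# ---------------------------------------------------------------------------
# near-zero-variance filter


def nzv_filter(
    X, freq_ratio_threshold: float = 19.0, unique_pct_threshold: float = 10.0
) -> SelectionMask:
    """caret-style NZV: drop a column iff it is constant, or the ratio of
    its most-common to second-most-common value is >= ``freq_ratio_threshold``
    AND its percentage of distinct values is <= ``unique_pct_threshold``."""
    if freq_ratio_threshold <= 0 or unique_pct_threshold <= 0:
        raise ConfigError("NZV thresholds must be > 0")
    arr, cols = _as_matrix(X)
    n = arr.shape[0]
    if n == 0 or arr.shape[1] == 0:
        raise DataError("empty matrix")
    keep = np.ones(arr.shape[1], dtype=bool)
    removed_by = np.full(arr.shape[1], "none", dtype=object)
    for j in range(arr.shape[1]):
        _, counts = np.unique(arr[:, j], return_counts=True)
        if len(counts) == 1:
            keep[j] = False
            removed_by[j] = "nzv"
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        unique_pct = 100.0 * len(counts) / n
        if freq_ratio >= freq_ratio_threshold and unique_pct <= unique_pct_threshold:
            keep[j] = False
            removed_by[j] = "nzv"
    return SelectionMask(keep=keep, removed_by=removed_by, columns=cols)


# ---------------------------------------------------------------------------
# correlation filter


def correlation_filter(X, r_threshold: float = 0.9) -> SelectionMask:
    """Greedy pairwise decorrelation: while some retained pair has
    |Pearson r| > threshold, take the worst pair and drop the member with
    the larger mean absolute correlation to all other retained columns
    (ties keep the lower column index). Deterministic given column order.
    """
    if not (0.0 < r_threshold <= 1.0):
        raise ConfigError("r_threshold must lie in (0, 1]")
    arr, cols = _as_matrix(X)
    if (arr.std(axis=0) == 0.0).any():
        raise DataError(
            "constant column present; run the near-zero-variance filter first"
        )
    p = arr.shape[1]
    keep = np.ones(p, dtype=bool)
    removed_by = np.full(p, "none", dtype=object)
    if p < 2:
        return SelectionMask(keep=keep, removed_by=removed_by, columns=cols)
    corr = np.abs(np.corrcoef(arr, rowvar=False))
    np.fill_diagonal(corr, 0.0)
    while True:
        active = np.flatnonzero(keep)
        if len(active) < 2:
            break
        sub = corr[np.ix_(active, active)]
        worst = sub.max()
        if worst <= r_threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = active[i_loc], active[j_loc]
        mean_a = sub[i_loc].sum() / (len(active) - 1)
        mean_b = sub[j_loc].sum() / (len(active) - 1)
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:  # tie: retain the lower column index
            drop = max(a, b)
        keep[drop] = False
        removed_by[drop] = "correlation"
    return SelectionMask(keep=keep, removed_by=removed_by, columns=cols)


# ---------------------------------------------------------------------------
# recursive feature elimination


def rfe(
    X,
    y,
    n_target: int,
    step: int = 1,
    estimator_spec: str = "logistic",
    random_state: int | None = None,
) -> np.ndarray:
    """Backward elimination driven by model importances.

    Repeatedly fits the base learner on the surviving features and removes
    the ``step`` lowest-importance ones (fewer on the last round so exactly
    ``n_target`` survive). Returns a full ranking over features: rank 1 for
    the features retained longest, larger ranks for earlier eliminations.
    Survivors of the final round are ordered by their final importances.
    """
    arr, _ = _as_matrix(X)
    y = np.asarray(y)
    p = arr.shape[1]
    if n_target < 1 or n_target > p:
        raise ConfigError(f"n_target must lie in [1, {p}], got {n_target}")
    if step < 1:
        raise ConfigError("step must be >= 1")
    est = make_base_learner(estimator_spec)
    if random_state is not None and "random_state" in est.get_params():
        est.set_params(random_state=random_state)

    surviving = list(range(p))
    ranking = np.empty(p, dtype=int)
    next_rank = p  # eliminated earliest -> worst rank
    while len(surviving) > n_target:
        model = clone(est)
        model.fit(arr[:, surviving], y)
        imp = base_importances(model)
        k = min(step, len(surviving) - n_target)
        # lowest-importance first; ties broken by higher column index
        order = sorted(range(len(surviving)), key=lambda i: (imp[i], -surviving[i]))
        for loc in order[:k]:
            ranking[surviving[loc]] = next_rank
            next_rank -= 1
        surviving = [s for i, s in enumerate(surviving) if i not in set(order[:k])]
    model = clone(est)
    model.fit(arr[:, surviving], y)
    imp = base_importances(model)
    order = sorted(range(len(surviving)), key=lambda i: (-imp[i], surviving[i]))
    for rank, loc in enumerate(order, start=1):
        ranking[surviving[loc]] = rank
    return ranking


# ---------------------------------------------------------------------------
# the bound pipeline


@dataclass
class PipelineConfig:
    """Settings for the full preprocessing/selection chain."""

    apply_spatial_sign: bool = True
    nzv_freq_ratio: float = 19.0
    nzv_unique_pct: float = 10.0
    corr_threshold: float = 0.9
    rfe_n_target: int | None = None  # None disables RFE
    rfe_step: int = 1
    rfe_estimator: str = "logistic"


class FeaturePipeline:
    """NZV -> correlation filter -> center/scale (+ spatial sign) -> RFE,
    fit on training rows only and frozen thereafter."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.mask_: SelectionMask | None = None
        self.preprocessor_: PreprocessModel | None = None
        self._survivor_idx: np.ndarray | None = None  # post NZV+corr
        self._rfe_local_idx: np.ndarray | None = None  # within survivors

    def fit(self, X, y=None) -> "FeaturePipeline":
        arr, cols = _as_matrix(X)
        cfg = self.config
        removed_by = np.full(arr.shape[1], "none", dtype=object)

        m_nzv = nzv_filter(arr, cfg.nzv_freq_ratio, cfg.nzv_unique_pct)
        removed_by[~m_nzv.keep] = "nzv"
        idx = np.flatnonzero(m_nzv.keep)

        if len(idx) == 0:
            raise DataError("no features survive the near-zero-variance filter")
        m_corr = correlation_filter(arr[:, idx], cfg.corr_threshold)
        removed_by[idx[~m_corr.keep]] = "correlation"
        idx = idx[m_corr.keep]

        self.preprocessor_ = fit_preprocessor(
            arr[:, idx], apply_spatial_sign=cfg.apply_spatial_sign
        )
        self.preprocessor_.columns = [cols[i] for i in idx]
        Z = apply_preprocessor(self.preprocessor_, arr[:, idx])

        if cfg.rfe_n_target is not None and cfg.rfe_n_target < len(idx):
            if y is None:
                raise DataError("RFE requires outcome labels")
            ranking = rfe(
                Z, y, cfg.rfe_n_target, step=cfg.rfe_step,
                estimator_spec=cfg.rfe_estimator,
            )
            local_keep = ranking <= cfg.rfe_n_target
            removed_by[idx[~local_keep]] = "rfe"
            self._rfe_local_idx = np.flatnonzero(local_keep)
        else:
            self._rfe_local_idx = np.arange(len(idx))

        self._survivor_idx = idx
        self.mask_ = SelectionMask(
            keep=removed_by == "none", removed_by=removed_by, columns=cols
        )
        return self

    def transform(self, X) -> np.ndarray:
        if self.mask_ is None:
            raise DataError("pipeline is not fitted")
        arr, cols = _as_matrix(X)
        if arr.shape[1] != len(self.mask_.columns):
            raise SchemaError(
                f"expected {len(self.mask_.columns)} columns, got {arr.shape[1]}"
            )
        Z = apply_preprocessor(self.preprocessor_, arr[:, self._survivor_idx])
        return Z[:, self._rfe_local_idx]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    @property
    def output_columns(self) -> list[str]:
        return [self.mask_.columns[i] for i in
                self._survivor_idx[self._rfe_local_idx]]
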