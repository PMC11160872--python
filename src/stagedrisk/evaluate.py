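"""Model evaluation: nested cross-validation and comparison statistics.

The harness runs stratified outer folds; inside each outer-training fold
it carves two stratified validation sets (the first tunes the cascade's
gate thresholds, the second is held out and reported separately), fits
both ensembles on the remaining rows, and scores Ensemble 1, Ensemble 2
and the staged model on the outer test fold. Across-fold averages and
standard deviations are reported per metric, alongside DeLong AUC
comparisons and confidence intervals and McNemar tests on sensitivity and
specificity computed from the pooled outer-test predictions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from ._exceptions import ConfigError, DataError
from .cascade import (
    STAGE1,
    STAGE2,
    dxa_requirement_rate,
    staged_predict,
    tune_thresholds,
)
from .ensemble import (
    EnsembleConfig,
    PredictionDistribution,
    feature_importance,
    fit_ensemble,
    predict_distribution,
)
from .preprocess import PipelineConfig

__all__ = [
    "CVConfig",
    "MetricsReport",
    "roc_auc",
    "binary_metrics",
    "delong",
    "delong_ci",
    "mcnemar_sens_spec",
    "uncertainty_percentile_auc",
    "nested_cv",
]

MODELS = ("ensemble1", "ensemble2", "staged")


# ---------------------------------------------------------------------------
# scalar metrics


def roc_auc(y, scores) -> float:
    """Mann–Whitney AUC: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("AUC requires both classes")
    return float(roc_auc_score(y, scores))


def binary_metrics(y, probabilities, cutoff: float = 0.5) -> dict[str, float]:
    """Accuracy, sensitivity and specificity at a probability cutoff
    (positive iff probability > cutoff). A metric undefined because its
    class is absent is reported as NaN rather than 0."""
    y = np.asarray(y)
    pred = np.asarray(probabilities) > cutoff
    pos, neg = y == 1, y == 0
    return {
        "accuracy": float((pred == y).mean()),
        "sensitivity": float(pred[pos].mean()) if pos.any() else float("nan"),
        "specificity": float((~pred[neg]).mean()) if neg.any() else float("nan"),
    }


# ---------------------------------------------------------------------------
# DeLong test for correlated AUCs (structural components / placement values)


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(x)
    mid = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1  # 1-based midrank
        i = j
    out = np.empty(n, dtype=float)
    out[order] = mid
    return out


def _delong_structural(y, score_matrix):
    """AUCs and the covariance matrix of their estimators.

    ``score_matrix`` is (k, n). Uses the midrank formulation of the
    placement values V10 (per positive) and V01 (per negative).
    """
    y = np.asarray(y)
    scores = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    pos = y == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise DataError("DeLong requires both classes")
    k = scores.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        sx, sy = scores[r, pos], scores[r, ~pos]
        tx = _midrank(sx)
        ty = _midrank(sy)
        tz = _midrank(np.concatenate([sx, sy]))
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
        aucs[r] = v10[r].mean()
    s10 = np.atleast_2d(np.cov(v10, ddof=1)) if m > 1 else np.zeros((k, k))
    s01 = np.atleast_2d(np.cov(v01, ddof=1)) if n > 1 else np.zeros((k, k))
    cov = s10 / m + s01 / n
    return aucs, cov


def delong(y, scores1, scores2) -> float:
    """Two-sided p-value for the difference of two correlated AUCs."""
    aucs, cov = _delong_structural(y, np.vstack([scores1, scores2]))
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 1e-15:
        if abs(aucs[0] - aucs[1]) < 1e-12:
            return 1.0
        raise DataError("degenerate variance in DeLong comparison")
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    return float(2.0 * scipy.stats.norm.sf(abs(z)))


def delong_ci(y, scores, level: float = 0.95) -> tuple[float, float, float]:
    """(AUC, lower, upper): Wald interval from the DeLong variance,
    truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise DataError("degenerate variance: constant scores")
    aucs, cov = _delong_structural(y, scores[None, :])
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    zq = scipy.stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, aucs[0] - zq * se)
    hi = min(1.0, aucs[0] + zq * se)
    return float(aucs[0]), lo, hi


# ---------------------------------------------------------------------------
# McNemar tests on sensitivity / specificity


def _mcnemar_p(b: int, c: int) -> float:
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]
    exact = (b + c) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(min(1.0, res.pvalue))


def mcnemar_sens_spec(y, pred1, pred2) -> tuple[float, float]:
    """Paired McNemar tests of two classifiers' sensitivity (within
    positive-labeled samples) and specificity (within negative-labeled
    samples). Exact binomial when the discordant count is below 25,
    otherwise continuity-corrected chi-square."""
    y = np.asarray(y)
    pred1 = np.asarray(pred1).astype(int)
    pred2 = np.asarray(pred2).astype(int)
    ps = []
    for label in (1, 0):
        m = y == label
        correct1 = pred1[m] == label
        correct2 = pred2[m] == label
        b = int((correct1 & ~correct2).sum())
        c = int((~correct1 & correct2).sum())
        ps.append(_mcnemar_p(b, c))
    return ps[0], ps[1]


# ---------------------------------------------------------------------------
# uncertainty-percentile analysis


def uncertainty_percentile_auc(
    y, dist: PredictionDistribution, percentile_grid=None
) -> pd.DataFrame:
    """AUC (with DeLong CI) on the subset of samples whose uncertainty is
    at or above each percentile of the uncertainty distribution. Walking
    up the grid keeps ever-smaller, ever-more-uncertain subsets; degenerate
    subsets are emitted with NaN."""
    y = np.asarray(y)
    if percentile_grid is None:
        percentile_grid = np.arange(0, 100, 10)
    percentile_grid = np.asarray(percentile_grid, dtype=float)
    if ((percentile_grid < 0) | (percentile_grid >= 100)).any():
        raise ConfigError("percentiles must lie in [0, 100)")
    rows = []
    for q in percentile_grid:
        thr = np.percentile(dist.sd, q)
        m = dist.sd >= thr
        sub_y, sub_mu = y[m], dist.mu[m]
        auc = lo = hi = float("nan")
        if len(np.unique(sub_y)) == 2:
            try:
                auc, lo, hi = delong_ci(sub_y, sub_mu)
            except DataError:
                auc = roc_auc(sub_y, sub_mu)
        rows.append(
            {"percentile": q, "n": int(m.sum()), "auc": auc,
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class CVConfig:
    """Outer/inner cross-validation settings. Defaults approximate a
    547-subject cohort: 10 stratified outer folds give ~492-row training
    folds and ~55-row test folds, from which two 45-row validation sets
    are carved."""

    n_outer_folds: int = 10
    n_validation: int = 45
    inner_folds: int = 3
    seed: int = 0

    def validate(self, n: int, n_pos: int) -> None:
        if self.n_outer_folds < 2:
            raise ConfigError("n_outer_folds must be >= 2")
        if n_pos < self.n_outer_folds:
            raise ConfigError(
                "too few positives to stratify across "
                f"{self.n_outer_folds} outer folds"
            )
        n_train = n - n // self.n_outer_folds
        if 2 * self.n_validation >= n_train - 10:
            raise ConfigError(
                "n_validation too large: two validation sets would exhaust "
                "the outer-training fold"
            )


@dataclass
class MetricsReport:
    """Results object of :func:`nested_cv`.

    ``per_fold`` holds one row per (fold, model) with AUC, accuracy,
    sensitivity and specificity; summaries, comparison statistics and the
    retention analysis hang off it.
    """

    per_fold: pd.DataFrame
    fold_info: pd.DataFrame
    pooled: pd.DataFrame
    delong_pvalues: dict[str, float]
    delong_pvalues_per_fold: dict[str, list[float]]
    delong_cis: dict[str, tuple[float, float, float]]
    mcnemar_pvalues: dict[str, tuple[float, float]]
    retention: dict
    importances: dict[str, pd.Series]
    val2_per_fold: pd.DataFrame
    cv_config: CVConfig

    def summary_frame(self) -> pd.DataFrame:
        grouped = self.per_fold.groupby("model")[
            ["auc", "accuracy", "sensitivity", "specificity"]
        ]
        avg = grouped.mean()
        std = grouped.std(ddof=1)
        frames = []
        for model in MODELS:
            frames.append(
                pd.DataFrame(
                    {"AVG": avg.loc[model], "STD": std.loc[model]}
                ).T.assign(model=model)
            )
        out = pd.concat(frames)
        out.index.name = "stat"
        return out.reset_index().set_index(["model", "stat"])

    def summary(self) -> str:
        frame = self.summary_frame()
        lines = [
            "Nested cross-validation report",
            "=" * 66,
            frame.to_string(float_format=lambda v: f"{v:.4f}"),
            "-" * 66,
            f"mean Stage-1 retention        {self.retention['mean_stage1_retention']:.4f}",
            "retention percentiles (25/50/75)  "
            + "/".join(
                f"{self.retention[k]:.4f}"
                for k in ("retention_p25", "retention_p50", "retention_p75")
            ),
            "-" * 66,
            "DeLong p-values (pooled outer-test predictions):",
        ]
        for pair, p in self.delong_pvalues.items():
            lines.append(f"  {pair:<24s} {p:.4g}")
        lines.append("McNemar p-values (sensitivity, specificity):")
        for pair, (ps, pp) in self.mcnemar_pvalues.items():
            lines.append(f"  {pair:<24s} {ps:.4g}, {pp:.4g}")
        lines.append("=" * 66)
        return "\n".join(lines)

    def roc_frames(self, n_grid: int = 101) -> pd.DataFrame:
        """Across-fold mean ROC with standard deviation, per model, on a
        common false-positive-rate grid (for mean-ROC plots)."""
        fpr_grid = np.linspace(0, 1, n_grid)
        frames = []
        for model in MODELS:
            col = {"ensemble1": "mu1", "ensemble2": "mu2", "staged": "p_final"}[model]
            tprs = []
            for fold, grp in self.pooled.groupby("fold"):
                if len(np.unique(grp["y"])) < 2:
                    continue
                fpr, tpr, _ = roc_curve(grp["y"], grp[col])
                tprs.append(np.interp(fpr_grid, fpr, tpr))
            tprs = np.vstack(tprs)
            frames.append(
                pd.DataFrame(
                    {
                        "model": model,
                        "fpr": fpr_grid,
                        "tpr_mean": tprs.mean(axis=0),
                        "tpr_sd": tprs.std(axis=0, ddof=1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def plot_roc(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.roc_frames()
        fig, ax = plt.subplots(figsize=(6, 5))
        for model, grp in frame.groupby("model"):
            ax.plot(grp["fpr"], grp["tpr_mean"], label=model)
            ax.fill_between(
                grp["fpr"],
                grp["tpr_mean"] - grp["tpr_sd"],
                grp["tpr_mean"] + grp["tpr_sd"],
                alpha=0.2,
            )
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _fold_metrics(y, scores) -> dict[str, float]:
    out = {"auc": roc_auc(y, scores)}
    out.update(binary_metrics(y, scores))
    return out


def nested_cv(
    cohort,
    cv: CVConfig | None = None,
    ens1_config: EnsembleConfig | None = None,
    ens2_config: EnsembleConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    sigma_grid=None,
    halfway_grid=None,
    log_fn=None,
) -> MetricsReport:
    """Run the full nested-CV experiment on a two-block cohort.

    Per outer fold: carve validation sets 1 and 2 from the outer-training
    fold; fit Ensemble 1 (Stage-1 block) and Ensemble 2 (both blocks) on
    the remainder, tuning any base-learner grid by stratified inner CV;
    tune the cascade thresholds on validation set 1; score all three
    models on the outer test fold. Validation set 2 is held out and
    reported separately.
    """
    cv = cv or CVConfig()
    ens1_config = ens1_config or EnsembleConfig()
    ens2_config = ens2_config or dataclasses.replace(EnsembleConfig(), seed=1)
    y = np.asarray(cohort.y)
    cv.validate(len(y), int(y.sum()))

    X1 = cohort.X1.reset_index(drop=True)
    combined = pd.concat(
        [X1, cohort.X2.reset_index(drop=True)], axis=1
    )

    skf = StratifiedKFold(
        n_splits=cv.n_outer_folds, shuffle=True, random_state=cv.seed
    )
    fold_rows, info_rows, pooled_rows, val2_rows = [], [], [], []
    routes_per_fold, imp1, imp2 = [], [], []

    for fold, (train_idx, test_idx) in enumerate(skf.split(X1, y)):
        rest, val1 = train_test_split(
            train_idx, test_size=cv.n_validation,
            stratify=y[train_idx], random_state=cv.seed + 31 * fold,
        )
        rest, val2 = train_test_split(
            rest, test_size=cv.n_validation,
            stratify=y[rest], random_state=cv.seed + 31 * fold + 1,
        )

        c1 = dataclasses.replace(
            ens1_config, seed=ens1_config.seed + 101 * fold,
            inner_folds=cv.inner_folds,
        )
        c2 = dataclasses.replace(
            ens2_config, seed=ens2_config.seed + 101 * fold + 50,
            inner_folds=cv.inner_folds,
        )
        ens1 = fit_ensemble(X1.iloc[rest], y[rest], c1, pipeline_config)
        ens2 = fit_ensemble(combined.iloc[rest], y[rest], c2, pipeline_config)

        thresholds = tune_thresholds(
            ens1, ens2, X1.iloc[val1], combined.iloc[val1], y[val1],
            sigma_grid=sigma_grid, halfway_grid=halfway_grid,
        )

        # held-out second validation set, reported but unused for tuning
        v2_scores = {
            "ensemble1": predict_distribution(ens1, X1.iloc[val2]).mu,
            "ensemble2": predict_distribution(ens2, combined.iloc[val2]).mu,
        }
        v2_scores["staged"] = staged_predict(
            ens1, ens2, X1.iloc[val2], combined.iloc[val2], thresholds
        ).p_final
        for model, s in v2_scores.items():
            val2_rows.append(
                {"fold": fold, "model": model, **_fold_metrics(y[val2], s)}
            )

        dist1 = predict_distribution(ens1, X1.iloc[test_idx])
        routing = staged_predict(
            ens1, ens2, X1.iloc[test_idx], combined.iloc[test_idx],
            thresholds, dist1=dist1,
        )
        dist2 = predict_distribution(ens2, combined.iloc[test_idx])

        scores = {
            "ensemble1": dist1.mu,
            "ensemble2": dist2.mu,
            "staged": routing.p_final,
        }
        for model, s in scores.items():
            row = {"fold": fold, "model": model, **_fold_metrics(y[test_idx], s)}
            if model == "staged":
                row["stage2_rate"] = routing.stage2_rate
            fold_rows.append(row)

        routes_per_fold.append(routing.routes)
        imp1.append(feature_importance(ens1))
        imp2.append(feature_importance(ens2))
        info = {
            "fold": fold,
            "n_train": len(rest),
            "n_val": cv.n_validation,
            "n_test": len(test_idx),
            "sigma_thr": thresholds.sigma_thr,
            "halfway_thr": thresholds.halfway_thr,
            "stage2_rate": routing.stage2_rate,
            "ens1_params": ens1.best_params,
            "ens2_params": ens2.best_params,
        }
        info_rows.append(info)
        if log_fn is not None:
            log_fn({"event": "fold_complete", **{
                k: v for k, v in info.items() if k not in
                ("ens1_params", "ens2_params")
            }})

        pooled_rows.append(
            pd.DataFrame(
                {
                    "fold": fold,
                    "y": y[test_idx],
                    "mu1": dist1.mu,
                    "s1": dist1.sd,
                    "mu2": dist2.mu,
                    "p_final": routing.p_final,
                    "route": routing.routes,
                    "id": np.asarray(cohort.ids)[test_idx],
                }
            )
        )

    per_fold = pd.DataFrame(fold_rows)
    pooled = pd.concat(pooled_rows, ignore_index=True)

    pairs = [("ensemble1", "ensemble2"), ("ensemble1", "staged"),
             ("ensemble2", "staged")]
    col = {"ensemble1": "mu1", "ensemble2": "mu2", "staged": "p_final"}
    delong_p, delong_fold, mcnemar_p = {}, {}, {}
    for a, b in pairs:
        key = f"{a}_vs_{b}"
        delong_p[key] = delong(pooled["y"], pooled[col[a]], pooled[col[b]])
        per_fold_ps = []
        for _, grp in pooled.groupby("fold"):
            try:
                per_fold_ps.append(delong(grp["y"], grp[col[a]], grp[col[b]]))
            except DataError:
                per_fold_ps.append(float("nan"))
        delong_fold[key] = per_fold_ps
        mcnemar_p[key] = mcnemar_sens_spec(
            pooled["y"], pooled[col[a]] > 0.5, pooled[col[b]] > 0.5
        )
    cis = {m: delong_ci(pooled["y"], pooled[col[m]]) for m in MODELS}

    return MetricsReport(
        per_fold=per_fold,
        fold_info=pd.DataFrame(info_rows),
        pooled=pooled,
        delong_pvalues=delong_p,
        delong_pvalues_per_fold=delong_fold,
        delong_cis=cis,
        mcnemar_pvalues=mcnemar_p,
        retention=dxa_requirement_rate(routes_per_fold),
        importances={
            "ensemble1": pd.concat(imp1, axis=1).mean(axis=1),
            "ensemble2": pd.concat(imp2, axis=1).mean(axis=1),
        },
        val2_per_fold=pd.DataFrame(val2_rows),
        cv_config=cv,
    )
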