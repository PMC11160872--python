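"""Baseline-characteristics statistics for a labeled cohort.

Standard case-control table machinery: per-level counts and within-group
percentages for categorical variables, group means and standard deviations
for continuous ones, with Fisher's exact test and Yates-corrected
chi-square on one-vs-rest 2x2 tables and Welch's unequal-variance t-test
(computable directly from printed summary statistics) for continuous
variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._exceptions import ConfigError, DataError

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "fisher_exact_p",
    "chi_square_p",
    "welch_t_p",
    "baseline_tables",
    "BaselineReport",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 table; rows are outcome groups (control / case),
    columns are category levels (yes / no)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ConfigError("contingency counts must be nonnegative integers")
        if sum(counts) == 0:
            raise ConfigError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _coerce_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable2x2):
        return table.as_array()
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ConfigError("expected a 2x2 table")
    return ContingencyTable2x2(*arr.ravel().tolist()).as_array()


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p: the total hypergeometric probability of
    all tables (margins fixed) no more probable than the observed one.
    A zero margin makes every admissible table equally extreme (p = 1)."""
    arr = _coerce_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])


def chi_square_p(table, continuity_correction: bool = True) -> float:
    """Pearson chi-square p (1 df) with Yates continuity correction by
    default."""
    arr = _coerce_table(table)
    row, col = arr.sum(axis=1), arr.sum(axis=0)
    expected = np.outer(row, col) / arr.sum()
    if (expected == 0).any():
        raise DataError("zero expected count; chi-square is undefined")
    _, p, _, _ = scipy.stats.chi2_contingency(arr, correction=continuity_correction)
    return float(p)


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group of a continuous variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")
        if self.n < 2:
            raise ConfigError("n must be >= 2")


def welch_t_p(g1: GroupSummary, g2: GroupSummary) -> float:
    """Two-sided Welch unequal-variance t-test from group summaries, with
    Welch–Satterthwaite degrees of freedom."""
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return 1.0
        raise DataError("zero variance in both groups with differing means")
    res = scipy.stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=False
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort-level report


@dataclass
class BaselineReport:
    """The four baseline tables: categorical counts, continuous summaries,
    categorical p-values, continuous p-values."""

    categorical_counts: pd.DataFrame
    continuous_summaries: pd.DataFrame
    categorical_pvalues: pd.DataFrame
    continuous_pvalues: pd.DataFrame

    def to_csv(self, out_dir) -> dict:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in {
            "categorical_counts": self.categorical_counts,
            "continuous_summaries": self.continuous_summaries,
            "categorical_pvalues": self.categorical_pvalues,
            "continuous_pvalues": self.continuous_pvalues,
        }.items():
            paths[name] = out / f"{name}.csv"
            frame.to_csv(paths[name], index=False)
        return paths

    def to_markdown(self) -> str:
        parts = []
        for title, frame in {
            "Categorical features: counts (percent within group)":
                self.categorical_counts,
            "Continuous features: mean (sd) per group": self.continuous_summaries,
            "Categorical features: chi-square and Fisher p-values":
                self.categorical_pvalues,
            "Continuous features: Welch t-test p-values": self.continuous_pvalues,
        }.items():
            parts.append(f"## {title}\n\n{frame.to_markdown(index=False)}\n")
        return "\n".join(parts)


def _one_vs_rest_table(values: pd.Series, level, y: np.ndarray) -> ContingencyTable2x2:
    is_level = (values == level).to_numpy()
    return ContingencyTable2x2(
        a=int((is_level & (y == 0)).sum()),
        b=int((~is_level & (y == 0)).sum()),
        c=int((is_level & (y == 1)).sum()),
        d=int((~is_level & (y == 1)).sum()),
    )


def baseline_tables(clinical_table: pd.DataFrame, y, schema: dict) -> BaselineReport:
    """Build the four baseline tables from a raw clinical table.

    ``schema`` maps column name -> "categorical" | "continuous"; columns
    not in the schema are ignored. Categorical features are tested one
    level versus all others; binary features additionally get a single
    collapsed row. Chi-square is flagged missing (NaN) when any expected
    count is zero; constant continuous features get a missing p-value.
    """
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise DataError("y must be binary")
    bad = [c for c in schema if c not in clinical_table.columns]
    if bad:
        raise ConfigError(f"schema names missing columns: {bad}")

    cat_cols = [c for c, t in schema.items() if t == "categorical"]
    cont_cols = [c for c, t in schema.items() if t == "continuous"]

    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    count_rows, catp_rows = [], []
    for col in cat_cols:
        values = clinical_table[col]
        levels = sorted(values.dropna().unique(), key=str)
        for level in levels:
            t = _one_vs_rest_table(values, level, y)
            count_rows.append(
                {
                    "feature": col,
                    "level": level,
                    "no_fracture_n": t.a,
                    "no_fracture_pct": 100.0 * t.a / n0 if n0 else float("nan"),
                    "fracture_n": t.c,
                    "fracture_pct": 100.0 * t.c / n1 if n1 else float("nan"),
                }
            )
            arr = t.as_array()
            expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
            chi_p = (
                float("nan") if (expected == 0).any() else chi_square_p(t)
            )
            catp_rows.append(
                {
                    "feature": col,
                    "level": level,
                    "chi_square_p": chi_p,
                    "fisher_p": fisher_exact_p(t),
                }
            )
        if len(levels) == 2:  # collapsed row for binary features
            t = _one_vs_rest_table(values, levels[0], y)
            arr = t.as_array()
            expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
            catp_rows.append(
                {
                    "feature": col,
                    "level": "(collapsed)",
                    "chi_square_p": (
                        float("nan") if (expected == 0).any() else chi_square_p(t)
                    ),
                    "fisher_p": fisher_exact_p(t),
                }
            )

    cont_rows, contp_rows = [], []
    for col in cont_cols:
        v = clinical_table[col].to_numpy(dtype=float)
        g0, g1 = v[y == 0], v[y == 1]
        s0 = GroupSummary(float(g0.mean()), float(g0.std(ddof=1)), len(g0))
        s1 = GroupSummary(float(g1.mean()), float(g1.std(ddof=1)), len(g1))
        cont_rows.append(
            {
                "feature": col,
                "no_fracture_mean": s0.mean,
                "no_fracture_sd": s0.sd,
                "fracture_mean": s1.mean,
                "fracture_sd": s1.sd,
            }
        )
        if s0.sd == 0 and s1.sd == 0:  # constant feature: p marked missing
            p = float("nan")
        else:
            p = welch_t_p(s0, s1)
        contp_rows.append({"feature": col, "welch_t_p": p})

    empty_counts = pd.DataFrame(
        columns=["feature", "level", "no_fracture_n", "no_fracture_pct",
                 "fracture_n", "fracture_pct"]
    )
    empty_catp = pd.DataFrame(columns=["feature", "level", "chi_square_p", "fisher_p"])
    empty_cont = pd.DataFrame(
        columns=["feature", "no_fracture_mean", "no_fracture_sd",
                 "fracture_mean", "fracture_sd"]
    )
    empty_contp = pd.DataFrame(columns=["feature", "welch_t_p"])
    return BaselineReport(
        categorical_counts=pd.DataFrame(count_rows) if count_rows else empty_counts,
        continuous_summaries=pd.DataFrame(cont_rows) if cont_rows else empty_cont,
        categorical_pvalues=pd.DataFrame(catp_rows) if catp_rows else empty_catp,
        continuous_pvalues=pd.DataFrame(contp_rows) if contp_rows else empty_contp,
    )
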