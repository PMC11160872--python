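"""Synthetic two-modality cohorts for staged risk prediction.

Real staged-screening studies pair a cheap clinical block (demographics,
lifestyle, history — mostly categorical, weakly informative) with an
expensive imaging-derived block (high-dimensional, internally correlated,
strongly informative). This module generates cohorts with that statistical
structure so the whole pipeline is testable without any restricted data.

The generative model is a noisy linear latent risk

    z_i = beta1 * g_i * u1_i + beta2 * u2_i + noise_sd * eps_i

where ``u1`` and ``u2`` are unit-variance linear reductions of the two
feature blocks, ``eps`` is standard normal, and ``g_i`` inflates the
clinical term for a random "easy" subset of subjects so that a fraction of
the cohort is confidently classifiable from the clinical block alone —
the premise a deferral cascade exploits. Labels are assigned by ranking
``z`` and marking exactly ``n_positives`` subjects positive, so cohort
composition is identical across seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ConfigError

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "inject_degeneracies",
    "raw_clinical_table",
    "write_cohort",
    "read_cohort",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the target study population: 547 subjects of whom 94
    are positive, a weak clinical signal and a strong, equicorrelated
    imaging signal.
    """

    n_subjects: int = 547
    n_positives: int | None = 94
    prevalence: float | None = None
    n_stage1: int = 10
    n_stage2: int = 40
    beta1: float = 0.4
    beta2: float = 1.2
    rho2: float = 0.5
    easy_fraction: float = 0.25
    easy_factor: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def resolved_positives(self) -> int:
        if self.n_positives is not None:
            return int(self.n_positives)
        return int(round(self.prevalence * self.n_subjects))

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.n_positives is None and self.prevalence is None:
            raise ConfigError("one of n_positives or prevalence is required")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise ConfigError("prevalence must lie in (0, 1)")
        k = self.resolved_positives()
        if not (0 < k < self.n_subjects):
            raise ConfigError("n_positives must satisfy 0 < n_positives < n_subjects")
        if self.n_stage1 < 1:
            raise ConfigError("n_stage1 must be >= 1")
        if self.n_stage2 < 1:
            raise ConfigError("n_stage2 must be >= 1")
        if not (0.0 <= self.rho2 < 1.0):
            raise ConfigError("rho2 must lie in [0, 1)")
        if not (0.0 <= self.easy_fraction <= 1.0):
            raise ConfigError("easy_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class Cohort:
    """A labeled two-block cohort.

    ``X1`` is the clinical (Stage-1) block, ``X2`` the imaging (Stage-2)
    block; rows are aligned. Oracle columns (``latent``, ``oracle_stage1``,
    ``oracle_stage2``) expose the generating signal for diagnostics and
    property tests; models never see them.
    """

    ids: np.ndarray
    X1: pd.DataFrame
    X2: pd.DataFrame
    y: np.ndarray
    latent: np.ndarray | None = None
    oracle_stage1: np.ndarray | None = None
    oracle_stage2: np.ndarray | None = None
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.y)
        if len(self.X1) != n or len(self.X2) != n or len(self.ids) != n:
            raise ConfigError("X1, X2, y and ids must have identical row counts")
        if not np.isin(self.y, (0, 1)).all():
            raise ConfigError("y must contain only {0, 1}")

    @property
    def n_subjects(self) -> int:
        return len(self.y)


def _unit_variance(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return v / sd if sd > 0 else v


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort under ``config``; bit-identical for equal configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p1, p2 = config.n_subjects, config.n_stage1, config.n_stage2

    # Clinical block: half continuous, half dummy-coded binary columns.
    n_cont = (p1 + 1) // 2
    cont = rng.standard_normal((n, n_cont))
    bin_p = rng.uniform(0.15, 0.5, size=p1 - n_cont)
    binary = (rng.random((n, p1 - n_cont)) < bin_p).astype(float)
    X1 = np.hstack([cont, binary])
    cols1 = [f"clin_c{i:02d}" for i in range(n_cont)] + [
        f"clin_b{i:02d}" for i in range(p1 - n_cont)
    ]

    # Imaging block: single-factor equicorrelated Gaussian, pairwise
    # correlation rho2 between every pair of columns.
    f = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, p2))
    X2 = np.sqrt(config.rho2) * f + np.sqrt(1.0 - config.rho2) * e
    cols2 = [f"img_{i:03d}" for i in range(p2)]

    w1 = rng.standard_normal(p1)
    w2 = rng.standard_normal(p2)
    u1 = _unit_variance((X1 - X1.mean(axis=0)) @ w1)
    u2 = _unit_variance((X2 - X2.mean(axis=0)) @ w2)

    gain = np.ones(n)
    n_easy = int(round(config.easy_fraction * n))
    if n_easy:
        gain[rng.choice(n, size=n_easy, replace=False)] = config.easy_factor

    eps = rng.standard_normal(n)
    lin1 = config.beta1 * gain * u1
    lin2 = config.beta2 * u2
    z = lin1 + lin2 + config.noise_sd * eps

    # Exact-count labels: the top-k latent risks are the positives.
    k = config.resolved_positives()
    y = np.zeros(n, dtype=int)
    y[np.argsort(z, kind="stable")[::-1][:k]] = 1

    ids = np.array([f"S{i:04d}" for i in range(n)])
    return Cohort(
        ids=ids,
        X1=pd.DataFrame(X1, columns=cols1),
        X2=pd.DataFrame(X2, columns=cols2),
        y=y,
        latent=z,
        oracle_stage1=lin1,
        oracle_stage2=lin2,
        config=config,
    )


def inject_degeneracies(
    cohort: Cohort, n_constant: int, n_duplicate: int, seed: int
) -> Cohort:
    """Append constant and exactly-duplicated columns to the clinical block.

    Provenance is recorded in the new column names (``const_*``,
    ``dup<j>_of_<name>``) so filter tests can assert which columns the
    near-zero-variance and correlation filters must remove.
    """
    if n_constant < 0 or n_duplicate < 0:
        raise ConfigError("n_constant and n_duplicate must be >= 0")
    rng = np.random.default_rng(seed)
    X1 = cohort.X1.copy()
    for i in range(n_constant):
        X1[f"const_{i:02d}"] = rng.uniform(-5, 5)
    source_pool = list(cohort.X1.columns)
    for j in range(n_duplicate):
        src = source_pool[rng.integers(len(source_pool))]
        X1[f"dup{j:02d}_of_{src}"] = X1[src].to_numpy()
    return Cohort(
        ids=cohort.ids,
        X1=X1,
        X2=cohort.X2,
        y=cohort.y,
        latent=cohort.latent,
        oracle_stage1=cohort.oracle_stage1,
        oracle_stage2=cohort.oracle_stage2,
        config=cohort.config,
    )


def raw_clinical_table(cohort: Cohort, seed: int | None = None) -> pd.DataFrame:
    """Emit an un-coded clinical table (categorical + continuous columns).

    Baseline-characteristics reporting works on raw category labels, not
    dummy codes; this derives a plausible raw table whose categorical
    levels are weakly associated with the outcome.
    """
    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    n = cohort.n_subjects
    y = cohort.y
    risk = cohort.latent if cohort.latent is not None else y.astype(float)
    age = 57.7 + 2.0 * y + 7.0 * rng.standard_normal(n)
    weight = 77.3 - 2.8 * y + 14.4 * rng.standard_normal(n)

    def _draw(levels, base_probs, shift):
        probs = np.asarray(base_probs, dtype=float)
        out = []
        for i in range(n):
            p = probs.copy()
            if y[i]:
                p = p * np.asarray(shift)
            p /= p.sum()
            out.append(levels[rng.choice(len(levels), p=p)])
        return out

    return pd.DataFrame(
        {
            "id": cohort.ids,
            "age": np.round(age, 1),
            "weight": np.round(weight, 1),
            "sex": _draw(["female", "male"], [0.5, 0.5], [1.15, 0.85]),
            "alcohol": _draw(
                ["never", "previous", "current"], [0.01, 0.01, 0.98], [5.0, 0.5, 1.0]
            ),
            "smoking": _draw(
                ["never", "previous", "current"], [0.55, 0.40, 0.05], [1.0, 0.9, 1.8]
            ),
            "risk_score": np.round(risk, 4),
        }
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write stage1.csv / stage2.csv / labels.csv plus a JSON config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stage1": out / "stage1.csv",
        "stage2": out / "stage2.csv",
        "labels": out / "labels.csv",
        "config": out / "cohort_config.json",
    }
    for key, block in (("stage1", cohort.X1), ("stage2", cohort.X2)):
        frame = block.copy()
        frame.insert(0, "id", cohort.ids)
        frame.to_csv(paths[key], index=False)
    pd.DataFrame({"id": cohort.ids, "y": cohort.y}).to_csv(paths["labels"], index=False)
    cfg = asdict(cohort.config) if cohort.config is not None else {}
    paths["config"].write_text(json.dumps(cfg, indent=2))
    return paths


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    p = Path(in_dir)
    s1 = pd.read_csv(p / "stage1.csv")
    s2 = pd.read_csv(p / "stage2.csv")
    labels = pd.read_csv(p / "labels.csv")
    cfg_path = p / "cohort_config.json"
    config = None
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        if raw:
            config = CohortConfig(**raw)
    return Cohort(
        ids=labels["id"].to_numpy(),
        X1=s1.drop(columns="id"),
        X2=s2.drop(columns="id"),
        y=labels["y"].to_numpy(),
        config=config,
    )
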