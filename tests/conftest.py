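import numpy as np
import pytest

from stagedrisk import CohortConfig, EnsembleConfig, generate_cohort
from stagedrisk.preprocess import PipelineConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A compact separable cohort for fast ensemble/cascade tests."""
    return generate_cohort(
        CohortConfig(
            n_subjects=200, n_positives=40, n_stage1=6, n_stage2=12,
            beta1=0.5, beta2=1.5, seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_ensembles(small_cohort):
    """Stage-1 and Stage-2 ensembles fit on the first 150 rows."""
    import pandas as pd

    from stagedrisk import fit_ensemble

    c = small_cohort
    combined = pd.concat([c.X1, c.X2], axis=1)
    train = np.arange(150)
    ens1 = fit_ensemble(
        c.X1.iloc[train], c.y[train], EnsembleConfig(n_base_models=10, seed=1)
    )
    ens2 = fit_ensemble(
        combined.iloc[train], c.y[train], EnsembleConfig(n_base_models=10, seed=2)
    )
    return c, combined, ens1, ens2
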