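import numpy as np
import pandas as pd
import pytest

from metarisk import CohortConfig, generate_cohort
from metarisk.evaluation import _base_columns, _encode_covariates, _log_features


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete study (both outcomes, two platforms)."""
    cfg = CohortConfig(
        n_cases_A=60,
        n_cases_B=50,
        n_controls=110,
        platform_sizes={"LC-MS": 30, "NMR": 12},
        n_signal_features=5,
        effect_size=0.8,
        n_batches=3,
        qc_every=8,
        seed=7,
    )
    return cfg, *generate_cohort(cfg)


def make_analysis_frame(cohort, matrix, outcome="B"):
    """Covariates + log metabolites + y for one outcome, complete-case covs."""
    frame = cohort.outcome_frame(outcome)
    enc = _encode_covariates(frame)
    enc = enc.fillna(enc.median(numeric_only=True))
    feats = _log_features(matrix, enc.index)
    out = pd.concat([enc, feats.reindex(enc.index)], axis=1)
    out["y"] = frame["y"].to_numpy()
    return out, _base_columns(enc)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
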