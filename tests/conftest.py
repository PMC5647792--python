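import numpy as np
import pandas as pd
import pytest

from lipidq.simcohort import SimConfig, generate_cohort
from lipidq.tableio import FeatureTable


@pytest.fixture(scope="session")
def small_cohort():
    """Small full-featured cohort: drift, batches, missingness, noise features."""
    cfg = SimConfig(n_features=80, seed=7)
    table, samples, truth = generate_cohort(cfg)
    return cfg, table, samples, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Complete cohort without drift/batch/missingness artifacts."""
    cfg = SimConfig(
        n_features=60, seed=11, drift_amplitude=0.0, n_batches=1,
        mcar_rate=0.0, mnar_strength=0.0, frac_noise_features=0.0,
    )
    table, samples, truth = generate_cohort(cfg)
    return cfg, table, samples, truth


def make_table(values, qc_cols=None, mz=None, rt=None, mode="positive"):
    """Hand-built FeatureTable + sample sheet from a 2D array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_inj = values.shape
    fids = [f"F{i}" for i in range(n_feat)]
    cols = [f"I{j}" for j in range(n_inj)]
    feats = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(300, 800, n_feat),
            "rt": rt if rt is not None else np.linspace(1, 8, n_feat),
            "ion_mode": [mode] * n_feat,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    table = FeatureTable(pd.DataFrame(values, index=feats.index, columns=cols), feats)
    qc_cols = set(qc_cols or [])
    rows = []
    for j, c in enumerate(cols):
        is_qc = j in qc_cols or c in qc_cols
        rows.append(
            {
                "sample_id": c,
                "role": "qc" if is_qc else "study",
                "group": "none" if is_qc else ("disease" if j % 2 else "healthy"),
                "batch": 1,
                "injection_order": j + 1,
            }
        )
    samples = pd.DataFrame(rows)
    return table, samples
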