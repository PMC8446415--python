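import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from irpair import ClinicalTable, ExpressionMatrix, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with strong true signal, shared across tests."""
    cfg = SimConfig(
        n_tumor=200,
        n_normal=40,
        n_lnc=60,
        n_irgene=40,
        n_other_coding=30,
        n_de_lnc=16,
        n_true_pairs=3,
        true_beta=(1.0, 1.0, 1.0),
        seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def toy_expression():
    values = pd.DataFrame(
        {
            "s1": [5.0, 3.0, 3.0],
            "s2": [1.0, 2.0, 8.0],
            "s3": [4.0, 4.0, 0.0],
        },
        index=["A", "B", "C"],
    )
    cls = pd.Series({"s1": "tumor", "s2": "tumor", "s3": "normal"})
    return ExpressionMatrix(values, cls)


@pytest.fixture()
def toy_surv():
    """Six patients, distinct event times, no censoring."""
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"p{i}" for i in range(1, 7)],
                "os_time": [31, 60, 90, 150, 210, 400],
                "os_event": [1, 1, 1, 1, 1, 1],
            }
        )
    )


def exponential_cohort(
    n, lp, h0=3e-4, censor_frac=0.0, seed=0, follow_up=None
):
    """Closed-form exponential proportional-hazards survival draw."""
    rng = np.random.default_rng(seed)
    lam = h0 * np.exp(np.asarray(lp, dtype=float))
    t = rng.exponential(1.0 / lam)
    ids = [f"p{i}" for i in range(n)]
    if censor_frac > 0:
        c = rng.uniform(0, np.quantile(t, 1 - censor_frac) * 2, n)
    elif follow_up is not None:
        c = np.full(n, follow_up)
    else:
        c = np.full(n, np.inf)
    event = (t <= c).astype(int)
    time = np.minimum(t, c)
    return ClinicalTable(
        pd.DataFrame({"sample_id": ids, "os_time": time, "os_event": event})
    )
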