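import numpy as np
import pandas as pd
import pytest

from kinresp.data import Dataset
from kinresp.model import KineticParams
from kinresp.regression import Formula, fit
from kinresp.synthetic import default_scenario, generate


@pytest.fixture(scope="session")
def canonical_params() -> KineticParams:
    """The canonical illustration parameter set of the kinetic model."""
    return KineticParams(T_n=37.5, r=0.04, p0=0.25, k=0.4, s=3)


@pytest.fixture(scope="session")
def noisy_dataset() -> Dataset:
    """Six-group synthetic dataset at default noise, reused across tests."""
    return generate(default_scenario(n_per_group=10, seed=7))


@pytest.fixture(scope="session")
def reference_fit(noisy_dataset):
    """pred2 (T_n, r shared; p0, k by group) fit of the shared dataset."""
    result = fit(noisy_dataset, Formula.pred(2, s=3))
    assert result.converged
    return result


def two_group_dataset(p0_a=0.25, p0_b=0.25, k_a=0.4, k_b=0.4, n=20,
                      noise_sd_log=0.01, subject_cv=0.0, seed=0,
                      labels=("X", "Y")) -> Dataset:
    """Small two-group scenario helper used by several null/power tests."""
    from kinresp.synthetic import GroupScenario, SyntheticConfig

    base = KineticParams(T_n=37.5, r=0.04, p0=0.25, k=0.4, s=3)
    cfg = SyntheticConfig(
        scenarios=(
            GroupScenario(labels[0], base.with_(p0=p0_a, k=k_a), n),
            GroupScenario(labels[1], base.with_(p0=p0_b, k=k_b), n),
        ),
        noise_sd_log=noise_sd_log,
        subject_cv=subject_cv,
        seed=seed,
    )
    return generate(cfg)


def manual_dataset(rows) -> Dataset:
    """Dataset from a list of (subject, group, time_h, temp_C) tuples."""
    return Dataset(
        pd.DataFrame(rows, columns=["subject", "group", "time_h", "temp_C"])
    )
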