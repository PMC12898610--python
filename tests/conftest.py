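import numpy as np
import pandas as pd
import pytest

from complement_pqtl.datatypes import ALL_MEASURES, ANALYTES, RATIO, Cohort, ProteinPanel
from complement_pqtl.simulate import (
    SimConfig,
    default_study_config,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def study_sim():
    """One cohort under the default study conditions (50 cases / 121 controls)."""
    return simulate_cohort(default_study_config(seed=5))


@pytest.fixture(scope="session")
def null_sim():
    """A cohort with no planted effects of any kind."""
    cfg = SimConfig(n_case=50, n_control=121, n_snps=30, seed=11)
    return simulate_cohort(cfg)


def make_panel(values: dict, index=None) -> ProteinPanel:
    """Build a ProteinPanel from per-analyte log2 arrays; missing analytes
    are filled with zeros and the ratio column is derived."""
    first = next(iter(values.values()))
    n = len(first)
    if index is None:
        index = pd.Index([f"S{i:03d}" for i in range(n)], name="id")
    data = {a: np.asarray(values.get(a, np.zeros(n)), dtype=float) for a in ANALYTES}
    df = pd.DataFrame(data, index=index)
    df[RATIO] = df["Bb"] - df["C3"]
    return ProteinPanel(df)


def make_cohort(n_case, n_control, rng=None, index=None) -> Cohort:
    n = n_case + n_control
    rng = rng or np.random.default_rng(0)
    if index is None:
        index = pd.Index([f"S{i:03d}" for i in range(n)], name="id")
    return Cohort(
        pd.DataFrame(
            {
                "group": ["case"] * n_case + ["control"] * n_control,
                "age": rng.uniform(25, 70, n),
                "sex": rng.choice(["male", "female"], n),
                "bmi": rng.uniform(18, 40, n),
            },
            index=index,
        )
    )
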