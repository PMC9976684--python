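import numpy as np
import pandas as pd
import pytest

import capomics as c
import capomics.simulate as sim
from capomics.pipeline import PipelineConfig, run_pipeline, training_view


@pytest.fixture(scope="session")
def small_design():
    """A reduced two-cohort design for fast unit tests."""
    return c.CohortDesign(
        group_sizes={
            "train": {"CON": 8, "NS_CAP": 8, "S_CAP": 8},
            "validation": {"CON": 10, "NS_CAP": 10, "S_CAP": 10},
        },
        n_features={"protein": 40, "metabolite": 80},
        missing_rate=0.05,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    tables, metadata, truth = c.generate_cohort(small_design)
    return tables, metadata, truth


@pytest.fixture(scope="session")
def default_config():
    """The full default study configuration at the panel-recovery seed."""
    return PipelineConfig().with_seed(11)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """The full default two-cohort study (500 proteins, 2500 metabolites)."""
    overrides = dict(default_config.simulation)
    overrides["seed"] = default_config.seeds["simulate"]
    design = sim.CohortDesign(**overrides)
    tables, metadata, truth = sim.generate_cohort(design)
    return tables, metadata, truth


@pytest.fixture(scope="session")
def default_train_view(default_cohort, default_config):
    tables, metadata, _ = default_cohort
    return training_view(tables, metadata, default_config)


@pytest.fixture(scope="session")
def default_report(default_config):
    """One full end-to-end run of the default study (shared across tests)."""
    return run_pipeline(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_table(values, layer="protein", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return c.IntensityTable(layer, pd.DataFrame(values, index=features, columns=samples))


def make_metadata(groups, cohort="train", prefix="S"):
    return pd.DataFrame({
        "sample_id": [f"{prefix}{i}" for i in range(len(groups))],
        "group": list(groups),
        "cohort": cohort,
    })
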