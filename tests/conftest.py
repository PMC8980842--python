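import warnings

import numpy as np
import pandas as pd
import pytest

import mirmod as mm

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_config():
    """A quick three-module cohort: 60 samples, 200 genes, 60 miRNAs."""
    return mm.SimulationConfig(
        n_cases=30, n_controls=30, n_genes=200, module_sizes=(50, 50, 50),
        n_mirs=60, targets_per_regulator=15, utr_length_range=(200, 400), seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return mm.generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator at its study-condition defaults (66 samples, 500 genes)."""
    return mm.generate_dataset(mm.SimulationConfig(seed=7))


def expr_from(array, feature_ids=None, sample_ids=None, kind="gene"):
    array = np.asarray(array, dtype=float)
    feature_ids = feature_ids or [f"g{i}" for i in range(array.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(array.shape[1])]
    return mm.ExpressionMatrix(pd.DataFrame(array, index=feature_ids, columns=sample_ids), kind=kind)


def annotation_for(sample_ids, groups, **extra):
    table = pd.DataFrame({"group": list(groups), **extra},
                         index=pd.Index(sample_ids, name="sample_id"))
    return mm.SampleAnnotation(table)
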