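import numpy as np
import pandas as pd
import pytest

from subtyper.classifier import ClassifierConfig
from subtyper.pipeline import PipelineConfig
from subtyper.synthetic import SubtypeSpec, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def fast_classifier_config():
    """Small learner settings for unit tests on tiny cohorts."""
    return ClassifierConfig(
        cv_folds=3,
        calibration_folds=2,
        rf_estimators=30,
        mlp_hidden=(16,),
        mlp_max_iter=150,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_config():
    """3 well-separated subtypes, 24 samples each, 500 genes."""
    return SyntheticConfig(
        n_genes=500,
        subtypes=[SubtypeSpec(f"T{i + 1}", 24, 15, 2.5) for i in range(3)],
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_pipeline_config(fast_classifier_config):
    return PipelineConfig(
        profile="ST",
        classifier=fast_classifier_config,
        threshold_bootstrap_sets=5,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cohort, tiny_pipeline_config):
    """A trained bundle on the tiny cohort, shared across tests."""
    from subtyper.pipeline import train_pipeline

    counts, table, _ = tiny_cohort
    bundle, report = train_pipeline(counts, table, tiny_pipeline_config)
    return bundle, report


def toy_counts(values, genes=None, samples=None):
    """Helper: CountMatrix from a nested list."""
    from subtyper.data_io import CountMatrix

    arr = np.asarray(values)
    genes = genes or [f"G{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))
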