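"""Shared fixtures: small programmatically generated datasets."""

import numpy as np
import pandas as pd
import pytest

from methsignal.meth_io import MethSample
from methsignal.simulator import SimConfig, simulate_dataset


def make_sample(records, sample_id="S", group="control"):
    """Build a MethSample from (chrom, pos, n_mc, n_uc) tuples."""
    data = pd.DataFrame(records, columns=["chrom", "pos", "n_mc", "n_uc"])
    return MethSample(sample_id=sample_id, group=group, data=data)


@pytest.fixture(scope="session")
def medium_dataset():
    """Medium effect-size simulated dataset shared across expensive tests."""
    return simulate_dataset(
        SimConfig(n_sites=8000, target_mean_tv=0.1332, seed=11, population_seed=101)
    )


@pytest.fixture(scope="session")
def medium_pipeline(medium_dataset):
    """A completed pipeline run on the medium dataset."""
    from methsignal.classifier import ClassifierSpec
    from methsignal.pipeline import PipelineConfig, run_pipeline

    ds = medium_dataset
    config = PipelineConfig(
        samples=ds.control + ds.treatment,
        reference_samples=ds.reference,
        chrom_lengths=ds.chrom_lengths,
        cutoff_method="classifier_posterior",
        classifier_spec=ClassifierSpec(family="pca_qda"),
        cv_resamples=60,
        seed=7,
    )
    return run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
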