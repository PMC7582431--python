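"""Shared fixtures: small synthetic corpora and a once-trained pipeline."""

import numpy as np
import pytest

from lncloc import model_eval, seq_io


@pytest.fixture(scope="session")
def small_dataset() -> seq_io.LabeledDataset:
    """A small 4-class imbalanced corpus with the default planted signals."""
    config = seq_io.SyntheticConfig(
        n_per_class={"cytoplasm": 12, "nucleus": 9, "ribosome": 6, "exosome": 6},
        length_range=(200, 300),
        seed=11,
    )
    return seq_io.generate_synthetic_dataset(config)


@pytest.fixture(scope="session")
def small_config() -> model_eval.PipelineConfig:
    return model_eval.PipelineConfig(seed=11, grid_cv_folds=3, ifs_cv_folds=3)


@pytest.fixture(scope="session")
def small_structures(small_dataset, small_config):
    return model_eval.compute_structures(small_dataset.sequences, small_config)


@pytest.fixture(scope="session")
def trained_bundle(small_dataset, small_config, small_structures):
    """Full pipeline fitted once on the small corpus, reused across tests."""
    return model_eval.train(small_dataset, small_config, small_structures)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
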