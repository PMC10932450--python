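"""Shared fixtures: packaged config, small synthetic datasets, the default run."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from libs_tissue import (
    DEFAULT_COUNTS,
    DatasetSpec,
    TissueClass,
    default_config,
    features_table,
    generate_dataset,
    preprocess_all,
)

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def catalog(config):
    return config.catalog


@pytest.fixture(scope="session")
def grid_wl(config):
    return config.grid.wavelengths()


@pytest.fixture(scope="session")
def model(config):
    return config.model


@pytest.fixture(scope="session")
def quiet_model(model):
    """The default model with noise and gain jitter switched off."""
    return dataclasses.replace(model, noise_sd_au=0.0, gain_log_sd=0.0)


@pytest.fixture(scope="session")
def small_dataset(model, grid_wl, catalog):
    """A fast 4 x 25 study-class dataset."""
    counts = {cls: 25 for cls in DEFAULT_COUNTS}
    return generate_dataset(
        model, DatasetSpec(counts=counts, seed=7), grid_wl=grid_wl, catalog=catalog
    )


@pytest.fixture(scope="session")
def small_vectors(small_dataset, catalog):
    return preprocess_all(small_dataset, catalog)


@pytest.fixture(scope="session")
def small_features(small_vectors, catalog):
    return features_table(small_vectors, catalog)


@pytest.fixture(scope="session")
def default_run(model, grid_wl, catalog):
    """The full study-condition run: published class counts, seed 42.

    Session-scoped because it is the anchor of several end-to-end checks and
    takes a few seconds to simulate and preprocess.
    """
    spectra = generate_dataset(
        model, DatasetSpec(counts=dict(DEFAULT_COUNTS), seed=42),
        grid_wl=grid_wl, catalog=catalog,
    )
    vectors = preprocess_all(spectra, catalog)
    features = features_table(vectors, catalog)
    return {"spectra": spectra, "vectors": vectors, "features": features}


def grouped(features, element):
    """Element values per tissue class (helper shared across test modules)."""
    out: dict[TissueClass, list[float]] = {}
    for f in features:
        out.setdefault(f.tissue, []).append(f.value(element))
    return {t: np.asarray(v) for t, v in out.items()}
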