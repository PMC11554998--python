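"""Shared fixtures: the default synthetic study, its features, and a trained panel."""

import numpy as np
import pytest

from purscreen import (
    FingerprintSpec,
    GeneratorConfig,
    curate_dataset,
    default_panel,
    featurize_dataset,
    generate_bioactivity_dataset,
    train_classifier,
)


@pytest.fixture(scope="session")
def default_bioactivity():
    """Raw records + ground truth at the default study conditions (seed 0)."""
    return generate_bioactivity_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def curated_default(default_bioactivity):
    records, _ = default_bioactivity
    return curate_dataset(records, cutoff_molar=5e-6)


@pytest.fixture(scope="session")
def Xy_default(curated_default):
    return featurize_dataset(curated_default, FingerprintSpec("circular", 3, 2048))


@pytest.fixture(scope="session")
def trained_panel(Xy_default):
    """The eight-model consensus panel trained on the default dataset."""
    X, y = Xy_default
    return {spec.name: train_classifier(spec, X, y) for spec in default_panel(seed=0)}
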