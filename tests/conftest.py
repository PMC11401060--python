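import warnings

import numpy as np
import pytest

from mutstruct.dataset import FeatureConfig, assemble_matrix, clean_dataset, grouped_split
from mutstruct.fixtures import (
    SynthConfig,
    build_extended_chain,
    build_ideal_helix,
    build_two_helix_bundle,
    synth_dataset,
)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def helix():
    return build_ideal_helix("A" * 26 + "LKVF", protein_id="HLX", bfactor=90.0)


@pytest.fixture(scope="session")
def extended():
    return build_extended_chain("ARNDCQEGHIKLMFPSTWYV", protein_id="EXT")


@pytest.fixture(scope="session")
def bundle():
    return build_two_helix_bundle("L" * 14, "L" * 14)


@pytest.fixture(scope="session")
def synth_small():
    """Separable planted-signal dataset: 3 proteins, 120 mutations."""
    config = SynthConfig(seed=7, n_proteins=3, length=40, n_mutations=40, noise=0.0)
    proteins, mutations = synth_dataset(config)
    dataset, rejected = clean_dataset(mutations, proteins)
    assert not rejected
    return config, dataset


# a light feature configuration for tests that only need plumbing speed
LIGHT_CONFIG = dict(
    include_structure=False,
    include_contacts=False,
    include_signatures=False,
)


@pytest.fixture(scope="session")
def synth_matrices(synth_small):
    """Train/val/test feature matrices on the separable preset (full features)."""
    _, dataset = synth_small
    config = FeatureConfig()
    train, val, test = grouped_split(dataset, seed=11)
    return (
        assemble_matrix(train, config),
        assemble_matrix(val, config),
        assemble_matrix(test, config),
    )
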