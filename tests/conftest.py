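"""Shared fixtures: tiny constructed spectra and a session-scoped synthetic
training dataset at the default study conditions (872 N / 527 O spectra)."""
from __future__ import annotations

import numpy as np
import pytest

from glycotyper import Ms2Spectrum, train
from glycotyper.synth import GeneratorConfig, generate_dataset


def make_spectrum(pairs, scan_id="scan1", precursor_mz=1000.0, charge=2):
    """Spectrum from (mz, intensity) pairs."""
    mz = [p[0] for p in pairs]
    inten = [p[1] for p in pairs]
    return Ms2Spectrum(scan_id, precursor_mz, charge, mz, inten)


@pytest.fixture(scope="session")
def paper_like_dataset():
    """Default-condition synthetic training set: 872 N + 527 O spectra, seed 1."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def trained_model(paper_like_dataset):
    ds = paper_like_dataset
    return train(ds.features, ds.labels, seed=1)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noiseless, jitter-free dataset where every fragment is emitted:
    search results are exactly predictable from the planted truth."""
    config = GeneratorConfig(
        seed=7,
        n_n=50,
        n_o=50,
        jitter_ppm=0.0,
        ms1_jitter_ppm=0.0,
        n_noise_peaks=0,
        frag_efficiency_by=1.0,
        frag_efficiency_y=1.0,
    )
    return generate_dataset(config)
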