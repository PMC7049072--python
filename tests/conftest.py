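"""Shared fixtures: small spectra, models and engine configurations.

Everything is generated programmatically; nothing is read from disk except
round-trip targets written into pytest's tmp_path.
"""

import numpy as np
import pytest

from demogen_ga import (
    DemographicModel,
    Dynamics,
    EngineConfig,
    Epoch,
    FrequencySpectrum,
    Split,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def spectrum_1pop():
    """Observed 1-population spectrum, n = 4."""
    return FrequencySpectrum(np.array([0.0, 10.0, 5.0, 2.0, 0.0]))


@pytest.fixture
def spectrum_2pop(rng):
    """Random observed 2-population spectrum, n = (4, 4)."""
    counts = rng.poisson(5.0, size=(5, 5)).astype(float)
    return FrequencySpectrum(counts)


@pytest.fixture
def model_2pop_migration():
    """Split with asymmetric migration and unequal daughter sizes."""
    return DemographicModel(
        (1, 1),
        [
            Split(0.5),
            Epoch(
                0.5,
                (1.5, 0.5),
                (Dynamics.SUDDEN, Dynamics.SUDDEN),
                ((0.0, 1.0), (0.5, 0.0)),
            ),
        ],
    )


@pytest.fixture
def model_1pop_growth():
    """Single population, sudden expansion to twice the ancestral size."""
    return DemographicModel((2,), [Epoch(0.3, (2.0,), (Dynamics.SUDDEN,))])


@pytest.fixture
def engine_small():
    return EngineConfig(sample_sizes=(6, 6))
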