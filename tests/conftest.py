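import dataclasses

import numpy as np
import pandas as pd
import pytest

from tachem import synthetic
from tachem.datatypes import EEMTensor, SpectralMatrix
from tachem.scenarios import default_scenarios


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def uvvis_default(scenarios):
    return synthetic.generate_uvvis_titration(scenarios["fe_ta_uvvis"])


@pytest.fixture(scope="session")
def uvvis_noiseless(scenarios):
    sc = dataclasses.replace(scenarios["fe_ta_uvvis"], noise_sd=0.0)
    return synthetic.generate_uvvis_titration(sc)


@pytest.fixture(scope="session")
def ta_eem_default(scenarios):
    return synthetic.generate_eem_set(scenarios["ta_eem"])


def make_spectral_matrix(absorbance, wavelengths=None, ph=None):
    """Minimal SpectralMatrix around a plain array for unit tests."""
    absorbance = np.atleast_2d(np.asarray(absorbance, dtype=float))
    n, m = absorbance.shape
    if wavelengths is None:
        wavelengths = 400.0 + 2.0 * np.arange(m)
    meta = pd.DataFrame(
        {
            "ph": ph if ph is not None else np.linspace(4.0, 8.0, n),
            "m_total": 2.0e-5,
            "ta_total_g_l": 0.034024,
        },
        index=pd.Index([f"s{i:02d}" for i in range(n)], name="sample_id"),
    )
    return SpectralMatrix(wavelengths, absorbance, meta)


def make_eem(intensities, emission=None, excitation=None, mask=None):
    """Minimal EEMTensor around a plain array for unit tests."""
    intensities = np.asarray(intensities, dtype=float)
    i, j, k = intensities.shape
    if emission is None:
        emission = 250.0 + 10.0 * np.arange(j)
    if excitation is None:
        excitation = 200.0 + 10.0 * np.arange(k)
    meta = pd.DataFrame(
        {"ph": np.linspace(3.5, 8.5, i), "composition": "TA"},
        index=pd.Index([f"e{n:02d}" for n in range(i)], name="sample_id"),
    )
    return EEMTensor(intensities, emission, excitation, meta, mask=mask)
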