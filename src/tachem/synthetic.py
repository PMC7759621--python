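"""Seeded synthetic datasets with the structure the estimators assume.

Three generators mirror the three experiments of the Fe(III)-TA study:

* a bilinear UV-vis pH titration, X = C S^T + E, whose concentration rows
  come from the single-site speciation model evaluated at each pH;
* a trilinear fluorescence EEM stack with first/second-order Rayleigh and
  water-Raman ridges, metal quenching, and proportional noise;
* a continuous-variation (Job) absorbance series under saturating
  multi-site binding.

Every generator draws all randomness from one integer seed and returns
its ground-truth factors for recovery testing.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import speciation
from .datatypes import EEMTensor, JobsSeries, SpectralMatrix
from .errors import ConfigurationError
from .scenarios import EEMScenario, JobsScenario, UvVisScenario


def generate_uvvis_titration(scenario: UvVisScenario) -> SpectralMatrix:
    """Simulate an absorbance-vs-wavelength titration matrix.

    Concentration rows follow the speciation closed form with the
    scenario's cK(pH) profiles; spectra are the Gaussian extinction bands
    of the scenario components (Beer-Lambert, 1 cm path).
    """
    if len(scenario.components) != 2:
        raise ConfigurationError(
            "the titration generator models exactly two complex species"
        )
    rng = np.random.default_rng(scenario.seed)
    wl = scenario.wavelength_grid
    ph = np.asarray(scenario.ph_values, dtype=float)
    ta_g_l = scenario.ta_total_g_l

    k1 = scenario.k1_ph_profile(ph)
    k2 = scenario.k2_ph_profile(ph)
    c1p = speciation.cprime(k1, ta_g_l)
    c2p = speciation.cprime(k2, ta_g_l)
    mta1, mta2, m_free = speciation.species_conc(c1p, c2p, scenario.m_total)

    C = np.column_stack([mta1, mta2])  # mol/L
    S = np.column_stack([c.spectrum(wl) for c in scenario.components])  # 1/(M cm)
    X = C @ S.T
    if scenario.noise_sd > 0:
        X = X + rng.normal(0.0, scenario.noise_sd, size=X.shape)

    ids = [f"s{i:02d}" for i in range(len(ph))]
    meta = pd.DataFrame(
        {
            "ph": ph,
            "m_total": scenario.m_total,
            "ta_total_g_l": ta_g_l,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    truth = {
        "C": C,
        "S": S,
        "m_free": m_free,
        "k1": k1,
        "k2": k2,
        "component_names": [c.name for c in scenario.components],
    }
    return SpectralMatrix(wl, X, meta, truth=truth)


def raman_emission(excitation_nm, shift_cm: float = 3400.0):
    """Emission wavelength of the Raman line for a given excitation."""
    ex = np.asarray(excitation_nm, dtype=float)
    return 1.0 / (1.0 / ex - shift_cm * 1e-7)


def _scatter_field(em, ex, params, scale: float) -> np.ndarray:
    """Additive scatter ridges on an (em x ex) grid, one sample slab."""
    E, X = np.meshgrid(em, ex, indexing="ij")
    out = params.rayleigh1_amp * scale * np.exp(
        -((E - X) ** 2) / (2.0 * params.rayleigh1_width**2)
    )
    out += params.rayleigh2_amp * scale * np.exp(
        -((E - 2.0 * X) ** 2) / (2.0 * params.rayleigh2_width**2)
    )
    em_raman = raman_emission(X, params.raman_shift_cm)
    out += params.raman_amp * scale * np.exp(
        -((E - em_raman) ** 2) / (2.0 * params.raman_width**2)
    )
    return out


def generate_eem_set(scenario: EEMScenario) -> EEMTensor:
    """Simulate a stack of EEM landscapes (sample x emission x excitation).

    The clean signal is exactly trilinear: sum over components of
    score(pH) * emission_loading x excitation_loading.  Components with
    the quench flag are suppressed by ``quench_factor`` when the metal is
    present.  Scatter ridges and Gaussian noise are added on top.
    """
    rng = np.random.default_rng(scenario.seed)
    em = scenario.emission_grid
    ex = scenario.excitation_grid
    ph = np.asarray(scenario.sample_ph_values, dtype=float)

    B = np.column_stack([c.emission_loading(em) for c in scenario.components])
    Cx = np.column_stack([c.excitation_loading(ex) for c in scenario.components])
    A = np.column_stack([c.score(ph) for c in scenario.components])
    if scenario.fe_present:
        for j, comp in enumerate(scenario.components):
            if comp.quench:
                A[:, j] = A[:, j] * scenario.quench_factor
    if np.any(A < 0):
        raise ConfigurationError("score profiles produced negative fluorescence")

    clean = np.einsum("in,jn,kn->ijk", A, B, Cx)
    scale = float(clean.max())
    data = clean.copy()
    if scenario.scatter is not None:
        data = data + _scatter_field(em, ex, scenario.scatter, scale)[None, :, :]
    # heteroscedastic detector model: additive floor + signal-proportional
    # (shot/source) term -- fluorescence counting noise grows with signal
    sd = scenario.noise_frac * scale + scenario.noise_prop * clean
    if scenario.noise_frac > 0 or scenario.noise_prop > 0:
        data = data + rng.normal(0.0, 1.0, size=data.shape) * sd

    ids = [f"e{i:02d}" for i in range(len(ph))]
    meta = pd.DataFrame(
        {
            "ph": ph,
            "composition": "Fe-TA" if scenario.fe_present else "TA",
        },
        index=pd.Index(ids, name="sample_id"),
    )
    truth = {
        "A": A,
        "B": B,
        "C": Cx,
        "clean": clean,
        "component_names": [c.name for c in scenario.components],
    }
    return EEMTensor(data, em, ex, meta, truth=truth)


def bound_metal(x, total: float, n_sites: int, binding_strength: float = math.inf):
    """Bound-metal concentration in a continuous-variation mixture.

    Metal is ``x * total``, ligand sites ``n_sites * (1 - x) * total``.
    Under saturating binding the bound amount is the lesser of the two;
    for a finite per-site association constant K the 1:1 site equilibrium
    quadratic is solved instead.
    """
    x = np.asarray(x, dtype=float)
    m = x * total
    sites = n_sites * (1.0 - x) * total
    if math.isinf(binding_strength):
        return np.minimum(m, sites)
    k = binding_strength
    s = m + sites + 1.0 / k
    return (s - np.sqrt(s * s - 4.0 * m * sites)) / 2.0


def generate_jobs_series(scenario: JobsScenario) -> JobsSeries:
    """Simulate a Job's-plot absorbance series at the analytic wavelength."""
    rng = np.random.default_rng(scenario.seed)
    x = np.asarray(scenario.molar_fractions, dtype=float)
    bound = bound_metal(
        x, scenario.total_conc, scenario.n_sites, scenario.binding_strength
    )
    absorbance = scenario.epsilon_per_site * bound
    if scenario.noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, scenario.noise_sd, size=x.shape)
    return JobsSeries(
        x,
        absorbance,
        scenario.total_conc,
        scenario.analytic_wavelength,
        truth={"bound": bound, "n_sites": scenario.n_sites},
    )
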