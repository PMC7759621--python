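"""Single-site conditional-constant speciation model.

The ligand is a heterogeneous macromolecule whose molar concentration is
ill-defined, so binding strength is expressed through a conditional
formation constant with the ligand as a mass concentration:

    cK = [MTA] / ([M] * (TA)_total)        (L/g)

with [MTA] the bound metal, [M] the free metal (mol/L) and (TA)_total the
total ligand in g/L.  The model assumes 1:1 metal-site complexes, a single
dominant site class, pH-independent site availability within the working
window, and no site-site interactions.  Two complex species (MTA1, MTA2)
are carried; with the dimensionless products c'K_n = cK_n * (TA)_total and
the metal mass balance

    (M)_total = [M] + [MTA1] + [MTA2]

the species concentrations follow in closed form:

    [MTAn] = c'K_n / (c'K_1 + c'K_2 + 1) * (M)_total

and the absorbance of a mixture at wavelength L is

    Abs_L = (eps1_L * f1 + eps2_L * f2) * (M)_total,   f_n = [MTAn]/(M)_total.

The proton-competition caveat: the binding sites do deprotonate below
~pH 5, which is precisely why cK is conditional and tabulated per pH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FreeMetalExhaustedError

#: numeric floor below which free metal is treated as exhausted (mol/L)
FREE_METAL_FLOOR = 1e-12

#: reference band maxima used to map resolved components to species, nm
SPECIES_LAMBDA_MAX = {"MTA1": 580.0, "MTA2": 513.0}

#: model preconditions (single-site formalism); assumption 5 is known to be
#: violated below ~pH 5, which the conditional (per-pH) constants absorb
MODEL_ASSUMPTIONS = (
    "1:1 metal-to-site complexes only",
    "one dominant ligand-site class in the working range",
    "site strength independent of position in the macromolecule",
    "number of active sites unaffected by chemical changes of the polymer",
    "no proton exchange of binding sites in the pH range (violated below pH 5; "
    "absorbed into the pH-conditional constants)",
    "no electrostatic site-site interactions",
)


@dataclass
class SpeciationParams:
    """Inputs of the absorbance prediction at one pH and wavelength."""

    k1: float  # conditional constant of MTA1, L/g
    k2: float  # L/g
    eps1: float  # extinction of MTA1 at the analytic wavelength, 1/(M cm)
    eps2: float  # 1/(M cm)
    ta_total: float  # g/L
    m_total: float  # mol/L
    wavelength: float = 570.0  # nm
    ph: float = 4.0

    def __post_init__(self):
        if min(self.k1, self.k2) < 0 or min(self.eps1, self.eps2) < 0:
            raise ConfigurationError("constants and extinctions must be >= 0")
        if min(self.ta_total, self.m_total) <= 0:
            raise ConfigurationError("totals must be > 0")


def conditional_k(c_mta, c_m_free, ta_total, floor: float = FREE_METAL_FLOOR):
    """Conditional formation constant cK = [MTA]/([M] (TA)_total), L/g."""
    if ta_total <= 0:
        raise ConfigurationError("ta_total must be > 0")
    c_m_free = np.asarray(c_m_free, dtype=float)
    if np.any(c_m_free <= floor):
        raise FreeMetalExhaustedError(
            f"free metal <= floor ({floor:g} mol/L); cK undefined"
        )
    return np.asarray(c_mta, dtype=float) / (c_m_free * ta_total)


def cprime(k, ta_total):
    """Dimensionless constant c'K = cK * (TA)_total."""
    k = np.asarray(k, dtype=float)
    if np.any(k < 0) or ta_total < 0:
        raise ConfigurationError("inputs must be >= 0")
    out = k * ta_total
    return out.item() if out.ndim == 0 else out


def species_conc(cprime1, cprime2, m_total):
    """Closed-form species concentrations from the mass balance.

    Returns ``(mta1, mta2, m_free)`` in mol/L; broadcasts over array
    inputs of the dimensionless constants.
    """
    if m_total <= 0:
        raise ConfigurationError("m_total must be > 0")
    c1 = np.asarray(cprime1, dtype=float)
    c2 = np.asarray(cprime2, dtype=float)
    denom = c1 + c2 + 1.0
    mta1 = c1 / denom * m_total
    mta2 = c2 / denom * m_total
    m_free = m_total - mta1 - mta2
    if mta1.ndim == 0:
        return mta1.item(), mta2.item(), m_free.item()
    return mta1, mta2, m_free


def predict_absorbance(params: SpeciationParams) -> float:
    """Absorbance (1 cm path) of the mixture from the two-species model."""
    c1 = cprime(params.k1, params.ta_total)
    c2 = cprime(params.k2, params.ta_total)
    denom = c1 + c2 + 1.0
    return (params.eps1 * c1 / denom + params.eps2 * c2 / denom) * params.m_total


def map_components_to_species(lambda_max_values) -> list:
    """Assign resolved components to MTA1/MTA2 by band-maximum proximity.

    Returns the species names in component order.  The longer-wavelength
    band (ref 580 nm) is MTA1, the shorter (ref 513 nm) MTA2.
    """
    lam = np.asarray(lambda_max_values, dtype=float)
    if len(lam) != 2:
        raise ConfigurationError("species mapping defined for exactly 2 components")
    names = ["MTA1", "MTA2"]
    refs = np.array([SPECIES_LAMBDA_MAX[n] for n in names])
    # two permutations: pick the one with smaller total wavelength mismatch
    if np.abs(lam - refs).sum() <= np.abs(lam - refs[::-1]).sum():
        return names
    return names[::-1]


def k_profile_from_mcr(
    mcr_result,
    sample_meta: pd.DataFrame,
    molecular_weight: float = 1701.20,
    m_floor: float = FREE_METAL_FLOOR,
    c_floor: float = 0.0,
) -> pd.DataFrame:
    """Tabulate cK1, cK2 per pH from resolved concentration profiles.

    ``mcr_result.C`` must be in mol/L (closure-scaled or extinction-
    calibrated).  Free metal comes from the mass balance; rows where it
    falls at or below ``m_floor`` are flagged ``saturated`` and carry no
    constants (the titration inflection region, where the balance is
    dominated by noise).  ``c_floor`` is a per-species quantification
    limit: a constant whose complex concentration is at or below it is
    still reported but marked non-quantifiable (curve-resolution noise
    makes such K values order-of-magnitude estimates only).

    Returns a DataFrame with columns ph, mta1, mta2, m_free, k1, k2,
    log_k1, log_k2, saturated, k1_quantifiable, k2_quantifiable.
    """
    for col in ("ph", "m_total", "ta_total_g_l"):
        if col not in sample_meta.columns:
            raise ConfigurationError(f"sample metadata missing column {col!r}")
    C = np.asarray(mcr_result.C, dtype=float)
    if C.shape[1] != 2:
        raise ConfigurationError("speciation mapping needs a 2-component model")
    order = map_components_to_species(mcr_result.lambda_max)
    c_mta1 = C[:, order.index("MTA1")]
    c_mta2 = C[:, order.index("MTA2")]
    m_total = sample_meta["m_total"].to_numpy(dtype=float)
    ta_total = sample_meta["ta_total_g_l"].to_numpy(dtype=float)
    m_free = m_total - c_mta1 - c_mta2
    saturated = m_free <= m_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = np.where(saturated, np.nan, c_mta1 / (m_free * ta_total))
        k2 = np.where(saturated, np.nan, c_mta2 / (m_free * ta_total))
        log_k1 = np.where(k1 > 0, np.log10(np.where(k1 > 0, k1, 1.0)), np.nan)
        log_k2 = np.where(k2 > 0, np.log10(np.where(k2 > 0, k2, 1.0)), np.nan)
    return pd.DataFrame(
        {
            "ph": sample_meta["ph"].to_numpy(dtype=float),
            "mta1": c_mta1,
            "mta2": c_mta2,
            "m_free": m_free,
            "k1": k1,
            "k2": k2,
            "log_k1": log_k1,
            "log_k2": log_k2,
            "saturated": saturated,
            "k1_quantifiable": ~saturated & (c_mta1 > c_floor),
            "k2_quantifiable": ~saturated & (c_mta2 > c_floor),
        },
        index=sample_meta.index,
    )


def validate_prediction(observed, predicted) -> pd.DataFrame:
    """Per-sample relative differences |obs - pred|/obs in percent.

    Samples with zero observed absorbance are flagged ``excluded`` and
    carry no percentage.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ConfigurationError("observed/predicted length mismatch")
    excluded = obs == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(excluded, np.nan, np.abs(obs - pred) / np.abs(obs) * 100.0)
    return pd.DataFrame(
        {"observed": obs, "predicted": pred, "rel_diff_pct": rel, "excluded": excluded}
    )
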