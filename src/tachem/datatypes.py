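"""In-memory containers for the spectral data handled by the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: metadata columns every UV-vis sample table must carry
META_COLUMNS = ("ph", "m_total", "ta_total_g_l")


@dataclass
class SpectralMatrix:
    """Samples x wavelengths absorbance block with per-sample chemistry.

    Attributes
    ----------
    wavelengths : (n_wl,) strictly increasing grid in nm.
    absorbance : (n_samples, n_wl) absorbance in AU (1 cm path).
    sample_meta : DataFrame indexed by sample id with columns
        ``ph``, ``m_total`` (mol/L) and ``ta_total_g_l`` (g/L).
    truth : optional dict with ground-truth ``C`` (mol/L) and ``S``
        (extinction, 1/(M cm)) factors when the matrix is synthetic.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_meta: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigurationError("wavelength grid must be strictly increasing")
        if self.absorbance.shape != (len(self.sample_meta), len(self.wavelengths)):
            raise ConfigurationError(
                f"absorbance shape {self.absorbance.shape} inconsistent with "
                f"{len(self.sample_meta)} samples x {len(self.wavelengths)} wavelengths"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ConfigurationError("absorbance contains non-finite values")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ConfigurationError(f"sample_meta missing columns: {missing}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]


@dataclass
class EEMTensor:
    """Stack of excitation-emission matrices (mode order: sample, em, ex).

    ``mask`` marks scatter-excised cells as True (missing); a freshly
    generated tensor has an all-False mask.
    """

    intensities: np.ndarray  # (n_samples, n_em, n_ex)
    emission: np.ndarray  # nm
    excitation: np.ndarray  # nm
    sample_meta: pd.DataFrame  # columns: ph, composition
    mask: np.ndarray = None  # type: ignore[assignment]
    truth: dict | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.excitation = np.asarray(self.excitation, dtype=float)
        for grid, name in ((self.emission, "emission"), (self.excitation, "excitation")):
            if np.any(np.diff(grid) <= 0):
                raise ConfigurationError(f"{name} grid must be strictly increasing")
        expected = (len(self.sample_meta), len(self.emission), len(self.excitation))
        if self.intensities.shape != expected:
            raise ConfigurationError(
                f"tensor shape {self.intensities.shape}, expected {expected}"
            )
        if self.mask is None:
            self.mask = np.zeros_like(self.intensities, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.isfinite(self.intensities[~self.mask])):
            raise ConfigurationError("unmasked intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def copy(self) -> "EEMTensor":
        return EEMTensor(
            self.intensities.copy(),
            self.emission.copy(),
            self.excitation.copy(),
            self.sample_meta.copy(),
            self.mask.copy(),
            self.truth,
        )


@dataclass
class JobsSeries:
    """Continuous-variation (Job) series at one analytic wavelength."""

    molar_fraction_metal: np.ndarray
    absorbance: np.ndarray  # AU
    total_conc: float  # mol/L
    wavelength: float  # nm
    truth: dict | None = None

    def __post_init__(self):
        self.molar_fraction_metal = np.asarray(self.molar_fraction_metal, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        x = self.molar_fraction_metal
        if np.any((x <= 0) | (x >= 1)):
            raise ConfigurationError("molar fractions must lie strictly in (0, 1)")
        if np.any(np.diff(x) <= 0):
            raise ConfigurationError("molar fractions must be strictly increasing")
        if len(x) != len(self.absorbance):
            raise ConfigurationError("fraction/absorbance length mismatch")
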