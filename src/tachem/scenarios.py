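"""Scenario definitions for the synthetic-data generators.

A scenario freezes the chemical conditions of one simulated experiment:
grids, totals, the pure-component band parameters, the pH dependence of
the conditional binding constants, and the noise model.  Packaged
defaults transcribe the Fe(III)-tannic-acid system: a 1:1 titration at
2.00e-5 mol/L total metal, two complex species (bands at 580 and 513 nm
with extinction maxima 3487 and 7576 1/(M cm)), conditional constants
anchored at pH 4 to 52.9 and 3.78 L/g, and TA treated as decagalloyl
glucose (1701.20 g/mol).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, ValidityRangeError

#: chemical validity window: below pH 3.5 the ligand reduces Fe(III),
#: above 8.5 the ligand itself is unstable
PH_WINDOW = (3.5, 8.5)

#: formal molecular weight of decagalloyl glucose, g/mol
TA_MOLECULAR_WEIGHT = 1701.20


def _grid(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass
class PureComponent:
    """Single Gaussian absorption band of one complex species."""

    name: str
    lambda_max: float  # nm
    epsilon_max: float  # 1/(M cm)
    band_fwhm: float  # nm

    def __post_init__(self):
        if self.epsilon_max <= 0:
            raise ConfigurationError(f"{self.name}: epsilon_max must be > 0")
        if self.band_fwhm <= 0:
            raise ConfigurationError(f"{self.name}: band_fwhm must be > 0")

    def spectrum(self, wavelengths: np.ndarray) -> np.ndarray:
        """Extinction profile on a wavelength grid, 1/(M cm)."""
        w = np.asarray(wavelengths, dtype=float)
        return self.epsilon_max * np.exp(
            -4.0 * math.log(2.0) * (w - self.lambda_max) ** 2 / self.band_fwhm**2
        )


@dataclass
class KProfile:
    """Piecewise-linear pH dependence of a conditional constant.

    log10 cK rises linearly with pH from the pH-4 anchor and is constant
    above ``plateau_ph``.
    """

    k_at_ph4: float  # L/g
    slope: float = 2.0  # log10 units per pH
    plateau_ph: float = 5.0

    def __call__(self, ph):
        ph = np.asarray(ph, dtype=float)
        logk = math.log10(self.k_at_ph4) + self.slope * (
            np.minimum(ph, self.plateau_ph) - 4.0
        )
        return 10.0**logk


@dataclass
class UvVisScenario:
    wavelength_start: float = 400.0
    wavelength_stop: float = 900.0
    wavelength_step: float = 2.0
    ph_values: list = field(default_factory=lambda: list(np.round(np.arange(4.5, 8.51, 0.25), 4)))
    m_total: float = 2.00e-5  # mol/L
    ta_molar_nominal: float = 2.00e-5  # mol/L
    ta_molecular_weight: float = TA_MOLECULAR_WEIGHT  # g/mol
    components: list = field(
        default_factory=lambda: [
            PureComponent("MTA1", 580.0, 3487.0, 150.0),
            PureComponent("MTA2", 513.0, 7576.0, 120.0),
        ]
    )
    k1_ph_profile: KProfile = field(default_factory=lambda: KProfile(52.9, 2.0, 5.0))
    k2_ph_profile: KProfile = field(default_factory=lambda: KProfile(3.78, 1.5, 7.0))
    noise_sd: float = 0.002  # AU
    seed: int = 20210

    def __post_init__(self):
        if self.wavelength_step <= 0:
            raise ConfigurationError("wavelength step must be > 0")
        if min(self.m_total, self.ta_molar_nominal) <= 0:
            raise ConfigurationError("total concentrations must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        lo, hi = PH_WINDOW
        bad = [p for p in self.ph_values if not lo <= p <= hi]
        if bad:
            raise ValidityRangeError(
                f"pH values {bad} outside the validity window [{lo}, {hi}]"
            )
        grid = self.wavelength_grid
        for comp in self.components:
            if not grid[0] <= comp.lambda_max <= grid[-1]:
                raise ConfigurationError(
                    f"{comp.name}: lambda_max {comp.lambda_max} nm outside grid"
                )

    @property
    def wavelength_grid(self) -> np.ndarray:
        return _grid(self.wavelength_start, self.wavelength_stop, self.wavelength_step)

    @property
    def ta_total_g_l(self) -> float:
        return self.ta_molar_nominal * self.ta_molecular_weight


@dataclass
class EEMComponent:
    """One fluorophore: Gaussian excitation peak(s) and emission band.

    The sample score follows a logistic pH profile
    ``score_base + score_amplitude / (1 + exp(-(pH - ph_midpoint)/ph_scale))``
    so components can switch on with pH, as the high-pH ligand band does.
    """

    name: str
    excitation_peaks: list  # nm; first entry is the main peak
    excitation_widths: list  # FWHM nm, one per peak
    excitation_amplitudes: list  # relative, one per peak
    emission_peak: float  # nm
    emission_width: float  # FWHM nm
    score_base: float = 0.0
    score_amplitude: float = 0.0
    ph_midpoint: float = 7.0
    ph_scale: float = 0.5
    quench: bool = False  # suppressed when the metal is present

    def __post_init__(self):
        k = len(self.excitation_peaks)
        if len(self.excitation_widths) != k or len(self.excitation_amplitudes) != k:
            raise ConfigurationError(f"{self.name}: excitation peak lists mismatched")

    def excitation_loading(self, grid: np.ndarray) -> np.ndarray:
        g = np.zeros_like(np.asarray(grid, dtype=float))
        for p, w, a in zip(
            self.excitation_peaks, self.excitation_widths, self.excitation_amplitudes
        ):
            g = g + a * np.exp(-4.0 * math.log(2.0) * (grid - p) ** 2 / w**2)
        return g / g.max()

    def emission_loading(self, grid: np.ndarray) -> np.ndarray:
        g = np.exp(
            -4.0 * math.log(2.0) * (np.asarray(grid, float) - self.emission_peak) ** 2
            / self.emission_width**2
        )
        return g / g.max()

    def score(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return self.score_base + self.score_amplitude / (
            1.0 + np.exp(-(ph - self.ph_midpoint) / self.ph_scale)
        )


@dataclass
class ScatterParams:
    """Rayleigh/Raman ridge parameters (Gaussian cross-sections along Em)."""

    rayleigh1_amp: float = 2.0  # x max clean signal
    rayleigh1_width: float = 4.0  # sd, nm (~10 nm FWHM, the bandpass)
    rayleigh2_amp: float = 0.6
    rayleigh2_width: float = 5.0
    raman_amp: float = 0.08
    raman_width: float = 4.0
    raman_shift_cm: float = 3400.0  # water Raman shift, 1/cm


@dataclass
class EEMScenario:
    excitation_start: float = 200.0
    excitation_stop: float = 500.0
    excitation_step: float = 10.0
    emission_start: float = 250.0
    emission_stop: float = 600.0
    emission_step: float = 10.0
    components: list = field(default_factory=list)
    sample_ph_values: list = field(
        default_factory=lambda: list(np.round(np.linspace(3.5, 8.5, 9), 4))
    )
    fe_present: bool = False
    quench_factor: float = 0.005
    scatter: ScatterParams | None = field(default_factory=ScatterParams)
    noise_frac: float = 0.01  # sd floor as fraction of max clean signal
    noise_prop: float = 0.03  # signal-proportional sd (shot/source noise)
    seed: int = 20211

    def __post_init__(self):
        if not self.components:
            raise ConfigurationError("EEM scenario needs at least one component")
        if self.noise_frac < 0 or self.noise_prop < 0:
            raise ConfigurationError("noise fractions must be >= 0")

    @property
    def excitation_grid(self) -> np.ndarray:
        return _grid(self.excitation_start, self.excitation_stop, self.excitation_step)

    @property
    def emission_grid(self) -> np.ndarray:
        return _grid(self.emission_start, self.emission_stop, self.emission_step)


def _ta_components() -> list:
    # TA-only landscape: main band Ex 210/Em 360 with a 260 nm excitation
    # shoulder, plus the high-pH band at Ex 325/Em 405
    return [
        EEMComponent(
            "peakA",
            [210.0, 260.0],
            [35.0, 45.0],
            [1.0, 0.45],
            360.0,
            80.0,
            score_base=100.0,
            score_amplitude=-25.0,
            ph_midpoint=6.5,
            ph_scale=1.0,
            quench=True,
        ),
        EEMComponent(
            "peakC",
            [325.0],
            [50.0],
            [1.0],
            405.0,
            90.0,
            score_base=1.0,
            score_amplitude=85.0,
            ph_midpoint=7.8,
            ph_scale=0.45,
            quench=False,
        ),
    ]


def _fe_ta_components() -> list:
    # with Fe(III) the main TA band is quenched; the surviving band sits
    # at Ex 260/Em 370
    return [
        EEMComponent(
            "peakA",
            [210.0, 260.0],
            [35.0, 45.0],
            [1.0, 0.45],
            360.0,
            80.0,
            score_base=100.0,
            score_amplitude=-25.0,
            ph_midpoint=6.5,
            ph_scale=1.0,
            quench=True,
        ),
        EEMComponent(
            "peakB",
            [260.0],
            [45.0],
            [1.0],
            370.0,
            80.0,
            score_base=60.0,
            score_amplitude=35.0,
            ph_midpoint=6.0,
            ph_scale=1.2,
            quench=False,
        ),
    ]


@dataclass
class JobsScenario:
    total_conc: float = 2.00e-5  # mol/L
    molar_fractions: list = field(
        default_factory=lambda: list(np.round(np.arange(0.1, 0.91, 0.1), 4))
    )
    n_sites: int = 4
    binding_strength: float = math.inf  # per-site association; inf = saturating
    analytic_wavelength: float = 570.0  # nm
    epsilon_per_site: float = 3472.0  # 1/(M cm) at the analytic wavelength
    noise_sd: float = 0.001  # AU
    seed: int = 20212

    def __post_init__(self):
        x = np.asarray(self.molar_fractions, dtype=float)
        if np.any((x <= 0) | (x >= 1)):
            raise ConfigurationError("molar fractions must lie in (0, 1)")
        if np.any(np.diff(x) <= 0):
            raise ConfigurationError("molar fractions must be strictly increasing")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.total_conc <= 0:
            raise ConfigurationError("total_conc must be > 0")


# ---------------------------------------------------------------------------
# packaged defaults and YAML (de)serialization


def default_scenarios() -> dict:
    """The packaged scenario set, keyed by name."""
    return {
        "fe_ta_uvvis": UvVisScenario(),
        "fe_ta_uvvis_wide": UvVisScenario(
            ph_values=list(np.round(np.arange(3.5, 8.51, 0.5), 4)), seed=20213
        ),
        "ta_eem": EEMScenario(components=_ta_components(), fe_present=False),
        "fe_ta_eem": EEMScenario(
            components=_fe_ta_components(), fe_present=True, seed=20214
        ),
        "fe_ta_jobs": JobsScenario(),
    }


_KINDS = {"uvvis": UvVisScenario, "eem": EEMScenario, "jobs": JobsScenario}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return ".inf"
    return obj


def save_scenario(scenario, path) -> None:
    """Write a scenario to a YAML file (with a ``kind`` discriminator)."""
    kind = {UvVisScenario: "uvvis", EEMScenario: "eem", JobsScenario: "jobs"}[
        type(scenario)
    ]
    payload = {"kind": kind, **_to_plain(scenario)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _build_uvvis(d: dict) -> UvVisScenario:
    d = dict(d)
    d["components"] = [PureComponent(**c) for c in d.get("components", [])] or None
    if d["components"] is None:
        d.pop("components")
    for key in ("k1_ph_profile", "k2_ph_profile"):
        if key in d and isinstance(d[key], dict):
            d[key] = KProfile(**d[key])
    return UvVisScenario(**d)


def _build_eem(d: dict) -> EEMScenario:
    d = dict(d)
    d["components"] = [EEMComponent(**c) for c in d.get("components", [])]
    if isinstance(d.get("scatter"), dict):
        d["scatter"] = ScatterParams(**d["scatter"])
    return EEMScenario(**d)


def _build_jobs(d: dict) -> JobsScenario:
    d = dict(d)
    if d.get("binding_strength") in (".inf", "inf", None):
        d["binding_strength"] = math.inf
    return JobsScenario(**d)


def load_scenario(name_or_path):
    """Load a scenario by packaged name or from a YAML file path."""
    defaults = default_scenarios()
    if str(name_or_path) in defaults:
        return defaults[str(name_or_path)]
    path = Path(name_or_path)
    if not path.exists():
        candidate = resources.files("tachem") / "scenarios" / f"{name_or_path}.yaml"
        if candidate.is_file():
            path = candidate
        else:
            raise ConfigurationError(
                f"unknown scenario {name_or_path!r}; packaged: {sorted(defaults)}"
            )
    payload = yaml.safe_load(Path(path).read_text())
    kind = payload.pop("kind", None)
    if kind not in _KINDS:
        raise ConfigurationError(f"scenario file must declare kind in {sorted(_KINDS)}")
    builder = {"uvvis": _build_uvvis, "eem": _build_eem, "jobs": _build_jobs}[kind]
    return builder(payload)
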