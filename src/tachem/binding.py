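"""Binding-capacity analysis: Job's method and saturation series.

Job's method of continuous variation fixes the total molar concentration
and varies the metal mole fraction x; for an n:1 metal-ligand complex
the absorbance of the complex peaks at x = n/(n+1).  The site
complexation capacity (SCC) then converts the stoichiometry into moles
of metal bound per gram of macromolecular ligand, which is the natural
unit when the ligand's molar mass is only formal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import JobsSeries
from .errors import ConfigurationError, NoSaturationError, UnbracketedMaximumError


@dataclass
class BindingCapacityReport:
    x_max: float  # metal molar fraction at the Job maximum
    n_sites: int  # metal per ligand stoichiometry
    scc: float  # site complexation capacity, mol/g
    mol_per_gram_at_max: float  # mol metal per g ligand at the maximum


def jobs_maximum(series: JobsSeries) -> tuple[float, int]:
    """Locate the Job's-plot maximum and infer the stoichiometry.

    The vertex of a quadratic through the top three points refines the
    maximum; when the vertex lies within half a grid step of a measured
    fraction it is snapped onto the grid (clean data then reproduces the
    direct grid reading).  ``n_sites = round(x/(1-x))``.
    """
    x = series.molar_fraction_metal
    y = series.absorbance
    if len(x) < 3:
        raise ConfigurationError("need at least 3 points")
    i = int(np.argmax(y))
    if i == 0 or i == len(x) - 1:
        raise UnbracketedMaximumError(
            f"series maximum at the grid edge (x = {x[i]:g})"
        )
    coef = np.polyfit(x[i - 1 : i + 2] - x[i], y[i - 1 : i + 2], 2)
    vertex = x[i] if coef[0] >= 0 else x[i] - coef[1] / (2.0 * coef[0])
    vertex = float(min(max(vertex, x[i - 1]), x[i + 1]))
    j = int(np.argmin(np.abs(x - vertex)))
    step = float(np.median(np.diff(x)))
    x_max = float(x[j]) if abs(vertex - x[j]) <= step / 2.0 else vertex
    n_sites = int(round(x_max / (1.0 - x_max)))
    return x_max, n_sites


def scc_from_stoichiometry(n_sites: int, molecular_weight: float) -> float:
    """SCC = n_sites / MW, mol of metal per gram of ligand."""
    if n_sites <= 0 or molecular_weight <= 0:
        raise ConfigurationError("inputs must be > 0")
    return n_sites / molecular_weight


def ligand_site_concentration(
    ta_molar: float, molecular_weight: float, scc: float
) -> float:
    """Total ligand-site concentration [L]_total in mol/L.

    Converts the nominal molar ligand concentration to a mass
    concentration (g/L) and multiplies by the SCC.
    """
    if ta_molar <= 0 or molecular_weight <= 0 or scc < 0:
        raise ConfigurationError("ta_molar and molecular_weight must be > 0, scc >= 0")
    return ta_molar * molecular_weight * scc


def binding_capacity_report(
    series: JobsSeries, molecular_weight: float
) -> BindingCapacityReport:
    """Full Job analysis: maximum, stoichiometry, and capacity."""
    x_max, n_sites = jobs_maximum(series)
    scc = scc_from_stoichiometry(n_sites, molecular_weight)
    return BindingCapacityReport(x_max, n_sites, scc, scc)


def saturation_breakpoint(ratios, absorbance) -> float:
    """Knot of a rise-then-plateau fit to a metal:ligand saturation series.

    Fits A = b + m*min(r, k) (continuous two-segment line, plateau slope
    fixed to zero) over a grid of candidate knots and returns the knot
    minimizing the residual sum of squares.  Raises NoSaturationError
    when a single straight line fits at least as well (no plateau).
    """
    r = np.asarray(ratios, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if len(r) < 4:
        raise ConfigurationError("need at least 4 points spanning the breakpoint")
    if np.any(np.diff(r) <= 0):
        raise ConfigurationError("ratios must be strictly increasing")

    def rss_linear():
        design = np.column_stack([np.ones_like(r), r])
        _, res, *_ = np.linalg.lstsq(design, a, rcond=None)
        return float(res[0]) if res.size else float(
            np.sum((a - design @ np.linalg.lstsq(design, a, rcond=None)[0]) ** 2)
        )

    candidates = np.unique(
        np.concatenate([r[1:-1], np.linspace(r[1], r[-2], 201)])
    )
    best_k, best_rss = None, np.inf
    for k in candidates:
        design = np.column_stack([np.ones_like(r), np.minimum(r, k)])
        coef, *_ = np.linalg.lstsq(design, a, rcond=None)
        rss = float(np.sum((a - design @ coef) ** 2))
        if rss < best_rss:
            best_k, best_rss = float(k), rss
    if rss_linear() <= best_rss + 1e-12 * max(1.0, float(np.sum(a * a))):
        raise NoSaturationError("absorbance rises to the last point; no plateau")
    return best_k
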