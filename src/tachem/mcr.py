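"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Soft bilinear modeling of a titration matrix X (samples x wavelengths):

    X = C S^T + E

with C the concentration profiles and S the pure spectra.  Initial pure
spectra come from SIMPLISMA pure-variable selection; the ALS loop then
alternates constrained least-squares half-steps for C (given S) and S
(given C).  Supported constraints: non-negativity on either factor, a
closure (mass-balance) constraint rescaling each concentration row to a
fixed total, unimodality of the concentration profiles, and spectra
normalization.  When closure is active the concentration scale is
absolute (mol/L), so by Beer-Lambert (1 cm path) the spectra come out in
molar extinction units, 1/(M cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._lsq import lstsq_multi, nnls_multi
from .datatypes import SpectralMatrix
from .errors import ConfigurationError, InitializationError

VALID_CONSTRAINTS = frozenset(
    {"nonneg_c", "nonneg_s", "closure", "unimodality", "normalization"}
)


@dataclass
class MCRConfig:
    n_components: int
    max_iter: int = 150
    tol: float = 1e-6  # relative RSS change between full iterations
    constraints: frozenset = frozenset({"nonneg_c", "nonneg_s"})
    closure_total: float | None = None  # mol/L, required with "closure"
    simplisma_offset: float = 1.0  # percent noise correction

    def __post_init__(self):
        self.constraints = frozenset(self.constraints)
        unknown = self.constraints - VALID_CONSTRAINTS
        if unknown:
            raise ConfigurationError(
                f"unknown constraints {sorted(unknown)}; "
                f"valid: {sorted(VALID_CONSTRAINTS)}"
            )
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if self.tol <= 0:
            raise ConfigurationError("tol must be > 0")
        if "closure" in self.constraints and not self.closure_total:
            raise ConfigurationError("closure constraint requires closure_total")


@dataclass
class MCRResult:
    C: np.ndarray  # samples x n, mol/L under closure
    S: np.ndarray  # wavelengths x n
    wavelengths: np.ndarray
    residuals: np.ndarray  # X - C S^T
    lambda_max: np.ndarray  # per component, nm (refined, grid-snapped)
    eps_max: np.ndarray  # per component, band-maximum value of S
    explained_variance: np.ndarray  # percent per component
    cumulative_explained_variance: float
    r2: float
    n_iter: int
    converged: bool
    rss_history: list = field(default_factory=list)
    closure_violation: bool = False  # closure raised RSS by > 10x tol somewhere
    rank_warning: bool = False  # n_components above numerical rank of X


def refine_peak(
    wavelengths: np.ndarray, spectrum: np.ndarray, window_nm: float = 30.0
) -> tuple[float, float]:
    """Band maximum by local quadratic refinement, snapped to the grid.

    A raw argmax wanders under noise when the band is broad relative to
    the grid step; fitting a parabola over +-window_nm (two passes, the
    second recentered on the first vertex) uses the whole band top.
    Returns ``(lambda_max, height)``; ``lambda_max`` is the grid point
    nearest the vertex.
    """
    wl = np.asarray(wavelengths, dtype=float)
    s = np.asarray(spectrum, dtype=float)
    center = wl[int(np.argmax(s))]
    vertex, height = center, float(s.max())
    for _ in range(2):
        sel = np.abs(wl - center) <= window_nm
        if sel.sum() < 3:
            break
        coef = np.polyfit(wl[sel], s[sel], 2)
        if coef[0] >= 0:  # no curvature maximum; keep argmax
            break
        v = -coef[1] / (2.0 * coef[0])
        v = min(max(v, wl[0]), wl[-1])
        vertex, height = v, float(np.polyval(coef, v))
        center = v
    lam = float(wl[int(np.argmin(np.abs(wl - vertex)))])
    return lam, height


def simplisma_init(
    X: SpectralMatrix | np.ndarray, n_components: int, offset: float = 1.0
) -> np.ndarray:
    """SIMPLISMA pure-variable selection of initial pure spectra.

    Treats each sample spectrum (row) as a candidate pure variable.
    Purity is std/(mean + alpha) with alpha = offset% of the largest row
    mean; after each pick, candidate purities are deflated by the
    determinant of the correlation-around-origin submatrix formed with
    the already-selected rows, which drives selection toward mutually
    independent (purest) rows.  Returns the selected rows as an
    (n_wavelengths x n_components) initial estimate of S.
    """
    A = X.absorbance if isinstance(X, SpectralMatrix) else np.atleast_2d(np.asarray(X, float))
    n_rows, n_cols = A.shape
    if n_components > n_rows:
        raise ConfigurationError("n_components exceeds the number of samples")
    mean = A.mean(axis=1)
    std = A.std(axis=1)
    alpha = offset / 100.0 * np.abs(mean).max()
    if np.all(std <= 1e-12 * max(np.abs(mean).max(), 1e-300)):
        raise InitializationError("all rows are constant; no pure variable exists")
    purity = std / (mean + alpha)
    # length-scaled rows for the correlation-around-origin matrix
    lam = np.sqrt(mean**2 + (std + alpha) ** 2)
    Z = A / (lam[:, None] * np.sqrt(n_cols))
    coo = Z @ Z.T
    selected: list[int] = []
    for _ in range(n_components):
        weights = np.empty(n_rows)
        for i in range(n_rows):
            idx = [i, *selected]
            weights[i] = np.linalg.det(coo[np.ix_(idx, idx)])
        score = np.where(np.isin(np.arange(n_rows), selected), -np.inf, weights * purity)
        # ties broken toward the lowest index (argmax returns the first)
        selected.append(int(np.argmax(score)))
    return A[selected].T.copy()


def _unimodal_project(col: np.ndarray) -> np.ndarray:
    """Crude unimodality repair: monotone envelopes away from the maximum."""
    out = col.copy()
    k = int(np.argmax(out))
    out[:k] = np.maximum.accumulate(out[:k])
    out[k + 1 :] = np.minimum.accumulate(out[k + 1 :])
    return out


def fit_mcr(X: SpectralMatrix, config: MCRConfig) -> MCRResult:
    """Run constrained alternating least squares on a titration matrix.

    Iterates C- and S-half-steps with the configured constraints until
    the relative RSS change drops below ``tol`` or ``max_iter`` is hit
    (non-convergence is flagged, not raised).  Components in the result
    are ordered by descending band maximum of S.
    """
    A = X.absorbance
    n_samples, n_wl = A.shape
    n = config.n_components
    if n > min(n_samples, n_wl):
        raise ConfigurationError("n_components exceeds matrix dimensions")
    rank = int(np.sum(np.linalg.svd(A, compute_uv=False) > 1e-10 * max(A.shape)))
    rank_warning = n > rank

    S = simplisma_init(X, n, config.simplisma_offset)  # n_wl x n
    C = np.zeros((n_samples, n))
    nonneg_c = "nonneg_c" in config.constraints
    nonneg_s = "nonneg_s" in config.constraints
    closure = "closure" in config.constraints
    ss_x = float(np.sum(A * A))

    rss_history: list[float] = []
    closure_violation = False
    converged = False
    n_iter = 0
    prev_rss = np.inf
    for n_iter in range(1, config.max_iter + 1):
        # C half-step: rows of C from the current spectra
        solver = nnls_multi if nonneg_c else lstsq_multi
        C = solver(S, A.T).T
        if "unimodality" in config.constraints:
            C = np.column_stack([_unimodal_project(C[:, k]) for k in range(n)])
        if closure:
            sums = C.sum(axis=1)
            scale = np.where(sums > 0, config.closure_total / np.where(sums > 0, sums, 1.0), 1.0)
            C = C * scale[:, None]
        # S half-step: spectra from the (constrained) concentrations
        solver = nnls_multi if nonneg_s else lstsq_multi
        S = solver(C, A).T
        if "normalization" in config.constraints:
            peaks = np.abs(S).max(axis=0)
            peaks = np.where(peaks > 0, peaks, 1.0)
            S = S / peaks
            C = C * peaks

        rss = float(np.sum((A - C @ S.T) ** 2))
        rss_history.append(rss)
        exact = rss <= 1e-14 * ss_x  # numerically perfect reconstruction
        if exact or (
            prev_rss < np.inf and abs(prev_rss - rss) <= config.tol * max(prev_rss, 1e-300)
        ):
            converged = True
            break
        prev_rss = rss

    if closure:
        # closure is a projection, not a descent step; a persistent jump
        # at the converged state means the stated mass balance is
        # inconsistent with the data -- reported, not raised
        solver = nnls_multi if nonneg_c else lstsq_multi
        C_free = solver(S, A.T).T
        rss_free = float(np.sum((A - C_free @ S.T) ** 2))
        rss_closed = float(np.sum((A - C @ S.T) ** 2))
        closure_violation = (
            rss_closed > 1e-12 * ss_x
            and (rss_closed - rss_free) / max(rss_free, 1e-300) > 10.0 * config.tol
        )

    # order components by descending band maximum
    peaks = [refine_peak(X.wavelengths, S[:, k]) for k in range(n)]
    order = np.argsort([-p[0] for p in peaks], kind="stable")
    C, S = C[:, order], S[:, order]
    lambda_max = np.array([peaks[k][0] for k in order])
    eps_max = np.array([peaks[k][1] for k in order])

    E = A - C @ S.T
    r2 = 1.0 - float(np.sum(E * E)) / ss_x if ss_x > 0 else np.nan
    ev = np.array(
        [100.0 * float(np.sum(np.outer(C[:, k], S[:, k]) ** 2)) / ss_x for k in range(n)]
    )
    return MCRResult(
        C=C,
        S=S,
        wavelengths=X.wavelengths,
        residuals=E,
        lambda_max=lambda_max,
        eps_max=eps_max,
        explained_variance=ev,
        cumulative_explained_variance=float(ev.sum()),
        r2=r2,
        n_iter=n_iter,
        converged=converged,
        rss_history=rss_history,
        closure_violation=closure_violation,
        rank_warning=rank_warning,
    )


def explained_variance(result: MCRResult, X: SpectralMatrix):
    """Per-component explained variance (%), cumulative (%), and R^2.

    R^2 = 1 - SS(E)/SS(X); each component contributes the sum of squares
    of its rank-1 layer c_k s_k^T (layers are not orthogonal, so the
    cumulative value need not equal 100 R^2).
    """
    A = X.absorbance
    ss_x = float(np.sum(A * A))
    if ss_x == 0:
        raise ConfigurationError("explained variance undefined for an all-zero matrix")
    E = A - result.C @ result.S.T
    r2 = 1.0 - float(np.sum(E * E)) / ss_x
    per = np.array(
        [
            100.0 * float(np.sum(np.outer(result.C[:, k], result.S[:, k]) ** 2)) / ss_x
            for k in range(result.C.shape[1])
        ]
    )
    return per, float(per.sum()), r2


def project_concentrations(X: SpectralMatrix, result: MCRResult) -> MCRResult:
    """Concentrations of new samples from already-resolved spectra.

    Solves one non-negative Beer-Lambert regression of each sample
    spectrum onto the result's pure spectra (no refit, so no rotational
    drift).  With S in extinction units the returned concentrations are
    mol/L.  This is the calibration-transfer step: resolve spectra once
    on a closure-consistent titration, then quantify any other series.
    """
    if len(X.wavelengths) != len(result.wavelengths) or not np.allclose(
        X.wavelengths, result.wavelengths
    ):
        raise ConfigurationError("wavelength grids differ between matrix and result")
    C = nnls_multi(result.S, X.absorbance.T).T
    E = X.absorbance - C @ result.S.T
    ss_x = float(np.sum(X.absorbance**2))
    return MCRResult(
        C=C,
        S=result.S.copy(),
        wavelengths=result.wavelengths,
        residuals=E,
        lambda_max=result.lambda_max.copy(),
        eps_max=result.eps_max.copy(),
        explained_variance=result.explained_variance.copy(),
        cumulative_explained_variance=result.cumulative_explained_variance,
        r2=1.0 - float(np.sum(E * E)) / ss_x if ss_x > 0 else np.nan,
        n_iter=0,
        converged=True,
        rss_history=[float(np.sum(E * E))],
        closure_violation=False,
        rank_warning=result.rank_warning,
    )


def calibrate_epsilon(result: MCRResult, eps_max_reference) -> MCRResult:
    """Fix the per-component scale of an unclosed fit by Beer-Lambert.

    Without closure the split of scale between each concentration column
    and its spectrum is arbitrary.  Given reference band-maximum
    extinctions (same component order as the result, i.e. descending
    lambda_max), each spectrum is rescaled so its band maximum equals the
    reference, and the concentration column is rescaled inversely; the
    reconstruction is unchanged and C becomes mol/L.
    """
    eps_ref = np.asarray(eps_max_reference, dtype=float)
    if eps_ref.shape != result.eps_max.shape:
        raise ConfigurationError("one reference extinction per component required")
    if np.any(result.eps_max <= 0):
        raise ConfigurationError("cannot calibrate a component with non-positive peak")
    factor = eps_ref / result.eps_max
    return MCRResult(
        C=result.C / factor,
        S=result.S * factor,
        wavelengths=result.wavelengths,
        residuals=result.residuals,
        lambda_max=result.lambda_max.copy(),
        eps_max=eps_ref.copy(),
        explained_variance=result.explained_variance.copy(),
        cumulative_explained_variance=result.cumulative_explained_variance,
        r2=result.r2,
        n_iter=result.n_iter,
        converged=result.converged,
        rss_history=list(result.rss_history),
        closure_violation=result.closure_violation,
        rank_warning=result.rank_warning,
    )
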