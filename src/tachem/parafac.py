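"""Trilinear decomposition of EEM stacks with scatter preprocessing.

The model is the standard PARAFAC/CANDECOMP form

    x_ijk = sum_n a_in b_jn c_kn + e_ijk

with mode 1 the sample, mode 2 the emission wavelength, and mode 3 the
excitation wavelength.  First- and second-order Rayleigh lines (Em = Ex,
Em = 2 Ex) and the water Raman line carry no compositional information
and are excised before fitting, then bridged by spline interpolation
along the emission axis.  The fit runs multi-start alternating least
squares under non-negativity; emission and excitation loadings are
rescaled to unit maximum with the scale absorbed into the sample scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._lsq import lstsq_multi, nnls_multi
from .datatypes import EEMTensor
from .errors import ConfigurationError, InterpolationError, OverMaskingError
from .synthetic import raman_emission


@dataclass
class ParafacConfig:
    n_components: int
    n_starts: int = 50
    max_iter: int = 5000
    tol: float = 1e-6
    nonneg_modes: frozenset = frozenset({"A", "B", "C"})
    rescale_modes: bool = True  # B and C columns to unit maximum

    def __post_init__(self):
        self.nonneg_modes = frozenset(self.nonneg_modes)
        if self.n_components < 1 or self.n_starts < 1:
            raise ConfigurationError("n_components and n_starts must be >= 1")
        if self.tol <= 0:
            raise ConfigurationError("tol must be > 0")
        bad = self.nonneg_modes - {"A", "B", "C"}
        if bad:
            raise ConfigurationError(f"unknown modes {sorted(bad)}")


@dataclass
class PARAFACResult:
    A: np.ndarray  # sample scores (carry the physical scale)
    B: np.ndarray  # emission loadings, unit maximum per component
    C: np.ndarray  # excitation loadings, unit maximum per component
    emission: np.ndarray
    excitation: np.ndarray
    loss_per_start: np.ndarray
    best_start: int
    n_iter: int  # iterations of the winning start
    converged: bool  # of the winning start
    r2: float
    loss_history: list = field(default_factory=list)
    core_consistency: float | None = None


def remove_scatter(
    eem: EEMTensor,
    rayleigh_widths: tuple = (15.0, 15.0),
    raman_width: float = 10.0,
    raman_shift_cm: float = 3400.0,
) -> EEMTensor:
    """Mask cells within the stated half-widths of the scatter lines.

    A width of zero disables masking for that line.  Raises if any
    excitation column would lose its entire emission range.
    """
    w1, w2 = (float(w) for w in rayleigh_widths)
    wr = float(raman_width)
    if min(w1, w2, wr) < 0:
        raise ConfigurationError("scatter widths must be >= 0")
    em = eem.emission[:, None]
    ex = eem.excitation[None, :]
    mask2d = np.zeros((len(eem.emission), len(eem.excitation)), dtype=bool)
    if w1 > 0:
        mask2d |= np.abs(em - ex) <= w1
    if w2 > 0:
        mask2d |= np.abs(em - 2.0 * ex) <= w2
    if wr > 0:
        mask2d |= np.abs(em - raman_emission(ex, raman_shift_cm)) <= wr
    dead = np.where(mask2d.all(axis=0))[0]
    if dead.size:
        raise OverMaskingError(
            f"widths mask the entire emission range at excitation "
            f"{eem.excitation[dead].tolist()} nm"
        )
    out = eem.copy()
    out.mask = out.mask | mask2d[None, :, :]
    return out


def _interp_slice(x, y, missing):
    """PCHIP fill of one 1-D slice; returns (values, anchor_gap, anchor_dy).

    ``anchor_gap`` is the distance between the bracketing good points of
    each filled cell and ``anchor_dy`` their value difference; cells
    beyond the good range are extended linearly from the local slope and
    get infinite gap/dy so a better-bracketed axis can take precedence.
    """
    good = ~missing
    xg, yg = x[good], y[good]
    vals = np.full(x.shape, np.nan)
    gap = np.full(x.shape, np.inf)
    dy = np.full(x.shape, np.inf)
    inside = missing & (x >= xg[0]) & (x <= xg[-1])
    if inside.any():
        if len(xg) > 1:
            vals[inside] = PchipInterpolator(xg, yg, extrapolate=False)(x[inside])
        else:
            vals[inside] = yg[0]
        left = np.searchsorted(xg, x[inside]) - 1
        gap[inside] = xg[left + 1] - xg[left]
        dy[inside] = np.abs(yg[left + 1] - yg[left])
    outside = missing & ~inside
    if outside.any():
        below = outside & (x < xg[0])
        above = outside & (x > xg[-1])
        if below.any():
            slope = (yg[1] - yg[0]) / (xg[1] - xg[0]) if len(xg) > 1 else 0.0
            vals[below] = yg[0] + slope * (x[below] - xg[0])
        if above.any():
            slope = (yg[-1] - yg[-2]) / (xg[-1] - xg[-2]) if len(xg) > 1 else 0.0
            vals[above] = yg[-1] + slope * (x[above] - xg[-1])
    return vals, gap, dy


def interpolate_scatter(eem: EEMTensor) -> EEMTensor:
    """Fill masked scatter bands by shape-preserving splines.

    Every masked cell is bridged twice with a monotone piecewise-cubic
    spline (PCHIP): along the emission axis of its (sample, excitation)
    slice and along the excitation axis of its (sample, emission) slice.
    The fill from the axis whose bracketing anchors agree better (then:
    the narrower bracket) is kept -- near the low-emission corner the
    merged Rayleigh/Raman bands leave the emission axis anchored on one
    side only, while the excitation axis still brackets the gap tightly.
    Cells outside any bracket are extended linearly from the local
    slope.  Negative fills are clipped to zero.  Raises when a slice has
    no unmasked points at all.
    """
    out = eem.copy()
    em, ex = eem.emission, eem.excitation
    for i in range(eem.shape[0]):
        slab = eem.intensities[i]
        mask = eem.mask[i]
        if not mask.any():
            continue
        v_em = np.full(slab.shape, np.nan)
        g_em = np.full(slab.shape, np.inf)
        d_em = np.full(slab.shape, np.inf)
        for k in range(len(ex)):
            if not mask[:, k].any():
                continue
            if mask[:, k].all():
                raise InterpolationError(
                    f"sample {i}, excitation {ex[k]:g} nm: "
                    "emission slice entirely masked"
                )
            v_em[:, k], g_em[:, k], d_em[:, k] = _interp_slice(
                em, slab[:, k], mask[:, k]
            )
        v_ex = np.full(slab.shape, np.nan)
        g_ex = np.full(slab.shape, np.inf)
        d_ex = np.full(slab.shape, np.inf)
        for j in range(len(em)):
            if not mask[j, :].any() or mask[j, :].all():
                continue
            v_ex[j, :], g_ex[j, :], d_ex[j, :] = _interp_slice(
                ex, slab[j, :], mask[j, :]
            )
        # prefer the axis with the smaller anchor disagreement, then the
        # narrower bracket; emission wins exact ties
        use_ex = (d_ex < d_em) | ((d_ex == d_em) & (g_ex < g_em))
        use_ex &= ~np.isnan(v_ex)
        fill = np.where(use_ex, v_ex, v_em)
        both_open = ~np.isfinite(g_em) & ~np.isfinite(g_ex)
        no_em = np.isnan(v_em)
        fill = np.where(no_em & ~np.isnan(v_ex), v_ex, fill)
        del both_open
        # clip only the filled cells; measured cells keep noise excursions
        out.intensities[i][mask] = np.clip(fill[mask], 0.0, None)
    out.mask = np.zeros_like(out.mask)
    return out


def _reconstruct(A, B, C):
    return np.einsum("in,jn,kn->ijk", A, B, C)


def _als_single(X, n, rng, config):
    """One ALS run from a random non-negative start; returns factors/loss."""
    I, J, K = X.shape
    B = rng.uniform(0.1, 1.0, size=(J, n))
    C = rng.uniform(0.1, 1.0, size=(K, n))
    A = np.zeros((I, n))
    X0 = X.reshape(I, J * K)  # mode-1 unfolding
    X1 = X.transpose(1, 0, 2).reshape(J, I * K)
    X2 = X.transpose(2, 0, 1).reshape(K, I * J)
    loss_prev = np.inf
    history = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        design = (B[:, None, :] * C[None, :, :]).reshape(J * K, n)
        solver = nnls_multi if "A" in config.nonneg_modes else lstsq_multi
        A = solver(design, X0.T).T
        design = (A[:, None, :] * C[None, :, :]).reshape(I * K, n)
        solver = nnls_multi if "B" in config.nonneg_modes else lstsq_multi
        B = solver(design, X1.T).T
        design = (A[:, None, :] * B[None, :, :]).reshape(I * J, n)
        solver = nnls_multi if "C" in config.nonneg_modes else lstsq_multi
        C = solver(design, X2.T).T
        loss = float(np.sum((X2 - C @ design.T) ** 2))
        history.append(loss)
        if loss_prev < np.inf and abs(loss_prev - loss) <= config.tol * max(loss_prev, 1e-300):
            converged = True
            break
        loss_prev = loss
    return A, B, C, history, converged, it


def fit_parafac(eem: EEMTensor, config: ParafacConfig, seed: int = 0) -> PARAFACResult:
    """Multi-start non-negative trilinear ALS; keeps the best final loss.

    The tensor must be complete (interpolate scatter first).  Start s
    draws its initial loadings from ``default_rng([seed, s])``, so runs
    are reproducible and starts independent.
    """
    if eem.mask.any():
        raise ConfigurationError(
            "tensor contains masked cells; run interpolate_scatter first"
        )
    X = eem.intensities
    n = config.n_components
    best = None
    losses = np.empty(config.n_starts)
    for s in range(config.n_starts):
        rng = np.random.default_rng([int(seed), s])
        A, B, C, history, converged, it = _als_single(X, n, rng, config)
        losses[s] = history[-1]
        if best is None or history[-1] < best[3][-1]:
            best = (A, B, C, history, converged, it, s)
    A, B, C, history, converged, it, s_best = best

    if config.rescale_modes:
        for M in (B, C):
            peaks = np.abs(M).max(axis=0)
            peaks = np.where(peaks > 0, peaks, 1.0)
            A = A * peaks
            M /= peaks

    ss_x = float(np.sum(X * X))
    r2 = 1.0 - history[-1] / ss_x if ss_x > 0 else np.nan
    result = PARAFACResult(
        A=A,
        B=B,
        C=C,
        emission=eem.emission,
        excitation=eem.excitation,
        loss_per_start=losses,
        best_start=s_best,
        n_iter=it,
        converged=converged,
        r2=r2,
        loss_history=history,
    )
    result.core_consistency = core_consistency(result, eem)
    return result


def core_consistency(result: PARAFACResult, eem: EEMTensor) -> float:
    """Core-consistency diagnostic (CORCONDIA), percent.

    Computes the least-squares Tucker core G for the fitted loadings and
    compares it with the superidentity T:
    ``100 (1 - SS(G - T)/SS(T))``.  A 1-component model returns 100 by
    convention (single-element core).  Returns NaN when a loading matrix
    is rank-deficient (cross-products singular).
    """
    A, B, C = result.A, result.B, result.C
    n = A.shape[1]
    if n == 1:
        return 100.0
    for M in (A, B, C):
        if np.linalg.matrix_rank(M, tol=1e-10 * max(M.shape)) < n:
            return float("nan")
    X = eem.intensities
    G = np.einsum(
        "pi,qj,rk,ijk->pqr",
        np.linalg.pinv(A),
        np.linalg.pinv(B),
        np.linalg.pinv(C),
        X,
    )
    T = np.zeros((n, n, n))
    for p in range(n):
        T[p, p, p] = 1.0
    return 100.0 * (1.0 - float(np.sum((G - T) ** 2)) / float(np.sum(T**2)))


def select_n_components(
    eem: EEMTensor,
    max_components: int = 4,
    seed: int = 0,
    n_starts: int = 50,
    max_iter: int = 5000,
    tol: float = 1e-6,
    threshold: float = 90.0,
):
    """Pick the model order by the core-consistency rule.

    Fits 1..max_components and returns the largest order whose core
    consistency stays at or above ``threshold`` (scanning stops at the
    first failure; order 1 is always admissible by convention).
    Returns ``(n_selected, diagnostics)`` where diagnostics maps order
    to its core consistency.
    """
    chosen = 1
    diagnostics = {}
    for n in range(1, max_components + 1):
        cfg = ParafacConfig(n, n_starts=n_starts, max_iter=max_iter, tol=tol)
        res = fit_parafac(eem, cfg, seed=seed)
        diagnostics[n] = res.core_consistency
        if n > 1 and not (res.core_consistency >= threshold):
            break
        chosen = n
    return chosen, diagnostics
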