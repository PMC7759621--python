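"""Small constrained least-squares kernels shared by the ALS engines.

The alternating half-steps of both bilinear (MCR) and trilinear (PARAFAC)
fits reduce to many independent non-negative least-squares problems that
share one design matrix.  For the component counts used here (n <= 6) the
optimum can be found exactly by enumerating active sets: the NNLS solution
restricted to its own support satisfies the unconstrained normal equations
on that support, so the feasible subset solution with minimal residual is
the global optimum.  This is vectorized over all right-hand sides at once,
which is orders of magnitude faster than looping scipy.optimize.nnls.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.optimize

_MAX_ENUM = 6


def nnls_multi(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x - b||, x >= 0 for every column b of B.

    Parameters
    ----------
    A : (m, n) design matrix shared by all problems.
    B : (m, p) stacked right-hand sides.

    Returns
    -------
    (n, p) array of non-negative solutions.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    m, n = A.shape
    if B.ndim == 1:
        B = B[:, None]
    if n > _MAX_ENUM:
        out = np.empty((n, B.shape[1]))
        for j in range(B.shape[1]):
            out[:, j], _ = scipy.optimize.nnls(A, B[:, j])
        return out

    p = B.shape[1]
    AtA = A.T @ A
    AtB = A.T @ B
    best_x = np.zeros((n, p))
    # RSS up to the constant ||b||^2: -2 x.AtB + x.AtA.x ; empty set scores 0
    best_score = np.zeros(p)
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            idx = list(subset)
            sub = AtA[np.ix_(idx, idx)]
            try:
                xs = np.linalg.solve(sub, AtB[idx, :])
            except np.linalg.LinAlgError:
                xs = np.linalg.lstsq(sub, AtB[idx, :], rcond=None)[0]
            feasible = np.all(xs >= 0, axis=0)
            if not feasible.any():
                continue
            score = -np.einsum("ij,ij->j", xs, AtB[idx, :])
            better = feasible & (score < best_score - 1e-300)
            if better.any():
                cols = np.where(better)[0]
                best_score[cols] = score[cols]
                best_x[:, cols] = 0.0
                best_x[np.ix_(idx, cols)] = xs[:, cols]
    return best_x


def lstsq_multi(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Unconstrained counterpart of :func:`nnls_multi`."""
    return np.linalg.lstsq(np.asarray(A, float), np.asarray(B, float), rcond=None)[0]
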