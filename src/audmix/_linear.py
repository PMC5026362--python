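"""Shared (weighted) least-squares kernel.

Both the pooled OLS baseline and the mixture M-step use this one solver, so
the single-cluster mixture reduces to OLS exactly, not merely to numerical
tolerance.
"""

from __future__ import annotations

import numpy as np


def weighted_least_squares(
    X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Solve min_beta sum_i w_i (y_i - beta.x_i)^2.

    Returns (beta, sigma2, se) where sigma2 is the weighted mean squared
    residual and se the coefficient standard errors from the weighted
    information matrix, sqrt(diag((X'WX)^-1) * sigma2).

    Raises ``np.linalg.LinAlgError`` if the (weighted) design is singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        Xw, yw = X, y
        wsum = float(len(y))
    else:
        w = np.asarray(w, dtype=float)
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = y * sw
        wsum = float(w.sum())
    if wsum <= 0:
        raise np.linalg.LinAlgError("total weight is zero")
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(f"weighted design is rank deficient (rank {rank})")
    resid = y - X @ beta
    if w is None:
        sigma2 = float(resid @ resid) / wsum
    else:
        sigma2 = float(w @ resid**2) / wsum
    xtwx_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.clip(np.diag(xtwx_inv), 0.0, None) * sigma2)
    return beta, sigma2, se
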