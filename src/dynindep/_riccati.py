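"""Innovations covariance of a linearly projected state-space process.

Shared primitive behind both conditional Granger causality and exact
dynamical dependence: observe an innovations-form model ``(A, C, K, V)``
through a full-rank map ``L`` (k x N) and recover the innovations covariance
of the projected process ``L X_t`` by solving the filtering discrete
algebraic Riccati equation (DARE).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = ["projected_innovations_cov"]


def projected_innovations_cov(model, L: np.ndarray) -> np.ndarray:
    """Innovations covariance of ``Y_t = L X_t``.

    The projected process has observation matrix ``L C``, state noise
    ``K e_t`` and observation noise ``L e_t``, hence noise covariances
    ``Q = K V K'``, ``R = L V L'`` and cross term ``S = K V L'``.  The
    filtering DARE is solved through its control-form dual
    (``scipy.linalg.solve_discrete_are`` with transposed system matrices)
    for the state prediction-error covariance P, giving

        V_Y = (L C) P (L C)' + R.

    Raises
    ------
    scipy.linalg.LinAlgError
        If the Riccati solver fails; the message carries conditioning
        diagnostics of the projected observation noise.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    A, C, K, V = model.A, model.C, model.K, model.V
    R = L @ V @ L.T
    if model.state_dim == 0:
        return R
    Cy = L @ C
    Q = K @ V @ K.T
    S = K @ V @ L.T
    try:
        P = linalg.solve_discrete_are(A.T, Cy.T, Q, R, s=S)
    except (linalg.LinAlgError, ValueError) as exc:
        cond = np.linalg.cond(R)
        raise linalg.LinAlgError(
            f"filtering DARE failed (cond(R) = {cond:.3g}): {exc}") from exc
    return Cy @ P @ Cy.T + R
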