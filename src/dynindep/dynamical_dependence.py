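"""Dynamical dependence of a linear coarse-graining.

The dynamical dependence (DD) of a macrovariable :math:`Y_t = M X_t` is the
transfer entropy from the history of the micro process X to the present of
Y.  For a stationary Gaussian linear system it reduces to a log-determinant
ratio of innovations covariances,

.. math:: T(X \\to Y) = \\tfrac12\\left[\\log\\det V_Y
          - \\log\\det (M V M^\\top)\\right],

where :math:`V_Y` is the innovations covariance of Y predicted from its own
history alone and :math:`M V M^\\top` is the (optimal) innovations
covariance of Y given the full micro history.  DD is reported in nats on
the transfer-entropy scale (the 1/2 factor); it is nonnegative, zero exactly
for dynamically independent (emergent) macros, and invariant under
nonsingular transformations of the macro space, so it descends to a function
on the Grassmannian of n-dimensional subspaces.

Three routes are provided:

``dd_exact``
    reference method; solves the filtering Riccati equation of the model
    observed through M.
``dd_spectral``
    quadrature proxy; replaces the Riccati solve by the Kolmogorov-Szego
    identity, evaluating the grid mean of ``log det M S(lambda) M*``.  The
    integrand is smooth and periodic so trapezoidal quadrature converges
    spectrally fast; this is the cheap objective used inside optimisation
    loops, and the one whose analytic gradient is available.
``dd_empirical``
    brute-force regression on simulated/observed data; the independent
    oracle for the other two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._riccati import projected_innovations_cov
from .linear_models import SSModel, TimeSeriesData, spectral_grid

__all__ = [
    "CoarseGraining",
    "DDValue",
    "SpectralCache",
    "dd_exact",
    "dd_spectral",
    "dd_gradient",
    "dd_empirical",
    "dd_empirical_se",
]

#: values in (-NEG_FLOOR, 0) are clamped to zero with a warning; anything
#: more negative signals a broken model and raises.
NEG_FLOOR = 1e-9

_JITTER = 1e-12


@dataclass
class CoarseGraining:
    """Orthonormal n x N coarse-graining matrix (a Stiefel point).

    Rows span the macro subspace; ``M M^T = I`` to 1e-12.  Macrovariables
    related by a rotation of the macro space are the same subspace, hence
    the same macro.
    """

    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        n, N = self.M.shape
        if not 0 < n <= N:
            raise ValueError("need 0 < n <= N rows")
        gram = self.M @ self.M.T
        if not np.allclose(gram, np.eye(n), atol=1e-12):
            raise ValueError("rows of M must be orthonormal (to 1e-12)")

    @property
    def scale(self) -> int:
        return self.M.shape[0]

    @property
    def n_micro(self) -> int:
        return self.M.shape[1]

    @classmethod
    def axis_aligned(cls, subset, n_micro: int) -> "CoarseGraining":
        """Selection of a node subset: rows are the coordinate axes e_i."""
        subset = list(subset)
        M = np.zeros((len(subset), n_micro))
        M[np.arange(len(subset)), subset] = 1.0
        return cls(M)


@dataclass
class DDValue:
    """A dynamical-dependence measurement, in nats."""

    value: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return self.value


def _floor(value: float, method: str, diagnostics: dict) -> DDValue:
    if value < -NEG_FLOOR:
        raise ValueError(
            f"dynamical dependence {value:.3e} is negative beyond the "
            "numerical floor; the model violates its invariants")
    if value < 0:
        if value < -1e-12:   # plain round-off at exact zeros stays silent
            warnings.warn(f"clamping small negative DD {value:.3e} to 0")
        value = 0.0
    return DDValue(value, method, diagnostics)


def _logdet_psd(mat: np.ndarray) -> float:
    """log det of a (near-)PSD matrix with trace-scaled jitter fallback."""
    sign, ld = np.linalg.slogdet(mat)
    if sign <= 0 or not np.isfinite(ld):
        jitter = _JITTER * np.trace(mat).real
        warnings.warn("near-singular matrix in log-det; adding jitter")
        sign, ld = np.linalg.slogdet(mat + jitter * np.eye(mat.shape[0]))
        if sign <= 0:
            raise np.linalg.LinAlgError("log-det of non-PD matrix")
    return float(ld)


def dd_exact(model: SSModel, M: CoarseGraining | np.ndarray) -> DDValue:
    """Exact DD via the filtering Riccati route (reference method)."""
    M = M if isinstance(M, CoarseGraining) else CoarseGraining(M)
    if M.n_micro != model.n_channels:
        raise ValueError("coarse-graining width must match model channels")
    VY = projected_innovations_cov(model, M.M)
    R = M.M @ model.V @ M.M.T
    resid = VY - R
    value = 0.5 * (_logdet_psd(VY) - _logdet_psd(R))
    return _floor(value, "exact",
                  {"riccati_residual_trace": float(np.trace(resid))})


class SpectralCache:
    """Precomputed spectral quantities of one model on one frequency grid.

    Holds the CPSD ``S(lambda)`` on a uniform [0, pi] grid together with
    normalised trapezoid weights, so repeated DD/gradient evaluations (the
    inner loop of optimisation) cost only small-matrix algebra.
    """

    def __init__(self, model: SSModel, nfreqs: int = 1024):
        self.model = model
        self.freqs = spectral_grid(nfreqs)
        H = model.transfer_function(self.freqs)
        self.S = H @ model.V @ H.conj().transpose(0, 2, 1)
        N = model.n_channels
        # frequency-stacked layout (N, F*N) so projections are single GEMMs
        self._S_flat = np.ascontiguousarray(
            self.S.transpose(1, 0, 2).reshape(N, nfreqs * N))
        w = np.ones(nfreqs)
        w[0] = w[-1] = 0.5
        self.weights = w / w.sum()
        self.V = model.V

    def _project(self, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(MS, SY)`` with shapes (F, n, N) and (F, n, n)."""
        n, N = M.shape
        F = self.freqs.size
        MS = np.ascontiguousarray(
            (M @ self._S_flat).reshape(n, F, N).transpose(1, 0, 2))
        SY = (MS.reshape(F * n, N) @ M.T).reshape(F, n, n)
        return MS, SY

    def value(self, M: np.ndarray) -> float:
        _, SY = self._project(M)
        R = M @ self.V @ M.T
        ld = _batch_logdet(SY)
        return 0.5 * float(self.weights @ ld - _logdet_psd(R))

    def value_and_grad(self, M: np.ndarray) -> tuple[float, np.ndarray]:
        MS, SY = self._project(M)
        ld = _batch_logdet(SY)
        G_spec = np.matmul(_batch_inv_hermitian(SY), MS).real     # (F, n, N)
        R = M @ self.V @ M.T
        MV = M @ self.V
        value = 0.5 * float(self.weights @ ld - _logdet_psd(R))
        grad = (np.tensordot(self.weights, G_spec, axes=1)
                - np.linalg.solve(R, MV))
        return value, grad


def _batch_det_hermitian(SY: np.ndarray) -> np.ndarray:
    """Determinants of a batch of small Hermitian matrices (closed forms
    for n <= 3, LAPACK otherwise); the result is real."""
    n = SY.shape[-1]
    if n == 1:
        return SY[..., 0, 0].real
    if n == 2:
        return (SY[..., 0, 0] * SY[..., 1, 1]
                - SY[..., 0, 1] * SY[..., 1, 0]).real
    if n == 3:
        a, b, c = SY[..., 0, 0], SY[..., 0, 1], SY[..., 0, 2]
        d, e, f = SY[..., 1, 0], SY[..., 1, 1], SY[..., 1, 2]
        g, h, i = SY[..., 2, 0], SY[..., 2, 1], SY[..., 2, 2]
        return (a * (e * i - f * h) - b * (d * i - f * g)
                + c * (d * h - e * g)).real
    sign, ld = np.linalg.slogdet(SY)
    return sign.real * np.exp(ld.real)


def _batch_inv_hermitian(SY: np.ndarray) -> np.ndarray:
    """Inverses of a batch of small Hermitian PD matrices (adjugate closed
    forms for n <= 3)."""
    n = SY.shape[-1]
    if n == 1:
        return 1.0 / SY
    if n == 2:
        det = (SY[..., 0, 0] * SY[..., 1, 1]
               - SY[..., 0, 1] * SY[..., 1, 0])[..., None, None]
        adj = np.empty_like(SY)
        adj[..., 0, 0] = SY[..., 1, 1]
        adj[..., 1, 1] = SY[..., 0, 0]
        adj[..., 0, 1] = -SY[..., 0, 1]
        adj[..., 1, 0] = -SY[..., 1, 0]
        return adj / det
    if n == 3:
        adj = np.empty_like(SY)
        for r in range(3):
            for c in range(3):
                r1, r2 = [k for k in range(3) if k != c]
                c1, c2 = [k for k in range(3) if k != r]
                minor = (SY[..., r1, c1] * SY[..., r2, c2]
                         - SY[..., r1, c2] * SY[..., r2, c1])
                adj[..., r, c] = (-1) ** (r + c) * minor
        det = _batch_det_hermitian(SY).astype(SY.dtype)
        return adj / det[..., None, None]
    return np.linalg.inv(SY)


def _batch_logdet(SY: np.ndarray) -> np.ndarray:
    det = _batch_det_hermitian(SY)
    bad = ~np.isfinite(det) | (det <= 0)
    if np.any(bad):
        warnings.warn("near-singular projected spectrum; adding jitter")
        n = SY.shape[-1]
        tr = np.einsum("fii->f", SY[bad]).real
        SYb = SY[bad] + (_JITTER * tr)[:, None, None] * np.eye(n)
        det = det.copy()
        det[bad] = _batch_det_hermitian(SYb)
        if np.any(det <= 0):
            raise np.linalg.LinAlgError("projected spectrum not PD")
    return np.log(det)


def dd_spectral(model: SSModel, M: CoarseGraining | np.ndarray,
                nfreqs: int = 1024, cache: SpectralCache | None = None
                ) -> DDValue:
    """Spectral-proxy DD via the Kolmogorov-Szego identity.

    ``DD = 1/2 [ mean_grid log det(M S(lambda) M*) - log det(M V M^T) ]``
    with trapezoidal weights on a uniform [0, pi] grid.
    """
    M = M if isinstance(M, CoarseGraining) else CoarseGraining(M)
    if cache is None:
        cache = SpectralCache(model, nfreqs)
    value = cache.value(M.M)
    return _floor(value, "spectral", {"nfreqs": len(cache.freqs)})


def dd_gradient(model: SSModel, M: CoarseGraining | np.ndarray,
                nfreqs: int = 1024, cache: SpectralCache | None = None
                ) -> np.ndarray:
    """Euclidean gradient of the spectral DD objective with respect to M.

    Accumulates the log-det derivative over the frequency grid:
    ``grad = mean_f Re[(M S_f M*)^{-1} M S_f] - (M V M^T)^{-1} M V``.
    Agrees with central finite differences of ``dd_spectral``.
    """
    M = M if isinstance(M, CoarseGraining) else CoarseGraining(M)
    if cache is None:
        cache = SpectralCache(model, nfreqs)
    _, grad = cache.value_and_grad(M.M)
    return grad


def dd_empirical(ts: TimeSeriesData, M: CoarseGraining | np.ndarray,
                 order: int) -> DDValue:
    """Brute-force DD estimate by lagged regression on data.

    Regresses ``Y_t = M X_t`` on its own past, and on its own past plus the
    full micro past, with ``order`` lags each; DD is half the log-det ratio
    of the two residual covariances.  Requires a strict coarse-graining
    (n < N): with n = N the restricted and full regressions coincide.
    """
    M = M if isinstance(M, CoarseGraining) else CoarseGraining(M)
    if M.scale >= M.n_micro:
        raise ValueError("empirical DD needs a strict coarse-graining (n < N)")
    x = ts.values
    N, T = x.shape
    n, p = M.scale, int(order)
    if T - p < 10 * (p * (n + N)):
        raise ValueError("insufficient samples for the requested lag order")
    y = M.M @ x
    Yt = y[:, p:].T
    own = np.concatenate([y[:, p - k:T - k] for k in range(1, p + 1)]).T
    full = np.concatenate(
        [own.T] + [x[:, p - k:T - k] for k in range(1, p + 1)]).T
    dd = 0.0
    res = {}
    for name, Z in (("own", own), ("full", full)):
        B, *_ = np.linalg.lstsq(Z, Yt, rcond=None)
        E = Yt - Z @ B
        res[name] = E.T @ E / E.shape[0]
    value = 0.5 * (_logdet_psd(res["own"]) - _logdet_psd(res["full"]))
    return DDValue(value, "empirical", {"order": p, "nobs": T - p})


def dd_empirical_se(model: SSModel, M: CoarseGraining, order: int,
                    nobs: int) -> float:
    """Asymptotic standard error of the empirical DD estimator.

    Under the large-sample chi-square approximation, ``2 T F_hat`` is
    non-central chi-square with ``d = n N p`` degrees of freedom (the number
    of constrained coefficients) and non-centrality ``2 T F``, so
    ``SE(F_hat) = sqrt(2 d + 8 T F) / (2 T)``, evaluated at the model value.
    """
    F = dd_exact(model, M).value
    d = M.scale * model.n_channels * order
    return float(np.sqrt(2 * d + 8 * nobs * F) / (2 * nobs))
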