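"""Delay-coupled Stefanescu-Jirsa 3D (SJ3D) neural-mass network simulator.

Each network node is a 3-mode mean-field reduction of a heterogeneous
population of excitatory and inhibitory Hindmarsh-Rose neurons whose
membrane excitabilities (input currents) are Gaussian distributed.  The
reduction follows the standard mode-decomposition construction: the
population state is expanded on three disjoint boxcar basis functions
("modes") supported on the terciles of the excitability distribution,
orthonormalised under the Gaussian measure, and the network equations are
Galerkin-projected onto this basis.  Per mode there are six state
variables — fast excitatory ``xi`` with its recovery ``eta`` and slow
adaptation ``tau``, and the inhibitory triple ``alpha, beta, gamma`` — so a
node carries 3 x 6 = 18 states and can produce the spike-burst dynamics of
the underlying Hindmarsh-Rose populations.

Because the boxcar modes have disjoint supports, the projected coefficients
have closed forms that double as test oracles: the cubic coefficients are
``3 a``, the quadratic ones ``sqrt(3) b`` (and ``sqrt(3) d``), mode-mixing
matrices ``A_ik = B_ik = C_ik = 1/3``, and the per-mode input currents are
the tercile-conditional means of the excitability distribution divided by
``sqrt(3)``.  The implementation computes all of them by quantile
quadrature so that mode counts other than three remain possible.

Inter-node coupling is mean-field consistent: the coupling observable of a
source node is its population mean ``xbar = sum_m w_m xi_m`` (``w_m`` the
mode masses), which — delayed by tract length over conduction speed and
weighted by the structural connectome and the global coupling G — is
injected into the ``xi`` equations of the target node, distributed over
modes by the same weights.  Dynamical noise is additive on the fast
variables (``xi`` and ``alpha``) of every mode with per-step standard
deviation ``sigma * sqrt(dt)``.

Integration uses the stochastic Heun predictor-corrector scheme (one shared
Gaussian increment per step, coupling input frozen across the two stages),
with an optional numba-compiled kernel for long network runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal, stats

from .linear_models import TimeSeriesData

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "SJ3DParams",
    "Connectome",
    "SweepGrid",
    "SJ3DTrajectory",
    "sj3d_derivatives",
    "heun_step",
    "heun_sde_step",
    "simulate_network",
    "extract_lfp",
    "make_connectomes",
    "default_initial_state",
]

N_STATE_VARS = 6
_BLOWUP = 1e6


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class SJ3DParams:
    """SJ3D neural-mass parameters.

    Base Hindmarsh-Rose constants ``a, b, c, d, r, s, x0`` are shared by the
    excitatory and inhibitory populations; ``K11`` (excitatory->excitatory),
    ``K12`` (inhibitory->excitatory) and ``K21`` (excitatory->inhibitory)
    couple the two masses; ``mu, sigma`` parametrise the Gaussian
    excitability distribution whose spread generates the mode heterogeneity.
    All projected per-mode coefficients are derived in ``__post_init__`` by
    quantile quadrature and live on the instance, so transcribed values can
    be dropped in afterwards if desired.
    """

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    r: float = 0.006
    s: float = 4.0
    x0: float = -1.6
    K11: float = 0.5
    K12: float = 0.1
    K21: float = 0.15
    mu: float = 3.3
    sigma: float = 0.3
    n_modes: int = 3
    n_quad: int = 1500
    #: which state variables receive dynamical noise
    noise_targets: tuple[str, ...] = ("xi", "alpha")

    # derived per-mode coefficients (filled in __post_init__)
    a_i: np.ndarray = field(init=False, repr=False)
    b_i: np.ndarray = field(init=False, repr=False)
    c_i: np.ndarray = field(init=False, repr=False)
    d_i: np.ndarray = field(init=False, repr=False)
    e_i: np.ndarray = field(init=False, repr=False)
    f_i: np.ndarray = field(init=False, repr=False)
    h_i: np.ndarray = field(init=False, repr=False)
    p_i: np.ndarray = field(init=False, repr=False)
    IE_i: np.ndarray = field(init=False, repr=False)
    II_i: np.ndarray = field(init=False, repr=False)
    m_i: np.ndarray = field(init=False, repr=False)
    n_i: np.ndarray = field(init=False, repr=False)
    A_ik: np.ndarray = field(init=False, repr=False)
    B_ik: np.ndarray = field(init=False, repr=False)
    C_ik: np.ndarray = field(init=False, repr=False)
    mode_mass: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_modes < 1 or self.n_quad < 10 * self.n_modes:
            raise ValueError("need n_modes >= 1 and enough quadrature points")
        for name in self.noise_targets:
            if name not in ("xi", "alpha"):
                raise ValueError("noise targets must be among ('xi','alpha')")
        self._derive_mode_coefficients()

    def _derive_mode_coefficients(self) -> None:
        nm, Q = self.n_modes, self.n_quad
        # excitability samples at quantile midpoints: equal measure 1/Q each
        I_q = stats.norm.ppf((np.arange(Q) + 0.5) / Q,
                             loc=self.mu, scale=self.sigma)

        def mdot(f, g=None):
            val = f if g is None else f * g
            return val.mean(axis=-1) if val.ndim > 1 else val.mean()

        # disjoint boxcar modes on equal-mass bins, orthonormal under the
        # quadrature measure
        edges = np.linspace(0, Q, nm + 1).astype(int)
        V = np.zeros((nm, Q))
        for i in range(nm):
            V[i, edges[i]:edges[i + 1]] = 1.0
        V /= np.sqrt(mdot(V * V))[:, None]

        mass = mdot(V)                       # integral of each mode
        self.mode_mass = mass
        self.A_ik = np.outer(mass, mass)     # mean-field mixing, exc->exc
        self.B_ik = np.outer(mass, mass)     # inh mean field onto exc modes
        self.C_ik = np.outer(mass, mass)     # exc mean field onto inh modes

        cubic = mdot(V ** 2, V ** 2)         # integral of V_i^4
        quad = mdot(V ** 2, V)               # integral of V_i^3
        self.a_i = self.a * cubic
        self.b_i = self.b * quad
        self.c_i = self.c * mass
        self.d_i = self.d * quad
        self.e_i = self.a * cubic
        self.f_i = self.b * quad
        self.h_i = self.c * mass
        self.p_i = self.d * quad
        self.IE_i = mdot(V, I_q[None, :])    # per-mode excitatory drive
        self.II_i = mdot(V, I_q[None, :])    # inhibitory drive (same law)
        self.m_i = self.r * self.s * self.x0 * mass
        self.n_i = self.r * self.s * self.x0 * mass

    @property
    def noise_mask(self) -> np.ndarray:
        """Boolean mask over the 6 state variables receiving noise."""
        mask = np.zeros(N_STATE_VARS, dtype=bool)
        if "xi" in self.noise_targets:
            mask[0] = True
        if "alpha" in self.noise_targets:
            mask[3] = True
        return mask


# --------------------------------------------------------------------------
# structural network
# --------------------------------------------------------------------------

@dataclass
class Connectome:
    """Structural network: coupling weights (target x source, zero
    diagonal), symmetric tract lengths in mm, and conduction speed in
    mm/ms."""

    weights: np.ndarray
    tracts: np.ndarray
    conduction_speed: float = 3.0
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tracts = np.asarray(self.tracts, dtype=float)
        if self.weights.shape != self.tracts.shape or \
                self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights and tracts must be same-shape square")
        if np.any(self.weights < 0) or np.any(self.tracts < 0):
            raise ValueError("weights and tracts must be nonnegative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-coupling weights must be zero")
        if not np.allclose(self.tracts, self.tracts.T):
            raise ValueError("tract lengths must be symmetric")
        if self.conduction_speed <= 0:
            raise ValueError("conduction speed must be positive")
        if self.labels is None:
            self.labels = [f"node{i + 1}" for i in range(self.n_nodes)]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def delay_steps(self, dt: float) -> np.ndarray:
        """Conduction delays rounded to integer integration steps."""
        steps = np.rint(self.tracts / self.conduction_speed / dt).astype(np.int64)
        bad = (self.weights > 0) & (steps < 1)
        if np.any(bad):
            raise ValueError("nonzero-weight connection with sub-step delay; "
                             "reduce dt or increase tract length")
        return steps

    def to_csv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".weights.csv"), self.weights,
                   delimiter=",")
        np.savetxt(prefix.with_suffix(".tracts.csv"), self.tracts,
                   delimiter=",")
        prefix.with_suffix(".meta.json").write_text(json.dumps(
            {"conduction_speed": self.conduction_speed, "labels": self.labels}))

    @classmethod
    def from_csv(cls, prefix: str | Path) -> "Connectome":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        return cls(np.loadtxt(prefix.with_suffix(".weights.csv"), delimiter=","),
                   np.loadtxt(prefix.with_suffix(".tracts.csv"), delimiter=","),
                   meta["conduction_speed"], meta["labels"])


#: 5-node fixture weights: two modules, {1,2,3} and {4,5}, strongly coupled
#: within and only weakly across, with directed asymmetries.  Synthetic,
#: structure-emulating values (module sizes and magnitudes, not transcribed
#: tractography numbers).
_COUPLED_WEIGHTS = np.array([
    [0.00, 3.00, 1.80, 0.30, 0.00],
    [2.40, 0.00, 2.70, 0.00, 0.18],
    [2.10, 1.50, 0.00, 0.24, 0.00],
    [0.15, 0.00, 0.27, 0.00, 3.60],
    [0.00, 0.21, 0.00, 2.70, 0.00],
])

_TRACTS = np.array([
    [0.0, 28.0, 35.0, 60.0, 72.0],
    [28.0, 0.0, 22.0, 55.0, 64.0],
    [35.0, 22.0, 0.0, 48.0, 58.0],
    [60.0, 55.0, 48.0, 0.0, 18.0],
    [72.0, 64.0, 58.0, 18.0, 0.0],
])


def make_connectomes(kind: str) -> Connectome:
    """Packaged 5-node fixtures: ``coupled`` (two-module asymmetric weight
    matrix) or ``uncoupled`` (zero weights, identical tracts)."""
    if kind == "coupled":
        return Connectome(_COUPLED_WEIGHTS.copy(), _TRACTS.copy())
    if kind == "uncoupled":
        return Connectome(np.zeros_like(_COUPLED_WEIGHTS), _TRACTS.copy())
    raise ValueError("kind must be 'coupled' or 'uncoupled'")


@dataclass
class SweepGrid:
    """The (G, eta) parameter lattice: log-spaced global-coupling and
    dynamical-noise values, endpoints inclusive."""

    g_values: np.ndarray
    noise_values: np.ndarray
    seeds_per_cell: int = 1

    def __post_init__(self) -> None:
        self.g_values = np.asarray(self.g_values, dtype=float)
        self.noise_values = np.asarray(self.noise_values, dtype=float)
        for v in (self.g_values, self.noise_values):
            if np.any(np.diff(v) <= 0):
                raise ValueError("grid values must be strictly increasing")

    @classmethod
    def default(cls) -> "SweepGrid":
        """The full study lattice: 20 x 20 log steps, G in [0.01, 0.31] and
        noise in [0.001, 0.1]."""
        return cls(np.geomspace(0.01, 0.31, 20), np.geomspace(0.001, 0.1, 20))

    @classmethod
    def reduced(cls, npoints: int) -> "SweepGrid":
        """Same ranges on a coarser lattice (for screening runs)."""
        return cls(np.geomspace(0.01, 0.31, npoints),
                   np.geomspace(0.001, 0.1, npoints))

    @property
    def shape(self) -> tuple[int, int]:
        return self.g_values.size, self.noise_values.size

    def cells(self):
        for i, g in enumerate(self.g_values):
            for j, eta in enumerate(self.noise_values):
                yield i, j, float(g), float(eta)


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def sj3d_derivatives(state: np.ndarray, params: SJ3DParams,
                     afferent: np.ndarray | None = None) -> np.ndarray:
    """Drift of the SJ3D network equations.

    ``state`` has shape ``(nodes, modes, 6)`` with variable order
    ``(xi, eta, tau, alpha, beta, gamma)``; ``afferent`` is the per-node,
    per-mode delayed coupling input (already scaled by G and the mode
    weights) entering only the ``xi`` equations.
    """
    state = np.asarray(state, dtype=float)
    if state.ndim != 3 or state.shape[1] != params.n_modes \
            or state.shape[2] != N_STATE_VARS:
        raise ValueError("state must have shape (nodes, modes, 6)")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state (integration blow-up?)")
    xi, eta, tau = state[..., 0], state[..., 1], state[..., 2]
    al, be, ga = state[..., 3], state[..., 4], state[..., 5]
    P = params
    aff = np.zeros_like(xi) if afferent is None else np.asarray(afferent)
    d = np.empty_like(state)
    sA = xi @ P.A_ik.T
    sB = al @ P.B_ik.T
    sC = xi @ P.C_ik.T
    d[..., 0] = (eta - P.a_i * xi ** 3 + P.b_i * xi ** 2 - tau
                 + P.K11 * (sA - xi) - P.K12 * (sB - xi) + P.IE_i + aff)
    d[..., 1] = P.c_i - P.d_i * xi ** 2 - eta
    d[..., 2] = P.r * P.s * xi - P.r * tau - P.m_i
    d[..., 3] = (be - P.e_i * al ** 3 + P.f_i * al ** 2 - ga
                 + P.K21 * (sC - al) + P.II_i)
    d[..., 4] = P.h_i - P.p_i * al ** 2 - be
    d[..., 5] = P.r * P.s * al - P.r * ga - P.n_i
    return d


def heun_step(drift, x: np.ndarray, dt: float,
              noise: np.ndarray | float = 0.0) -> np.ndarray:
    """One stochastic Heun (predictor-corrector) step with additive noise.

    The same noise increment enters predictor and corrector; with zero
    noise this is the deterministic Heun scheme (second-order accurate).
    """
    fx = drift(x)
    pred = x + dt * fx + noise
    return x + 0.5 * dt * (fx + drift(pred)) + noise


def heun_sde_step(state: np.ndarray, params: SJ3DParams, noise_sigma: float,
                  dt: float, rng: np.random.Generator,
                  afferent: np.ndarray | None = None) -> np.ndarray:
    """One Heun step of the SJ3D network with additive dynamical noise on
    the designated fast variables.

    The per-step increment has standard deviation ``noise_sigma *
    sqrt(dt)`` (``noise_sigma`` in units of state per sqrt(ms)).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = np.asarray(state, dtype=float)
    if np.any(np.abs(state) > _BLOWUP):
        raise FloatingPointError("state magnitude exceeds blow-up bound")
    noise = np.zeros_like(state)
    mask = params.noise_mask
    incr = noise_sigma * np.sqrt(dt) * rng.standard_normal(
        state.shape[:2] + (int(mask.sum()),))
    noise[..., np.where(mask)[0]] = incr
    return heun_step(lambda s: sj3d_derivatives(s, params, afferent),
                     state, dt, noise)


def default_initial_state(params: SJ3DParams, n_nodes: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Seeded initial condition: mode-scaled Hindmarsh-Rose rest values with
    small Gaussian jitter."""
    scale = 1.0 / np.sqrt(params.n_modes)
    x_rest = params.x0 * scale
    y_rest = (params.c - params.d * params.x0 ** 2) * scale
    base = np.array([x_rest, y_rest, 0.0, x_rest, y_rest, 0.0])
    state = np.tile(base, (n_nodes, params.n_modes, 1))
    return state + 0.1 * rng.standard_normal(state.shape)


# --------------------------------------------------------------------------
# network integration
# --------------------------------------------------------------------------

@dataclass
class SJ3DTrajectory:
    """Raw integration output: the fast excitatory variable per node and
    mode at integration resolution, plus the final full state."""

    xi: np.ndarray            # (nsteps, nodes, modes)
    dt: float                 # ms
    params: SJ3DParams
    final_state: np.ndarray   # (nodes, modes, 6)

    @property
    def n_steps(self) -> int:
        return self.xi.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt


@njit(cache=True)
def _drift_kernel(xi, eta, tau, al, be, ga, aff,
                  a_i, b_i, c_i, d_i, e_i, f_i, h_i, p_i,
                  IE, II, m_i, n_i, mw, A, B, C,
                  K11, K12, K21, r, s,
                  dxi, deta, dtau, dal, dbe, dga):
    nn, nm = xi.shape
    for i in range(nn):
        for m in range(nm):
            sA = 0.0
            sB = 0.0
            sC = 0.0
            for k in range(nm):
                sA += A[m, k] * xi[i, k]
                sB += B[m, k] * al[i, k]
                sC += C[m, k] * xi[i, k]
            x = xi[i, m]
            w = al[i, m]
            dxi[i, m] = (eta[i, m] - a_i[m] * x ** 3 + b_i[m] * x * x
                         - tau[i, m] + K11 * (sA - x) - K12 * (sB - x)
                         + IE[m] + mw[m] * aff[i])
            deta[i, m] = c_i[m] - d_i[m] * x * x - eta[i, m]
            dtau[i, m] = r * s * x - r * tau[i, m] - m_i[m]
            dal[i, m] = (be[i, m] - e_i[m] * w ** 3 + f_i[m] * w * w
                         - ga[i, m] + K21 * (sC - w) + II[m])
            dbe[i, m] = h_i[m] - p_i[m] * w * w - be[i, m]
            dga[i, m] = r * s * w - r * ga[i, m] - n_i[m]


@njit(cache=True)
def _integrate_chunk(state, hist, t0, noise, out, W, dsteps, G, dt,
                     a_i, b_i, c_i, d_i, e_i, f_i, h_i, p_i,
                     IE, II, m_i, n_i, mw, A, B, C,
                     K11, K12, K21, r, s, noise_xi, noise_al):
    """Advance one chunk of steps; returns -1 on success or the failing
    step index on blow-up.  ``hist`` is a ring buffer of the mean-field
    coupling observable xbar; ``state`` is (nodes, modes, 6) updated in
    place; ``out`` records xi after each step."""
    nsteps = noise.shape[0]
    nn, nm = state.shape[0], state.shape[1]
    L = hist.shape[0]
    xi = state[:, :, 0]
    eta = state[:, :, 1]
    tau = state[:, :, 2]
    al = state[:, :, 3]
    be = state[:, :, 4]
    ga = state[:, :, 5]
    d1 = np.empty((nn, nm))
    d2 = np.empty((nn, nm))
    d3 = np.empty((nn, nm))
    d4 = np.empty((nn, nm))
    d5 = np.empty((nn, nm))
    d6 = np.empty((nn, nm))
    e1 = np.empty((nn, nm))
    e2 = np.empty((nn, nm))
    e3 = np.empty((nn, nm))
    e4 = np.empty((nn, nm))
    e5 = np.empty((nn, nm))
    e6 = np.empty((nn, nm))
    p1 = np.empty((nn, nm))
    p2 = np.empty((nn, nm))
    p3 = np.empty((nn, nm))
    p4 = np.empty((nn, nm))
    p5 = np.empty((nn, nm))
    p6 = np.empty((nn, nm))
    aff = np.empty(nn)
    sdt = np.sqrt(dt)
    for t in range(nsteps):
        tg = t0 + t
        for i in range(nn):
            acc = 0.0
            for j in range(nn):
                w = W[i, j]
                if w != 0.0:
                    acc += w * hist[(tg - dsteps[i, j]) % L, j]
            aff[i] = G * acc
        _drift_kernel(xi, eta, tau, al, be, ga, aff,
                      a_i, b_i, c_i, d_i, e_i, f_i, h_i, p_i,
                      IE, II, m_i, n_i, mw, A, B, C,
                      K11, K12, K21, r, s,
                      d1, d2, d3, d4, d5, d6)
        for i in range(nn):
            for m in range(nm):
                nxi = sdt * noise[t, i, m, 0] if noise_xi else 0.0
                nal = sdt * noise[t, i, m, 1] if noise_al else 0.0
                p1[i, m] = xi[i, m] + dt * d1[i, m] + nxi
                p2[i, m] = eta[i, m] + dt * d2[i, m]
                p3[i, m] = tau[i, m] + dt * d3[i, m]
                p4[i, m] = al[i, m] + dt * d4[i, m] + nal
                p5[i, m] = be[i, m] + dt * d5[i, m]
                p6[i, m] = ga[i, m] + dt * d6[i, m]
        _drift_kernel(p1, p2, p3, p4, p5, p6, aff,
                      a_i, b_i, c_i, d_i, e_i, f_i, h_i, p_i,
                      IE, II, m_i, n_i, mw, A, B, C,
                      K11, K12, K21, r, s,
                      e1, e2, e3, e4, e5, e6)
        for i in range(nn):
            xb = 0.0
            for m in range(nm):
                nxi = sdt * noise[t, i, m, 0] if noise_xi else 0.0
                nal = sdt * noise[t, i, m, 1] if noise_al else 0.0
                xi[i, m] += 0.5 * dt * (d1[i, m] + e1[i, m]) + nxi
                eta[i, m] += 0.5 * dt * (d2[i, m] + e2[i, m])
                tau[i, m] += 0.5 * dt * (d3[i, m] + e3[i, m])
                al[i, m] += 0.5 * dt * (d4[i, m] + e4[i, m]) + nal
                be[i, m] += 0.5 * dt * (d5[i, m] + e5[i, m])
                ga[i, m] += 0.5 * dt * (d6[i, m] + e6[i, m])
                if abs(xi[i, m]) > _BLOWUP or not np.isfinite(xi[i, m]):
                    return tg
                out[t, i, m] = xi[i, m]
                xb += mw[m] * xi[i, m]
            hist[(tg + 1) % L, i] = xb
    return -1


def simulate_network(connectome: Connectome, params: SJ3DParams | None = None,
                     G: float = 0.1, noise_sigma: float = 0.01,
                     duration_ms: float = 5000.0, dt: float = 2.0 ** -6,
                     seed: int | np.random.Generator = 0,
                     noise_scale: float | None = None,
                     chunk_steps: int = 8192) -> SJ3DTrajectory:
    """Integrate the delay-coupled SJ3D network.

    The delay line is seeded with the initial mean-field values; dynamical
    noise ``v_i(t)`` with per-step standard deviation
    ``noise_sigma * sqrt(dt)`` acts on the fast variables throughout.  Fully
    reproducible given the seed; noise is drawn identically whether or not
    couplings are zero, so ``G = 0`` on a coupled connectome reproduces the
    uncoupled run bit for bit.

    Raises
    ------
    FloatingPointError
        On integration blow-up, naming the (G, noise) cell.
    """
    params = params or SJ3DParams()
    rng = np.random.default_rng(seed)
    nn, nm = connectome.n_nodes, params.n_modes
    dsteps = connectome.delay_steps(dt) if np.any(connectome.weights) else \
        np.ones((nn, nn), dtype=np.int64)
    L = int(dsteps.max()) + 2
    nsteps = int(round(duration_ms / dt))
    state = default_initial_state(params, nn, rng)
    hist = np.tile((state[:, :, 0] * params.mode_mass).sum(axis=1), (L, 1))
    out = np.empty((nsteps, nn, nm))
    mask = params.noise_mask
    noise_xi, noise_al = bool(mask[0]), bool(mask[3])
    args = (params.a_i, params.b_i, params.c_i, params.d_i, params.e_i,
            params.f_i, params.h_i, params.p_i, params.IE_i, params.II_i,
            params.m_i, params.n_i, params.mode_mass,
            params.A_ik, params.B_ik, params.C_ik,
            params.K11, params.K12, params.K21, params.r, params.s)
    t0 = 0
    while t0 < nsteps:
        nc = min(chunk_steps, nsteps - t0)
        noise = noise_sigma * rng.standard_normal((nc, nn, nm, 2))
        fail = _integrate_chunk(state, hist, t0, noise, out[t0:t0 + nc],
                                connectome.weights, dsteps, float(G),
                                float(dt), *args, noise_xi, noise_al)
        if fail >= 0:
            raise FloatingPointError(
                f"integration blow-up at t = {fail * dt:.1f} ms in cell "
                f"(G={G:.4g}, noise={noise_sigma:.4g})")
        t0 += nc
    return SJ3DTrajectory(out, dt, params, state)


def extract_lfp(trajectory: SJ3DTrajectory, fs_out: float = 256.0,
                discard_ms: float = 500.0) -> TimeSeriesData:
    """LFP-like observable: per node, sum ``xi`` over modes, discard the
    initial transient, anti-alias low-pass and decimate to ``fs_out``, then
    z-score per channel."""
    dt = trajectory.dt
    fs_in = 1000.0 / dt
    down = fs_in / fs_out
    if abs(down - round(down)) > 1e-9 or down < 1:
        raise ValueError("fs_out must integer-divide the integration rate")
    ndiscard = int(round(discard_ms / dt))
    if ndiscard >= trajectory.n_steps:
        raise ValueError("trajectory shorter than the discard window")
    lfp = trajectory.xi.sum(axis=2).T[:, ndiscard:]     # (nodes, steps)
    scale = np.abs(lfp).max() + 1.0
    if np.any(lfp.std(axis=1) < 1e-10 * scale):
        raise ValueError("constant trajectory channel cannot be z-scored")
    dec = signal.resample_poly(lfp, up=1, down=int(round(down)), axis=1)
    return TimeSeriesData(dec, fs=fs_out).zscored()
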