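"""Minimisation of dynamical dependence over the Stiefel manifold.

At each macro scale n the DD objective is minimised over orthonormal n x N
coarse-grainings by projected gradient descent with an adaptive step size:
the Euclidean gradient is projected onto the Grassmannian horizontal space
at M, a descent step is taken and the candidate is re-orthonormalised by a
QR retraction.  Accepted steps grow the step size, rejected ones shrink it;
runs terminate on a gradient tolerance, an iteration cap, or step-size
underflow.

Because the DD landscape has many local minima, each scale is attacked with
many random restarts.  A cheap pre-optimisation pass (spectral proxy on a
coarse frequency grid, relaxed tolerance) is followed by clustering of the
runs — single linkage on the maximal principal angle between final
subspaces, refined by grouping DD values — and only one representative per
cluster is polished at full tolerance.  The *emergent n-macro* is the run
with minimal final DD.

The whole ensemble is deterministic given (model, config.seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dynamical_dependence import CoarseGraining, SpectralCache, dd_exact
from .linear_models import SSModel
from .localisation import macro_similarity

__all__ = [
    "OptimConfig",
    "OptimisationRun",
    "RunEnsemble",
    "random_stiefel",
    "tangent_project",
    "retract",
    "step",
    "minimise_dd",
    "preoptimise_and_cluster",
    "optimise_scale",
    "sweep_scales",
]


@dataclass(frozen=True)
class OptimConfig:
    """Optimisation schedule.

    Defaults follow the study protocol: 100 random restarts, at most 10,000
    iterations per run, gradient tolerance 1e-10.  The adaptive step rule
    multiplies the step by ``step_grow`` on acceptance and by
    ``step_shrink`` on rejection (candidate discarded), stopping if the step
    underflows ``step_min``.  Pre-optimisation uses the spectral proxy on
    ``preopt_nfreqs`` frequencies at the relaxed ``preopt_grad_tol``.
    """

    n_restarts: int = 100
    max_iters: int = 10_000
    grad_tol: float = 1e-10
    step0: float = 0.1
    step_grow: float = 1.1
    step_shrink: float = 0.5
    step_min: float = 1e-14
    preopt_nfreqs: int = 256
    polish_nfreqs: int = 1024
    preopt_grad_tol: float = 1e-6
    cluster_angle: float = 0.05
    cluster_dd_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_restarts, self.preopt_nfreqs, self.polish_nfreqs) <= 0:
            raise ValueError("counts must be positive")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")
        if not 0 < self.grad_tol < self.step0:
            raise ValueError("need 0 < grad_tol < initial step size")


@dataclass
class OptimisationRun:
    """One gradient-descent trajectory.

    ``history`` holds the DD value at the start plus after every *accepted*
    step, hence is non-increasing.
    """

    history: np.ndarray
    M_final: CoarseGraining
    converged: bool
    reason: str
    grad_norm: float
    seed: int

    @property
    def dd_final(self) -> float:
        return float(self.history[-1]) if len(self.history) else np.nan


@dataclass
class RunEnsemble:
    """Restart ensemble at one scale: runs, inter-run similarity (maximal
    principal angle, zero diagonal), cluster partition and the emergent
    macro (minimal final DD; ties broken by lowest run index)."""

    scale: int
    runs: list[OptimisationRun]
    similarity: np.ndarray
    clusters: list[list[int]]
    emergent_index: int

    @property
    def emergent_macro(self) -> OptimisationRun:
        return self.runs[self.emergent_index]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "scale": self.scale,
            "emergent_index": self.emergent_index,
            "clusters": self.clusters,
            "similarity": self.similarity.tolist(),
            "runs": [{
                "history": r.history.tolist(),
                "M_final": r.M_final.M.tolist(),
                "converged": r.converged,
                "reason": r.reason,
                "grad_norm": r.grad_norm,
                "seed": r.seed,
            } for r in self.runs],
        }))

    def similarity_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.similarity, delimiter=",")


# --------------------------------------------------------------------------
# manifold primitives
# --------------------------------------------------------------------------

def random_stiefel(n: int, N: int,
                   seed: int | np.random.Generator = 0) -> CoarseGraining:
    """Uniform (rotation-invariant) random point on the Stiefel manifold of
    orthonormal n x N row matrices, via sign-fixed QR of a Gaussian."""
    if not 0 < n < N:
        raise ValueError("need 0 < n < N")
    rng = np.random.default_rng(seed)
    return CoarseGraining(_orthonormalise(rng.standard_normal((n, N))))


def _orthonormalise(M: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(M.T)
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    return (Q * sign).T


def tangent_project(M: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Project a Euclidean gradient onto the Grassmannian horizontal space
    at M (components along the row space of M are removed; the objective is
    invariant along them)."""
    return G - (G @ M.T) @ M


def retract(M: np.ndarray) -> np.ndarray:
    """QR-based retraction onto the Stiefel manifold (sign-fixed for
    determinism); the retraction of a zero step returns M exactly up to
    round-off."""
    return _orthonormalise(M)


def step(model: SSModel, M: CoarseGraining, step_size: float,
         cache: SpectralCache | None = None,
         nfreqs: int = 1024) -> CoarseGraining:
    """One projected-gradient descent step of the given size (candidate
    only; no acceptance test)."""
    if cache is None:
        cache = SpectralCache(model, nfreqs)
    _, grad = cache.value_and_grad(M.M)
    G = tangent_project(M.M, grad)
    return CoarseGraining(retract(M.M - step_size * G))


# --------------------------------------------------------------------------
# descent loop
# --------------------------------------------------------------------------

def minimise_dd(model: SSModel, n: int, config: OptimConfig | None = None,
                M0: CoarseGraining | None = None,
                cache: SpectralCache | None = None,
                grad_tol: float | None = None,
                seed: int | None = None) -> OptimisationRun:
    """Minimise DD at scale n by adaptive-step projected gradient descent.

    Non-convergence within ``max_iters`` is a recorded outcome, not an
    error.  The spectral objective on ``cache`` (default
    ``config.polish_nfreqs`` frequencies) drives both values and gradients.
    """
    config = config or OptimConfig()
    tol = config.grad_tol if grad_tol is None else grad_tol
    run_seed = config.seed if seed is None else seed
    if M0 is None:
        M0 = random_stiefel(n, model.n_channels, run_seed)
    if cache is None:
        cache = SpectralCache(model, config.polish_nfreqs)
    M = M0.M.copy()
    if config.max_iters == 0:
        return OptimisationRun(np.array([]), CoarseGraining(M), False,
                               "max_iters=0", np.nan, run_seed)
    dd, grad = cache.value_and_grad(M)
    history = [dd]
    step_size = config.step0
    converged, reason, gnorm = False, "max_iters", np.nan
    for _ in range(config.max_iters):
        G = tangent_project(M, grad)
        gnorm = float(np.linalg.norm(G))
        if gnorm < tol:
            converged, reason = True, "grad_tol"
            break
        cand = retract(M - step_size * G)
        dd_cand = cache.value(cand)
        if dd_cand < dd:
            M, dd = cand, dd_cand
            _, grad = cache.value_and_grad(M)
            history.append(dd)
            step_size *= config.step_grow
        else:
            step_size *= config.step_shrink
            if step_size < config.step_min:
                converged, reason = True, "step_underflow"
                break
    # re-orthonormalise against drift before publishing
    M = retract(M)
    return OptimisationRun(np.asarray(history), CoarseGraining(M),
                           converged, reason, gnorm, run_seed)


# --------------------------------------------------------------------------
# restart ensembles
# --------------------------------------------------------------------------

def _similarity_matrix(runs: list[OptimisationRun]) -> np.ndarray:
    R = len(runs)
    sim = np.zeros((R, R))
    for i in range(R):
        for j in range(i + 1, R):
            sim[i, j] = sim[j, i] = macro_similarity(runs[i].M_final,
                                                     runs[j].M_final)
    return sim


def _cluster_runs(runs: list[OptimisationRun], sim: np.ndarray,
                  angle_cut: float, dd_tol: float) -> list[list[int]]:
    """Single-linkage clusters on maximal principal angle, each refined by
    splitting where sorted final-DD values gap by more than ``dd_tol``."""
    R = len(runs)
    if R == 1:
        return [[0]]
    labels = fcluster(linkage(squareform(sim, checks=False), method="single"),
                      t=angle_cut, criterion="distance")
    clusters: list[list[int]] = []
    for lab in np.unique(labels):
        idx = [int(i) for i in np.where(labels == lab)[0]]
        idx.sort(key=lambda i: runs[i].dd_final)
        group = [idx[0]]
        for i in idx[1:]:
            if runs[i].dd_final - runs[group[-1]].dd_final > dd_tol:
                clusters.append(group)
                group = [i]
            else:
                group.append(i)
        clusters.append(group)
    return clusters


def preoptimise_and_cluster(model: SSModel, n: int,
                            config: OptimConfig | None = None) -> RunEnsemble:
    """Cheap restart pass: ``n_restarts`` runs of the spectral proxy on the
    coarse grid at relaxed tolerance, clustered into basins; the ensemble
    carries all runs, their similarity matrix and the cluster partition."""
    config = config or OptimConfig()
    cache = SpectralCache(model, config.preopt_nfreqs)
    child_seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_restarts)
    runs = [minimise_dd(model, n, config, cache=cache,
                        grad_tol=config.preopt_grad_tol, seed=int(s))
            for s in child_seeds]
    sim = _similarity_matrix(runs)
    clusters = _cluster_runs(runs, sim, config.cluster_angle,
                             config.cluster_dd_tol)
    dds = [r.dd_final for r in runs]
    return RunEnsemble(n, runs, sim, clusters, int(np.argmin(dds)))


def optimise_scale(model: SSModel, n: int,
                   config: OptimConfig | None = None) -> RunEnsemble:
    """Full optimisation at one scale: pre-optimise, cluster, then polish
    one representative per cluster on the fine grid at full tolerance.

    Polished final DD values are re-evaluated with the exact (Riccati)
    method; the emergent macro attains the minimum over representatives,
    ties broken by lowest run index.
    """
    config = config or OptimConfig()
    pre = preoptimise_and_cluster(model, n, config)
    cache = SpectralCache(model, config.polish_nfreqs)
    polished = []
    for group in pre.clusters:
        rep = min(group, key=lambda i: (pre.runs[i].dd_final, i))
        run = minimise_dd(model, n, config, M0=pre.runs[rep].M_final,
                          cache=cache, seed=pre.runs[rep].seed)
        dd_ex = dd_exact(model, run.M_final).value
        hist = np.append(run.history, dd_ex) if len(run.history) else \
            np.array([dd_ex])
        # exact value can sit a hair above the proxy; keep history monotone
        hist = np.minimum.accumulate(hist)
        polished.append(replace(run, history=hist))
    sim = _similarity_matrix(polished)
    dds = [r.dd_final for r in polished]
    emergent = int(np.argmin(dds))
    clusters = [[i] for i in range(len(polished))]
    return RunEnsemble(n, polished, sim, clusters, emergent)


def sweep_scales(model: SSModel, config: OptimConfig | None = None,
                 scales: list[int] | None = None) -> dict[int, RunEnsemble]:
    """Emergent macros across candidate spatial scales (default 2..N-1)."""
    N = model.n_channels
    scales = scales or list(range(2, N))
    return {n: optimise_scale(
        model, n, replace(config or OptimConfig(),
                          seed=(config or OptimConfig()).seed + 7919 * n))
        for n in scales}
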