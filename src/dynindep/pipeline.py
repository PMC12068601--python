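"""End-to-end experiment orchestration.

For every cell of a (global coupling G, dynamical noise eta) lattice and
each connectome kind (coupled / uncoupled control) the pipeline simulates
the SJ3D network, extracts the LFP-like observable, fits a linear
state-space model, minimises dynamical dependence at the requested macro
scales, and records the emergent macro with its DD value and per-node
contribution vector.  Aggregation produces heatmap tables (DD per cell,
contribution per node per cell) and coupled-versus-uncoupled Wilcoxon
rank-sum comparisons of node contributions across the whole lattice.

Cells are seeded independently from a master seed (counter-based spawning),
simulated independently, and written to per-cell JSON files, so sweeps are
resumable and any subset reproduces identically to a full run.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dynamical_dependence import CoarseGraining
from .linear_models import estimate_ss, estimate_var
from .localisation import node_contribution
from .sj3d import (Connectome, SJ3DParams, SweepGrid, extract_lfp,
                   make_connectomes, simulate_network)
from .stiefel_optim import OptimConfig, optimise_scale

__all__ = [
    "SweepConfig",
    "SweepResult",
    "GroupComparison",
    "analyse_cell",
    "run_sweep",
    "heatmap_tables",
    "balanced_band_mask",
    "contribution_entropy",
    "rank_sum_z",
    "wilcoxon_compare",
    "report",
    "load_bundle",
]


@dataclass
class SweepConfig:
    """Full experiment configuration (echoed verbatim into result bundles)."""

    grid: SweepGrid = field(default_factory=SweepGrid.default)
    kinds: tuple[str, ...] = ("coupled", "uncoupled")
    scales: tuple[int, ...] = (2, 3)
    duration_ms: float = 5000.0
    dt: float = 2.0 ** -6
    fs_out: float = 256.0
    discard_ms: float = 500.0
    var_max_order: int = 8
    n_restarts: int = 100
    max_iters: int = 10_000
    seed: int = 0

    def optim(self, seed: int) -> OptimConfig:
        return OptimConfig(n_restarts=self.n_restarts,
                           max_iters=self.max_iters, seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {"g_values": self.grid.g_values.tolist(),
                     "noise_values": self.grid.noise_values.tolist(),
                     "seeds_per_cell": self.grid.seeds_per_cell}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        d = dict(d)
        g = d.pop("grid")
        return cls(grid=SweepGrid(np.array(g["g_values"]),
                                  np.array(g["noise_values"]),
                                  g.get("seeds_per_cell", 1)),
                   kinds=tuple(d.pop("kinds")), scales=tuple(d.pop("scales")),
                   **d)


@dataclass
class SweepResult:
    """Per-kind sweep outcome: one record per lattice cell.

    Each record holds the cell coordinates, fitted model metadata and, per
    macro scale, the minimal DD, the emergent macro basis and the node
    contribution vector; failed cells carry an ``error`` entry instead.
    """

    kind: str
    grid: SweepGrid
    records: dict[tuple[int, int], dict]

    def n_ok(self) -> int:
        return sum("error" not in r for r in self.records.values())

    def cell_values(self, scale: int, key: str = "dd") -> np.ndarray:
        """Matrix of per-cell scalars (G on rows, noise on columns)."""
        out = np.full(self.grid.shape, np.nan)
        for (i, j), rec in self.records.items():
            sc = rec.get("scales", {}).get(str(scale))
            if sc is not None:
                out[i, j] = sc[key]
        return out

    def contributions(self, scale: int, node: int) -> np.ndarray:
        """Flat per-cell contribution sample for one node at one scale,
        in lattice order; NaN for failed cells."""
        out = np.full(math.prod(self.grid.shape), np.nan)
        for idx, (i, j) in enumerate(
                (i, j) for i in range(self.grid.shape[0])
                for j in range(self.grid.shape[1])):
            sc = self.records.get((i, j), {}).get("scales", {}).get(str(scale))
            if sc is not None:
                out[idx] = sc["node_contribution"][node]
        return out


@dataclass
class GroupComparison:
    """Wilcoxon rank-sum comparison of one node's contribution
    distributions, coupled versus uncoupled, across the lattice."""

    node: int
    scale: int
    z: float
    p: float
    direction: str

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# single-cell analysis
# --------------------------------------------------------------------------

def _cell_seed(master: int, kind: str, i: int, j: int) -> int:
    # process-independent counter-based spawning (no str hash randomisation)
    kind_id = int.from_bytes(kind.encode()[:4].ljust(4, b"\0"), "little")
    ss = np.random.SeedSequence([master, kind_id % (2 ** 31), i, j])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def analyse_cell(connectome: Connectome, G: float, noise_sigma: float,
                 config: SweepConfig, seed: int,
                 params: SJ3DParams | None = None) -> dict:
    """Simulate one lattice cell and run the DI analysis on it."""
    traj = simulate_network(connectome, params, G=G, noise_sigma=noise_sigma,
                            duration_ms=config.duration_ms, dt=config.dt,
                            seed=seed)
    lfp = extract_lfp(traj, fs_out=config.fs_out,
                      discard_ms=config.discard_ms)
    var = estimate_var(lfp, config.var_max_order, "AIC")
    horizon = max(2, min(2 * var.order,
                         lfp.n_samples // (6 * lfp.n_channels)))
    ss_model = estimate_ss(lfp, horizon, horizon, "AIC")
    rec: dict = {"G": G, "noise": noise_sigma, "seed": seed,
                 "var_order": var.order, "ss_dim": ss_model.state_dim,
                 "scales": {}}
    for k, n in enumerate(config.scales):
        ens = optimise_scale(ss_model, n,
                             config.optim(seed=seed + 1 + k))
        M = ens.emergent_macro.M_final
        rec["scales"][str(n)] = {
            "dd": ens.emergent_macro.dd_final,
            "M": M.M.tolist(),
            "node_contribution": [node_contribution(M, i)
                                  for i in range(lfp.n_channels)],
            "converged": ens.emergent_macro.converged,
            "n_clusters": len(ens.runs),
        }
    return rec


def run_sweep(config: SweepConfig, out_dir: str | Path | None = None,
              params: SJ3DParams | None = None,
              progress: bool = False) -> dict[str, SweepResult]:
    """Run (or resume) the full sweep for every connectome kind.

    Per-cell failures are recorded and skipped; with ``out_dir`` set, each
    completed cell is written to ``<kind>_<i>_<j>.json`` and re-runs load
    existing records instead of recomputing them.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    params = params or SJ3DParams()
    results: dict[str, SweepResult] = {}
    for kind in config.kinds:
        conn = make_connectomes(kind)
        records: dict[tuple[int, int], dict] = {}
        for i, j, g, eta in config.grid.cells():
            cell_file = (out_path / f"{kind}_{i}_{j}.json"
                         if out_path is not None else None)
            if cell_file is not None and cell_file.exists():
                records[(i, j)] = json.loads(cell_file.read_text())
                continue
            seed = _cell_seed(config.seed, kind, i, j)
            try:
                rec = analyse_cell(conn, g, eta, config, seed, params)
            except (FloatingPointError, ValueError, np.linalg.LinAlgError) as exc:
                rec = {"G": g, "noise": eta, "seed": seed, "error": str(exc)}
            records[(i, j)] = rec
            if cell_file is not None:
                cell_file.write_text(json.dumps(rec))
            if progress:  # pragma: no cover - cosmetic
                print(f"[{kind} {i},{j}] done", flush=True)
        results[kind] = SweepResult(kind, config.grid, records)
    return results


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def heatmap_tables(results: dict[str, SweepResult],
                   scales: tuple[int, ...] = (2, 3)
                   ) -> dict[tuple, pd.DataFrame]:
    """Figure-equivalent tables: DD per cell keyed ``('dd', kind, n)`` and
    node contributions keyed ``('contribution', kind, n, node)``.

    Rows are global-coupling values (y-axis), columns dynamical-noise
    values (x-axis), both log-spaced lattices; missing cells are NaN.
    """
    tables: dict[tuple, pd.DataFrame] = {}
    for kind, res in results.items():
        idx = pd.Index(res.grid.g_values, name="G")
        cols = pd.Index(res.grid.noise_values, name="noise")
        n_nodes = _n_nodes(res)
        for n in scales:
            tables[("dd", kind, n)] = pd.DataFrame(
                res.cell_values(n, "dd"), index=idx, columns=cols)
            for node in range(n_nodes):
                mat = np.full(res.grid.shape, np.nan)
                flat = res.contributions(n, node)
                mat.flat[:] = flat
                tables[("contribution", kind, n, node)] = pd.DataFrame(
                    mat, index=idx, columns=cols)
    return tables


def _n_nodes(res: SweepResult) -> int:
    for rec in res.records.values():
        for sc in rec.get("scales", {}).values():
            return len(sc["node_contribution"])
    return 0


def balanced_band_mask(grid: SweepGrid, band: int = 3) -> np.ndarray:
    """Cells where the lattice ranks of G and noise differ by at most
    ``band`` — the regime where integration and segregation are balanced."""
    ng, ne = grid.shape
    ri = (np.arange(ng) / max(ng - 1, 1))[:, None]
    rj = (np.arange(ne) / max(ne - 1, 1))[None, :]
    scale = max(ng, ne) - 1
    return np.abs(ri - rj) * scale <= band + 1e-12


def contribution_entropy(scores) -> float:
    """Shannon entropy (nats) of a normalised node-contribution vector; low
    entropy = localised macro, high entropy = distributed."""
    p = np.asarray(scores, dtype=float)
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def rank_sum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum statistic of x versus y.

    Returns ``(W, Z)``: the rank sum of x and its normal-approximation
    z-score with tie correction.  Positive Z means x tends to exceed y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    allv = np.concatenate([x, y])
    ranks = stats.rankdata(allv)
    W = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    var = n1 * n2 * (n1 + n2 + 1) / 12.0 * stats.tiecorrect(ranks)
    z = 0.0 if var == 0 else (W - mu) / np.sqrt(var)
    return W, float(z)


def wilcoxon_compare(coupled: SweepResult, uncoupled: SweepResult,
                     node: int, scale: int, alternative: str = "two-sided",
                     method: str = "asymptotic") -> GroupComparison:
    """Compare one node's contribution distribution between the coupled and
    uncoupled (control) sweeps across the whole lattice.

    Two-sided by default; ``alternative='greater'`` tests coupled >
    uncoupled.  ``method='exact'`` enumerates the null distribution (small
    samples, no ties) via the Mann-Whitney correspondence.
    """
    a = coupled.contributions(scale, node)
    b = uncoupled.contributions(scale, node)
    ok_a, ok_b = ~np.isnan(a), ~np.isnan(b)
    if coupled.grid.shape != uncoupled.grid.shape:
        raise ValueError("sweeps cover different lattices")
    if not (np.array_equal(ok_a, ok_b)):
        raise ValueError("coupled and uncoupled cell sets do not match")
    a, b = a[ok_a], b[ok_b]
    _, z = rank_sum_z(a, b)
    if method == "exact":
        res = stats.mannwhitneyu(a, b, alternative=alternative,
                                 method="exact")
        p = float(res.pvalue)
    elif method == "asymptotic":
        if alternative == "two-sided":
            p = 2 * stats.norm.sf(abs(z))
        elif alternative == "greater":
            p = stats.norm.sf(z)
        elif alternative == "less":
            p = stats.norm.cdf(z)
        else:
            raise ValueError("unknown alternative")
    else:
        raise ValueError("method must be 'asymptotic' or 'exact'")
    direction = "coupled>uncoupled" if z > 0 else (
        "coupled<uncoupled" if z < 0 else "none")
    return GroupComparison(node, scale, z, min(max(p, np.nextafter(0, 1)), 1.0),
                           direction)


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def report(results: dict[str, SweepResult],
           comparisons: list[GroupComparison],
           config: SweepConfig, out_dir: str | Path) -> dict:
    """Write the consolidated machine-readable bundle.

    ``bundle.json`` holds the config echo, every per-cell record and the
    comparison statistics; DD and contribution tables are additionally
    emitted as CSV.  Loading the bundle reproduces all in-memory tables
    exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = {
        "config": config.to_dict(),
        "results": {kind: {f"{i},{j}": rec
                           for (i, j), rec in res.records.items()}
                    for kind, res in results.items()},
        "comparisons": [c.to_dict() for c in comparisons],
    }
    (out / "bundle.json").write_text(json.dumps(bundle, sort_keys=True))
    for key, df in heatmap_tables(results, config.scales).items():
        name = "_".join(str(k) for k in key)
        df.to_csv(out / f"{name}.csv")
    return bundle


def load_bundle(out_dir: str | Path) -> tuple[dict[str, SweepResult],
                                              list[GroupComparison],
                                              SweepConfig]:
    """Inverse of :func:`report` (from ``bundle.json``)."""
    bundle = json.loads((Path(out_dir) / "bundle.json").read_text())
    config = SweepConfig.from_dict(bundle["config"])
    results = {}
    for kind, recs in bundle["results"].items():
        records = {tuple(int(v) for v in key.split(",")): rec
                   for key, rec in recs.items()}
        results[kind] = SweepResult(kind, config.grid, records)
    comparisons = [GroupComparison(**c) for c in bundle["comparisons"]]
    return results, comparisons, config
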