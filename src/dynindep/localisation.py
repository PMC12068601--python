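"""Localisation of macrovariables over micro-level nodes.

A macro subspace (row space of a coarse-graining M) is *localised* when it
aligns with few coordinate axes of the micro state space, each axis being a
node/channel.  Alignment is quantified by principal angles: the score of a
node (or node subset) is the angle to the macro subspace normalised to
[0, 1], with 1 meaning coplanarity and 0 orthogonality.  All scores are
invariant under re-parametrisations ``M -> Phi M`` of the macro space.

A useful identity: with ``theta_i`` the angle between axis ``e_i`` and the
row space of an orthonormal n x N matrix M, ``sum_i cos^2 theta_i = n``
(trace of the orthogonal projector onto the row space).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles

from .dynamical_dependence import CoarseGraining

__all__ = [
    "ContributionMap",
    "principal_angles",
    "node_contribution",
    "grouped_contribution",
    "macro_similarity",
    "contribution_map",
]

#: exhaustive subset enumeration guard (C(N, n) growth)
MAX_NODES_FOR_SUBSETS = 15

HALF_PI = np.pi / 2


def _as_matrix(M) -> np.ndarray:
    return M.M if isinstance(M, CoarseGraining) else np.atleast_2d(np.asarray(M, float))


def principal_angles(U: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Principal angles between the column spaces of U and W.

    Bases are orthonormalised internally; angles come from the singular
    values of the inner-product matrix, clipped to [0, 1] before the
    arc-cosine, and are returned sorted ascending in [0, pi/2].  The count
    is the smaller subspace dimension.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if U.ndim != 2 or W.ndim != 2 or U.shape[1] == 0 or W.shape[1] == 0:
        raise ValueError("zero-dimensional subspace")
    return np.sort(subspace_angles(U, W))


def node_contribution(M: CoarseGraining | np.ndarray, node: int,
                      form: str = "angle") -> float:
    """Contribution of a single node to the macro subspace, in [0, 1].

    The principal angle theta between the coordinate axis ``e_node`` and the
    row space of M satisfies ``cos theta = ||M e_node||`` for orthonormal M.
    The default score is ``1 - theta / (pi/2)`` (normalised angle); pass
    ``form='cos'`` for the cosine itself.  Both give 1 for a node lying in
    the subspace and 0 for a node orthogonal to it.
    """
    Mm = _as_matrix(M)
    if not 0 <= node < Mm.shape[1]:
        raise ValueError("node index out of range")
    c = min(1.0, float(np.linalg.norm(Mm[:, node])))
    if form == "cos":
        return c
    if form != "angle":
        raise ValueError("form must be 'angle' or 'cos'")
    return 1.0 - np.arccos(c) / HALF_PI


def grouped_contribution(M: CoarseGraining | np.ndarray, subset) -> float:
    """Contribution of an n-subset of nodes to an n-dimensional macro.

    Score is ``1 - theta_max / (pi/2)`` with theta_max the *largest*
    principal angle between ``span{e_i : i in subset}`` and the row space of
    M: the score is 1 iff the subset plane and the macro plane coincide, and
    0 if some direction of the subset is orthogonal to the macro.
    """
    Mm = _as_matrix(M)
    subset = sorted(set(int(i) for i in subset))
    if len(subset) != Mm.shape[0]:
        raise ValueError("subset cardinality must equal the macro scale")
    E = np.eye(Mm.shape[1])[:, subset]
    theta_max = float(principal_angles(Mm.T, E).max())
    return 1.0 - theta_max / HALF_PI


def macro_similarity(M1, M2) -> float:
    """Distance between two macros: the maximal principal angle between
    their row spaces, in [0, pi/2].

    For macros of different scales (n1 < n2) only ``n1`` angles exist; a
    near-zero value then indicates that the smaller macro is nested inside
    the larger one.
    """
    A = _as_matrix(M1).T
    B = _as_matrix(M2).T
    return float(principal_angles(A, B).max())


@dataclass
class ContributionMap:
    """Per-node and per-subset localisation scores of one macro."""

    node_scores: np.ndarray
    subset_scores: dict[tuple[int, ...], float]
    best_subset: tuple[int, ...]
    display_threshold: float = 0.1
    #: sum of squared axis-angle cosines; equals the macro scale n
    cos2_sum: float = field(default=0.0)

    def labelled_subsets(self) -> dict[tuple[int, ...], float]:
        """Subsets whose score exceeds the display threshold (the only ones
        labelled in reports)."""
        return {s: v for s, v in self.subset_scores.items()
                if v > self.display_threshold}

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": np.arange(len(self.node_scores)),
                             "score": self.node_scores})

    def subset_frame(self) -> pd.DataFrame:
        rows = [{"subset": "+".join(str(i) for i in s), "score": v,
                 "is_best": s == self.best_subset}
                for s, v in sorted(self.subset_scores.items())]
        return pd.DataFrame(rows)


def contribution_map(M: CoarseGraining | np.ndarray,
                     display_threshold: float = 0.1,
                     form: str = "angle") -> ContributionMap:
    """Exhaustive localisation of a macro: all single-node scores and all
    C(N, n) grouped-node scores, with the best-aligned subset flagged."""
    Mm = _as_matrix(M)
    n, N = Mm.shape
    if N > MAX_NODES_FOR_SUBSETS:
        raise ValueError(
            f"subset enumeration limited to N <= {MAX_NODES_FOR_SUBSETS}")
    node_scores = np.array([node_contribution(Mm, i, form=form)
                            for i in range(N)])
    subset_scores = {tuple(s): grouped_contribution(Mm, s)
                     for s in combinations(range(N), n)}
    best = max(subset_scores, key=subset_scores.get)
    cos2 = float(sum(np.linalg.norm(Mm[:, i]) ** 2 for i in range(N)))
    return ContributionMap(node_scores, subset_scores, best,
                           display_threshold, cos2)
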