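"""Structural priors and penalty terms for structured sparse CCA.

Three kinds of structure enter the model:

* a *chain* over adjacent features (fused paired group lasso, FGL), with
  nonnegative edge weights ``w[i]`` on the edge (i, i+1);
* an arbitrary *feature graph* (graph-guided paired group lasso, GGL),
  an edge list over feature pairs;
* a *connectivity Laplacian* (GraphNet), a quadratic smoothing penalty
  ``u' L u`` with ``L = diag(C 1) - C`` built from a sign-insensitive
  connectivity matrix C.

The pairwise group penalties are non-smooth; the solver handles them by
iterative reweighting through diagonal matrices D_X, D_Y whose entries are
reciprocal square roots of adjacent-pair magnitudes, floored at a small
``eps`` to keep them finite (the implicit smoothing of the penalties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .datatypes import DataMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .solver import HyperParams


class StructureError(ValueError):
    """Raised when a structural prior violates its invariants."""


@dataclass
class ChainWeights:
    """Nonnegative weights on the chain edges (i, i+1), length d-1.

    The conceptual boundary weights w_{0,1} and w_{d,d+1} are identically
    zero and never stored.
    """

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise StructureError("chain weights must be a vector")
        if np.any(self.w < 0) or not np.all(np.isfinite(self.w)):
            raise StructureError("chain weights must be finite and nonnegative")

    @property
    def n_features(self) -> int:
        return self.w.size + 1


@dataclass
class FeatureGraph:
    """Weighted undirected feature graph as an edge list.

    Edges are stored once as (i, j, w) with 0 <= i < j < num_nodes and
    w >= 0; duplicate pairs are rejected.
    """

    edges: list[tuple[int, int, float]]
    num_nodes: int

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        norm: list[tuple[int, int, float]] = []
        for i, j, w in self.edges:
            i, j, w = int(i), int(j), float(w)
            if i == j:
                raise StructureError(f"self-loop ({i},{j}) not allowed")
            if i > j:
                i, j = j, i
            if not (0 <= i < j < self.num_nodes):
                raise StructureError(
                    f"edge ({i},{j}) out of range for {self.num_nodes} nodes"
                )
            if (i, j) in seen:
                raise StructureError(f"duplicate edge ({i},{j})")
            if w < 0 or not np.isfinite(w):
                raise StructureError(f"edge ({i},{j}) has invalid weight {w}")
            seen.add((i, j))
            norm.append((i, j, w))
        self.edges = norm

    def adjacency(self) -> list[list[tuple[int, float]]]:
        """Neighbor list: for each node, [(neighbor, weight), ...]."""
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.num_nodes)]
        for i, j, w in self.edges:
            adj[i].append((j, w))
            adj[j].append((i, w))
        return adj


@dataclass
class ConnectivityLaplacian:
    """Connectivity matrix C (symmetric, nonnegative, zero diagonal) and its
    combinatorial Laplacian L = diag(C 1) - C.

    L is symmetric positive semidefinite with the constant vector in its
    null space, so u' L u = sum_{i<j} C_ij (u_i - u_j)^2.
    """

    C: np.ndarray
    L: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise StructureError("connectivity matrix must be square")
        if not np.allclose(C, C.T, atol=1e-12):
            raise StructureError("connectivity matrix must be symmetric")
        if np.any(C < 0):
            raise StructureError("connectivity matrix must be nonnegative")
        if np.any(np.diag(C) != 0):
            raise StructureError("connectivity matrix must have zero diagonal")
        self.C = C
        if self.L is None:
            self.L = np.diag(C.sum(axis=1)) - C

    @property
    def n_features(self) -> int:
        return self.C.shape[0]


@dataclass
class PenaltyState:
    """Diagonals of the reweighting matrices D_X (length p) and D_Y (length q).

    All entries are finite and positive by the eps-guard in
    :func:`update_penalty_state`.
    """

    dX: np.ndarray
    dY: np.ndarray


@dataclass
class StructurePack:
    """All structural priors for one data view.

    ``chain`` drives the FGL penalty, ``graph`` the GGL penalty and
    ``laplacian`` the GraphNet penalty; any may be None (penalty absent).
    """

    chain: ChainWeights | None = None
    graph: FeatureGraph | None = None
    laplacian: ConnectivityLaplacian | None = None


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    """Column-pairwise Pearson correlations; all-zero columns give r = 0."""
    v = values - values.mean(axis=0)
    norms = np.linalg.norm(v, axis=0)
    zero = norms <= 1e-12
    safe = np.where(zero, 1.0, norms)
    vn = v / safe
    r = vn.T @ vn
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return r


def build_chain_weights(X: DataMatrix, scheme: str = "unit") -> ChainWeights:
    """Chain weights for the FGL penalty on X's features.

    ``unit`` gives all-ones weights; ``abs_corr`` uses |Pearson r| between
    adjacent columns (all-zero columns contribute weight 0).
    """
    d = X.n_features
    if d < 2:
        raise StructureError("chain needs at least 2 features")
    if scheme == "unit":
        return ChainWeights(np.ones(d - 1))
    if scheme == "abs_corr":
        v = X.values - X.values.mean(axis=0)
        norms = np.linalg.norm(v, axis=0)
        w = np.empty(d - 1)
        for i in range(d - 1):
            if norms[i] <= 1e-12 or norms[i + 1] <= 1e-12:
                w[i] = 0.0
                continue
            r = float(v[:, i] @ v[:, i + 1] / (norms[i] * norms[i + 1]))
            if not np.isfinite(r):
                raise StructureError(
                    f"non-finite correlation between columns {i} and {i + 1}"
                )
            w[i] = min(abs(r), 1.0)
        return ChainWeights(w)
    raise StructureError(f"unknown chain scheme {scheme!r}")


def build_feature_graph(
    Y: DataMatrix,
    scheme: str = "threshold_abs_corr",
    threshold: float = 0.5,
    edges: list[tuple[int, int, float]] | None = None,
) -> FeatureGraph:
    """Feature graph for the GGL penalty on Y's features.

    ``threshold_abs_corr`` links (j, k) iff |r(col_j, col_k)| >= threshold,
    with weight |r|; ``chain_plus_corr`` additionally guarantees the chain
    edges (j, j+1) with unit weight, so the penalty always induces
    structured sparsity even when no correlation clears the threshold;
    ``from_file`` validates a user-supplied edge list (passed via
    ``edges``).
    """
    q = Y.n_features
    if scheme in ("threshold_abs_corr", "chain_plus_corr"):
        if not (0.0 < threshold < 1.0):
            raise StructureError(f"threshold must lie in (0,1), got {threshold}")
        r = np.abs(_pearson_matrix(Y.values))
        pairs: dict[tuple[int, int], float] = {}
        for j in range(q):
            for k in range(j + 1, q):
                if r[j, k] >= threshold:
                    pairs[(j, k)] = float(r[j, k])
        if scheme == "chain_plus_corr":
            for j in range(q - 1):
                pairs.setdefault((j, j + 1), 1.0)
        out = [(j, k, w) for (j, k), w in sorted(pairs.items())]
        return FeatureGraph(out, q)
    if scheme == "from_file":
        if edges is None:
            raise StructureError("from_file scheme requires an edge list")
        return FeatureGraph(list(edges), q)
    raise StructureError(f"unknown graph scheme {scheme!r}")


def build_connectivity_laplacian(
    M: DataMatrix,
    scheme: str = "abs_corr",
    sparsify_threshold: float = 0.0,
) -> ConnectivityLaplacian:
    """Sign-insensitive connectivity C and Laplacian L for GraphNet.

    C_ij = |r_ij| (``abs_corr``) or r_ij^2 (``sq_corr``) for i != j, entries
    below ``sparsify_threshold`` zeroed; L = diag(C 1) - C.
    """
    if sparsify_threshold < 0:
        raise StructureError("sparsify_threshold must be >= 0")
    r = _pearson_matrix(M.values)
    if scheme == "abs_corr":
        C = np.abs(r)
    elif scheme == "sq_corr":
        C = r**2
    else:
        raise StructureError(f"unknown connectivity scheme {scheme!r}")
    np.fill_diagonal(C, 0.0)
    C[C < sparsify_threshold] = 0.0
    C = (C + C.T) / 2.0  # exact symmetry against floating-point asymmetry
    if np.any(C < 0):
        raise StructureError("internal error: negative connectivity entries")
    return ConnectivityLaplacian(C)


def fgl_penalty(u: np.ndarray, chain: ChainWeights, lam: float) -> float:
    """lam * sum_i w_i sqrt(u_i^2 + u_{i+1}^2) over the chain edges."""
    u = np.asarray(u, dtype=float)
    if u.size != chain.n_features:
        raise StructureError("loading length does not match chain weights")
    pairs = np.sqrt(u[:-1] ** 2 + u[1:] ** 2)
    return float(lam * np.sum(chain.w * pairs))


def ggl_penalty(v: np.ndarray, graph: FeatureGraph, lam: float) -> float:
    """lam * sum_{(j,k) in E} w_jk sqrt(v_j^2 + v_k^2) over graph edges."""
    v = np.asarray(v, dtype=float)
    if v.size != graph.num_nodes:
        raise StructureError("loading length does not match graph nodes")
    total = 0.0
    for j, k, w in graph.edges:
        total += w * np.sqrt(v[j] ** 2 + v[k] ** 2)
    return float(lam * total)


def graphnet_penalty(u: np.ndarray, lap: ConnectivityLaplacian) -> float:
    """Quadratic form u' L u (nonnegative; zero for constant u)."""
    u = np.asarray(u, dtype=float)
    if u.size != lap.n_features:
        raise StructureError("loading length does not match Laplacian")
    val = float(u @ lap.L @ u)
    return max(val, 0.0)  # clip tiny negative round-off


def penalty_values(
    u: np.ndarray,
    v: np.ndarray,
    sx: StructurePack,
    sy: StructurePack,
    hp: "HyperParams",
) -> dict[str, float]:
    """Evaluate all four penalty terms at (u, v).

    Returns a record with keys ``fgl``, ``ggl``, ``graphnet_u``,
    ``graphnet_v`` (GraphNet values are the raw quadratic forms, without
    their lambda/2 coefficients).
    """
    fgl = fgl_penalty(u, sx.chain, hp.lambda1) if sx.chain is not None else 0.0
    ggl = ggl_penalty(v, sy.graph, hp.lambda2) if sy.graph is not None else 0.0
    gn_u = graphnet_penalty(u, sx.laplacian) if sx.laplacian is not None else 0.0
    gn_v = graphnet_penalty(v, sy.laplacian) if sy.laplacian is not None else 0.0
    return {"fgl": fgl, "ggl": ggl, "graphnet_u": gn_u, "graphnet_v": gn_v}


def _huber_norm(s: np.ndarray, eps: float) -> np.ndarray:
    """eps-smoothed magnitude: s - eps/2 for s >= eps, s^2/(2 eps) below.

    This is the function whose gradient the reweighting diagonals realize
    (weight 1/max(s, eps)); it equals the exact magnitude up to eps/2 and
    is what the alternating solver actually decreases.
    """
    return np.where(s >= eps, s - eps / 2.0, s**2 / (2.0 * eps))


def fgl_penalty_smoothed(
    u: np.ndarray, chain: ChainWeights, lam: float, eps: float
) -> float:
    """eps-smoothed FGL penalty (the solver's Lyapunov form)."""
    u = np.asarray(u, dtype=float)
    if u.size != chain.n_features:
        raise StructureError("loading length does not match chain weights")
    pairs = np.sqrt(u[:-1] ** 2 + u[1:] ** 2)
    return float(lam * np.sum(chain.w * _huber_norm(pairs, eps)))


def ggl_penalty_smoothed(
    v: np.ndarray, graph: FeatureGraph, lam: float, eps: float
) -> float:
    """eps-smoothed GGL penalty (the solver's Lyapunov form)."""
    v = np.asarray(v, dtype=float)
    if v.size != graph.num_nodes:
        raise StructureError("loading length does not match graph nodes")
    total = 0.0
    for j, k, w in graph.edges:
        s = np.sqrt(v[j] ** 2 + v[k] ** 2)
        total += w * float(_huber_norm(np.asarray(s), eps))
    return float(lam * total)


def chain_reweight_diagonal(
    u: np.ndarray, chain: ChainWeights, eps: float
) -> np.ndarray:
    """Diagonal of D_X: dX_i = w_{i-1,i}/sqrt(u_{i-1}^2+u_i^2)
    + w_{i,i+1}/sqrt(u_i^2+u_{i+1}^2), boundary terms zero, denominators
    floored at eps."""
    u = np.asarray(u, dtype=float)
    p = u.size
    if p != chain.n_features:
        raise StructureError("loading length does not match chain weights")
    pair = np.maximum(np.sqrt(u[:-1] ** 2 + u[1:] ** 2), eps)
    d = np.zeros(p)
    d[:-1] += chain.w / pair
    d[1:] += chain.w / pair
    return d


def graph_reweight_diagonal(
    v: np.ndarray, graph: FeatureGraph, eps: float
) -> np.ndarray:
    """Diagonal of D_Y: dY_j = sum_{m:(j,m) in E} w_jm/sqrt(v_j^2+v_m^2)."""
    v = np.asarray(v, dtype=float)
    if v.size != graph.num_nodes:
        raise StructureError("loading length does not match graph nodes")
    d = np.zeros(graph.num_nodes)
    for j, k, w in graph.edges:
        pair = max(np.sqrt(v[j] ** 2 + v[k] ** 2), eps)
        d[j] += w / pair
        d[k] += w / pair
    return d


def update_penalty_state(
    u: np.ndarray,
    v: np.ndarray,
    sx: StructurePack,
    sy: StructurePack,
    eps: float = 1e-6,
) -> PenaltyState:
    """Recompute the reweighting diagonals D_X, D_Y at the current (u, v).

    Sides without a chain/graph get a zero diagonal (penalty absent).
    """
    if eps <= 0:
        raise StructureError("eps must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    dX = (
        chain_reweight_diagonal(u, sx.chain, eps)
        if sx.chain is not None
        else np.zeros(u.size)
    )
    dY = (
        graph_reweight_diagonal(v, sy.graph, eps)
        if sy.graph is not None
        else np.zeros(v.size)
    )
    if not (np.all(np.isfinite(dX)) and np.all(np.isfinite(dY))):
        raise StructureError("non-finite reweighting diagonal")
    return PenaltyState(dX=dX, dY=dY)


def default_structures(
    X: DataMatrix,
    Y: DataMatrix,
    chain_scheme: str = "unit",
    graph_scheme: str = "chain_plus_corr",
    graph_threshold: float = 0.5,
    conn_scheme: str = "abs_corr",
    conn_threshold: float = 0.0,
    graph_edges: list[tuple[int, int, float]] | None = None,
) -> tuple[StructurePack, StructurePack]:
    """Build the default structure packs: chain + GraphNet on X, feature
    graph + GraphNet on Y."""
    sx = StructurePack(
        chain=build_chain_weights(X, chain_scheme),
        laplacian=build_connectivity_laplacian(X, conn_scheme, conn_threshold),
    )
    graph = build_feature_graph(Y, graph_scheme, graph_threshold, edges=graph_edges)
    if not graph.edges:
        warnings.warn(
            "feature graph has no edges; GGL penalty is inactive", stacklevel=2
        )
    sy = StructurePack(
        graph=graph,
        laplacian=build_connectivity_laplacian(Y, conn_scheme, conn_threshold),
    )
    return sx, sy
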