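"""Graph-theory layer: metrics, null models, modularity, permutation tests.

The group connectomes are undirected graphs over the ROI set (binary for
the structural branch, positive-weighted for the functional branch). This
module provides

* segregation/integration metrics — clustering coefficient, characteristic
  path length, global efficiency;
* degree-preserving rewired null ensembles and the small-worldness ratios
  gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda;
* modularity maximisation (restarted Louvain, best-of-``n_iter`` by the
  Newman Q objective, recomputed independently from the returned
  assignment);
* density thresholding of weighted matrices and the two-cohort
  nonparametric permutation test of network measures across densities.

Modularity of a partition with communities c over a weighted graph:

    Q = sum_c [ W_c / v - (S_c / v)^2 ]

with ``W_c`` the total (ordered-pair) weight inside community c, ``S_c``
the total strength of its nodes, and ``v`` the total weight of the graph
counting both directions. For binary graphs this is the usual
edges-minus-expected form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectome import GroupWeightedConnectome
from .roi import RoiSet

__all__ = [
    "Partition",
    "GraphMetrics",
    "NullEnsemble",
    "PermutationResult",
    "modularity_q",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "rewire_null",
    "small_worldness",
    "detect_modules",
    "threshold_at_density",
    "permutation_compare",
]

Mode = Literal["binary", "weighted"]


@dataclass
class Partition:
    """ROI -> module assignment with its modularity score."""

    assignment: dict[str, int]
    q: float
    roi_set: RoiSet

    def __post_init__(self) -> None:
        if set(self.assignment) != set(self.roi_set.labels):
            raise ValueError("assignment must cover the roi_set exactly")
        ids = sorted(set(self.assignment.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"module ids must be contiguous from 1, got {ids}")
        if not -1.0 - 1e-9 <= self.q <= 1.0 + 1e-9:
            raise ValueError(f"modularity q={self.q} outside [-1, 1]")

    @property
    def n_modules(self) -> int:
        return max(self.assignment.values())

    def labels_array(self) -> np.ndarray:
        """Module ids in canonical roi_set order."""
        return np.array([self.assignment[l] for l in self.roi_set], dtype=int)


@dataclass
class GraphMetrics:
    c: float
    l: float
    e_global: float
    q: float | None = None
    gamma: float | None = None
    lambda_ratio: float | None = None
    sigma: float | None = None


@dataclass
class NullEnsemble:
    """Degree-preserving rewired surrogates of one binary graph."""

    graphs: list[np.ndarray]
    seed: int

    @property
    def n(self) -> int:
        return len(self.graphs)


@dataclass
class PermutationResult:
    observed: float
    p_value: float | None
    ci_low: float | None
    ci_high: float | None
    n_perm_valid: int
    missing: bool = False


def _as_sym(adj: np.ndarray, *, allow_negative: bool = False) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got {adj.shape}")
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not allow_negative and np.any(adj < 0):
        raise ValueError("negative weights are not supported")
    adj = adj.copy()
    np.fill_diagonal(adj, 0.0)
    return adj


def modularity_q(adj: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity of a labelled partition over a (weighted) graph."""
    adj = _as_sym(adj)
    labels = np.asarray(labels)
    if labels.shape != (adj.shape[0],):
        raise ValueError("labels must give one module id per node")
    v = adj.sum()  # counts both directions
    if v == 0:
        return 0.0
    strength = adj.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        w_c = adj[np.ix_(mask, mask)].sum()
        s_c = strength[mask].sum()
        q += w_c / v - (s_c / v) ** 2
    return float(q)


def clustering_coefficient(adj: np.ndarray, mode: Mode = "binary") -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean.

    Binary: triangles around a node over its possible neighbour pairs
    (0 for degree < 2). Weighted: Onnela's geometric-mean-of-weights
    variant, with weights scaled by the network maximum.
    """
    adj = _as_sym(adj)
    a = (adj > 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    if mode == "binary":
        paths = np.diag(a @ a @ a)
    elif mode == "weighted":
        wmax = adj.max()
        if wmax == 0:
            return np.zeros(adj.shape[0]), 0.0
        w3 = np.cbrt(adj / wmax)
        paths = np.diag(w3 @ w3 @ w3)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, paths / np.where(denom > 0, denom, 1.0), 0.0)
    return c, float(c.mean())


def _distances(adj: np.ndarray, mode: Mode) -> np.ndarray:
    if mode == "binary":
        return shortest_path((adj > 0).astype(float), method="D", unweighted=True)
    if mode == "weighted":
        with np.errstate(divide="ignore"):
            lengths = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), 0.0)
        return shortest_path(lengths, method="D", unweighted=False)
    raise ValueError(f"unknown mode {mode!r}")


def characteristic_path_length(adj: np.ndarray, mode: Mode = "binary") -> float:
    """Mean shortest-path length over connected node pairs.

    Disconnected pairs are excluded from the mean (their count is logged
    via a warning); an edgeless graph has no path length at all.
    """
    adj = _as_sym(adj)
    if (adj > 0).sum() == 0:
        raise ValueError("path length undefined for an edgeless graph")
    d = _distances(adj, mode)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int((off & ~np.isfinite(d)).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} disconnected ordered pairs excluded from path length",
            stacklevel=2,
        )
    return float(d[finite].mean())


def global_efficiency(adj: np.ndarray, mode: Mode = "binary") -> float:
    """Mean inverse shortest-path length over all ordered pairs (0 if disconnected)."""
    adj = _as_sym(adj)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    if (adj > 0).sum() == 0:
        return 0.0
    d = _distances(adj, mode)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].mean())


def rewire_null(adj: np.ndarray, n: int = 20, seed: int = 0) -> NullEnsemble:
    """Degree-preserving rewired surrogates (double-edge swaps).

    Each surrogate applies 10x|E| successful swaps, preserving node count,
    edge count and the exact degree sequence. Graphs with no legal swap
    (e.g. complete graphs) are returned as unmodified copies with a
    warning.
    """
    adj = _as_sym(adj)
    if not np.isin(adj, (0.0, 1.0)).all():
        raise ValueError("rewiring nulls require a binary graph; threshold first")
    g = nx.from_numpy_array(adj)
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    degrees = sorted(d for _, d in g.degree())
    rng = np.random.default_rng(seed)
    graphs: list[np.ndarray] = []
    complete = n_edges == n_nodes * (n_nodes - 1) // 2
    for _ in range(n):
        h = g.copy()
        if complete or n_edges < 2:
            warnings.warn("graph admits no double-edge swap; null equals input", stacklevel=2)
        else:
            try:
                nx.double_edge_swap(
                    h,
                    nswap=10 * n_edges,
                    max_tries=1000 * n_edges + 1000,
                    seed=int(rng.integers(2**31)),
                )
            except nx.NetworkXError:
                warnings.warn("rewiring failed to find swaps; null equals input", stacklevel=2)
                h = g.copy()
        assert sorted(d for _, d in h.degree()) == degrees, "degree sequence not preserved"
        graphs.append(nx.to_numpy_array(h, nodelist=sorted(h.nodes())))
    return NullEnsemble(graphs=graphs, seed=seed)


def small_worldness(
    adj: np.ndarray, ensemble: NullEnsemble, mode: Mode = "binary"
) -> tuple[float, float, float]:
    """gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda vs the ensemble."""
    _, c = clustering_coefficient(adj, mode)
    l = characteristic_path_length(adj, mode)
    c_rand = float(np.mean([clustering_coefficient(h, mode)[1] for h in ensemble.graphs]))
    l_rand = float(np.mean([characteristic_path_length(h, mode) for h in ensemble.graphs]))
    gamma = c / c_rand
    lambda_ratio = l / l_rand
    return gamma, lambda_ratio, gamma / lambda_ratio


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary community labels to 1..K in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def detect_modules(
    adj: np.ndarray,
    roi_set: RoiSet,
    mode: Mode = "binary",
    n_iter: int = 1000,
    seed: int = 0,
) -> Partition:
    """Modularity maximisation by restarted Louvain.

    The heuristic is restarted ``n_iter`` times with seed-derived orders and
    the partition with the highest Q is returned (ties: first encountered).
    Q is recomputed from the returned assignment with :func:`modularity_q`,
    independent of whatever the optimizer reported.
    """
    adj = _as_sym(adj)
    if len(roi_set) != adj.shape[0]:
        raise ValueError("roi_set size must match adjacency")
    if mode == "binary" and not np.isin(adj, (0.0, 1.0)).all():
        raise ValueError("binary mode requires a 0/1 adjacency")
    if adj.sum() == 0:
        warnings.warn("all-zero matrix: returning a single module with q = 0", stacklevel=2)
        return Partition(
            assignment={l: 1 for l in roi_set}, q=0.0, roi_set=roi_set
        )
    g = nx.from_numpy_array(adj)
    rng = np.random.default_rng(seed)
    best_labels: np.ndarray | None = None
    best_q = -np.inf
    n = adj.shape[0]
    for _ in range(n_iter):
        communities = nx.community.louvain_communities(
            g, weight="weight", seed=int(rng.integers(2**31))
        )
        labels = np.empty(n, dtype=int)
        for cid, members in enumerate(communities):
            labels[list(members)] = cid
        q = modularity_q(adj, labels)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels
    assert best_labels is not None
    labels = _relabel_contiguous(best_labels)
    q = modularity_q(adj, labels)
    return Partition(
        assignment={roi_set[i]: int(labels[i]) for i in range(n)},
        q=q,
        roi_set=roi_set,
    )


def threshold_at_density(
    weighted: GroupWeightedConnectome | np.ndarray, density: float
) -> np.ndarray:
    """Binarize a weighted matrix by keeping its strongest edges.

    Keeps the top ``floor(density * n(n-1)/2)`` positive-weight edges; ties
    at the cut are broken by lexicographic ROI-pair order so the output is
    reproducible. At density 1 every positive edge is kept.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    w = weighted.weights if isinstance(weighted, GroupWeightedConnectome) else weighted
    w = _as_sym(np.asarray(w, dtype=float))
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    k = math.floor(density * n * (n - 1) / 2)
    positive = vals > 0
    # lexicographic (i, j) tie-break: stable sort on -weight keeps index order
    order = np.argsort(-vals, kind="stable")
    order = order[positive[order]][: min(k, int(positive.sum()))]
    out = np.zeros_like(w)
    out[iu[order], ju[order]] = 1.0
    out[ju[order], iu[order]] = 1.0
    return out


# ---------------------------------------------------------------------------
# Two-cohort permutation test
# ---------------------------------------------------------------------------

_R_CLIP = 1.0 - 1e-6


def _group_weights_from_z(z_stack: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Fisher-average a subset of pre-z-transformed subject matrices."""
    g = np.tanh(z_stack[idx].mean(axis=0))
    g = np.where(g > 0, g, 0.0)
    np.fill_diagonal(g, 0.0)
    return g


def _binary_metric(adj: np.ndarray, metric: str, seed: int) -> float:
    if (adj > 0).sum() == 0:
        return math.nan
    if metric == "clustering":
        return clustering_coefficient(adj, "binary")[1]
    if metric == "path_length":
        d = _distances(adj, "binary")
        off = ~np.eye(adj.shape[0], dtype=bool)
        finite = np.isfinite(d) & off
        if not finite.any():
            return math.nan
        return float(d[finite].mean())
    if metric == "efficiency":
        return global_efficiency(adj, "binary")
    if metric == "modularity":
        # small restart budget: this runs inside the permutation loop
        g = nx.from_numpy_array(adj)
        rng = np.random.default_rng(seed)
        best = -np.inf
        n = adj.shape[0]
        for _ in range(5):
            communities = nx.community.louvain_communities(
                g, weight="weight", seed=int(rng.integers(2**31))
            )
            labels = np.empty(n, dtype=int)
            for cid, members in enumerate(communities):
                labels[list(members)] = cid
            best = max(best, modularity_q(adj, labels))
        return float(best)
    raise ValueError(f"unknown metric {metric!r}")


def permutation_compare(
    cohort_a: Sequence[np.ndarray],
    cohort_b: Sequence[np.ndarray],
    metric: str = "clustering",
    densities: Sequence[float | None] = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50),
    n_perm: int = 1000,
    seed: int = 0,
    builder: Literal["fisher", "consistency"] = "fisher",
    min_fraction: float = 0.5,
) -> dict[float | None, PermutationResult]:
    """Nonparametric two-cohort test of a network measure across densities.

    Subject matrices are pooled; at each permutation the subjects are
    reassigned to two groups of the original sizes, each group's network is
    rebuilt, and the measure recomputed. Two group builders are available,
    matching the two connectome branches:

    * ``"fisher"`` — subject correlation matrices are Fisher-averaged,
      negatives zeroed, and the group matrix thresholded at each target
      density;
    * ``"consistency"`` — subject binary matrices are averaged into an
      edge-consistency fraction matrix; a density of ``None`` applies the
      group-consistency criterion (fraction >= ``min_fraction``, the
      network's native density), a numeric density keeps the most
      consistent edges.

    At a matched density only edge *ranking* differences between cohorts
    are visible; cohort differences in overall connection probability
    surface at the native consistency threshold.

    Two-sided ``p = (1 + #{|diff_perm| >= |diff_obs|}) / (n_perm + 1)``;
    the confidence band is the 2.5/97.5 percentile range of the
    permutation distribution. Densities where the measure is undefined
    (disconnected or empty graphs) are reported missing, never fabricated.
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("need at least two subjects per cohort")
    pooled = [np.asarray(m, dtype=float) for m in list(cohort_a) + list(cohort_b)]
    stack = np.stack(pooled)
    if builder == "fisher":
        stack = np.arctanh(np.clip(stack, -_R_CLIP, _R_CLIP))
    elif builder == "consistency":
        if not np.isin(stack, (0.0, 1.0)).all():
            raise ValueError("consistency builder expects binary subject matrices")
    else:
        raise ValueError(f"unknown builder {builder!r}")
    for m in stack:
        np.fill_diagonal(m, 0.0)

    def group_adj(idx: np.ndarray, density: float | None) -> np.ndarray:
        if builder == "fisher":
            if density is None:
                raise ValueError("fisher builder requires a numeric density")
            return threshold_at_density(_group_weights_from_z(stack, idx), density)
        fraction = stack[idx].mean(axis=0)
        if density is None:
            return (fraction >= min_fraction - 1e-12).astype(float)
        return threshold_at_density(fraction, density)

    n_a = len(cohort_a)
    n_tot = stack.shape[0]
    rng = np.random.default_rng(seed)
    metric_seed = int(rng.integers(2**31))

    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_tot)
    results: dict[float | None, PermutationResult] = {}
    perms = [rng.permutation(n_tot) for _ in range(n_perm)]
    for density in densities:
        key = None if density is None else float(density)
        obs_a = _binary_metric(group_adj(idx_a, density), metric, metric_seed)
        obs_b = _binary_metric(group_adj(idx_b, density), metric, metric_seed)
        observed = obs_a - obs_b
        if math.isnan(observed):
            results[key] = PermutationResult(
                observed=math.nan, p_value=None, ci_low=None, ci_high=None,
                n_perm_valid=0, missing=True,
            )
            continue
        diffs = np.empty(n_perm)
        for k, perm in enumerate(perms):
            pa = _binary_metric(group_adj(perm[:n_a], density), metric, metric_seed)
            pb = _binary_metric(group_adj(perm[n_a:], density), metric, metric_seed)
            diffs[k] = pa - pb
        valid = diffs[~np.isnan(diffs)]
        p = (1.0 + float((np.abs(valid) >= abs(observed)).sum())) / (valid.size + 1.0)
        results[key] = PermutationResult(
            observed=float(observed),
            p_value=p,
            ci_low=float(np.percentile(valid, 2.5)),
            ci_high=float(np.percentile(valid, 97.5)),
            n_perm_valid=int(valid.size),
        )
    return results
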