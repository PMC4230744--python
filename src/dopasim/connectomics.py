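"""Functional connectivity and weighted graph analysis of BOLD signals.

Pairwise statistical similarity between regional time series is measured by
the normalized mutual information

    NMI(X, Y) = I(X; Y) / sqrt(H(X) H(Y)),

the raw mutual information normalized by the geometric mean of the two
Shannon entropies, bounded in [0, 1] (0 for independent signals, 1 for
mutually dependent ones).  Entropies are plug-in estimates from equal-width
histograms with ceil(sqrt(length)) bins by default.  The symmetric NMI
matrix is then read as a weighted, undirected, unthresholded graph and
summarized per node by strength, degree, the Onnela geometric-mean
clustering coefficient and Latora local efficiency (inverse shortest paths
within the neighborhood, distances = inverse weights); clustering and
efficiency are additionally normalized against an ensemble of null networks
that preserve size, density and the weight multiset.  Rest/task contrasts
are assessed with a paired sign-flip permutation test controlling
family-wise error through the maximal statistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .params import ParameterError

__all__ = [
    "entropy",
    "nmi",
    "nmi_matrix",
    "NmiNetwork",
    "GraphMetricsResult",
    "PermutationTestResult",
    "nodal_strength",
    "nodal_degree",
    "weighted_clustering",
    "local_efficiency",
    "null_ensemble",
    "normalized_metrics",
    "compute_graph_metrics",
    "paired_permutation_test",
]


def default_bins(length: int) -> int:
    return int(np.ceil(np.sqrt(length)))


def entropy(x: np.ndarray, bins: int) -> float:
    """Plug-in Shannon entropy (bits) of an equal-width histogram of x."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ParameterError("cannot estimate entropy of an empty series")
    if bins < 2:
        raise ParameterError("need at least 2 bins")
    if x.size < bins:
        raise ParameterError("series shorter than the number of bins")
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def nmi(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """Normalized mutual information of two equally long series, in [0, 1].

    A constant series carries zero entropy, so no shared information is
    measurable; the coefficient is then defined as 0 and a warning is
    emitted.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ParameterError("series lengths differ")
    if bins is None:
        bins = default_bins(x.size)
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    if hx == 0.0 or hy == 0.0:
        warnings.warn("constant series has zero entropy; NMI defined as 0",
                      stacklevel=2)
        return 0.0
    nz = pxy > 0
    hxy = float(-(pxy[nz] * np.log2(pxy[nz])).sum())
    mi = hx + hy - hxy
    return float(min(1.0, max(0.0, mi / np.sqrt(hx * hy))))


@dataclass
class NmiNetwork:
    """Symmetric [0,1] NMI connectivity matrix with unit diagonal."""

    matrix: np.ndarray
    bins: int
    source: str = "model"      # model | data
    condition: str = "rest"    # rest | task

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ParameterError("NMI matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ParameterError("NMI matrix must be symmetric")
        if np.any(m < 0) or np.any(m > 1):
            raise ParameterError("NMI entries must lie in [0, 1]")
        if not np.allclose(np.diag(m), 1.0):
            raise ParameterError("NMI diagonal must be 1")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def nmi_matrix(signals, bins: int | None = None, source: str = "model",
               condition: str = "rest") -> NmiNetwork:
    """All-pairs NMI of a (time x regions) panel (or BoldSignal)."""
    values = getattr(signals, "values", signals)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ParameterError("need a (time x regions) panel with >= 2 regions")
    n = values.shape[1]
    if bins is None:
        bins = default_bins(values.shape[0])
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = nmi(values[:, i], values[:, j], bins=bins)
    return NmiNetwork(matrix=m, bins=bins, source=source, condition=condition)


# ---------------------------------------------------------------------------
# weighted graph metrics (full networks, no thresholding)

def _weights(W) -> np.ndarray:
    w = np.array(getattr(W, "matrix", W), dtype=float)
    np.fill_diagonal(w, 0.0)
    return w


def nodal_strength(W) -> np.ndarray:
    """Sum of attached edge weights per node."""
    return _weights(W).sum(axis=1)


def nodal_degree(W) -> np.ndarray:
    """Number of strictly positive edges per node."""
    return (_weights(W) > 0).sum(axis=1)


def weighted_clustering(W) -> np.ndarray:
    """Onnela clustering: mean geometric mean of triangle edge weights.

    Weights are scaled by the network maximum before taking cube roots;
    nodes with fewer than two neighbors score 0.
    """
    w = _weights(W)
    mx = w.max()
    k = nodal_degree(w).astype(float)
    if mx == 0:
        return np.zeros(w.shape[0])
    a = np.cbrt(w / mx)
    cyc3 = np.diag(a @ a @ a)
    denom = k * (k - 1)
    out = np.zeros(w.shape[0])
    mask = denom > 0
    out[mask] = cyc3[mask] / denom[mask]
    return out


def local_efficiency(W) -> np.ndarray:
    """Latora local efficiency per node.

    For each node, the subgraph induced by its neighbors is traversed with
    edge lengths 1/weight; efficiency is the mean inverse shortest-path
    length over ordered neighbor pairs.  Nodes with fewer than two
    neighbors score 0.
    """
    w = _weights(W)
    n = w.shape[0]
    out = np.zeros(n)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = lengths[np.ix_(nbrs, nbrs)]
        d = dijkstra(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        out[i] = inv[np.isfinite(inv)].sum() / (k * (k - 1))
    return out


def null_ensemble(W, n: int = 100, seed: int = 0) -> np.ndarray:
    """Null networks preserving size, density and the weight multiset.

    Each surrogate redistributes the observed off-diagonal weights
    uniformly at random over the edge positions of a symmetric graph of the
    same size (a full weight-multiset shuffle), so strength totals and the
    weight distribution are conserved exactly.
    """
    if n < 1:
        raise ParameterError("need at least one null network")
    w = _weights(W)
    m = w.shape[0]
    iu = np.triu_indices(m, k=1)
    vals = w[iu]
    rng = np.random.default_rng(seed)
    out = np.zeros((n, m, m))
    for s in range(n):
        shuffled = rng.permutation(vals)
        surr = np.zeros((m, m))
        surr[iu] = shuffled
        out[s] = surr + surr.T
    return out


@dataclass
class GraphMetricsResult:
    """Per-node metrics of one network, raw and null-normalized."""

    strength: np.ndarray
    degree: np.ndarray
    clustering: np.ndarray
    efficiency: np.ndarray
    clustering_norm: np.ndarray | None = None
    efficiency_norm: np.ndarray | None = None
    n_null: int = 0
    null_seed: int = 0


def normalized_metrics(W, ensemble: np.ndarray):
    """Observed clustering/efficiency divided by the null-ensemble means.

    Nodes whose ensemble-mean metric is zero have no defined normalization
    and are reported as NaN.
    """
    ensemble = np.asarray(ensemble)
    if ensemble.ndim != 3 or ensemble.shape[0] < 1:
        raise ParameterError("ensemble must be a non-empty stack of matrices")
    c_obs = weighted_clustering(W)
    e_obs = local_efficiency(W)
    c_null = np.mean([weighted_clustering(g) for g in ensemble], axis=0)
    e_null = np.mean([local_efficiency(g) for g in ensemble], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_hat = np.where(c_null > 0, c_obs / c_null, np.nan)
        e_hat = np.where(e_null > 0, e_obs / e_null, np.nan)
    return c_hat, e_hat


def compute_graph_metrics(W, n_null: int = 100, seed: int = 0) -> GraphMetricsResult:
    """All nodal metrics plus null-normalized clustering and efficiency."""
    ens = null_ensemble(W, n=n_null, seed=seed)
    c_hat, e_hat = normalized_metrics(W, ens)
    return GraphMetricsResult(
        strength=nodal_strength(W), degree=nodal_degree(W),
        clustering=weighted_clustering(W), efficiency=local_efficiency(W),
        clustering_norm=c_hat, efficiency_norm=e_hat,
        n_null=n_null, null_seed=seed)


# ---------------------------------------------------------------------------
# paired permutation test with max-statistic FWE control

@dataclass
class PermutationTestResult:
    observed: np.ndarray       # per-node differences a - b
    null_max: np.ndarray       # max statistic per permutation
    p_fwe: np.ndarray          # FWE-adjusted p per node, in (0, 1]
    n_perm: int
    seed: int
    exhaustive: bool = False


def paired_permutation_test(a: np.ndarray, b: np.ndarray,
                            n_perm: int = 1000, seed: int = 0,
                            exhaustive: bool | None = None) -> PermutationTestResult:
    """Sign-flip permutation test of paired per-node metrics with FWE control.

    Under the null the paired differences d = a - b are symmetric about
    zero, so their signs are exchangeable.  Each permutation flips the sign
    of every node's difference independently and studentizes the flipped
    vector by its own mean and standard deviation, z_i = (e_i - mean(e)) /
    sd(e); the null distribution is the maximum of z across nodes, and the
    adjusted p-value of node i is the fraction of permutations whose
    maximum reaches node i's observed studentized difference.  The
    within-permutation studentization is what gives the max statistic a
    fine-grained, exactly exchangeable null — the raw signed maximum is
    dominated by the largest |d_i| in half of all flips and cannot reject.
    The identity assignment is always included, so p in [1/n_perm, 1]; with
    ``exhaustive`` (default: automatic for 2^n <= n_perm) all 2^n sign
    assignments are enumerated and the test is exact.  All-zero differences
    give p = 1 at every node.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("a and b must be 1-d arrays of equal length")
    if n_perm < 100:
        raise ParameterError("need at least 100 permutations")
    d = a - b
    n = d.size
    if exhaustive is None:
        exhaustive = n <= 20 and 2 ** n <= n_perm
    rng = np.random.default_rng(seed)
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
        signs[0] = 1.0  # identity assignment always included
    flipped = signs * d

    def studentize(e):
        sd = e.std(axis=-1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return (e - e.mean(axis=-1, keepdims=True)) / sd

    null_max = studentize(flipped).max(axis=1)
    z_obs = studentize(d[None, :])[0]
    p = (null_max[:, None] >= z_obs[None, :]).mean(axis=0)
    return PermutationTestResult(observed=d, null_max=null_max,
                                 p_fwe=p, n_perm=len(signs), seed=seed,
                                 exhaustive=exhaustive)
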