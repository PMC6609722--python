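"""Regularized partial-correlation networks and differential network tests.

A Gaussian graphical model is estimated by the graphical lasso; the L1
penalty is selected by the Extended Bayesian Information Criterion (EBIC).
Edge stability is summarized over bootstrap resamples, communities are found
by the walktrap algorithm, and the dependence of the network on a clinical
outcome is tested by a permutation network-comparison test on a median split
of the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import statsmodels.api as sm
# the private solver entry point skips the heavy estimator-API validation,
# which dominates runtime in permutation loops re-fitting thousands of paths
from sklearn.covariance._graph_lasso import _graphical_lasso as _sk_graphical_lasso_core
from statsmodels.stats.multitest import multipletests

from .exceptions import ConvergenceError, ValidationError
from .preprocess import ProcessedMatrix

__all__ = [
    "PartialCorrelationNetwork",
    "BootstrapSummary",
    "CommunityPartition",
    "NetworkComparisonResult",
    "sample_correlation",
    "graphical_lasso",
    "precision_to_partial_correlations",
    "lambda_max",
    "make_lambda_grid",
    "ebic",
    "ebic_select",
    "bootstrap_network",
    "kkt_violation",
    "walktrap_communities",
    "compare_networks",
    "validate_interaction",
]


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, ProcessedMatrix):
        return data.values.to_numpy(dtype=float), list(data.values.columns)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    return arr, [f"V{i + 1}" for i in range(arr.shape[1])]


@dataclass
class PartialCorrelationNetwork:
    """A symmetric partial-correlation weight matrix at one penalty."""

    weights: np.ndarray
    penalty: float
    ebic: float
    node_labels: list[str]
    sample_size: int
    precision: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValidationError("weight matrix must be symmetric")
        if np.abs(np.diag(w)).max() != 0.0:
            raise ValidationError("weight matrix diagonal must be zero")
        if np.abs(w).max() > 1.0 + 1e-10:
            raise ValidationError("partial correlations must lie in [-1, 1]")
        self.weights = w

    @property
    def n_edges(self) -> int:
        return int((np.triu(self.weights, 1) != 0).sum())

    def edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.weights, 1))
        return pd.DataFrame(
            {
                "node_a": [self.node_labels[a] for a in i],
                "node_b": [self.node_labels[b] for b in j],
                "weight": self.weights[i, j],
            }
        )


@dataclass
class BootstrapSummary:
    median_weights: np.ndarray
    inclusion_frequency: np.ndarray
    n_boot: int
    node_labels: list[str]
    n_redrawn: int = 0


@dataclass
class CommunityPartition:
    labels: np.ndarray
    modularity: float
    steps: int


@dataclass
class NetworkComparisonResult:
    """Permutation test of network invariance between two outcome groups.

    ``stat_structure`` is M, the maximum absolute edge-weight difference;
    ``stat_global_strength`` is S, the absolute difference in total absolute
    edge weight.  ``per_edge`` covers every edge with nonzero observed weight
    in either group, with Holm-adjusted permutation p-values.
    """

    stat_structure: float
    stat_global_strength: float
    p_structure: float
    p_global: float
    per_edge: pd.DataFrame
    n_perm: int
    network_low: PartialCorrelationNetwork
    network_high: PartialCorrelationNetwork


def sample_correlation(data) -> np.ndarray:
    """Pearson correlation matrix with unit diagonal."""
    X, labels = _as_matrix(data)
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 samples")
    if np.isnan(X).any():
        raise ValidationError("input contains missing values")
    sd = X.std(axis=0)
    if (sd == 0).any():
        dead = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance columns: {dead}")
    S = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(S, 1.0)
    return S


def graphical_lasso(
    S: np.ndarray, lam: float, tol: float = 1e-4, max_iter: int = 200
) -> np.ndarray:
    """L1-penalized precision estimate.

    Maximizes ``log det(Theta) - tr(S Theta) - lam * sum_{i!=j} |Theta_ij|``
    (the diagonal is unpenalized).  ``lam=0`` returns the unpenalized maximum
    likelihood estimate, the direct inverse of S.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValidationError("lam must be >= 0")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValidationError("S must be symmetric")
    if lam == 0.0:
        cond = np.linalg.cond(S)
        if cond > 1e12:
            raise ConvergenceError(f"S is ill-conditioned (cond={cond:.2e}); use lam > 0")
        theta = np.linalg.inv(S)
        return (theta + theta.T) / 2.0
    off = np.abs(S - np.diag(np.diag(S)))
    if lam >= off.max():
        # full shrinkage: the solution is diagonal, Theta_ii = 1 / S_ii
        return np.diag(1.0 / np.diag(S))
    # the coordinate-descent dual gap can hover just outside tol even at a
    # valid solution; judge convergence by the KKT residual of the penalized
    # objective rather than by the solver's dual-gap warning alone
    last_message = ""
    for iters in (max_iter, 4 * max_iter):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                _, theta, costs, _ = _sk_graphical_lasso_core(
                    S,
                    alpha=lam,
                    cov_init=None,
                    mode="cd",
                    tol=tol,
                    enet_tol=1e-4,
                    max_iter=iters,
                    verbose=False,
                    eps=np.finfo(np.float64).eps,
                )
            except FloatingPointError as exc:
                raise ConvergenceError(f"graphical lasso failed at lam={lam}: {exc}") from exc
        theta = (theta + theta.T) / 2.0
        gap = abs(costs[-1][1])
        messages = [str(w.message) for w in caught if "did not converge" in str(w.message)]
        if not messages and gap <= tol:
            return theta
        if kkt_violation(theta, S, lam) <= 100.0 * tol:
            return theta
        last_message = messages[0] if messages else f"dual gap {gap:.3e} above tol at lam={lam}"
    raise ConvergenceError(last_message)


def kkt_violation(theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Maximum stationarity residual of the penalized log-likelihood.

    At the optimum, (Theta^-1 - S)_ij equals lam * sign(Theta_ij) on nonzero
    off-diagonal entries, lies within [-lam, lam] on zero entries, and is 0
    on the diagonal.
    """
    G = np.linalg.inv(theta) - S
    off = ~np.eye(theta.shape[0], dtype=bool)
    nz = off & (theta != 0)
    z = off & (theta == 0)
    viol = np.abs(np.diag(G)).max() if theta.shape[0] else 0.0
    if nz.any():
        viol = max(viol, np.abs(G[nz] - lam * np.sign(theta[nz])).max())
    if z.any():
        viol = max(viol, max(0.0, (np.abs(G[z]) - lam).max()))
    return float(viol)


def precision_to_partial_correlations(theta: np.ndarray) -> np.ndarray:
    """w_ij = -theta_ij / sqrt(theta_ii * theta_jj), zero diagonal."""
    theta = np.asarray(theta, dtype=float)
    d = np.diag(theta)
    if (d <= 0).any():
        raise ValidationError("precision matrix must have positive diagonal")
    w = -theta / np.sqrt(np.outer(d, d))
    np.fill_diagonal(w, 0.0)
    return w


def lambda_max(S: np.ndarray) -> float:
    """Smallest penalty at which the estimated graph is empty."""
    return float(np.abs(S - np.diag(np.diag(S))).max())


def make_lambda_grid(S: np.ndarray, n_lambda: int = 100, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to ratio * lambda_max."""
    lmax = lambda_max(S)
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def ebic(theta: np.ndarray, S: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a precision estimate.

    -2 * loglik + E * log(n) + 4 * gamma * E * log(p), where E counts the
    nonzero upper-diagonal entries and loglik is the Gaussian log-likelihood
    at theta.
    """
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    loglik = 0.5 * n * (logdet - np.trace(S @ theta) - p * np.log(2.0 * np.pi))
    E = int((np.triu(theta, 1) != 0).sum())
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def ebic_select(
    data,
    lambda_grid: np.ndarray | None = None,
    gamma: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> PartialCorrelationNetwork:
    """Estimate the partial-correlation network at the EBIC-optimal penalty.

    Fits the graphical lasso along the penalty grid (descending) and returns
    the network minimizing EBIC; ties favour the larger penalty, i.e. the
    sparser model.  Penalties at which the fit fails are skipped; if every
    fit fails the last error propagates.
    """
    X, labels = _as_matrix(data)
    n = X.shape[0]
    S = sample_correlation(X)
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(S)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if lambda_grid.size == 0:
        raise ValidationError("lambda_grid must be non-empty")

    best = None
    last_error: Exception | None = None
    for lam in lambda_grid:
        try:
            theta = graphical_lasso(S, lam, tol=tol, max_iter=max_iter)
        except ConvergenceError as exc:
            last_error = exc
            continue
        score = ebic(theta, S, n, gamma=gamma)
        if best is None or score < best[0]:
            best = (score, lam, theta)
    if best is None:
        raise last_error if last_error is not None else ConvergenceError("all fits failed")
    score, lam, theta = best
    return PartialCorrelationNetwork(
        weights=precision_to_partial_correlations(theta),
        penalty=float(lam),
        ebic=score,
        node_labels=labels,
        sample_size=n,
        precision=theta,
    )


def bootstrap_network(
    data,
    n_boot: int = 1000,
    lambda_grid: np.ndarray | None = None,
    gamma: float = 0.5,
    seed: int | None = None,
    refit_lambda: bool = True,
) -> BootstrapSummary:
    """Median partial correlations and edge inclusion over bootstrap resamples.

    Subjects are resampled with replacement; the penalty is re-selected per
    resample by default (``refit_lambda=False`` fixes the full-data penalty).
    Resamples in which some column has zero variance are redrawn and counted.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    X, labels = _as_matrix(data)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    fixed_grid = lambda_grid
    if not refit_lambda:
        full = ebic_select(X, lambda_grid=lambda_grid, gamma=gamma)
        fixed_grid = np.array([full.penalty])

    stack = np.empty((n_boot, p, p))
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            if (Xb.std(axis=0) > 0).all():
                break
            n_redrawn += 1
        net = ebic_select(Xb, lambda_grid=fixed_grid, gamma=gamma)
        stack[b] = net.weights
    median = np.median(stack, axis=0)
    inclusion = (stack != 0).mean(axis=0)
    median[inclusion == 0.0] = 0.0
    np.fill_diagonal(median, 0.0)
    return BootstrapSummary(
        median_weights=median,
        inclusion_frequency=inclusion,
        n_boot=n_boot,
        node_labels=labels,
        n_redrawn=n_redrawn,
    )


def _weights_of(network) -> tuple[np.ndarray, list[str]]:
    if isinstance(network, PartialCorrelationNetwork):
        return network.weights, network.node_labels
    if isinstance(network, BootstrapSummary):
        return network.median_weights, network.node_labels
    w = np.asarray(network, dtype=float)
    return w, [f"V{i + 1}" for i in range(w.shape[0])]


def walktrap_communities(network, steps: int = 4) -> CommunityPartition:
    """Walktrap community detection on absolute edge weights.

    Random walks of length ``steps`` drive the agglomerative merge sequence;
    the partition is cut at maximum modularity (computed on absolute
    weights).  A graph with no edges yields singleton communities with
    modularity 0.
    """
    w, _ = _weights_of(network)
    p = w.shape[0]
    if p < 1:
        raise ValidationError("network must have at least one node")
    absw = np.abs(np.triu(w, 1))
    ii, jj = np.nonzero(absw)
    if len(ii) == 0:
        return CommunityPartition(labels=np.arange(p), modularity=0.0, steps=steps)
    g = igraph.Graph(n=p, edges=list(zip(ii.tolist(), jj.tolist())))
    weights = absw[ii, jj].tolist()
    dendrogram = g.community_walktrap(weights=weights, steps=steps)
    clustering = dendrogram.as_clustering()
    labels = np.asarray(clustering.membership)
    modularity = float(g.modularity(labels, weights=weights))
    return CommunityPartition(labels=labels, modularity=modularity, steps=steps)


def _comparison_stats(w1: np.ndarray, w2: np.ndarray) -> tuple[float, float, np.ndarray]:
    diff = np.triu(w1 - w2, 1)
    M = float(np.abs(diff).max()) if diff.size else 0.0
    S = float(abs(np.abs(np.triu(w1, 1)).sum() - np.abs(np.triu(w2, 1)).sum()))
    return M, S, np.abs(diff)


def compare_networks(
    data,
    outcome,
    n_perm: int = 1000,
    seed: int | None = None,
    include_outcome_node: bool = False,
    lambda_grid: np.ndarray | None = None,
    gamma: float = 0.5,
    min_group: int = 10,
    tol: float = 1e-4,
) -> NetworkComparisonResult:
    """Permutation network-comparison test against a median split of the outcome.

    Subjects at or below the outcome median form the low group.  Both group
    networks are EBIC-selected; the structure statistic M (maximum absolute
    edge difference) and global-strength statistic S are referred to a
    permutation null built by shuffling group labels and re-estimating both
    networks.  p-values use the add-one convention.  Per-edge p-values come
    from the same permutations, Holm-adjusted over the edges with nonzero
    observed weight in either group.
    """
    X, labels = _as_matrix(data)
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must have at least 2 distinct values")
    low_mask = y <= np.median(y)
    n_low, n_high = int(low_mask.sum()), int((~low_mask).sum())
    if min(n_low, n_high) < min_group:
        raise ValidationError(
            f"median split produced a group below {min_group} subjects "
            f"(low={n_low}, high={n_high})"
        )
    if include_outcome_node:
        z = (y - y.mean()) / y.std()
        X = np.column_stack([X, z])
        labels = labels + ["OUTCOME"]

    def estimate(mask: np.ndarray) -> PartialCorrelationNetwork:
        frame = pd.DataFrame(X[mask], columns=labels)
        return ebic_select(frame, lambda_grid=lambda_grid, gamma=gamma, tol=tol)

    net_low = estimate(low_mask)
    net_high = estimate(~low_mask)
    M_obs, S_obs, edge_obs = _comparison_stats(net_low.weights, net_high.weights)

    rng = np.random.default_rng(seed)
    count_M = count_S = 0
    edge_counts = np.zeros_like(edge_obs)
    perm = low_mask.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        p_low = estimate(perm)
        p_high = estimate(~perm)
        M, S, edge = _comparison_stats(p_low.weights, p_high.weights)
        count_M += M >= M_obs
        count_S += S >= S_obs
        edge_counts += edge >= edge_obs
    p_structure = (1.0 + count_M) / (1.0 + n_perm)
    p_global = (1.0 + count_S) / (1.0 + n_perm)

    family = np.triu((net_low.weights != 0) | (net_high.weights != 0), 1)
    ii, jj = np.nonzero(family)
    per_edge = pd.DataFrame(
        {
            "node_a": [labels[a] for a in ii],
            "node_b": [labels[b] for b in jj],
            "diff": (net_low.weights - net_high.weights)[ii, jj],
            "p_raw": (1.0 + edge_counts[ii, jj]) / (1.0 + n_perm),
        }
    )
    if len(per_edge):
        per_edge["p_adjusted"] = multipletests(per_edge["p_raw"], method="holm")[1]
    else:
        per_edge["p_adjusted"] = pd.Series(dtype=float)
    return NetworkComparisonResult(
        stat_structure=M_obs,
        stat_global_strength=S_obs,
        p_structure=p_structure,
        p_global=p_global,
        per_edge=per_edge,
        n_perm=n_perm,
        network_low=net_low,
        network_high=net_high,
    )


def validate_interaction(met_a, met_b, outcome, covariates: pd.DataFrame | None = None):
    """Moderation check: regress met_a on met_b, outcome and their product.

    Returns (interaction coefficient, p-value); a constant outcome makes the
    product term unidentifiable and yields (nan, nan) with a warning.
    """
    a = np.asarray(met_a, dtype=float)
    b = np.asarray(met_b, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValidationError("inputs must have equal length")
    if np.ptp(y) == 0.0:
        warnings.warn("outcome is constant; interaction term dropped")
        return float("nan"), float("nan")
    X = pd.DataFrame({"const": 1.0, "met_b": b, "outcome": y, "met_b:outcome": b * y})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("collinear design in interaction model")
    res = sm.OLS(a, X).fit()
    return float(res.params["met_b:outcome"]), float(res.pvalues["met_b:outcome"])
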