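"""Trait covariance-network estimation and stability diagnostics.

The network is built on the Spearman correlation matrix of the trait table.
Two estimators are exposed behind one switch:

* ``"correlation"`` — edges are the pairwise Spearman coefficients
  themselves (the correlation-matrix view);
* ``"ebicglasso"`` (default) — regularized partial correlations: graphical
  lasso over a log-spaced penalty grid with the model selected by the
  extended BIC, so each edge is conditioned on all other nodes and spurious
  indirect associations are suppressed.

Diagnostics follow the standard psychometric-network workflow: node
centrality (strength, eigenvector on absolute weights, signed expected
influence), nonparametric row-resampling bootstrap of edge weights whose
95% interval defines the significant (unweighted) edge set, and the
case-dropping subset bootstrap summarized by the correlation-stability
(CS) coefficient — the largest fraction of subjects that can be dropped
while the subset centralities still correlate at least ``r_threshold``
with the full-sample centralities in at least ``certainty`` of resamples.
CS-coefficients below 0.25 flag an unstable metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.covariance import graphical_lasso

from .impute import ImputationSet

__all__ = [
    "CorrelationMatrix",
    "CovarianceNetwork",
    "EdgeStability",
    "CSResult",
    "correlation_matrix",
    "estimate_network",
    "centrality",
    "edge_bootstrap",
    "cs_coefficient",
    "plot_network",
]


@dataclass
class CorrelationMatrix:
    """All-pairs Spearman correlations with p-values and pair counts."""

    nodes: list[str]
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    n_pairs: pd.DataFrame
    n_samples: int


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 4 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return float("nan"), float("nan"), n
    res = stats.spearmanr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue), n


def _pool_fisher_z(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average correlation matrices across imputations on the Fisher-z scale."""
    zs = []
    for t in tables:
        r = t.corr(method="spearman").to_numpy()
        zs.append(np.arctanh(np.clip(r, -0.999999, 0.999999)))
    pooled = np.tanh(np.mean(zs, axis=0))
    np.fill_diagonal(pooled, 1.0)
    return pd.DataFrame(pooled, index=tables[0].columns, columns=tables[0].columns)


def correlation_matrix(
    data: Union[pd.DataFrame, ImputationSet],
    nodes: Optional[Sequence[str]] = None,
    pooling: str = "fisher-z",
) -> CorrelationMatrix:
    """Spearman correlation matrix of a trait table or an imputation set.

    An :class:`ImputationSet` is pooled by Fisher-z averaging of the m
    per-table matrices (``pooling="first"`` uses the first completed table
    only). P-values are unadjusted; pairs involving a constant column are
    set missing with a warning.
    """
    if isinstance(data, ImputationSet):
        tables = list(data.completed_tables)
        if nodes is not None:
            tables = [t[list(nodes)] for t in tables]
        if pooling == "first":
            tables = tables[:1]
        elif pooling != "fisher-z":
            raise ValueError("pooling must be 'fisher-z' or 'first'")
        rho = _pool_fisher_z(tables)
        ref = tables[0]
    else:
        ref = data if nodes is None else data[list(nodes)]
        rho = ref.corr(method="spearman")
    names = list(rho.columns)
    if len(ref) < 4:
        raise ValueError("need at least 4 subjects")
    p = len(names)
    pv = np.full((p, p), np.nan)
    npairs = np.zeros((p, p), dtype=int)
    X = ref.to_numpy(dtype=float)
    for i in range(p):
        pv[i, i] = 0.0
        npairs[i, i] = int(np.sum(~np.isnan(X[:, i])))
        for j in range(i + 1, p):
            r_ij, p_ij, n_ij = _spearman_pair(X[:, i], X[:, j])
            if np.isnan(r_ij):
                warnings.warn(
                    f"correlation undefined for pair ({names[i]}, {names[j]})",
                    stacklevel=2,
                )
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
            pv[i, j] = pv[j, i] = p_ij
            npairs[i, j] = npairs[j, i] = n_ij
    return CorrelationMatrix(
        nodes=names,
        rho=rho,
        pvalues=pd.DataFrame(pv, index=names, columns=names),
        n_pairs=pd.DataFrame(npairs, index=names, columns=names),
        n_samples=len(ref),
    )


def _nearest_psd_corr(S: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and rescale to a unit-diagonal matrix."""
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= -1e-10:
        return S
    warnings.warn(
        f"correlation matrix repaired to nearest PSD "
        f"(smallest eigenvalue {vals.min():.3e})",
        stacklevel=3,
    )
    vals = np.clip(vals, min_eig, None)
    R = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def _partial_from_precision(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def _ebic_glasso_weights(
    S: np.ndarray,
    n: int,
    gamma: float,
    n_lambda: int,
    lambda_min_ratio: float,
) -> tuple[np.ndarray, float]:
    """EBIC-selected graphical-lasso partial correlations from a correlation matrix."""
    p = S.shape[0]
    S = _nearest_psd_corr(S)
    lam_max = float(np.max(np.abs(S - np.eye(p))))
    if lam_max <= 0:
        return np.zeros((p, p)), 0.0
    grid = np.logspace(
        np.log10(lam_max * lambda_min_ratio), np.log10(lam_max), n_lambda
    )
    best = (np.inf, None, None)
    for lam in grid:
        try:
            with warnings.catch_warnings():
                # small penalties routinely stop at max_iter with a tiny
                # residual dual gap; the EBIC comparison is insensitive to it
                warnings.simplefilter("ignore")
                _, theta = graphical_lasso(S, alpha=float(lam), max_iter=200)
        except FloatingPointError:
            continue
        off = theta[np.triu_indices(p, 1)]
        n_edges = int(np.sum(np.abs(off) > 1e-10))
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            continue
        ll = (n / 2.0) * (logdet - np.trace(S @ theta))
        ebic = -2.0 * ll + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)
        if ebic < best[0]:
            best = (ebic, theta, float(lam))
    if best[1] is None:
        raise ValueError("graphical lasso failed on every penalty value")
    return _partial_from_precision(best[1]), best[2]


class CovarianceNetwork(BaseEstimator):
    """Trait covariance-network estimator over a subjects x traits table.

    Parameters
    ----------
    estimator : {"ebicglasso", "correlation"}
        "ebicglasso" gives regularized partial correlations (graphical
        lasso, extended-BIC model selection with hyperparameter ``gamma``);
        "correlation" gives the raw Spearman matrix with a zero diagonal.
    gamma : float
        EBIC sparsity hyperparameter (0 = plain BIC).
    n_lambda, lambda_min_ratio : int, float
        Log-spaced penalty grid for the graphical lasso.

    Fitted attributes: ``nodes_``, ``weights_`` (symmetric, zero-diagonal),
    ``corr_`` (the Spearman matrix used), ``n_samples_`` and, for the
    regularized estimator, ``lambda_`` (the selected penalty).
    """

    def __init__(
        self,
        estimator: str = "ebicglasso",
        gamma: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        pooling: str = "fisher-z",
        lambda_fixed: Optional[float] = None,
    ):
        self.estimator = estimator
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.pooling = pooling
        self.lambda_fixed = lambda_fixed

    def fit(self, X, y=None) -> "CovarianceNetwork":
        if self.estimator not in ("ebicglasso", "correlation"):
            raise ValueError(
                "estimator must be 'ebicglasso' or 'correlation', "
                f"got {self.estimator!r}"
            )
        if isinstance(X, CorrelationMatrix):
            corr = X.rho
            n = X.n_samples
        elif isinstance(X, ImputationSet):
            cm = correlation_matrix(X, pooling=self.pooling)
            corr, n = cm.rho, cm.n_samples
        else:
            X = pd.DataFrame(X)
            corr = X.corr(method="spearman")
            n = len(X)
        nodes = list(corr.columns)
        S = corr.to_numpy(dtype=float)
        if np.isnan(S).any():
            raise ValueError(
                "correlation matrix contains undefined entries; drop or "
                "impute the offending columns first"
            )
        if self.estimator == "correlation":
            W = S.copy()
            np.fill_diagonal(W, 0.0)
            self.lambda_ = None
        elif self.lambda_fixed is not None:
            # penalty chosen elsewhere (e.g. once on the full sample before a
            # bootstrap); skip EBIC model selection
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, theta = graphical_lasso(
                    _nearest_psd_corr(S), alpha=float(self.lambda_fixed),
                    max_iter=200,
                )
            W = _partial_from_precision(theta)
            self.lambda_ = float(self.lambda_fixed)
        else:
            W, self.lambda_ = _ebic_glasso_weights(
                S, n, self.gamma, self.n_lambda, self.lambda_min_ratio
            )
        self.nodes_ = nodes
        self.weights_ = (W + W.T) / 2.0
        self.corr_ = S
        self.n_samples_ = int(n)
        return self

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights_, index=self.nodes_, columns=self.nodes_)


def estimate_network(
    data,
    estimator: str = "ebicglasso",
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> CovarianceNetwork:
    """Fit a :class:`CovarianceNetwork` on a table, correlation matrix or
    imputation set (functional wrapper)."""
    return CovarianceNetwork(
        estimator=estimator, gamma=gamma, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
    ).fit(data)


def centrality(network) -> pd.DataFrame:
    """Node centrality metrics of a fitted network.

    strength: sum of absolute incident edge weights. expected_influence:
    signed sum of incident weights (one-step), separating the role of
    negative edges that strength masks. eigenvector: entry of the principal
    eigenvector of the absolute weight matrix, scaled to a maximum of 1;
    an empty network leaves it undefined and reports zeros with a warning.
    """
    if isinstance(network, CovarianceNetwork):
        W, nodes = network.weights_, network.nodes_
    else:
        W = np.asarray(network, dtype=float)
        nodes = list(range(W.shape[0]))
    absW = np.abs(W)
    strength = absW.sum(axis=1)
    expected_influence = W.sum(axis=1)
    if absW.sum() == 0:
        warnings.warn("eigenvector centrality undefined on an empty network",
                      stacklevel=2)
        eig = np.zeros(len(nodes))
    else:
        vals, vecs = np.linalg.eigh(absW)
        v = np.abs(vecs[:, np.argmax(vals)])
        eig = v / v.max() if v.max() > 0 else v
    return pd.DataFrame(
        {
            "strength": strength,
            "eigenvector": eig,
            "expected_influence": expected_influence,
        },
        index=pd.Index(nodes, name="node"),
    )


@dataclass
class EdgeStability:
    """Row-resampling bootstrap summary of every edge weight."""

    edges: pd.DataFrame  # node_a, node_b, weight, boot_mean, ci_low, ci_high,
    #                      sign_agreement, significant
    mask: pd.DataFrame   # boolean significance matrix (the unweighted view)
    n_boot: int
    seed: Optional[int]
    n_degenerate: int = 0


def edge_bootstrap(
    table: pd.DataFrame,
    estimator: Optional[CovarianceNetwork] = None,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
    selection: str = "refit",
) -> EdgeStability:
    """Nonparametric edge-weight bootstrap (subjects resampled with replacement).

    Each resample re-estimates the full network; per-edge percentile
    intervals at ``ci_level`` define the significance mask (interval
    excluding zero), i.e. the unweighted network. Resamples on which an
    edge is undefined (a constant column) are dropped from that edge's
    interval denominator.

    ``selection="refit"`` reruns EBIC penalty selection inside every
    resample; ``selection="fixed"`` selects the penalty once on the full
    sample and reuses it, trading a little fidelity for a large speedup in
    simulation studies.
    """
    table = pd.DataFrame(table)
    if len(table) < 8:
        raise ValueError("need at least 8 subjects for the edge bootstrap")
    if selection not in ("refit", "fixed"):
        raise ValueError("selection must be 'refit' or 'fixed'")
    est = estimator if estimator is not None else CovarianceNetwork()
    full = clone(est).fit(table)
    if selection == "fixed" and full.lambda_ is not None:
        est = clone(est)
        est.set_params(lambda_fixed=full.lambda_)
    nodes = full.nodes_
    p = len(nodes)
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, p, p), np.nan)
    n_degenerate = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            idx = rng.integers(0, len(table), len(table))
            sample = table.iloc[idx]
            const = [c for c in sample.columns
                     if sample[c].nunique(dropna=True) <= 1]
            try:
                if const:
                    # fit the sub-network on the informative columns; edges
                    # touching a degenerate column stay NaN for this resample
                    n_degenerate += 1
                    keep = [c for c in nodes if c not in const]
                    if len(keep) < 2:
                        continue
                    fit = clone(est).fit(sample[keep])
                    ii = np.asarray([nodes.index(c) for c in keep])
                    boots[b][np.ix_(ii, ii)] = fit.weights_
                else:
                    boots[b] = clone(est).fit(sample).weights_
            except (ValueError, np.linalg.LinAlgError):
                n_degenerate += 1
    alpha = (1 - ci_level) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        boot_mean = np.nanmean(boots, axis=0)
        lo = np.nanquantile(boots, alpha, axis=0)
        hi = np.nanquantile(boots, 1 - alpha, axis=0)
    sign_full = np.sign(full.weights_)
    with np.errstate(invalid="ignore"):
        agree = np.nanmean(np.sign(boots) == sign_full[None], axis=0)
    mask = (lo > 0) | (hi < 0)
    np.fill_diagonal(mask, False)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            rows.append({
                "node_a": nodes[i], "node_b": nodes[j],
                "weight": full.weights_[i, j],
                "boot_mean": boot_mean[i, j],
                "ci_low": lo[i, j], "ci_high": hi[i, j],
                "sign_agreement": agree[i, j],
                "significant": bool(mask[i, j]),
            })
    return EdgeStability(
        edges=pd.DataFrame(rows),
        mask=pd.DataFrame(mask, index=nodes, columns=nodes),
        n_boot=n_boot,
        seed=seed,
        n_degenerate=n_degenerate,
    )


def plot_network(network: CovarianceNetwork, ax=None, threshold: float = 1e-10):
    """Circular-layout diagnostic plot of a fitted network (requires matplotlib).

    Edge width tracks |weight|; solid lines are positive edges, dashed
    negative. Intended as a quick visual check, not publication graphics.
    """
    import matplotlib.pyplot as plt  # optional dependency

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    nodes = network.nodes_
    p = len(nodes)
    angles = 2 * np.pi * np.arange(p) / p
    xy = np.column_stack([np.cos(angles), np.sin(angles)])
    W = network.weights_
    for i in range(p):
        for j in range(i + 1, p):
            w = W[i, j]
            if abs(w) <= threshold:
                continue
            ax.plot(
                xy[[i, j], 0], xy[[i, j], 1],
                lw=4 * abs(w), alpha=0.8,
                ls="-" if w > 0 else "--",
                color="tab:red" if w > 0 else "tab:blue",
                zorder=1,
            )
    ax.scatter(xy[:, 0], xy[:, 1], s=400, c="white", edgecolors="black", zorder=2)
    for (x, y), name in zip(xy, nodes):
        ax.annotate(name, (1.15 * x, 1.15 * y), ha="center", va="center",
                    fontsize=8)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


@dataclass
class CSResult:
    """Case-dropping bootstrap stability of one centrality metric."""

    metric: str
    drop_proportions: np.ndarray
    fractions: np.ndarray  # fraction of resamples with corr >= r_threshold
    cs_coefficient: float
    r_threshold: float
    certainty: float
    reliable: bool = field(init=False)

    def __post_init__(self) -> None:
        self.reliable = self.cs_coefficient >= 0.25


def cs_coefficient(
    table: pd.DataFrame,
    metric: str = "expected_influence",
    estimator: Optional[CovarianceNetwork] = None,
    drop_grid: Optional[Sequence[float]] = None,
    n_boot: int = 1000,
    r_threshold: float = 0.7,
    certainty: float = 0.95,
    seed: Optional[int] = None,
    min_subjects: int = 4,
) -> CSResult:
    """Correlation-stability coefficient of a centrality metric.

    For each drop proportion, subjects are subsampled without replacement,
    the network and metric recomputed, and the node-wise Pearson correlation
    with the full-sample metric recorded. The CS-coefficient is the largest
    drop proportion (scanning upward while the certainty rule keeps holding)
    at which at least ``certainty`` of resamples correlate >= ``r_threshold``.
    Resamples where the metric is undefined (e.g. an empty network) count as
    below threshold.
    """
    table = pd.DataFrame(table)
    if metric not in ("strength", "eigenvector", "expected_influence"):
        raise ValueError(f"unknown centrality metric {metric!r}")
    est = estimator if estimator is not None else CovarianceNetwork()
    full_metric = centrality(clone(est).fit(table))[metric].to_numpy()
    if drop_grid is None:
        drop_grid = np.round(np.arange(0.05, 0.751, 0.05), 2)
    drop_grid = np.sort(np.asarray(drop_grid, dtype=float))
    n = len(table)
    rng = np.random.default_rng(seed)
    fractions = np.zeros(len(drop_grid))
    cs = 0.0
    failed = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gi, drop in enumerate(drop_grid):
            keep = int(round(n * (1 - drop)))
            if keep < min_subjects:
                failed = True
                fractions[gi:] = np.nan
                break
            ok = 0
            for _ in range(n_boot):
                idx = rng.choice(n, size=keep, replace=False)
                try:
                    sub = centrality(clone(est).fit(table.iloc[idx]))[metric]
                except (ValueError, np.linalg.LinAlgError):
                    continue
                sub = sub.to_numpy()
                if np.ptp(sub) == 0 or np.ptp(full_metric) == 0:
                    continue
                r = np.corrcoef(sub, full_metric)[0, 1]
                if np.isfinite(r) and r >= r_threshold:
                    ok += 1
            fractions[gi] = ok / n_boot
            if fractions[gi] >= certainty and not failed:
                cs = float(drop_grid[gi])
            else:
                # stability is assessed on the contiguous run from the
                # smallest drop level; later recoveries are noise
                failed = True
                fractions[gi + 1:] = np.nan
                break
    return CSResult(
        metric=metric,
        drop_proportions=drop_grid,
        fractions=fractions,
        cs_coefficient=cs,
        r_threshold=r_threshold,
        certainty=certainty,
    )
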