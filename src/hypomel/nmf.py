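"""Rank-2 nonnegative matrix factorization with dual cluster ordering.

X ~ W H with W, H >= 0, fit by Lee-Seung multiplicative updates on the
Frobenius objective, best of several random restarts. The two factors
act as prototypical expression patterns: samples and features are each
assigned to the pattern they load most on (a dual clustering), and
within each cluster ordered by descending *leverage* — the normalized
squared loading, which measures how exclusively a row or feature
belongs to its cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray  # samples x k
    H: np.ndarray  # k x features
    error_trace: np.ndarray  # Frobenius error per iteration (best restart)
    k: int
    seed: int
    restarts: int
    n_iter: int
    sample_names: list[str]
    feature_names: list[str]

    @property
    def final_error(self) -> float:
        return float(self.error_trace[-1])


@dataclass
class NMFOrdering:
    """Cluster assignments, leverages and induced orderings."""

    samples: pd.DataFrame  # index sample, cols: cluster, leverage, rank
    features: pd.DataFrame
    sample_order: list[str]
    feature_order: list[str]
    lead_cluster: int  # cluster whose block comes first in the ordering


def _mu_fit(X, k, rng, max_iter, tol):
    m, n = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, size=(m, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n)) * scale
    trace = []
    prev = np.linalg.norm(X - W @ H, "fro")
    trace.append(prev)
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        err = np.linalg.norm(X - W @ H, "fro")
        trace.append(err)
        if prev > 0 and (prev - err) / max(prev, _EPS) < tol:
            break
        prev = err
    return W, H, np.asarray(trace), it


def nmf_factorize(
    X,
    k: int = 2,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFResult:
    """Multiplicative-update NMF, best of ``restarts`` random initializations.

    ``X`` may be a :class:`~hypomel.pairs.SplitMatrix`, a DataFrame or a
    2-D array; entries must be nonnegative and finite. The returned error
    trace (Frobenius norm per iteration of the winning restart) is
    non-increasing by the Lee-Seung monotonicity guarantee.
    """
    sample_names = feature_names = None
    if hasattr(X, "to_array"):  # SplitMatrix
        sample_names = list(X.values.index)
        feature_names = list(X.values.columns)
        X = X.to_array()
    elif isinstance(X, pd.DataFrame):
        sample_names = list(X.index)
        feature_names = list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.isfinite(X).all():
        raise ValueError("X contains missing or non-finite entries")
    if (X < 0).any():
        raise ValueError("X contains negative entries; split it first")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(X.shape)={min(X.shape)}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if sample_names is None:
        sample_names = [f"s{i}" for i in range(X.shape[0])]
        feature_names = [f"f{j}" for j in range(X.shape[1])]

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        W, H, trace, n_iter = _mu_fit(X, k, rng, max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace, n_iter)
    W, H, trace, n_iter = best
    return NMFResult(
        W=W, H=H, error_trace=trace, k=k, seed=seed, restarts=restarts,
        n_iter=n_iter, sample_names=sample_names, feature_names=feature_names,
    )


def _assign(loadings: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Cluster = argmax loading (ties -> first); leverage = normalized sq loading.

    Rows with all-zero loadings get the sentinel cluster 0 with leverage 0.
    """
    sq = loadings**2
    total = sq.sum(axis=1)
    cluster = np.argmax(loadings, axis=1) + 1  # ties resolved to the first cluster
    zero = total == 0
    cluster = np.where(zero, 0, cluster)
    leverage = np.zeros(len(names))
    nz = ~zero
    leverage[nz] = sq[nz, cluster[nz] - 1] / total[nz]
    if zero.any():
        warnings.warn(f"all-zero loadings for: {[names[i] for i in np.flatnonzero(zero)]}")
    return pd.DataFrame({"cluster": cluster, "leverage": leverage},
                        index=pd.Index(names))


def _order_block(tab: pd.DataFrame, lead: int) -> list[str]:
    """Lead-cluster block first, then the other, then unassigned (cluster 0);
    descending leverage within each, label tie-break."""
    order = []
    rest = [c for c in sorted(tab["cluster"].unique(), key=lambda c: (c == 0, c))
            if c != lead]
    for c in ([lead] + rest):
        block = tab[tab["cluster"] == c]
        block = block.sort_values(
            by=["leverage"], ascending=False, kind="stable"
        )
        # deterministic tie-break by label among equal leverages
        block = block.iloc[
            np.lexsort((block.index.to_numpy(), -block["leverage"].to_numpy()))
        ]
        order.extend(block.index)
    return order


def dual_cluster_order(res: NMFResult) -> NMFOrdering:
    """Assign samples (rows of W) and features (columns of H) to clusters
    and order each by cluster block then descending leverage.

    The global sample ordering puts the cluster with the larger total W
    mass first; the same lead cluster heads the feature ordering.
    """
    if res.k != 2:
        raise ValueError("dual clustering is defined for k = 2 factorizations")
    samples = _assign(res.W, res.sample_names)
    features = _assign(res.H.T, res.feature_names)
    mass = res.W.sum(axis=0)
    lead = int(np.argmax(mass)) + 1  # ties -> cluster 1
    sample_order = _order_block(samples, lead)
    feature_order = _order_block(features, lead)
    samples = samples.copy()
    features = features.copy()
    samples["rank"] = samples.groupby("cluster")["leverage"].rank(
        ascending=False, method="first"
    ).astype(int)
    features["rank"] = features.groupby("cluster")["leverage"].rank(
        ascending=False, method="first"
    ).astype(int)
    return NMFOrdering(
        samples=samples, features=features,
        sample_order=sample_order, feature_order=feature_order,
        lead_cluster=lead,
    )


def top_leverage_feature(ordering: NMFOrdering, cluster: int | None = None) -> str:
    """Feature with the largest leverage (optionally within one cluster)."""
    tab = ordering.features
    if cluster is not None:
        tab = tab[tab["cluster"] == cluster]
        if tab.empty:
            raise ValueError(f"no features assigned to cluster {cluster}")
    best = tab["leverage"].to_numpy()
    idx = np.lexsort((tab.index.to_numpy(), -best))[0]
    return str(tab.index[idx])
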