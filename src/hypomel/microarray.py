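"""Two-color microarray normalization.

Processing chain for Cy5 (hypoxia) / Cy3 (normoxia) probe intensities:

    MA transform -> per-array loess on M vs A -> channel-wise quantile
    normalization of log2 single-channel intensities -> inter-array
    quantile normalization of M -> replicated-probe summarization ->
    KNN imputation of missing gene-level values

Each stage consumes and returns an :class:`MAMatrix` (or a gene-level
:class:`pandas.DataFrame` for the last two stages) and records the stage
tag, so intermediate outputs can be inspected or written to disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class TwoColorArraySet:
    """Probe-level two-channel intensities for a set of arrays.

    Attributes
    ----------
    red, green : DataFrame, probes x samples
        Cy5 (test / hypoxia) and Cy3 (reference / normoxia) median signals.
        NaN marks a missing measurement.
    flags : DataFrame of bool, probes x samples
        True where the feature-extraction flags mark a probe unreliable;
        flagged entries are treated as missing downstream.
    probe_gene : Series, probe -> gene
        Multimap carrying replicated probes (several probes per gene).
    """

    red: pd.DataFrame
    green: pd.DataFrame
    flags: pd.DataFrame
    probe_gene: pd.Series

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.flags.shape):
            raise ValueError("red, green and flags must share shape")
        if not self.red.index.equals(self.green.index):
            raise ValueError("red/green probe indexes differ")
        unmapped = self.red.index.difference(self.probe_gene.index)
        if len(unmapped):
            raise ValueError(f"probes without gene mapping: {list(unmapped[:5])}")

    @property
    def n_probes(self) -> int:
        return self.red.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.red.columns)


@dataclass
class MAMatrix:
    """M (log2 R/G) and A (mean log2 intensity) values per probe per sample."""

    M: pd.DataFrame
    A: pd.DataFrame
    stage: str = "raw"
    history: list[str] = field(default_factory=list)

    def with_stage(self, M: pd.DataFrame, A: pd.DataFrame, stage: str) -> "MAMatrix":
        return MAMatrix(M=M, A=A, stage=stage, history=self.history + [self.stage])


def ma_transform(arrays: TwoColorArraySet) -> MAMatrix:
    """Compute M = log2(R/G), A = (log2 R + log2 G) / 2; flagged -> missing.

    Raises ``ValueError`` naming the probe if an unflagged, non-missing
    intensity is zero or negative.
    """
    R = arrays.red.to_numpy(float).copy()
    G = arrays.green.to_numpy(float).copy()
    flag = arrays.flags.to_numpy(bool)
    R[flag] = np.nan
    G[flag] = np.nan
    with np.errstate(invalid="ignore"):
        bad = ((R <= 0) | (G <= 0)) & ~np.isnan(R) & ~np.isnan(G)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive unflagged intensity at probe {arrays.red.index[i]!r}, "
            f"sample {arrays.red.columns[j]!r}"
        )
    # either channel missing -> both M and A missing
    miss = np.isnan(R) | np.isnan(G)
    R[miss] = np.nan
    G[miss] = np.nan
    logR, logG = np.log2(R), np.log2(G)
    M = pd.DataFrame(logR - logG, index=arrays.red.index, columns=arrays.red.columns)
    A = pd.DataFrame((logR + logG) / 2, index=arrays.red.index, columns=arrays.red.columns)
    return MAMatrix(M=M, A=A, stage="raw")


def loess_normalize(ma: MAMatrix, span: float = 0.3) -> MAMatrix:
    """Per-array loess: M' = M - loess_fit(M ~ A); A unchanged.

    Removes intensity-dependent dye bias. Requires at least 10 finite
    (M, A) points per sample; ``span`` is the lowess fraction in (0, 1].
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    Mn = ma.M.copy()
    for col in ma.M.columns:
        m = ma.M[col].to_numpy(float)
        a = ma.A[col].to_numpy(float)
        ok = np.isfinite(m) & np.isfinite(a)
        if ok.sum() < 10:
            raise ValueError(f"sample {col!r}: fewer than 10 finite (M, A) points")
        fit = lowess(m[ok], a[ok], frac=span, it=0, return_sorted=False)
        vals = m.copy()
        vals[ok] = m[ok] - fit
        Mn[col] = vals
    return ma.with_stage(Mn, ma.A.copy(), "loess")


def quantile_normalize(X: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns, preserving missing values in place.

    Each column's sorted finite values are replaced by the across-column
    mean quantile function; for columns with differing numbers of finite
    values the reference is evaluated by linear interpolation. A single
    column is returned unchanged with a warning.
    """
    if X.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returning input unchanged")
        return X.copy()
    vals = X.to_numpy(float)
    n = vals.shape[0]
    grid = np.linspace(0.0, 1.0, n)
    per_col_sorted = []
    for j in range(vals.shape[1]):
        v = np.sort(vals[np.isfinite(vals[:, j]), j])
        if v.size == 0:
            raise ValueError(f"column {X.columns[j]!r} has no finite values")
        pts = np.linspace(0.0, 1.0, v.size) if v.size > 1 else np.array([0.5])
        per_col_sorted.append(np.interp(grid, pts, v))
    ref = np.mean(per_col_sorted, axis=0)

    out = vals.copy()
    for j in range(vals.shape[1]):
        ok = np.isfinite(vals[:, j])
        m = int(ok.sum())
        order = np.argsort(vals[ok, j], kind="stable")
        pts = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
        new_sorted = np.interp(pts, grid, ref)
        col = out[:, j]
        idx = np.flatnonzero(ok)[order]
        col[idx] = new_sorted
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def channel_quantile_normalize(ma: MAMatrix) -> MAMatrix:
    """Quantile-normalize log2 R and log2 G across arrays, then recompute M, A."""
    logR = ma.A + ma.M / 2
    logG = ma.A - ma.M / 2
    logRq = quantile_normalize(logR)
    logGq = quantile_normalize(logG)
    return ma.with_stage(logRq - logGq, (logRq + logGq) / 2, "channel-quantile")


def m_quantile_normalize(ma: MAMatrix) -> MAMatrix:
    """Inter-array quantile normalization applied to the M values."""
    return ma.with_stage(quantile_normalize(ma.M), ma.A.copy(), "inter-array-quantile")


def summarize_probes(ma: MAMatrix, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse replicated probes: per gene per sample, mean of non-missing M.

    A gene whose probes are all missing in a sample yields NaN there
    (left for imputation).
    """
    unmapped = ma.M.index.difference(probe_map.index)
    if len(unmapped):
        raise ValueError(f"unmapped probes: {list(unmapped[:5])}")
    genes = probe_map.reindex(ma.M.index)
    return ma.M.groupby(genes).mean()


def knn_impute(X: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing cells from the k nearest genes (rows).

    Distance between genes is the root-mean-square difference over
    co-observed columns; a missing cell is filled with the plain mean of
    the target column's values among the k nearest genes that observe it.
    Rows with no observed value at all raise ``ValueError``.
    """
    vals = X.to_numpy(float)
    n_rows = vals.shape[0]
    if k >= n_rows:
        raise ValueError(f"k={k} must be < number of genes ({n_rows})")
    obs = np.isfinite(vals)
    empty = ~obs.any(axis=1)
    if empty.any():
        raise ValueError(f"rows fully missing: {list(X.index[empty][:5])}")
    out = vals.copy()
    need = np.flatnonzero(~obs.all(axis=1))
    for i in need:
        # RMS distance to every other gene over co-observed columns
        both = obs[i] & obs
        diff = vals[i] - vals
        with np.errstate(invalid="ignore"):
            sq = np.where(both, diff**2, 0.0)
        counts = both.sum(axis=1)
        dist = np.full(n_rows, np.inf)
        nz = counts > 0
        dist[nz] = np.sqrt(sq[nz].sum(axis=1) / counts[nz])
        dist[i] = np.inf
        order = np.argsort(dist, kind="stable")
        for j in np.flatnonzero(~obs[i]):
            donors = [r for r in order if obs[r, j] and np.isfinite(dist[r])][:k]
            if donors:
                out[i, j] = vals[donors, j].mean()
            else:  # no gene observes this column among comparable rows
                out[i, j] = vals[i, obs[i]].mean()
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def normalize_two_color(
    arrays: TwoColorArraySet, span: float = 0.3, knn_k: int = 10
) -> pd.DataFrame:
    """Full chain from probe intensities to an imputed gene-level M matrix."""
    ma = ma_transform(arrays)
    ma = loess_normalize(ma, span=span)
    ma = channel_quantile_normalize(ma)
    ma = m_quantile_normalize(ma)
    gene_m = summarize_probes(ma, arrays.probe_gene)
    return knn_impute(gene_m, k=knn_k)
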