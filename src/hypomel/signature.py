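"""Moderated-t differential expression and the hypoxia signature gate.

The design is one-sample on M values: each array already encodes the
hypoxia-vs-normoxia contrast as log2(Cy5/Cy3), so the per-gene linear
model reduces to a mean and a residual variance. Variances are shrunk
toward a common prior by the empirical-Bayes method-of-moments fit on
log variances, yielding moderated t statistics; p values pass through
Benjamini-Hochberg, and the signature is the set of genes clearing both
a linear fold-change gate and the FDR gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EBayesHyper:
    """Prior for residual variances: s0^2 with d0 degrees of freedom.

    d0 = 0 means no shrinkage (ordinary t); d0 = inf means full shrinkage
    (every gene's variance replaced by s0^2).
    """

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if self.s02 <= 0:
            raise ValueError("prior variance s0^2 must be > 0")
        if self.d0 < 0:
            raise ValueError("prior df d0 must be >= 0")


@dataclass
class Signature:
    up: list[str]
    down: list[str]
    table: pd.DataFrame
    up_fold: float
    down_fold: float
    fdr_threshold: float

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


def fit_gene_models(M: pd.DataFrame) -> pd.DataFrame:
    """Per-gene one-sample fit: mean M, residual variance s2, df = n - 1.

    Missing entries are ignored per gene; every gene needs >= 2 samples.
    """
    vals = M.to_numpy(float)
    n_obs = np.isfinite(vals).sum(axis=1)
    if (n_obs < 2).any():
        bad = M.index[n_obs < 2]
        raise ValueError(f"genes with fewer than 2 observations: {list(bad[:5])}")
    mean = np.nanmean(vals, axis=1)
    s2 = np.nanvar(vals, axis=1, ddof=1)
    return pd.DataFrame(
        {"mean": mean, "s2": s2, "df": (n_obs - 1).astype(float), "n": n_obs},
        index=M.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_hyperparameters(s2: np.ndarray, df: float) -> EBayesHyper:
    """Method-of-moments fit of (d0, s0^2) on log sample variances.

    Matches the scaled-F model: s2 ~ s0^2 * F(df, d0). Zero variances are
    excluded from estimation; if every variance is zero the fit is
    degenerate and raises.
    """
    s2 = np.asarray(s2, float)
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all gene variances are zero; cannot fit prior")
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    if n < 2:
        return EBayesHyper(d0=math.inf, s02=float(np.exp(emean)))
    evar = float(((e - emean) ** 2).sum() / (n - 1))
    rhs = evar - float(special.polygamma(1, df / 2.0))
    if rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    else:
        d0 = math.inf
        s02 = float(np.exp(emean))
    return EBayesHyper(d0=d0, s02=s02)


def ebayes_moderate(
    stats_df: pd.DataFrame, hyper: EBayesHyper | None = None
) -> pd.DataFrame:
    """Moderate variances and compute moderated t and p per gene.

    s~2 = (d0 s0^2 + d s2) / (d0 + d); t = mean / (s~ / sqrt(n)); p from a
    t distribution with d0 + d degrees of freedom (normal when d0 = inf).
    When ``hyper`` is None the prior is estimated from the data.
    """
    s2 = stats_df["s2"].to_numpy(float)
    df = stats_df["df"].to_numpy(float)
    n = stats_df["n"].to_numpy(float)
    mean = stats_df["mean"].to_numpy(float)
    if hyper is None:
        dfs = np.unique(df)
        if dfs.size != 1:
            raise ValueError("automatic prior estimation requires a balanced design")
        hyper = estimate_hyperparameters(s2, float(dfs[0]))
    if math.isinf(hyper.d0):
        s2_mod = np.full_like(s2, hyper.s02)
        df_total = np.full_like(df, np.inf)
    else:
        s2_mod = (hyper.d0 * hyper.s02 + df * s2) / (hyper.d0 + df)
        df_total = hyper.d0 + df
    if (s2_mod <= 0).any():
        raise ValueError("degenerate: moderated variance is zero (all s2 zero, d0=0?)")
    with np.errstate(divide="ignore"):
        t = mean / np.sqrt(s2_mod / n)
    p = np.where(
        np.isinf(df_total),
        2 * stats.norm.sf(np.abs(t)),
        2 * stats.t.sf(np.abs(t), df_total),
    )
    out = stats_df.copy()
    out["s2_mod"] = s2_mod
    out["t"] = t
    out["p"] = p
    out.attrs["d0"] = hyper.d0
    out.attrs["s02"] = hyper.s02
    return out


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(p, float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def signed_fold(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2^m for m >= 0, -2^-m for m < 0."""
    m = np.asarray(log2fc, float)
    return np.where(m >= 0, 2.0**m, -(2.0 ** (-m)))


def select_signature(
    stats_df: pd.DataFrame,
    up_fold: float = 2.5,
    down_fold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> Signature:
    """Apply the fold-change / FDR gate.

    Up: linear ratio >= ``up_fold`` (inclusive) and FDR < threshold.
    Down: linear ratio <= 1 / ``down_fold`` ("fold change <= -down_fold"
    in signed-fold convention) and FDR < threshold. Both fold thresholds
    are on the linear scale and must exceed 1.
    """
    if up_fold <= 1 or down_fold <= 1:
        raise ValueError("fold thresholds must be > 1 (linear scale)")
    tab = stats_df.copy()
    if "fdr" not in tab.columns:
        tab["fdr"] = bh_fdr(tab["p"].to_numpy())
    ratio = 2.0 ** tab["mean"].to_numpy(float)
    tab["fold"] = signed_fold(tab["mean"].to_numpy(float))
    sig = tab["fdr"].to_numpy(float) < fdr_threshold
    up_mask = (ratio >= up_fold) & sig
    down_mask = (ratio <= 1.0 / down_fold) & sig
    tab["direction"] = np.where(up_mask, "up", np.where(down_mask, "down", "none"))
    tab["passed"] = up_mask | down_mask
    up = list(tab.index[up_mask][np.argsort(-tab["mean"].to_numpy()[up_mask], kind="stable")])
    down = list(tab.index[down_mask][np.argsort(tab["mean"].to_numpy()[down_mask], kind="stable")])
    return Signature(
        up=up, down=down, table=tab,
        up_fold=up_fold, down_fold=down_fold, fdr_threshold=fdr_threshold,
    )


def derive_signature(
    gene_m: pd.DataFrame,
    up_fold: float = 2.5,
    down_fold: float = 2.0,
    fdr_threshold: float = 0.05,
    hyper: EBayesHyper | None = None,
) -> Signature:
    """Fit models, moderate, adjust and gate in one call."""
    stats_df = ebayes_moderate(fit_gene_models(gene_m), hyper=hyper)
    stats_df["fdr"] = bh_fdr(stats_df["p"].to_numpy())
    return select_signature(stats_df, up_fold, down_fold, fdr_threshold)
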