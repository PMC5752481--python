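"""Differential pairs: correlated gene pairs and their split encoding.

Two genes whose expression is highly correlated across samples share
most of their biological and technical variation; the per-sample
difference of their log2 values (the "differential pair") cancels that
shared variation and isolates whatever distinguishes them — e.g. a
treatment-response effect. The signed differential-pair matrix is then
encoded as a nonnegative split matrix [D+ | D-] so that nonnegative
factorization applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenePair:
    gene_a: str
    gene_b: str
    r: float

    @property
    def label(self) -> str:
        return f"{self.gene_a}/{self.gene_b}"


@dataclass
class PairSet:
    pairs: list[GenePair]
    threshold: float

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def labels(self) -> list[str]:
        return [p.label for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.gene_a, p.gene_b, p.r) for p in self.pairs],
            columns=["gene_a", "gene_b", "r"],
        )


@dataclass
class DiffMatrix:
    """Samples x pairs matrix of within-pair log2 differences."""

    values: pd.DataFrame
    pairs: PairSet


@dataclass
class SplitMatrix:
    """Nonnegative encoding [D+ | D-]; provenance maps column -> (pair, sign)."""

    values: pd.DataFrame
    provenance: list[tuple[GenePair, int]]

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(float)


def find_correlated_pairs(expr: pd.DataFrame, threshold: float = 0.80) -> PairSet:
    """All unordered gene pairs with Pearson r strictly above ``threshold``.

    Pairs are stored once in canonical orientation (gene_a lexicographically
    first) and sorted by (gene_a, gene_b). Constant genes are excluded with
    a warning; anti-correlated pairs never qualify (the threshold is signed).
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate genes")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 genes")
    vals = expr.to_numpy(float)
    sd = vals.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"excluding constant genes: {list(expr.columns[constant])}")
    keep = ~constant
    genes = list(expr.columns[keep])
    corr = np.corrcoef(vals[:, keep], rowvar=False)
    found = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if corr[i, j] > threshold:
                a, b = sorted((genes[i], genes[j]))
                found.append(GenePair(a, b, float(corr[i, j])))
    found.sort(key=lambda p: (p.gene_a, p.gene_b))
    return PairSet(pairs=found, threshold=threshold)


def make_diff_matrix(expr: pd.DataFrame, pairs: PairSet) -> DiffMatrix:
    """D[i, p] = log2 expr of gene_a - log2 expr of gene_b, per pair."""
    missing = {g for p in pairs for g in (p.gene_a, p.gene_b)} - set(expr.columns)
    if missing:
        raise KeyError(f"genes absent from expression matrix: {sorted(missing)}")
    cols = {p.label: expr[p.gene_a] - expr[p.gene_b] for p in pairs}
    values = pd.DataFrame(cols, index=expr.index)
    return DiffMatrix(values=values, pairs=pairs)


def split_nonneg(diff: DiffMatrix) -> SplitMatrix:
    """Split signed D into [D+ | D-] with D+ = max(D, 0), D- = max(-D, 0)."""
    vals = diff.values.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("differential matrix contains non-finite values")
    pos = np.maximum(vals, 0.0)
    neg = np.maximum(-vals, 0.0)
    columns = [f"{p.label}+" for p in diff.pairs] + [f"{p.label}-" for p in diff.pairs]
    values = pd.DataFrame(
        np.hstack([pos, neg]), index=diff.values.index, columns=columns
    )
    provenance = [(p, +1) for p in diff.pairs] + [(p, -1) for p in diff.pairs]
    return SplitMatrix(values=values, provenance=provenance)
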