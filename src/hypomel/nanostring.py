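"""Normalization of digital count data (NanoString-style).

Raw counts per sample x gene, with each gene playing one role:
``target``, ``housekeeping``, ``positive`` (spiked positive controls) or
``negative`` (water wells measuring nonspecific background). The chain:

1. positive-control normalization — rescale each lane so the geometric
   mean of its positive controls matches the cohort average;
2. background subtraction — deduct the per-lane mean of the water-well
   counts from target and housekeeping genes, flooring at a small value;
3. content normalization — rescale by the housekeeping geometric mean
   (optional; the codeset carries 6 housekeeping genes for this), then
   log2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import gmean

ROLES = ("target", "housekeeping", "positive", "negative")


@dataclass
class CountMatrix:
    """Samples x genes counts with gene roles and optional outcome labels."""

    counts: pd.DataFrame
    roles: pd.Series
    labels: pd.Series | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        missing = self.counts.columns.difference(self.roles.index)
        if len(missing):
            raise ValueError(f"genes without a role: {list(missing[:5])}")
        bad = set(self.roles.unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if self.stage != "log2" and (self.counts.to_numpy(float) < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.labels is not None:
            extra = self.counts.index.difference(self.labels.index)
            if len(extra):
                raise ValueError(f"samples without labels: {list(extra[:5])}")

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g in self.counts.columns if self.roles[g] == role]

    @property
    def target_genes(self) -> list[str]:
        return self.genes_with_role("target")

    @property
    def housekeeping_genes(self) -> list[str]:
        return self.genes_with_role("housekeeping")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def expression(self, include_housekeeping: bool = True) -> pd.DataFrame:
        """Target (and optionally housekeeping) columns only."""
        cols = self.target_genes + (self.housekeeping_genes if include_housekeeping else [])
        return self.counts[cols]


def positive_control_normalize(cm: CountMatrix) -> CountMatrix:
    """Scale each lane by (cohort mean of positive-control geomeans) / (its own)."""
    pos = cm.genes_with_role("positive")
    if not pos:
        raise ValueError("no positive-control genes")
    pc = cm.counts[pos].to_numpy(float)
    if (pc <= 0).any():
        raise ValueError("zero or negative positive-control count")
    gm = gmean(pc, axis=1)
    scale = gm.mean() / gm
    counts = cm.counts.mul(scale, axis=0)
    return replace(cm, counts=counts, stage="posnorm")


def subtract_background(cm: CountMatrix, floor: float = 1.0) -> CountMatrix:
    """Deduct per-lane mean water-well counts from target/housekeeping genes."""
    neg = cm.genes_with_role("negative")
    if not neg:
        raise ValueError("no negative-control (water) genes")
    if floor <= 0:
        raise ValueError("floor must be positive")
    bg = cm.counts[neg].mean(axis=1)
    counts = cm.counts.copy()
    cols = cm.target_genes + cm.housekeeping_genes
    counts[cols] = np.maximum(counts[cols].sub(bg, axis=0), floor)
    return replace(cm, counts=counts, stage="bgsub")


def content_normalize(cm: CountMatrix, log2: bool = True) -> CountMatrix:
    """Housekeeping content normalization, then (optionally) log2.

    Per-sample factor = cohort mean of housekeeping geometric means over
    the sample's own housekeeping geometric mean; targets and
    housekeeping genes are multiplied by it.
    """
    hk = cm.housekeeping_genes
    if not hk:
        raise ValueError("no housekeeping genes")
    hkc = cm.counts[hk].to_numpy(float)
    if (hkc <= 0).any():
        raise ValueError("non-positive housekeeping count; subtract background with a floor first")
    gm = gmean(hkc, axis=1)
    factor = gm.mean() / gm
    counts = cm.counts.copy()
    cols = cm.target_genes + hk
    counts[cols] = counts[cols].mul(factor, axis=0)
    stage = "contentnorm"
    if log2:
        counts[cols] = np.log2(counts[cols])
        stage = "log2"
    return replace(cm, counts=counts, stage=stage)


def log_transform(cm: CountMatrix, floor: float = 1.0) -> CountMatrix:
    """log2 of target/housekeeping columns with flooring (no content step)."""
    counts = cm.counts.copy()
    cols = cm.target_genes + cm.housekeeping_genes
    counts[cols] = np.log2(np.maximum(counts[cols], floor))
    return replace(cm, counts=counts, stage="log2")


def normalize_counts(
    cm: CountMatrix, floor: float = 1.0, content: bool = True
) -> CountMatrix:
    """Full chain: positive controls -> background -> content (+ log2)."""
    out = subtract_background(positive_control_normalize(cm), floor=floor)
    if content:
        return content_normalize(out, log2=True)
    return log_transform(out, floor=floor)
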