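"""Comparative-Ct (2^-ddCt) relative quantification.

Ct values are threshold cycles: one PCR cycle equals one doubling, so a
gene's expression is proportional to 2^-Ct and differences of Ct are
log2 fold changes. Normalization subtracts the mean Ct of one or more
housekeeping genes per condition (arithmetic mean on the Ct scale, i.e.
geometric mean on the expression scale), then the test-vs-reference
difference of normalized Cts gives the fold change 2^-ddCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("gene", "condition", "replicate", "ct", "is_hk")


@dataclass
class CtTable:
    """Long-format Ct measurements.

    ``data`` columns: gene, condition, replicate, ct, is_hk. Ct values
    must lie in (0, 45) and every condition must carry at least one
    housekeeping gene.
    """

    data: pd.DataFrame
    hk_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        ct = self.data["ct"].to_numpy(float)
        if not ((ct > 0) & (ct < 45)).all():
            raise ValueError("Ct values must lie in (0, 45) cycles")
        if not self.hk_genes:
            self.hk_genes = sorted(self.data.loc[self.data["is_hk"], "gene"].unique())
        for cond, sub in self.data.groupby("condition"):
            if not set(self.hk_genes) & set(sub["gene"]):
                raise ValueError(f"condition {cond!r} has no housekeeping gene")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def mean_ct(self, gene: str, condition: str) -> float:
        sub = self.data[(self.data["gene"] == gene) & (self.data["condition"] == condition)]
        if sub.empty:
            raise KeyError(f"no Ct for gene {gene!r} in condition {condition!r}")
        return float(sub["ct"].mean())


def delta_delta_ct(
    table: CtTable,
    gene: str,
    hk_set: Sequence[str] | None = None,
    test: str = "hypoxia",
    reference: str = "normoxia",
) -> float:
    """Fold change of ``gene`` in ``test`` vs ``reference`` by 2^-ddCt.

    dCt_cond = Ct_gene,cond - mean(Ct_hk,cond); ddCt = dCt_test - dCt_ref.
    Replicates are averaged on the Ct scale first.
    """
    hk = list(hk_set) if hk_set is not None else table.hk_genes
    if not hk:
        raise ValueError("housekeeping set is empty")
    d_ct = {}
    for cond in (test, reference):
        hk_means = [table.mean_ct(h, cond) for h in hk]
        d_ct[cond] = table.mean_ct(gene, cond) - float(np.mean(hk_means))
    ddct = d_ct[test] - d_ct[reference]
    return float(2.0 ** (-ddct))


def quantify_panel(
    table: CtTable,
    hk_set: Sequence[str] | None = None,
    test: str = "hypoxia",
    reference: str = "normoxia",
    divergence_limit: float = 1.0,
) -> pd.DataFrame:
    """Fold changes for every non-housekeeping gene in the table.

    Duplicate wells diverging by more than ``divergence_limit`` cycles
    trigger a warning (never an error). Returns a DataFrame indexed by
    gene with columns ``fold`` and ``log2_fold``.
    """
    hk = list(hk_set) if hk_set is not None else table.hk_genes
    for (gene, cond), sub in table.data.groupby(["gene", "condition"]):
        spread = sub["ct"].max() - sub["ct"].min()
        if len(sub) > 1 and spread > divergence_limit:
            warnings.warn(
                f"divergent replicates for {gene} in {cond}: range {spread:.2f} cycles"
            )
    genes = [g for g in table.genes if g not in hk]
    folds = [delta_delta_ct(table, g, hk, test=test, reference=reference) for g in genes]
    return pd.DataFrame(
        {"fold": folds, "log2_fold": np.log2(folds)}, index=pd.Index(genes, name="gene")
    )
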