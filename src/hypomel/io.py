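"""Readers and writers for the TSV/CSV interchange formats.

All matrices travel as TSV with an explicit orientation sentinel: the
first header cell is ``sample`` when rows are samples and ``gene`` when
rows are genes (the matrix is transposed on read so that in-memory
expression matrices are always samples x genes). Gene roles and sample
labels live in sidecar TSVs. A simplified RCC-like CSV (CodeClass,
Name, Accession, one count column per lane) is accepted for NanoString
realism.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .microarray import TwoColorArraySet
from .nanostring import ROLES, CountMatrix
from .qpcr import CtTable

_RCC_CLASS_TO_ROLE = {
    "endogenous": "target",
    "housekeeping": "housekeeping",
    "positive": "positive",
    "negative": "negative",
}


def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        i = np.argwhere(bad.to_numpy())[0]
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: non-numeric cell {df.iloc[i[0], i[1]]!r} at line {i[0] + 2}, "
            f"column {df.columns[i[1]]!r}"
        )
    return out


def _read_matrix(path) -> pd.DataFrame:
    """Samples x genes matrix; orientation resolved by the header sentinel."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = header[1:]
    dups = {c for c in cols if cols.count(c) > 1}
    if dups:
        raise ValueError(f"{path}: duplicated column {sorted(dups)[0]!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    sentinel = (df.index.name or "").strip().lower()
    if sentinel == "gene":
        df = df.T
        df.index.name = "sample"
    elif sentinel != "sample":
        raise ValueError(
            f"{path}: first header cell must be 'sample' or 'gene', got {df.index.name!r}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene {dup!r}")
    return _check_numeric(df, path)


def read_expression_tsv(path) -> pd.DataFrame:
    return _read_matrix(path)


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_roles(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "role"} <= set(df.columns):
        raise ValueError(f"{path}: roles sidecar needs columns gene, role")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicated gene {dup!r}")
    roles = df.set_index("gene")["role"].str.lower()
    bad = set(roles.unique()) - set(ROLES)
    if bad:
        raise ValueError(f"{path}: unknown roles {sorted(bad)}")
    return roles


def write_roles(roles: pd.Series, path) -> None:
    roles.rename("role").rename_axis("gene").to_frame().to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "status"} <= set(df.columns):
        raise ValueError(f"{path}: labels sidecar needs columns sample, status")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"{path}: duplicated sample {dup!r}")
    return df.set_index("sample")["status"]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("status").rename_axis("sample").to_frame().to_csv(path, sep="\t")


def read_counts(counts_path, roles_path, labels_path=None) -> CountMatrix:
    counts = _read_matrix(counts_path)
    roles = read_roles(roles_path)
    missing = counts.columns.difference(roles.index)
    if len(missing):
        raise ValueError(f"{roles_path}: roles missing for genes {list(missing[:5])}")
    labels = read_labels(labels_path) if labels_path is not None else None
    return CountMatrix(counts=counts, roles=roles.reindex(counts.columns),
                       labels=labels, stage="raw")


def write_counts(cm: CountMatrix, counts_path, roles_path, labels_path=None) -> None:
    write_expression_tsv(cm.counts, counts_path)
    write_roles(cm.roles, roles_path)
    if labels_path is not None and cm.labels is not None:
        write_labels(cm.labels, labels_path)


def read_rcc_csv(path) -> CountMatrix:
    """Simplified RCC-like CSV: CodeClass, Name, Accession, then one
    count column per lane."""
    df = pd.read_csv(path)
    needed = {"CodeClass", "Name", "Accession"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)} plus lanes")
    lanes = [c for c in df.columns if c not in needed]
    if not lanes:
        raise ValueError(f"{path}: no lane columns")
    if df["Name"].duplicated().any():
        dup = df.loc[df["Name"].duplicated(), "Name"].iloc[0]
        raise ValueError(f"{path}: duplicated gene {dup!r}")
    cls = df["CodeClass"].str.lower()
    bad = set(cls.unique()) - set(_RCC_CLASS_TO_ROLE)
    if bad:
        raise ValueError(f"{path}: unknown CodeClass values {sorted(bad)}")
    roles = pd.Series(cls.map(_RCC_CLASS_TO_ROLE).to_numpy(),
                      index=df["Name"].to_numpy(), name="role")
    counts = _check_numeric(df[lanes].set_axis(df["Name"], axis=0), path).T
    counts.index.name = "sample"
    return CountMatrix(counts=counts, roles=roles, stage="raw")


def read_two_color_tsv(path) -> TwoColorArraySet:
    """Long format: sample, probe, gene, red, green, flag."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample", "probe", "gene", "red", "green", "flag"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    dup = df.duplicated(subset=["sample", "probe"])
    if dup.any():
        r = df.loc[dup].iloc[0]
        raise ValueError(f"{path}: duplicated (sample, probe) = ({r['sample']}, {r['probe']})")
    probe_gene = df.drop_duplicates("probe").set_index("probe")["gene"]
    red = df.pivot(index="probe", columns="sample", values="red")
    green = df.pivot(index="probe", columns="sample", values="green")
    flags = df.pivot(index="probe", columns="sample", values="flag").astype(bool)
    return TwoColorArraySet(red=red, green=green, flags=flags,
                            probe_gene=probe_gene.reindex(red.index))


def write_two_color_tsv(arrays: TwoColorArraySet, path) -> None:
    rows = []
    for s in arrays.samples:
        for p in arrays.red.index:
            rows.append((s, p, arrays.probe_gene[p], arrays.red.at[p, s],
                         arrays.green.at[p, s], bool(arrays.flags.at[p, s])))
    pd.DataFrame(rows, columns=["sample", "probe", "gene", "red", "green", "flag"]) \
        .to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "condition", "replicate", "ct", "is_hk"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    df["is_hk"] = df["is_hk"].astype(bool)
    return CtTable(data=df)


def write_ct_table(table: CtTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
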