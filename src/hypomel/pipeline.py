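"""End-to-end driver: counts -> normalization -> pairs -> NMF -> tests.

`run_pipeline` executes the published chain on a labeled count cohort:
normalize (positive controls, background, optional housekeeping
content), find correlated gene pairs, build and split the
differential-pair matrix, factorize at rank 2, order samples and pairs
by leverage, run the permutation rank-sum test on the sample ordering,
and t-test the top-leverage differential pair between responders and
non-responders. Every stage's output is kept in the result bundle and,
when an output directory is given, written to disk together with the
resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as hio
from .nanostring import CountMatrix, normalize_counts
from .nmf import NMFOrdering, NMFResult, dual_cluster_order, nmf_factorize, top_leverage_feature
from .pairs import DiffMatrix, PairSet, SplitMatrix, find_correlated_pairs, make_diff_matrix, split_nonneg
from .permtest import PairTestResult, PermResult, pair_ttest, permutation_test

logger = logging.getLogger("hypomel")


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold of the chain, serializable to/from YAML."""

    seed: int = 0
    # normalization
    background_floor: float = 1.0
    content_normalize: bool = True
    # pair search
    correlation_threshold: float = 0.80
    include_housekeeping: bool = True  # 32-gene universe (26 targets + 6 hk)
    # NMF
    k: int = 2
    restarts: int = 20
    max_iter: int = 2000
    tol: float = 1e-6
    # permutation test
    permutations: int = 100_000
    alternative: str = "two-sided"
    exhaustive_limit: int = 200_000
    # pair t-test
    equal_var: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    normalized: CountMatrix
    pairs: PairSet
    diff: DiffMatrix
    split: SplitMatrix
    nmf: NMFResult
    ordering: NMFOrdering
    perm: PermResult
    top_pair: str
    top_pair_cluster: int
    pair_test: PairTestResult
    summary: dict = field(default_factory=dict)


def _summarize(res: PipelineResult) -> dict:
    return {
        "n_samples": len(res.normalized.samples),
        "n_pairs": len(res.pairs),
        "pairs": res.pairs.labels(),
        "top_pair": res.top_pair,
        "top_pair_cluster": res.top_pair_cluster,
        "nmf_final_error": res.nmf.final_error,
        "sample_order": res.ordering.sample_order,
        "ranksum": res.perm.to_dict(),
        "pair_ttest": {
            "pair": res.top_pair,
            "t": res.pair_test.t,
            "df": res.pair_test.df,
            "p": res.pair_test.p,
            "mean_responder": res.pair_test.mean_responder,
            "mean_nonresponder": res.pair_test.mean_nonresponder,
        },
        "seed": res.config.seed,
    }


def run_pipeline(
    cfg: PipelineConfig, counts: CountMatrix, outdir: str | Path | None = None
) -> PipelineResult:
    """Run the full differential-pair discovery chain on a count cohort."""
    if counts.labels is None:
        raise ValueError("pipeline requires responder labels on the count matrix")
    logger.info("normalizing %d samples x %d genes (seed=%d)",
                len(counts.samples), counts.counts.shape[1], cfg.seed)
    normalized = normalize_counts(
        counts, floor=cfg.background_floor, content=cfg.content_normalize
    )
    expr = normalized.expression(include_housekeeping=cfg.include_housekeeping)

    pairs = find_correlated_pairs(expr, threshold=cfg.correlation_threshold)
    logger.info("found %d correlated pairs at r > %.2f", len(pairs),
                cfg.correlation_threshold)
    if len(pairs) == 0:
        raise RuntimeError("pair-search stage: no pairs above the correlation threshold")
    diff = make_diff_matrix(expr, pairs)
    split = split_nonneg(diff)

    nmf_res = nmf_factorize(
        split, k=cfg.k, seed=cfg.seed, restarts=cfg.restarts,
        max_iter=cfg.max_iter, tol=cfg.tol,
    )
    ordering = dual_cluster_order(nmf_res)

    perm = permutation_test(
        ordering.sample_order, counts.labels, B=cfg.permutations,
        seed=cfg.seed, alternative=cfg.alternative,
        exhaustive_limit=cfg.exhaustive_limit,
    )

    top_feature = top_leverage_feature(ordering)
    top_pair_obj, _sign = next(
        (p, s) for (p, s) in split.provenance
        if f"{p.label}{'+' if s > 0 else '-'}" == top_feature
    )
    top_pair = top_pair_obj.label
    top_cluster = int(ordering.features.loc[top_feature, "cluster"])
    pair_test = pair_ttest(diff.values[top_pair], counts.labels,
                           equal_var=cfg.equal_var)

    res = PipelineResult(
        config=cfg, normalized=normalized, pairs=pairs, diff=diff, split=split,
        nmf=nmf_res, ordering=ordering, perm=perm, top_pair=top_pair,
        top_pair_cluster=top_cluster, pair_test=pair_test,
    )
    res.summary = _summarize(res)

    if outdir is not None:
        out = hio.ensure_dir(outdir)
        cfg.to_yaml(out / "config.yaml")
        hio.write_expression_tsv(normalized.counts, out / "normalized_log2.tsv")
        pairs.to_frame().to_csv(out / "pairs.tsv", sep="\t", index=False)
        hio.write_expression_tsv(diff.values, out / "diff_matrix.tsv")
        hio.write_expression_tsv(split.values, out / "split_matrix.tsv")
        pd.DataFrame(nmf_res.W, index=nmf_res.sample_names,
                     columns=[f"factor{i+1}" for i in range(nmf_res.k)]) \
            .rename_axis("sample").to_csv(out / "nmf_W.tsv", sep="\t")
        pd.DataFrame(nmf_res.H.T, index=nmf_res.feature_names,
                     columns=[f"factor{i+1}" for i in range(nmf_res.k)]) \
            .rename_axis("feature").to_csv(out / "nmf_H.tsv", sep="\t")
        ordering.samples.rename_axis("sample").to_csv(out / "sample_ordering.tsv", sep="\t")
        ordering.features.rename_axis("feature").to_csv(out / "feature_ordering.tsv", sep="\t")
        with open(out / "summary.json", "w") as fh:
            json.dump(res.summary, fh, indent=2, sort_keys=True)
        logger.info("wrote results to %s", out)
    return res
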