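"""Synthetic data generators for every pipeline stage.

Three modalities are emulated, each with the statistical structure its
downstream estimator assumes so that the whole chain is testable as an
inverse problem with no external data:

* a NanoString-style count cohort (default 19 patients: 9 responders,
  10 non-responders; 26 targets + 6 housekeeping genes) with planted
  correlated gene pairs, one of which carries a group difference in its
  within-pair log-ratio, multiplicative per-lane scale factors, spiked
  positive-control ladders and low water-well background;
* a two-color microarray panel (default 10 cell lines) with planted
  up-/down-regulated genes, a smooth intensity-dependent dye bias for
  the loess stage to remove, replicated probes, flags and holes;
* a qPCR Ct table whose true fold changes are recoverable by 2^-ddCt.

Every generator is a pure function of its config: the seed fully
determines the output, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microarray import TwoColorArraySet
from .nanostring import CountMatrix
from .qpcr import CtTable


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic count cohort.

    Defaults mirror the clinical cohort the pipeline targets: 19 FFPE
    samples (9 responders / 10 non-responders to anti-PD1) profiled on a
    32-gene codeset (26 targets, 6 housekeeping). Noise and effect-size
    defaults are implementer-chosen (no cohort estimates exist) and are
    documented in the methods note.
    """

    seed: int = 0
    n_responders: int = 9
    n_nonresponders: int = 10
    n_target_genes: int = 26
    n_housekeeping: int = 6
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    n_correlated_pairs: int = 8
    pair_correlation: float = 0.9
    pair_base_offset_sd: float = 0.25
    planted_pair_effect: float = 2.0
    noise_sd: float = 0.25
    sample_scale_range: tuple[float, float] = (0.7, 1.4)
    background_level: float = 12.0
    base_log2_range: tuple[float, float] = (8.0, 12.0)
    hk_log2_range: tuple[float, float] = (10.0, 13.0)

    def __post_init__(self) -> None:
        if self.n_responders <= 0 or self.n_nonresponders <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 < self.pair_correlation <= 1:
            raise ValueError("pair_correlation must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.planted_pair_effect != 0 and self.noise_sd == 0 and self.pair_correlation == 0:
            raise ValueError("degenerate: planted effect with zero noise and zero correlation")
        if 2 * self.n_correlated_pairs > self.n_target_genes:
            raise ValueError("2 * n_correlated_pairs cannot exceed n_target_genes")
        if self.n_pos_controls < 1 or self.n_neg_controls < 1:
            raise ValueError("need at least one positive and one negative control")
        lo, hi = self.sample_scale_range
        if not 0 < lo <= hi:
            raise ValueError("sample_scale_range must be positive and ordered")

    @property
    def planted_pair(self) -> tuple[str, str]:
        """The differential pair: first two target genes, canonical order."""
        return ("T01", "T02")


@dataclass(frozen=True)
class MicroarraySimConfig:
    """Configuration of the synthetic two-color panel.

    ``up_fold`` is the true linear hypoxia/normoxia ratio of planted
    up-regulated genes (>= 2.5 so they clear the signature gate);
    ``down_fold`` is signed, e.g. -4.0 plants genes at linear ratio 1/4.
    Dye bias is a smooth function of mean log-intensity A so that the
    loess stage can remove it.
    """

    seed: int = 0
    n_lines: int = 10
    n_genes: int = 400
    n_up: int = 26
    n_down: int = 9
    up_fold: float = 4.0
    down_fold: float = -4.0
    intensity_noise_sd: float = 0.1
    dye_bias_amplitude: float = 0.3
    channel_scale_sd: float = 0.2
    replicate_probe_fraction: float = 0.2
    flagged_fraction: float = 0.02
    missing_fraction: float = 0.02
    base_log2_range: tuple[float, float] = (8.0, 14.0)

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down exceeds n_genes")
        if self.up_fold < 2.5:
            raise ValueError("up_fold must be >= 2.5 (the signature gate)")
        if self.down_fold > -2:
            raise ValueError("down_fold must be <= -2 (signed fold)")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")
        for frac in (self.replicate_probe_fraction, self.flagged_fraction,
                     self.missing_fraction):
            if not 0 <= frac < 1:
                raise ValueError("fractions must lie in [0, 1)")


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def _shared_factor_sd(rho: float, noise_sd: float, shift_var: float) -> float:
    """Shared-factor sd giving a pooled Pearson correlation of ``rho``.

    For genes A = f + eA (+ group shift with between-group variance v)
    and B = f + eB, the pooled correlation is
    t / sqrt((t + c + v)(t + c)) with t = Var(f), c = noise variance.
    Solving for t gives the positive root of
    (1 - rho^2) u^2 - (2 c + rho^2 v) u + c^2 = 0 with u = t + c.
    With v = 0 this reduces to t = c * rho / (1 - rho), the plain
    within-group construction.
    """
    c = noise_sd**2
    if noise_sd == 0 or rho >= 1:
        # correlation 1 by construction; keep a nonzero factor for spread
        return max(noise_sd, 0.5)
    a = 1.0 - rho**2
    b = 2.0 * c + rho**2 * shift_var
    u = (b + np.sqrt(b**2 - 4.0 * a * c**2)) / (2.0 * a)
    return float(np.sqrt(u - c))


def simulate_nanostring_cohort(cfg: SimConfig) -> CountMatrix:
    """Generate a labeled count cohort with planted correlated pairs.

    Latent expression is log-normal on the log2 scale. Correlated pairs
    share a per-sample latent factor whose variance is solved so the
    pooled Pearson correlation equals ``pair_correlation`` (for the
    shifted pair the within-group correlation then exceeds it). The
    first pair carries ``planted_pair_effect`` on gene T01 in
    responders, shifting the group mean of log2(T01/T02) by that
    amount. Counts are round(2^latent * lane scale) plus Poisson
    background, floored at 1; water wells draw from the background alone.
    """
    rng = np.random.default_rng(cfg.seed)
    n_r, n_nr = cfg.n_responders, cfg.n_nonresponders
    n = n_r + n_nr
    samples = [f"R{i + 1:02d}" for i in range(n_r)] + [f"N{i + 1:02d}" for i in range(n_nr)]
    responder = np.array([True] * n_r + [False] * n_nr)

    targets = _gene_names("T", cfg.n_target_genes)
    hks = _gene_names("HK", cfg.n_housekeeping)
    poss = _gene_names("POS", cfg.n_pos_controls)
    negs = _gene_names("NEG", cfg.n_neg_controls)

    lo, hi = cfg.base_log2_range
    base = rng.uniform(lo, hi, size=cfg.n_target_genes)
    sd = cfg.noise_sd
    rho = cfg.pair_correlation
    frac_r = n_r / n
    shift_var = frac_r * (1.0 - frac_r) * cfg.planted_pair_effect**2

    log2x = np.empty((n, cfg.n_target_genes))
    in_pair = np.zeros(cfg.n_target_genes, dtype=bool)
    for p in range(cfg.n_correlated_pairs):
        ia, ib = 2 * p, 2 * p + 1
        in_pair[[ia, ib]] = True
        # correlated genes share similar expression levels: the second
        # member sits near the first on the log2 scale
        base[ib] = base[ia] + rng.normal(0.0, cfg.pair_base_offset_sd)
        # pair 0 carries the group shift; its shared-factor variance is
        # solved so the *pooled* correlation still equals rho
        f_sd = _shared_factor_sd(rho, sd, shift_var if p == 0 else 0.0)
        f = rng.normal(0.0, f_sd, size=n)
        log2x[:, ia] = base[ia] + f + rng.normal(0.0, sd, size=n)
        log2x[:, ib] = base[ib] + f + rng.normal(0.0, sd, size=n)
        if p == 0:
            log2x[responder, ia] += cfg.planted_pair_effect
    free = np.flatnonzero(~in_pair)
    log2x[:, free] = base[free] + rng.normal(0.0, sd, size=(n, free.size))

    hk_lo, hk_hi = cfg.hk_log2_range
    hk_base = rng.uniform(hk_lo, hk_hi, size=cfg.n_housekeeping)
    log2_hk = hk_base + rng.normal(0.0, sd / 2.0, size=(n, cfg.n_housekeeping))

    # spiked positive-control ladder, identical input in every lane
    pos_ladder = np.linspace(6.0, 15.0, cfg.n_pos_controls)

    s_lo, s_hi = cfg.sample_scale_range
    scale = np.exp(rng.uniform(np.log(s_lo), np.log(s_hi), size=n))

    def to_counts(log2_mat: np.ndarray) -> np.ndarray:
        lam = cfg.background_level * scale[:, None]
        bg = rng.poisson(lam, size=log2_mat.shape)
        raw = np.round(2.0**log2_mat * scale[:, None] + bg)
        return np.maximum(raw, 1.0)

    counts_t = to_counts(log2x)
    counts_hk = to_counts(log2_hk)
    counts_pos = np.maximum(np.round(2.0**pos_ladder[None, :] * scale[:, None]), 1.0)
    counts_neg = np.maximum(
        rng.poisson(cfg.background_level * scale[:, None],
                    size=(n, cfg.n_neg_controls)).astype(float), 1.0)

    counts = pd.DataFrame(
        np.hstack([counts_t, counts_hk, counts_pos, counts_neg]),
        index=pd.Index(samples, name="sample"),
        columns=targets + hks + poss + negs,
    )
    roles = pd.Series(
        ["target"] * len(targets) + ["housekeeping"] * len(hks)
        + ["positive"] * len(poss) + ["negative"] * len(negs),
        index=counts.columns, name="role",
    )
    labels = pd.Series(np.where(responder, "R", "NR"), index=counts.index, name="status")
    return CountMatrix(counts=counts, roles=roles, labels=labels, stage="raw")


def true_pair_log_ratio_shift(cfg: SimConfig) -> float:
    """Generative group difference in mean log2(T01/T02)."""
    return cfg.planted_pair_effect


def simulate_microarray_panel(cfg: MicroarraySimConfig) -> TwoColorArraySet:
    """Generate probe-level Cy5/Cy3 intensities for the hypoxia panel.

    Gene truth: the first ``n_up`` genes have log2 ratio log2(up_fold),
    the next ``n_down`` have -log2(|down_fold|), the rest 0. The dye
    bias added to each observed M is ``amplitude * sin(2*pi*(A - lo) /
    (hi - lo))``, smooth in A. Per-line channel offsets emulate labeling
    efficiency differences (removed by channel quantile normalization).
    Flags and missing holes are planted in exact counts.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names("G", cfg.n_genes)
    m_true = np.zeros(cfg.n_genes)
    m_true[: cfg.n_up] = np.log2(cfg.up_fold)
    m_true[cfg.n_up: cfg.n_up + cfg.n_down] = -np.log2(abs(cfg.down_fold))

    # replicated probes: first chunk of genes carries two probes
    n_dup = int(np.floor(cfg.replicate_probe_fraction * cfg.n_genes))
    probe_gene: list[str] = list(genes)
    probe_gene += genes[:n_dup]
    probes = [f"P{i + 1:04d}" for i in range(len(probe_gene))]
    probe_map = pd.Series(probe_gene, index=pd.Index(probes, name="probe"), name="gene")
    gene_idx = pd.Index(genes).get_indexer(probe_gene)
    n_probes = len(probes)

    lo, hi = cfg.base_log2_range
    a_gene = rng.uniform(lo, hi, size=cfg.n_genes)
    lines = [f"L{i + 1:02d}" for i in range(cfg.n_lines)]

    red = np.empty((n_probes, cfg.n_lines))
    green = np.empty((n_probes, cfg.n_lines))
    c_red = rng.normal(0.0, cfg.channel_scale_sd, size=cfg.n_lines)
    c_green = rng.normal(0.0, cfg.channel_scale_sd, size=cfg.n_lines)
    for j in range(cfg.n_lines):
        a = a_gene[gene_idx] + rng.normal(0.0, 0.2, size=n_probes)
        bias = cfg.dye_bias_amplitude * np.sin(2.0 * np.pi * (a - lo) / (hi - lo))
        m = m_true[gene_idx] + bias + rng.normal(0.0, cfg.intensity_noise_sd, size=n_probes)
        red[:, j] = 2.0 ** (a + m / 2.0 + c_red[j])
        green[:, j] = 2.0 ** (a - m / 2.0 + c_green[j])
    if (red <= 0).any() or (green <= 0).any():
        raise ValueError("generated non-positive intensity")  # unreachable by construction

    total = n_probes * cfg.n_lines
    n_flag = int(np.floor(cfg.flagged_fraction * total))
    n_miss = int(np.floor(cfg.missing_fraction * total))
    chosen = rng.choice(total, size=n_flag + n_miss, replace=False)
    flags = np.zeros(total, dtype=bool)
    flags[chosen[:n_flag]] = True
    red_flat, green_flat = red.ravel(), green.ravel()
    red_flat[chosen[n_flag:]] = np.nan
    green_flat[chosen[n_flag:]] = np.nan

    idx = pd.Index(probes, name="probe")
    return TwoColorArraySet(
        red=pd.DataFrame(red_flat.reshape(red.shape), index=idx, columns=lines),
        green=pd.DataFrame(green_flat.reshape(green.shape), index=idx, columns=lines),
        flags=pd.DataFrame(flags.reshape(red.shape), index=idx, columns=lines),
        probe_gene=probe_map,
    )


def true_microarray_log2_folds(cfg: MicroarraySimConfig) -> pd.Series:
    """Planted per-gene log2 ratios, indexed like the generated genes."""
    m = np.zeros(cfg.n_genes)
    m[: cfg.n_up] = np.log2(cfg.up_fold)
    m[cfg.n_up: cfg.n_up + cfg.n_down] = -np.log2(abs(cfg.down_fold))
    return pd.Series(m, index=pd.Index(_gene_names("G", cfg.n_genes), name="gene"))


def simulate_ct_table(
    seed: int,
    genes: list[str],
    true_folds: dict[str, float],
    hk_genes: list[str],
    noise_sd: float = 0.0,
    n_replicates: int = 2,
    conditions: tuple[str, str] = ("hypoxia", "normoxia"),
) -> CtTable:
    """Generate a Ct table whose 2^-ddCt estimates recover ``true_folds``.

    Ct = baseline - log2(expression) + noise; the test condition carries
    a global loading offset (same for all genes, removed by housekeeping
    normalization) and each gene's expression is multiplied by its true
    fold there. Housekeeping genes must have true fold 1.
    """
    for g in genes:
        if true_folds.get(g, 1.0) <= 0:
            raise ValueError(f"fold for {g!r} must be > 0")
    for h in hk_genes:
        if h not in genes:
            raise ValueError(f"housekeeping gene {h!r} not in gene list")
        if true_folds.get(h, 1.0) != 1.0:
            raise ValueError(f"housekeeping gene {h!r} must have true fold 1")
    test, reference = conditions
    rng = np.random.default_rng(seed)
    baseline = {g: rng.uniform(22.0, 30.0) for g in genes}
    loading = {test: rng.uniform(-1.0, 1.0), reference: 0.0}
    rows = []
    for g in genes:
        fold = true_folds.get(g, 1.0)
        for cond in conditions:
            log2_expr = np.log2(fold) if cond == test else 0.0
            for rep in range(1, n_replicates + 1):
                ct = baseline[g] + loading[cond] - log2_expr + rng.normal(0.0, noise_sd)
                rows.append((g, cond, rep, float(np.clip(ct, 1e-6, 44.999)), g in hk_genes))
    data = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct", "is_hk"])
    return CtTable(data=data, hk_genes=list(hk_genes))
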