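"""Moderated-t machinery: shrinkage limits, method-of-moments recovery,
BH step-up against a brute-force oracle, and the fold/FDR gate."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypomel.signature import (
    EBayesHyper,
    bh_fdr,
    derive_signature,
    ebayes_moderate,
    estimate_hyperparameters,
    fit_gene_models,
    select_signature,
)
from hypomel.microarray import normalize_two_color
from hypomel.synth import MicroarraySimConfig, simulate_microarray_panel


class TestFitGeneModels:
    def test_constant_gene(self):
        out = fit_gene_models(pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"]))
        assert out.loc["g", "mean"] == 2.0
        assert out.loc["g", "s2"] == 0.0
        assert out.loc["g", "df"] == 2.0

    def test_hand_variance(self):
        out = fit_gene_models(pd.DataFrame([[1.0, 3.0]], index=["g"]))
        assert out.loc["g", "mean"] == 2.0
        assert out.loc["g", "s2"] == 2.0
        assert out.loc["g", "df"] == 1.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.normal(size=(20, 10)))
        out = fit_gene_models(M)
        np.testing.assert_allclose(out["mean"], M.mean(axis=1))
        np.testing.assert_allclose(out["s2"], M.var(axis=1, ddof=1))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_gene_models(pd.DataFrame([[1.0]], index=["g"]))


class TestEBayes:
    @pytest.fixture()
    def stats_df(self):
        rng = np.random.default_rng(1)
        M = pd.DataFrame(rng.normal(0.5, 1.0, size=(50, 8)))
        return fit_gene_models(M)

    def test_d0_zero_is_ordinary_t(self, stats_df):
        out = ebayes_moderate(stats_df, EBayesHyper(d0=0.0, s02=1.0))
        n = stats_df["n"].to_numpy()
        ordinary = stats_df["mean"] / np.sqrt(stats_df["s2"] / n)
        np.testing.assert_allclose(out["t"], ordinary)

    def test_d0_inf_is_full_shrinkage(self, stats_df):
        out = ebayes_moderate(stats_df, EBayesHyper(d0=math.inf, s02=1.0))
        n = stats_df["n"].to_numpy()
        np.testing.assert_allclose(out["t"], stats_df["mean"] * np.sqrt(n))

    def test_variance_ranking_preserved(self, stats_df):
        out = ebayes_moderate(stats_df)
        order_raw = np.argsort(stats_df["s2"].to_numpy())
        order_mod = np.argsort(out["s2_mod"].to_numpy())
        np.testing.assert_array_equal(order_raw, order_mod)

    def test_method_of_moments_recovery(self):
        # s2 ~ s02 * F(d, d0): estimates within 25% of truth at 2000 genes
        rng = np.random.default_rng(7)
        d0, s02, d, n_genes = 4.0, 0.05, 9, 2000
        sigma2 = d0 * s02 / rng.chisquare(d0, n_genes)
        s2 = sigma2 * rng.chisquare(d, n_genes) / d
        h = estimate_hyperparameters(s2, d)
        assert h.d0 == pytest.approx(d0, rel=0.25)
        assert h.s02 == pytest.approx(s02, rel=0.25)

    def test_all_zero_variances_rejected(self):
        stats_df = fit_gene_models(pd.DataFrame([[1.0, 1.0, 1.0]], index=["g"]))
        with pytest.raises(ValueError):
            estimate_hyperparameters(stats_df["s2"].to_numpy(), 2.0)


def _brute_bh(p):
    """Textbook step-up: p_(i) * m / i, cumulative min from the right."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2, 0.2]), [0.2] * 4)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_stepup(self, p):
        np.testing.assert_allclose(bh_fdr(p), _brute_bh(np.asarray(p)), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_relabeling_invariance_and_monotone(self, p):
        p = np.asarray(p)
        adj = bh_fdr(p)
        perm = np.argsort(p, kind="stable")[::-1]
        np.testing.assert_allclose(bh_fdr(p[perm]), adj[perm], atol=1e-12)
        # monotone: adjusted values ordered like the raw p-values
        assert (np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def _stats_frame(log2fc, fdr):
    return pd.DataFrame(
        {"mean": log2fc, "s2": 1.0, "df": 9.0, "n": 10,
         "t": 0.0, "p": fdr, "fdr": fdr},
        index=[f"g{i}" for i in range(len(log2fc))],
    )


class TestSelectSignature:
    def test_boundary_fold_inclusive(self):
        sig = select_signature(_stats_frame([np.log2(2.5)], [0.001]))
        assert sig.up == ["g0"]

    def test_no_pass_empty(self):
        sig = select_signature(_stats_frame([0.1, -0.1], [0.5, 0.5]))
        assert sig.up == [] and sig.down == []

    def test_down_gate_is_reciprocal(self):
        # linear ratio 0.5 == signed fold -2: sits exactly on the gate
        sig = select_signature(_stats_frame([-1.0], [0.001]), down_fold=2.0)
        assert sig.down == ["g0"]

    def test_threshold_monotone(self):
        rng = np.random.default_rng(3)
        frame = _stats_frame(rng.normal(0, 2, 40), rng.uniform(0, 0.2, 40))
        base = select_signature(frame, up_fold=3.0, down_fold=3.0, fdr_threshold=0.05)
        wider = select_signature(frame, up_fold=2.5, down_fold=2.0, fdr_threshold=0.1)
        assert set(base.up) <= set(wider.up) and set(base.down) <= set(wider.down)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            select_signature(_stats_frame([1.0], [0.01]), up_fold=0.9)

    def test_end_to_end_panel_recovery(self):
        # planted 26 up (fold 4) and 9 down (fold 1/4) at noise 0.1:
        # the gate returns exactly the planted split
        cfg = MicroarraySimConfig(seed=3)
        gene_m = normalize_two_color(simulate_microarray_panel(cfg))
        sig = derive_signature(gene_m)
        assert (sig.n_up, sig.n_down) == (26, 9)
        assert set(sig.up) == {f"G{i:02d}" for i in range(1, 27)}
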