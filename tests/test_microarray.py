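"""Two-color normalization stages against hand computations and
brute-force oracles, plus the chain-level recovery invariant."""

import numpy as np
import pandas as pd
import pytest

from hypomel.microarray import (
    MAMatrix,
    TwoColorArraySet,
    knn_impute,
    loess_normalize,
    ma_transform,
    normalize_two_color,
    quantile_normalize,
    summarize_probes,
)
from hypomel.synth import MicroarraySimConfig, simulate_microarray_panel, true_microarray_log2_folds


def _arrays(red, green, flags=None, genes=None):
    red = pd.DataFrame(red, dtype=float)
    red.index = [f"P{i}" for i in range(red.shape[0])]
    red.columns = [f"S{j}" for j in range(red.shape[1])]
    green = pd.DataFrame(np.asarray(green, float), index=red.index, columns=red.columns)
    if flags is None:
        flags = np.zeros(red.shape, bool)
    flags = pd.DataFrame(np.asarray(flags, bool), index=red.index, columns=red.columns)
    if genes is None:
        genes = list(red.index)
    return TwoColorArraySet(red=red, green=green, flags=flags,
                            probe_gene=pd.Series(genes, index=red.index))


class TestMATransform:
    def test_equal_channels_give_zero_m(self):
        ma = ma_transform(_arrays([[100.0]], [[100.0]]))
        assert ma.M.iloc[0, 0] == 0.0
        assert ma.A.iloc[0, 0] == pytest.approx(np.log2(100))

    def test_fourfold_ratio(self):
        ma = ma_transform(_arrays([[400.0]], [[100.0]]))
        assert ma.M.iloc[0, 0] == pytest.approx(2.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        r, g = rng.uniform(10, 1000, (5, 4)), rng.uniform(10, 1000, (5, 4))
        ma = ma_transform(_arrays(r, g))
        np.testing.assert_allclose(ma.M.to_numpy(), np.log2(r) - np.log2(g))
        np.testing.assert_allclose(ma.A.to_numpy(), (np.log2(r) + np.log2(g)) / 2)

    def test_flagged_becomes_missing(self):
        ma = ma_transform(_arrays([[100.0], [200.0]], [[100.0], [100.0]],
                                  flags=[[True], [False]]))
        assert np.isnan(ma.M.iloc[0, 0]) and np.isfinite(ma.M.iloc[1, 0])

    def test_nonpositive_unflagged_names_probe(self):
        with pytest.raises(ValueError, match="P0"):
            ma_transform(_arrays([[0.0]], [[100.0]]))


class TestLoess:
    def test_constant_m_centered(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(8, 14, 200)
        ma = MAMatrix(M=pd.DataFrame({"s": np.full(200, 1.5)}),
                      A=pd.DataFrame({"s": a}))
        out = loess_normalize(ma)
        assert np.abs(out.M["s"]).max() < 1e-6  # M - mean(M) = 0

    def test_smooth_bias_removed(self):
        # noiseless planted bias b(A): residual after loess < 0.05
        rng = np.random.default_rng(2)
        a = rng.uniform(8, 14, 400)
        bias = 0.3 * np.sin(2 * np.pi * (a - 8) / 6)
        ma = MAMatrix(M=pd.DataFrame({"s": 1.0 + bias}), A=pd.DataFrame({"s": a}))
        out = loess_normalize(ma, span=0.3)
        assert np.abs(out.M["s"]).max() < 0.05

    @pytest.mark.parametrize("span", [0.0, 1.5, -0.2])
    def test_bad_span_rejected(self, span):
        ma = MAMatrix(M=pd.DataFrame({"s": np.ones(20)}),
                      A=pd.DataFrame({"s": np.arange(20.0)}))
        with pytest.raises(ValueError):
            loess_normalize(ma, span=span)

    def test_too_few_points(self):
        ma = MAMatrix(M=pd.DataFrame({"s": np.ones(5)}),
                      A=pd.DataFrame({"s": np.arange(5.0)}))
        with pytest.raises(ValueError, match="fewer than 10"):
            loess_normalize(ma)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        X = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(X), X)

    def test_hand_computed_two_columns(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(X)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_complete_columns_share_sorted_values(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(50, 4)))
        out = quantile_normalize(X).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 3)))
        once = quantile_normalize(X)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_missing_preserved_in_place(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(X)
        assert np.isnan(out.iloc[1, 0]) and np.isfinite(out.to_numpy()[~np.isnan(X.to_numpy())]).all()

    def test_single_column_warns_identity(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(X)
        pd.testing.assert_frame_equal(out, X)


class TestSummarizeProbes:
    def test_replicated_probe_mean(self):
        ma = MAMatrix(M=pd.DataFrame({"s": [1.0, 3.0]}, index=["p1", "p2"]),
                      A=pd.DataFrame({"s": [10.0, 10.0]}, index=["p1", "p2"]))
        out = summarize_probes(ma, pd.Series({"p1": "g", "p2": "g"}))
        assert out.loc["g", "s"] == 2.0

    def test_single_probe_passthrough(self):
        ma = MAMatrix(M=pd.DataFrame({"s": [1.5]}, index=["p1"]),
                      A=pd.DataFrame({"s": [10.0]}, index=["p1"]))
        out = summarize_probes(ma, pd.Series({"p1": "g"}))
        assert out.loc["g", "s"] == 1.5

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(5)
        n_probes, genes = 30, [f"g{i}" for i in range(10)]
        pmap = pd.Series(rng.choice(genes, n_probes),
                         index=[f"p{i}" for i in range(n_probes)])
        M = pd.DataFrame(rng.normal(size=(n_probes, 3)), index=pmap.index)
        M.iloc[rng.choice(n_probes, 5, replace=False), 0] = np.nan
        out = summarize_probes(MAMatrix(M=M, A=M * 0), pmap)
        for g in set(pmap):
            for j in range(3):
                vals = M.iloc[:, j][pmap == g].dropna()
                expect = vals.mean() if len(vals) else np.nan
                got = out.loc[g].iloc[j]
                assert (np.isnan(expect) and np.isnan(got)) or got == pytest.approx(expect)

    def test_unmapped_probe_rejected(self):
        ma = MAMatrix(M=pd.DataFrame({"s": [1.0]}, index=["p1"]),
                      A=pd.DataFrame({"s": [1.0]}, index=["p1"]))
        with pytest.raises(ValueError):
            summarize_probes(ma, pd.Series({"other": "g"}))


def _brute_knn(X, k):
    """Independent brute-force KNN imputation with the same convention."""
    vals = X.to_numpy(float)
    out = vals.copy()
    n = vals.shape[0]
    for i in range(n):
        for j in range(vals.shape[1]):
            if np.isfinite(vals[i, j]):
                continue
            dists = []
            for r in range(n):
                if r == i:
                    continue
                both = np.isfinite(vals[i]) & np.isfinite(vals[r])
                if not both.any():
                    continue
                d = np.sqrt(np.mean((vals[i, both] - vals[r, both]) ** 2))
                dists.append((d, r))
            dists.sort(key=lambda t: (t[0], t[1]))
            donors = [r for _, r in dists if np.isfinite(vals[r, j])][:k]
            out[i, j] = np.mean([vals[r, j] for r in donors])
    return out


class TestKNNImpute:
    def test_duplicate_row_fills_exactly(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [9.0, 9.0, 9.0]])
        out = knn_impute(X, k=1)
        assert out.iloc[1, 2] == 3.0

    def test_identity_when_complete(self):
        X = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        pd.testing.assert_frame_equal(knn_impute(X, k=2), X)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(6, 4)))
        X.iloc[0, 1] = np.nan
        X.iloc[3, 2] = np.nan
        X.iloc[5, 0] = np.nan
        np.testing.assert_allclose(knn_impute(X, k=2).to_numpy(), _brute_knn(X, 2))

    def test_fully_missing_row_rejected(self):
        X = pd.DataFrame([[np.nan, np.nan], [1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            knn_impute(X, k=1)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            knn_impute(pd.DataFrame([[1.0], [2.0]]), k=2)


class TestChain:
    def test_recovers_true_folds(self):
        cfg = MicroarraySimConfig(seed=7, intensity_noise_sd=0.1)
        gene_m = normalize_two_color(simulate_microarray_panel(cfg))
        truth = true_microarray_log2_folds(cfg)
        est = gene_m.mean(axis=1).reindex(truth.index)
        assert np.corrcoef(est, truth)[0, 1] > 0.99

    def test_sample_permutation_equivariant(self):
        cfg = MicroarraySimConfig(seed=8, n_genes=60, n_up=3, n_down=2,
                                  missing_fraction=0.0, flagged_fraction=0.0)
        arrays = simulate_microarray_panel(cfg)
        out = normalize_two_color(arrays)
        perm = list(reversed(arrays.samples))
        shuffled = TwoColorArraySet(
            red=arrays.red[perm], green=arrays.green[perm],
            flags=arrays.flags[perm], probe_gene=arrays.probe_gene,
        )
        out_perm = normalize_two_color(shuffled)
        pd.testing.assert_frame_equal(out[perm], out_perm)
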