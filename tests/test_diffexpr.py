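"""NB differential-expression estimators: normalization, dispersion,
Wald testing, filtering and FDR adjustment."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_count_matrix
from top3seq.diffexpr import (
    CountMatrix,
    adaptive_filter,
    bh_adjust,
    call_de,
    estimate_dispersions,
    independent_filter,
    nb_wald_test,
    run_de,
    size_factors,
)


def bh_brute_force(p):
    """Step-up from the definition: adjp_i = min over j with p_j >= p_i of
    m * p_j / rank_j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    ranks = np.empty(m, dtype=int)
    order = np.argsort(p, kind="mergesort")
    ranks[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        out[i] = min(1.0, min(candidates))
    return out


def nb_counts(rng, mu, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestSizeFactors:
    def test_identical_samples_unity(self):
        m = make_count_matrix(np.tile([[10], [20], [30]], 2), ["a", "b"])
        assert np.allclose(size_factors(m), [1.0, 1.0])

    def test_exact_doubling_splits_geometrically(self):
        base = np.array([[10], [20], [50]])
        m = make_count_matrix(np.hstack([base, 2 * base]), ["a", "b"])
        assert np.allclose(size_factors(m), [2 ** -0.5, 2 ** 0.5])

    def test_recovers_planted_library_sizes(self):
        rng = np.random.default_rng(42)
        mu = np.exp(rng.normal(4, 1, 1500))
        lib = np.array([0.5, 1.0, 2.0])
        counts = nb_counts(rng, mu[:, None] * lib[None, :], 0.05, (1500, 3))
        m = make_count_matrix(counts, ["a", "a", "a"])
        sf = size_factors(m).values
        ratio = sf / sf[1]
        assert np.allclose(ratio, lib / lib[1], rtol=0.05)

    def test_geometric_mean_is_one(self, default_expression):
        tx, _, sheet, _ = default_expression
        m = CountMatrix(tx, sheet.set_index("sample_id")["condition"])
        sf = size_factors(m)
        assert abs(np.mean(np.log(sf.values))) < 1e-9

    def test_error_without_common_reference_then_fallback(self):
        counts = np.array([[5, 0], [0, 7]])
        m = make_count_matrix(counts, ["a", "b"])
        with pytest.raises(ValueError, match="pseudo"):
            size_factors(m)
        sf = size_factors(m, pseudo_reference=True)
        assert (sf > 0).all()


class TestDispersions:
    def test_poisson_truth_gives_small_alpha(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(100, 1000, 2000)
        counts = rng.poisson(mu[:, None], (2000, 6))
        m = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        disp = estimate_dispersions(m, size_factors(m))
        assert np.nanmedian(disp.values) <= 0.05

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.normal(5, 1, 2000))
        counts = nb_counts(rng, np.repeat(mu[:, None], 6, axis=1), 0.2, (2000, 6))
        m = make_count_matrix(counts, ["a"] * 6)
        disp = estimate_dispersions(m, size_factors(m))
        assert 0.1 <= np.nanmedian(disp.values) <= 0.4

    def test_all_zero_feature_excluded(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        m = make_count_matrix(counts, ["a", "a", "b", "b"])
        disp = estimate_dispersions(m, size_factors(m))
        assert np.isnan(disp.iloc[0]) and np.isfinite(disp.iloc[1])

    def test_single_replicate_everywhere_warns(self):
        counts = np.array([[10, 12], [30, 20], [7, 9]])
        m = make_count_matrix(counts, ["a", "b"])
        with pytest.warns(UserWarning, match="replicates"):
            disp = estimate_dispersions(m, size_factors(m))
        assert np.isfinite(disp).all()


class TestWald:
    def test_identical_matrices_zero_lfc(self):
        rng = np.random.default_rng(2)
        half = rng.poisson(50, (100, 3))
        m = make_count_matrix(np.hstack([half, half]), ["a"] * 3 + ["b"] * 3)
        res = nb_wald_test(m, ("a", "b"), estimate_dispersions(m, size_factors(m)),
                           sf=size_factors(m))
        assert np.allclose(res["log2fc"], 0.0)

    def test_group_swap_negates_lfc_keeps_p(self, default_expression):
        tx, _, sheet, _ = default_expression
        sub = tx.iloc[:400]
        m = CountMatrix(sub, sheet.set_index("sample_id")["condition"])
        sf = size_factors(m)
        disp = estimate_dispersions(m, sf)
        fwd = nb_wald_test(m, ("wt", "null26"), disp, sf=sf)
        rev = nb_wald_test(m, ("null26", "wt"), disp, sf=sf)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], equal_nan=True)
        assert np.allclose(fwd["p"], rev["p"], equal_nan=True)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(3)
        mu = np.exp(rng.normal(5, 1, 2000))
        counts = nb_counts(rng, np.repeat(mu[:, None], 6, axis=1), 0.05, (2000, 6))
        m = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        res = nb_wald_test(m, ("a", "b"), estimate_dispersions(m, size_factors(m)),
                           sf=size_factors(m))
        frac = np.nanmean(res["p"] < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_power_for_fourfold_change_at_mean_200(self):
        rng = np.random.default_rng(4)
        n_eff, n_null = 500, 1500
        mu_c = np.concatenate([np.full(n_eff, 200.0), np.exp(rng.normal(5, 1, n_null))])
        mu_t = mu_c.copy()
        mu_t[:n_eff] = mu_c[:n_eff] / 4.0  # planted log2fc = -2
        c = nb_counts(rng, np.repeat(mu_c[:, None], 3, axis=1), 0.05, (2000, 3))
        t = nb_counts(rng, np.repeat(mu_t[:, None], 3, axis=1), 0.05, (2000, 3))
        m = make_count_matrix(np.hstack([c, t]), ["ctl"] * 3 + ["trt"] * 3)
        res = run_de(m, ("ctl", "trt"))
        detected = (res["adjp"].values[:n_eff] < 0.05)
        assert detected.mean() >= 0.8

    def test_lfc_shrinkage_pulls_toward_zero(self):
        rng = np.random.default_rng(5)
        mu = np.exp(rng.normal(4, 1, 500))
        counts = nb_counts(rng, np.repeat(mu[:, None], 6, axis=1), 0.1, (500, 6))
        m = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        sf = size_factors(m)
        disp = estimate_dispersions(m, sf)
        plain = nb_wald_test(m, ("a", "b"), disp, sf=sf)
        shrunk = nb_wald_test(m, ("a", "b"), disp, sf=sf, shrink_lfc=True)
        assert shrunk.attrs["lfc_shrunk"]
        assert (shrunk["log2fc"].abs() <= plain["log2fc"].abs() + 1e-12).all()


class TestBH:
    def test_single_p(self):
        assert np.allclose(bh_adjust([0.04]), [0.04])

    def test_hand_computed_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equals_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_brute_force(p))

    def test_nan_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.04])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], bh_adjust(np.array([0.01, 0.04])))

    def test_readjustment_never_decreases(self):
        rng = np.random.default_rng(7)
        p = rng.random(100)
        once = bh_adjust(p)
        assert (bh_adjust(once) >= once - 1e-12).all()

    def test_idempotent_on_constant_vectors(self):
        const = np.full(50, 0.3)
        assert np.allclose(bh_adjust(const), const)

    def test_adjp_at_least_p(self, default_de):
        res, _ = default_de
        ok = res["adjp"].notna()
        assert (res.loc[ok, "adjp"] >= res.loc[ok, "p"] - 1e-12).all()


class TestFilterAndCalls:
    def test_quantile_zero_filters_nothing(self, default_de):
        res, _ = default_de
        out = independent_filter(res, 0.0)
        assert out["adjp"].notna().sum() == res["p"].notna().sum()

    def test_quantile_counts(self):
        res = pd.DataFrame({
            "base_mean": np.arange(100, dtype=float),
            "p": np.full(100, 0.5),
            "log2fc": np.zeros(100),
        }, index=[f"f{i}" for i in range(100)])
        out = independent_filter(res, 0.25)
        assert out["adjp"].notna().sum() == 75

    def test_filtering_never_loses_high_mean_true_positives(self, default_de):
        res, truth = default_de
        true_ids = truth.loc[
            (truth["true_lfc_null26"] != 0) & (truth["baseline_mean"] >= 100),
            "transcript_id",
        ]
        unfiltered = call_de(independent_filter(res, 0.0))
        filtered = call_de(independent_filter(res, 0.25))
        n_unf = unfiltered.loc[true_ids, "call"].isin(["up", "down"]).sum()
        n_fil = filtered.loc[true_ids, "call"].isin(["up", "down"]).sum()
        assert n_fil >= n_unf

    def test_adaptive_filter_maximizes_discoveries(self, default_de):
        res, _ = default_de
        auto = adaptive_filter(res)
        n_auto = (auto["adjp"] < 0.05).sum()
        for q in (0.0, 0.25, 0.5):
            assert n_auto >= (independent_filter(res, q)["adjp"] < 0.05).sum()

    def test_call_examples(self):
        res = pd.DataFrame({
            "base_mean": [100.0, 100.0],
            "log2fc": [-2.0, 0.5],
            "se": [0.1, 0.1],
            "p": [0.001, 0.02],
            "adjp": [0.01, 0.04],
        }, index=["a", "b"])
        out = call_de(res)
        assert out.loc["a", "call"] == "down"
        assert out.loc["b", "call"] == "ns"

    def test_strict_vs_inclusive_boundary(self):
        res = pd.DataFrame({
            "base_mean": [10.0], "log2fc": [1.0], "se": [0.1],
            "p": [0.001], "adjp": [0.01],
        }, index=["a"])
        assert call_de(res, comparator="inclusive").loc["a", "call"] == "up"
        assert call_de(res, comparator="strict").loc["a", "call"] == "ns"

    def test_down_calls_shrink_as_alpha_tightens(self, default_de):
        res, _ = default_de
        counts = [
            (call_de(res, alpha=a)["call"] == "down").sum()
            for a in (0.05, 0.005, 0.0002)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestCrossCheck:
    def test_log2fc_agrees_with_reference_nb_implementation(self):
        """Independent cross-check of the closed-form two-group estimator
        against an established NB GLM implementation on a small sim."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        from top3seq.simulate import SimConfig, gen_annotation, gen_expression

        cfg = SimConfig(seed=2, n_genes=150)
        _, truth = gen_annotation(cfg)
        tx, _, sheet, _ = gen_expression(cfg, truth)
        keep = [s for s in tx.columns if s.startswith(("wt", "null26"))]
        cond = sheet.set_index("sample_id")["condition"].loc[keep]
        res = run_de(CountMatrix(tx[keep], cond), ("wt", "null26"))

        dds = DeseqDataSet(
            counts=tx[keep].T, metadata=pd.DataFrame({"condition": cond}),
            design="~condition", quiet=True,
        )
        dds.deseq2()
        st = DeseqStats(dds, contrast=["condition", "null26", "wt"], quiet=True)
        st.summary()
        both = res.join(st.results_df[["log2FoldChange"]], how="inner")
        ok = both["base_mean"] > 50
        r = np.corrcoef(both.loc[ok, "log2fc"], both.loc[ok, "log2FoldChange"])[0, 1]
        assert r > 0.98
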