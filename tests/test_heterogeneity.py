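"""Population statistics: moments, Fano, fingerprints, coupling, DE."""

import numpy as np
import pandas as pd
import pytest

from osmohet import PipelineConfig, preprocess
from osmohet.heterogeneity import (cluster_vs_population_test,
                                   coupling_correlation, de_wilcoxon,
                                   expression_fingerprint, fano_factor,
                                   gene_fano, group_stats, usage_vs_strength)
from osmohet.signatures import GeneSignature
from conftest import make_dataset


def score_frame(values, groups):
    return pd.DataFrame({"score": values, "group": groups})


class TestGroupStats:
    def test_closed_form_moments(self):
        out = group_stats(score_frame([1, 2, 3], ["a"] * 3), "group")
        row = out.iloc[0]
        assert row["mean"] == 2.0
        assert row["variance"] == 1.0
        assert row["fano"] == 0.5
        assert row["median"] == 2.0

    def test_constant_vector_has_zero_fano(self):
        out = group_stats(score_frame([2.0] * 5, ["a"] * 5), "group")
        assert out.iloc[0]["variance"] == 0.0
        assert out.iloc[0]["fano"] == 0.0

    def test_singleton_group_flagged_undefined(self):
        out = group_stats(score_frame([1.0], ["a"]), "group")
        assert np.isnan(out.iloc[0]["sd"])

    def test_poisson_fano_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5.0, size=5000)
        assert abs(fano_factor(x) - 1.0) < 0.08

    def test_zero_mean_fano_is_nan(self):
        assert np.isnan(fano_factor(np.zeros(10)))
        counts = np.zeros((5, 2))
        counts[:, 1] = [1, 2, 3, 4, 5]
        fano = gene_fano(counts)
        assert np.isnan(fano[0]) and np.isfinite(fano[1])


class TestFingerprint:
    def test_detected_counts_and_top_gene(self, cfg):
        counts = np.array([[5, 0, 2], [0, 0, 0], [3, 3, 0]])
        ds = preprocess(make_dataset(counts), cfg)
        sig = GeneSignature("s", ["g0", "g1", "g2"], "induced")
        fp, summary = expression_fingerprint(ds, sig)
        assert list(summary["n_detected"]) == [2, 0, 2]
        assert summary["top_gene"].iloc[0] == "g0"
        assert summary["top_gene"].iloc[1] is None
        # tie at max -> lexicographically first gene id
        assert summary["top_gene"].iloc[2] == "g0"
        assert fp.to_numpy().tolist() == [[1, 0, 1], [0, 0, 0], [1, 1, 0]]


class TestUsageVsStrength:
    def test_monotone_construction_gives_rho_one(self, cfg):
        counts = np.zeros((5, 10), dtype=int)
        for i in range(5):
            counts[i, :i + 1] = 5
        ds = preprocess(make_dataset(counts), cfg)
        sig = GeneSignature("s", [f"g{j}" for j in range(8)], "induced")
        _, rho = usage_vs_strength(ds, sig)
        assert rho == pytest.approx(1.0)

    def test_degenerate_cases_flagged(self, cfg):
        ds = preprocess(make_dataset(np.ones((5, 6), dtype=int)), cfg)
        sig = GeneSignature("s", ["g0", "g1"], "induced")
        _, rho = usage_vs_strength(ds, sig)
        assert np.isnan(rho)
        ds2 = preprocess(make_dataset(np.ones((2, 6), dtype=int)), cfg)
        _, rho2 = usage_vs_strength(ds2, sig)
        assert np.isnan(rho2)


class TestCouplingCorrelation:
    def _tables(self, x, y, cond="NaCl"):
        idx = pd.Index([f"c{i}" for i in range(len(x))], name="cell_id")
        ind = pd.DataFrame({"score": x, "condition": cond}, index=idx)
        rep = pd.DataFrame({"score": y, "condition": cond}, index=idx)
        return ind, rep

    def test_perfect_anticorrelation(self):
        x = np.linspace(0, 1, 20)
        out = coupling_correlation(*self._tables(x, -x))
        assert out.iloc[0]["pearson_r"] == pytest.approx(-1.0)
        assert out.iloc[0]["slope"] == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(1)
        out = coupling_correlation(
            *self._tables(rng.standard_normal(2000),
                          rng.standard_normal(2000)))
        assert abs(out.iloc[0]["pearson_r"]) < 0.05

    def test_tiny_group_undefined(self):
        out = coupling_correlation(*self._tables([1, 2], [2, 1]))
        assert np.isnan(out.iloc[0]["pearson_r"])


class TestDEWilcoxon:
    def _dataset(self, counts):
        cfg = PipelineConfig()
        return preprocess(make_dataset(counts), cfg), cfg

    def test_identical_groups_empty_up_set(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(3.0, size=(40, 30))
        counts[20:] = counts[:20]
        ds, cfg = self._dataset(counts)
        mask = np.arange(40) < 20
        de = de_wilcoxon(ds, mask, ~mask, cfg)
        assert not de["up"].any() and not de["down"].any()

    def test_bh_qvalues_monotone_in_p_rank(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3.0, size=(30, 40))
        counts[:15, :5] *= 3
        ds, cfg = self._dataset(counts)
        mask = np.arange(30) < 15
        de = de_wilcoxon(ds, mask, ~mask, cfg).sort_values("pval")
        assert (np.diff(de["qval"].to_numpy()) >= -1e-12).all()

    def test_empty_group_errors(self):
        ds, cfg = self._dataset(np.ones((4, 3), dtype=int))
        with pytest.raises(ValueError):
            de_wilcoxon(ds, np.zeros(4, bool), np.ones(4, bool), cfg)


class TestClusterVsPopulation:
    def test_shifted_cluster_maximally_significant(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal(1000)
        values[:50] += 3.0
        labels = np.where(np.arange(1000) < 50, "shifted", "rest")
        out = cluster_vs_population_test(
            pd.DataFrame({"score": values}), labels).set_index("cluster")
        assert out.loc["shifted", "qval"] < 0.0001
        assert out.loc["shifted", "stars"] == "****"

    def test_null_cluster_usually_not_significant(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(200):
            values = rng.standard_normal(300)
            labels = np.where(np.arange(300) < 40, "a", "b")
            out = cluster_vs_population_test(
                pd.DataFrame({"score": values}), labels)
            p = out.set_index("cluster").loc["a", "pval"]
            rejections += p < 0.05
        assert rejections / 200 <= 0.075

    def test_single_cluster_boundary(self):
        out = cluster_vs_population_test(
            pd.DataFrame({"score": [1.0, 2.0, 3.0]}), ["only"] * 3)
        # a cluster equal to the population: rank-sum is its own reference
        assert out.iloc[0]["pval"] > 0.9
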