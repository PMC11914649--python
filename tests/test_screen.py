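"""Subpopulation thresholds, Gini mean difference and the genotype screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmohet import PipelineConfig, preprocess
from osmohet.screen import (basal_threshold, classify_basal_stressed,
                            classify_hyper_responsive, coexpression_score,
                            gini_mean_difference, screen_genotypes,
                            SENTINEL_GENES)
from conftest import make_dataset


def gmd_brute(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    total = sum(abs(x[i] - x[j]) for i in range(n) for j in range(i + 1, n))
    return 2.0 * total / (n * (n - 1))


class TestGMD:
    @pytest.mark.parametrize("x, expected", [
        ([0.0, 1.0], 1.0),
        ([3.0, 3.0, 3.0], 0.0),
        ([0.0, 1.0, 2.0], 4.0 / 3.0),
    ])
    def test_known_values(self, x, expected):
        assert gini_mean_difference(x) == pytest.approx(expected)

    def test_undefined_below_two_points(self):
        assert np.isnan(gini_mean_difference([1.0]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_sorted_formula_equals_brute_force(self, x):
        fast = gini_mean_difference(x)
        brute = gmd_brute(x)
        assert fast == pytest.approx(brute, rel=1e-12, abs=1e-9)


class TestBasalThreshold:
    def test_interpolated_last_decile(self, cfg):
        scores = np.arange(1, 101) / 100.0
        thr = basal_threshold(scores, cfg)
        assert thr == pytest.approx(0.9010, abs=1e-4)
        # by construction ~10% of cells sit strictly above
        assert np.isclose((scores > thr).mean(), 0.10, atol=0.01)

    def test_constant_scores_degenerate(self, cfg):
        thr = basal_threshold(np.full(50, 0.3), cfg)
        assert thr == 0.3
        assert not classify_basal_stressed(np.full(50, 0.3), thr).any()

    def test_boundary_is_strict(self):
        assert not classify_basal_stressed([0.5], 0.5)[0]
        assert classify_basal_stressed([0.500001], 0.5)[0]

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(0)
        scores = rng.random(500)
        thrs = [basal_threshold(scores, PipelineConfig(basal_quantile=q))
                for q in (0.5, 0.7, 0.9, 0.95)]
        assert thrs == sorted(thrs)


class TestHyperResponsive:
    def test_threshold_is_mean_plus_gmd(self):
        x = np.array([0.1, 0.2, 0.3, 0.9])
        flags, thr = classify_hyper_responsive(x)
        assert thr == pytest.approx(x.mean() + gini_mean_difference(x))
        assert list(flags) == [False, False, False, True]

    def test_constant_scores_flag_nobody(self):
        flags, thr = classify_hyper_responsive(np.full(20, 0.4))
        assert not flags.any()
        assert thr == pytest.approx(0.4)

    def test_boundary_is_strict(self):
        x = np.array([0.0, 1.0])
        flags, thr = classify_hyper_responsive(x)
        assert thr == pytest.approx(1.5)  # mean 0.5 + gmd 1.0
        assert not flags.any()


class TestCoexpression:
    def _sentinel_ds(self, rows):
        """Pad each cell with a filler gene so library sizes are equal and
        the log-normalization preserves the constructed ordering."""
        cfg = PipelineConfig()
        rows = np.asarray(rows)
        genes = list(SENTINEL_GENES) + ["BG1"]
        target = rows.sum(axis=1).max() + 10
        filler = (target - rows.sum(axis=1))[:, None]
        counts = np.hstack([rows, filler])
        return preprocess(make_dataset(counts, gene_ids=genes), cfg)

    def test_extremes_with_single_neighbor(self):
        rows = np.array([
            [9, 9, 9, 9, 9, 9],
            [9, 9, 9, 9, 9, 0],   # one sentinel at population minimum
            [4, 4, 4, 4, 4, 4],   # intermediate on every sentinel
            [2, 2, 2, 2, 2, 2],   # carries the per-gene minimum elsewhere
        ])
        ds = self._sentinel_ds(rows)
        co = coexpression_score(ds, neighbor_k=1)
        assert co.iloc[0] == pytest.approx(1.0)
        assert co.iloc[1] == 0.0
        assert 0.0 < co.iloc[2] < 1.0

    def test_missing_sentinel_errors(self, cfg):
        ds = preprocess(make_dataset(np.ones((3, 3), dtype=int)), cfg)
        with pytest.raises(ValueError, match="STL1"):
            coexpression_score(ds)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        rows = rng.poisson(3.0, size=(40, 6))
        ds = self._sentinel_ds(rows)
        a = coexpression_score(ds)
        b = coexpression_score(self._sentinel_ds(rows))
        pd.testing.assert_series_equal(a, b)


class TestScreen:
    def _scores(self, spec):
        """spec: list of (genotype, condition, scores list)."""
        rows = []
        for geno, cond, vals in spec:
            for v in vals:
                rows.append({"score": v, "genotype": geno, "condition": cond})
        df = pd.DataFrame(rows)
        df.index = pd.Index([f"c{i}" for i in range(len(df))], name="cell_id")
        return df

    def _base_spec(self):
        rng = np.random.default_rng(0)
        wt = list(rng.normal(0.2, 0.05, size=100))
        return [("WT-1", "control", wt), ("WT-2", "control", wt),
                ("WT-1", "NaCl", wt), ("WT-2", "NaCl", wt)]

    def test_fraction_above_threshold_flags(self, cfg):
        spec = self._base_spec()
        # 4 of 10 cells clearly above the WT last decile
        spec.append(("mutA", "control", [0.9] * 4 + [0.1] * 6))
        tab = screen_genotypes(self._scores(spec), cfg, wt_label="WT")
        row = tab[(tab["genotype"] == "mutA")
                  & (tab["condition"] == "control")].iloc[0]
        assert row["pct_above_basal_threshold"] == pytest.approx(40.0)
        assert row["flag_basal"]

    def test_low_cell_count_excluded_without_flags(self, cfg):
        spec = self._base_spec()
        spec.append(("mutB", "control", [0.9] * 5))
        tab = screen_genotypes(self._scores(spec), cfg, wt_label="WT")
        row = tab[(tab["genotype"] == "mutB")
                  & (tab["condition"] == "control")].iloc[0]
        assert row["excluded_low_n"]
        assert not row["flag_basal"] and not row["flag_variable"]
        # values still reported
        assert row["pct_above_basal_threshold"] == pytest.approx(100.0)

    def test_flags_invariant_to_ordering_and_unrelated_genotypes(self, cfg):
        rng = np.random.default_rng(1)
        spec = self._base_spec()
        spec.append(("mutC", "NaCl", list(rng.normal(0.2, 0.25, size=50))))
        spec.append(("mutD", "NaCl", list(rng.normal(0.2, 0.05, size=50))))
        full = screen_genotypes(self._scores(spec), cfg, wt_label="WT")
        flag_c = full.set_index(["genotype", "condition"]).loc[
            ("mutC", "NaCl"), "flag_variable"]
        assert flag_c
        reduced = screen_genotypes(
            self._scores(list(reversed(spec[:-1]))), cfg, wt_label="WT")
        flag_c2 = reduced.set_index(["genotype", "condition"]).loc[
            ("mutC", "NaCl"), "flag_variable"]
        assert flag_c2 == flag_c

    def test_missing_wild_type_errors(self, cfg):
        df = self._scores([("mutA", "NaCl", [0.1] * 10)])
        with pytest.raises(ValueError):
            screen_genotypes(df, cfg, wt_label="WT")
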