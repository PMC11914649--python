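"""Consensus signature construction and the rank-based per-cell score."""

import numpy as np
import pandas as pd
import pytest

from osmohet import PipelineConfig, preprocess
from osmohet.data import FormatError
from osmohet.signatures import (GeneSignature, build_consensus_signatures,
                                percent_expressing, score_signature)
from conftest import make_dataset


def brute_force_scores(expr, gene_ids, sig_genes, rank_cap):
    """Independent reference for the rank-based signature score.

    Naive per-cell ranking: for each gene, rank = (number of strictly
    larger values) + (1 + number of ties including itself) / 2, computed
    by explicit comparison; capped ranks; U statistic from the summed
    capped ranks.
    """
    scores = []
    sig_idx = [i for i, g in enumerate(gene_ids) if g in set(sig_genes)]
    n = len(sig_idx)
    for row in expr:
        total = 0.0
        for i in sig_idx:
            larger = sum(1 for v in row if v > row[i])
            ties = sum(1 for v in row if v == row[i])
            rank = larger + (1 + ties) / 2.0
            total += min(rank, rank_cap + 1)
        u = total - n * (n + 1) / 2.0
        scores.append(min(max(1.0 - u / (n * rank_cap), 0.0), 1.0))
    return np.array(scores)


def scored_dataset(counts, gene_ids=None):
    cfg = PipelineConfig()
    ds = preprocess(make_dataset(counts, gene_ids=gene_ids), cfg)
    return ds, cfg


class TestScoreSignature:
    def test_perfect_and_null_cells(self):
        # cell 0 expresses the whole signature at the top ranks -> score 1
        counts = np.zeros((2, 10), dtype=int)
        counts[0, :3] = [9, 8, 7]
        counts[0, 3:] = 1
        counts[1, 3:] = 1
        ds, cfg = scored_dataset(counts)
        cfg.rank_cap = 5
        sig = GeneSignature("s", ["g0", "g1", "g2"], "induced")
        scores = score_signature(ds, sig, cfg)["score"]
        assert scores.iloc[0] == 1.0
        # cell 1: signature genes all zero, tie rank (4+10+1)/2 = 7.5 > cap
        expected = brute_force_scores(
            np.asarray(ds.layers["lognorm"].todense()), ds.gene_ids,
            sig.genes, cfg.rank_cap)
        np.testing.assert_allclose(scores.to_numpy(), expected)

    def test_single_gene_beyond_cap_scores_zero(self):
        counts = np.ones((1, 30), dtype=int)
        counts[0, 0] = 0  # signature gene at the bottom tie
        ds, cfg = scored_dataset(counts)
        cfg.rank_cap = 10
        sig = GeneSignature("s", ["g0"], "induced")
        assert score_signature(ds, sig, cfg)["score"].iloc[0] == 0.0

    def test_matches_brute_force_on_random_matrices(self, cfg):
        rng = np.random.default_rng(10)
        for _ in range(20):
            counts = rng.poisson(1.5, size=(8, 25))
            ds = preprocess(make_dataset(counts), cfg)
            sig_genes = list(rng.choice(ds.gene_ids, size=5, replace=False))
            local = PipelineConfig(rank_cap=int(rng.integers(5, 30)))
            got = score_signature(ds, GeneSignature("s", sig_genes,
                                                    "induced"), local)
            expected = brute_force_scores(
                np.asarray(ds.layers["lognorm"].todense()), ds.gene_ids,
                sig_genes, local.rank_cap)
            np.testing.assert_allclose(got["score"].to_numpy(), expected)

    def test_invariant_to_permuting_nonsignature_values(self, cfg):
        rng = np.random.default_rng(4)
        counts = rng.poisson(2.0, size=(6, 20))
        ds = preprocess(make_dataset(counts), cfg)
        sig = GeneSignature("s", ["g0", "g1"], "induced")
        base = score_signature(ds, sig, cfg)["score"].to_numpy()
        perm = counts.copy()
        perm[:, 2:] = perm[:, 2:][:, rng.permutation(18)]
        ds2 = preprocess(make_dataset(perm), cfg)
        again = score_signature(ds2, sig, cfg)["score"].to_numpy()
        np.testing.assert_allclose(base, again)

    def test_monotone_in_signature_gene_expression(self, cfg):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2.0, size=(5, 15))
        sig = GeneSignature("s", ["g3"], "induced")
        prev = None
        for bump in (0, 2, 8):
            c = counts.copy()
            c[:, 3] += bump
            ds = preprocess(make_dataset(c), cfg)
            s = score_signature(ds, sig, cfg)["score"].to_numpy()
            if prev is not None:
                assert (s >= prev - 1e-12).all()
            prev = s

    def test_absent_signature_errors(self, cfg):
        ds = preprocess(make_dataset(np.ones((2, 3), dtype=int)), cfg)
        with pytest.raises(ValueError, match="nope"):
            score_signature(ds, GeneSignature("nope", ["zz"], "induced"), cfg)


class TestConsensusBuilder:
    def _table(self, n_qualifying, klass="up"):
        sign = 1.0 if klass == "up" else -1.0
        rows = [{"gene": f"q{i}", "log2fc": sign * (1.0 + i * 0.01),
                 "pval": 0.01} for i in range(n_qualifying)]
        rows += [{"gene": f"x{i}", "log2fc": 0.0, "pval": 0.5}
                 for i in range(300)]
        return pd.DataFrame(rows)

    def test_top_200_largest_fold_changes_selected(self):
        sigs = build_consensus_signatures(self._table(250))
        ind = sigs["induced"]
        assert len(ind.genes) == 200
        # the 200 largest fold changes are q50..q249
        assert set(ind.genes) == {f"q{i}" for i in range(50, 250)}

    def test_shortfall_returns_all_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="osmohet"):
            sigs = build_consensus_signatures(self._table(150, klass="down"))
        assert len(sigs["repressed"].genes) == 150
        assert any("repressed" in r.message for r in caplog.records)

    def test_boundary_gene_eligible(self):
        table = pd.DataFrame([
            {"gene": "edge", "log2fc": 1.0, "pval": 0.04},
            {"gene": "flat", "log2fc": 0.0, "pval": 0.5},
        ])
        sigs = build_consensus_signatures(table)
        assert "edge" in sigs["induced"].genes

    def test_unresponsive_nearest_zero(self):
        table = pd.DataFrame(
            [{"gene": f"u{i}", "log2fc": 0.002 * i - 0.25, "pval": 0.3}
             for i in range(250)])
        sigs = build_consensus_signatures(table)
        unr = sigs["unresponsive"]
        assert len(unr.genes) == 200
        kept = table.set_index("gene").loc[unr.genes, "log2fc"].abs()
        dropped = table[~table["gene"].isin(unr.genes)]["log2fc"].abs()
        assert kept.max() <= dropped.min() + 1e-12

    def test_missing_columns_is_format_error(self):
        with pytest.raises(FormatError):
            build_consensus_signatures(pd.DataFrame({"gene": ["a"]}))


class TestPercentExpressing:
    def test_fraction_and_zero_case(self, cfg):
        counts = np.array([[0, 0], [0, 0], [3, 0], [1, 0]])
        meta = pd.DataFrame({"condition": ["NaCl"] * 4},
                            index=[f"c{i}" for i in range(4)])
        ds = preprocess(make_dataset(counts, meta=meta), cfg)
        sig = GeneSignature("s", ["g0", "g1"], "induced")
        out = percent_expressing(ds, sig).set_index("gene")
        assert out.loc["g0", "fraction_expressing"] == 0.5
        assert out.loc["g1", "fraction_expressing"] == 0.0
        assert out.loc["g1", "scaled_mean"] == 0.0
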