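"""Synthetic-data generators: construction guarantees and determinism."""

import numpy as np
import pytest

from osmohet.signatures import build_consensus_signatures
from osmohet.syndata import (GenotypeSpec, SimSpec, TraceSimSpec,
                             generate_counts, generate_frames,
                             generate_growth_and_fc, generate_traces)


class TestGenerateCounts:
    def test_deterministic_given_seed(self):
        spec = SimSpec(n_cells_per_group=50, n_background_genes=300, seed=9)
        ds1, t1 = generate_counts(spec)
        ds2, t2 = generate_counts(spec)
        assert (ds1.counts != ds2.counts).nnz == 0
        assert t1.equals(t2)

    def test_basal_fraction_zero_means_no_control_amplitude(self):
        spec = SimSpec(n_cells_per_group=200, n_background_genes=300,
                       basal_fraction=0.0, seed=1)
        _, truth = generate_counts(spec)
        control = truth[truth["condition"] == "control"]
        assert (control["amplitude"] == 0).all()
        assert not control["responding"].any()

    def test_doublet_rate_binomial(self):
        gt = [GenotypeSpec(f"g{i}", 100) for i in range(10)]
        spec = SimSpec(genotype_table=gt, n_background_genes=300,
                       conditions=("control",), doublet_rate=0.05, seed=2)
        _, truth = generate_counts(spec)
        n_dbl = truth["doublet"].sum()
        # ~Binomial(1000, 0.05): within 4 sigma of 50
        assert abs(n_dbl - 50) < 4 * np.sqrt(1000 * 0.05 * 0.95)

    def test_budget_conserved_under_coupling(self):
        base = dict(n_cells_per_group=40, n_background_genes=200,
                    hyper_fraction=0.0, seed=5)
        _, _, m0 = generate_counts(SimSpec(coupling_kappa=0.0, **base),
                                   return_masses=True)
        _, _, m1 = generate_counts(SimSpec(coupling_kappa=0.8, **base),
                                   return_masses=True)
        np.testing.assert_allclose(m0.sum(axis=1), m1.sum(axis=1), rtol=1e-9)

    def test_ground_truth_is_exhaustive(self):
        spec = SimSpec(n_cells_per_group=30, n_background_genes=200, seed=3)
        ds, truth = generate_counts(spec)
        assert len(truth) == ds.n_cells
        assert truth["cell_id"].is_unique
        for col in ("amplitude", "responding", "basal_stressed", "hyper",
                    "doublet", "n_used"):
            assert truth[col].notna().all()

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimSpec(hyper_fraction=1.5)
        with pytest.raises(ValueError):
            SimSpec(nb_dispersion=0.0)


class TestGenerateTraces:
    def test_noiseless_induced_pre_stimulus_at_baseline(self):
        spec = TraceSimSpec(n_traces=10, kind="induced", noise_sd=0.0,
                            baseline_cv=0.0, fraction_high_basal=0.0, seed=0)
        ts, truth = generate_traces(spec)
        np.testing.assert_allclose(ts.intensities[:, :10], 100.0)
        assert (truth["repressor_class"] == "n/a").all()

    def test_high_repressor_drop_level(self):
        spec = TraceSimSpec(n_traces=20, noise_sd=0.0, baseline_cv=0.0,
                            repressed_drop_fraction=0.8,
                            fraction_low_repressor=0.0, seed=1)
        ts, truth = generate_traces(spec)
        # long after the stimulus the level settles at baseline*(1-drop)
        np.testing.assert_allclose(ts.intensities[:, -1], 20.0, atol=0.1)

    def test_high_basal_fraction_binomial(self):
        spec = TraceSimSpec(n_traces=500, fraction_high_basal=0.1, seed=2)
        _, truth = generate_traces(spec)
        n_hb = truth["high_basal"].sum()
        assert abs(n_hb - 50) < 4 * np.sqrt(500 * 0.1 * 0.9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TraceSimSpec(n_pre_points=0)
        with pytest.raises(ValueError):
            TraceSimSpec(kind="other")


class TestGenerateFrames:
    def test_noiseless_no_spot_constant_inside_mask(self):
        fs = generate_frames(n_frames=4, noise_sd=0.0, spot_fraction=0.0,
                             seed=0)
        for f in range(4):
            vals = fs.frames[f][fs.nucleus_mask]
            assert np.ptp(vals) == 0.0

    def test_spot_has_exactly_spot_px_bright_pixels(self):
        fs = generate_frames(n_frames=6, noise_sd=0.0, spot_px=12,
                             spot_amplitude=200.0, spot_fraction=1.0, seed=1)
        for f in range(6):
            assert (fs.frames[f] > 100.0).sum() == 12

    def test_deterministic_given_seed(self):
        a = generate_frames(n_frames=5, noise_sd=2.0, seed=7)
        b = generate_frames(n_frames=5, noise_sd=2.0, seed=7)
        np.testing.assert_array_equal(a.frames, b.frames)
        assert a.truth.equals(b.truth)

    def test_spot_larger_than_nucleus_rejected(self):
        with pytest.raises(ValueError):
            generate_frames(n_frames=1, nucleus_radius=2, spot_px=100)


class TestGrowthAndFC:
    def test_carrying_capacity_bounds_od(self):
        growth, _ = generate_growth_and_fc(
            ["WT"], {"WT": 5.0}, n_replicates=2, seed=0)
        assert growth["od"].max() <= 1.2 * 1.2  # K times noise headroom

    def test_zero_benefit_equalizes_conditions_in_expectation(self):
        growth, _ = generate_growth_and_fc(
            ["WT"], {"WT": 0.0}, n_replicates=6, seed=1)
        end = growth[growth["t_min"] == growth["t_min"].max()]
        pre = end[end["condition"] == "prestress_then_stress"]["od"].mean()
        direct = end[end["condition"] == "stress"]["od"].mean()
        assert pre == pytest.approx(direct, rel=0.05)

    def test_excess_benefit_rejected(self):
        with pytest.raises(ValueError):
            generate_growth_and_fc(["WT"], {"WT": 100.0}, seed=0)

    def test_planted_fold_changes_feed_consensus_builder(self):
        _, fc = generate_growth_and_fc(["WT"], {"WT": 5.0}, seed=2)
        sigs = build_consensus_signatures(fc)
        assert len(sigs["induced"].genes) == 200
        assert len(sigs["repressed"].genes) == 200
        assert len(sigs["unresponsive"].genes) == 200
        # selection rule: the 200 largest fold changes among qualifiers
        table = fc.set_index("gene")
        sel = table.loc[sigs["induced"].genes]
        assert (sel["log2fc"] >= 1.0).all() and (sel["pval"] < 0.05).all()
        qualifiers = fc[(fc["log2fc"] >= 1.0) & (fc["pval"] < 0.05)]
        cutoff = qualifiers["log2fc"].nlargest(200).min()
        assert sel["log2fc"].min() >= cutoff - 1e-12
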