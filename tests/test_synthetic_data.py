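"""Generator contracts: mutation clock, Balding–Nichols moments,
determinism, and degenerate limits."""

import numpy as np
import pytest

from fadsevo.synthetic_data import (
    ClineSimConfig,
    HaplogroupSimConfig,
    MutationBudgetError,
    PanelSimConfig,
    simulate_cline_table,
    simulate_frequency_panel,
    simulate_haplogroup_alignment,
)


class TestHaplogroupAlignment:
    def test_derived_mutation_counts_follow_the_clock(self):
        """Per-derived-haplotype private mutation counts are Poisson with
        mean tmrca_derived * a_hc / (2 t_hc) * L_hq (~21.0 at defaults)."""
        counts = []
        for seed in range(40):
            cfg = HaplogroupSimConfig(seed=seed, n_ancestral=5)
            aln = simulate_haplogroup_alignment(cfg)
            derived = aln.haplotypes[(aln.metadata["cluster"] == "derived").to_numpy()]
            # private mutations live at high-quality sites only
            diffs = (derived != aln.ancestor[None, :])[:, aln.high_quality].sum(axis=1)
            counts.extend(diffs.tolist())
        counts = np.asarray(counts, dtype=float)
        expected = cfg.tmrca_derived * cfg.a_hc / (2 * cfg.t_hc) * cfg.length_high_quality
        assert expected == pytest.approx(21.0, abs=0.05)  # hand evaluation
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_zero_time_limit_gives_identical_derived_haplotypes(self):
        cfg = HaplogroupSimConfig(
            n_derived=8, n_ancestral=2, length_total=2_000, length_high_quality=1_900,
            tmrca_derived=0.0, seed=5,
        )
        aln = simulate_haplogroup_alignment(cfg)
        derived = aln.haplotypes[(aln.metadata["cluster"] == "derived").to_numpy()]
        assert (derived == derived[0]).all()

    def test_same_seed_reproduces_alignment_exactly(self):
        cfg = HaplogroupSimConfig(seed=3, n_derived=6, n_ancestral=6,
                                  length_total=1_000, length_high_quality=950)
        a = simulate_haplogroup_alignment(cfg)
        b = simulate_haplogroup_alignment(cfg)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.ancestor, b.ancestor)
        assert np.array_equal(a.high_quality, b.high_quality)
        assert a.metadata.equals(b.metadata)

    def test_mutation_budget_violation_is_an_explicit_error(self):
        cfg = HaplogroupSimConfig(
            n_derived=50, n_ancestral=50, length_total=200, length_high_quality=150,
            tmrca_derived=5e8, tmrca_all=1e9, seed=0,
        )
        with pytest.raises(MutationBudgetError):
            simulate_haplogroup_alignment(cfg)

    def test_high_quality_mask_has_configured_count(self, small_alignment):
        assert int(small_alignment.high_quality.sum()) == 1_900

    def test_config_invariants_rejected(self):
        with pytest.raises(ValueError):
            HaplogroupSimConfig(tmrca_derived=2e6, tmrca_all=1e6)
        with pytest.raises(ValueError):
            HaplogroupSimConfig(length_total=100, length_high_quality=200)
        with pytest.raises(ValueError):
            HaplogroupSimConfig(a_hc=0.0)


class TestFrequencyPanel:
    def test_balding_nichols_across_population_variance(self):
        """E[across-population variance] = F * E[p(1-p)] under the model;
        with ancestral p ~ U(0.05, 0.95), E[p(1-p)] = 0.1825."""
        F = 0.05
        cfg = PanelSimConfig(
            n_sites=10_000, sample_sizes=(2_000, 2_000, 2_000),
            drift_f=(F, F, F), seed=2,
        )
        panel = simulate_frequency_panel(cfg)
        freqs = np.stack(
            [panel[f"{p}_ALT"] / (panel[f"{p}_REF"] + panel[f"{p}_ALT"]) for p in "ABC"]
        )
        s2 = freqs.var(axis=0, ddof=1)
        assert s2.mean() == pytest.approx(F * 0.1825, rel=0.10)

    def test_no_drift_limit_frequencies_agree_across_populations(self):
        cfg = PanelSimConfig(
            n_sites=500, sample_sizes=(5_000, 5_000, 5_000),
            drift_f=(1e-9, 1e-9, 1e-9), seed=4,
        )
        panel = simulate_frequency_panel(cfg)
        freqs = np.stack(
            [panel[f"{p}_ALT"] / (panel[f"{p}_REF"] + panel[f"{p}_ALT"]) for p in "ABC"]
        )
        # only binomial noise around the shared draw: SE ~ sqrt(pq/1e4) < 0.005
        assert np.abs(freqs - freqs.mean(axis=0)).max() < 0.03

    def test_selected_site_shifts_focal_population_only(self):
        cfg = PanelSimConfig(
            n_sites=100, sample_sizes=(5_000, 5_000, 5_000),
            drift_f=(1e-6, 1e-6, 1e-6), ancestral_freq_range=(0.5, 0.5),
            selected_site=(7, 0.5), seed=9,
        )
        panel = simulate_frequency_panel(cfg)
        row = panel.iloc[7]
        assert row["A_ALT"] / (row["A_REF"] + row["A_ALT"]) > 0.98
        assert row["B_ALT"] / (row["B_REF"] + row["B_ALT"]) == pytest.approx(0.5, abs=0.05)

    def test_degenerate_drift_rejected(self):
        with pytest.raises(ValueError):
            PanelSimConfig(drift_f=(0.0, 0.1, 0.1))
        with pytest.raises(ValueError):
            PanelSimConfig(drift_f=(1.0, 0.1, 0.1))

    def test_same_seed_reproduces_panel(self):
        cfg = PanelSimConfig(n_sites=200, seed=7)
        assert simulate_frequency_panel(cfg).equals(simulate_frequency_panel(cfg))


class TestClineTable:
    def test_noiseless_table_is_exactly_linear_in_latitude(self):
        cfg = ClineSimConfig(
            noise_sd=0.0, beta_admixture=0.0, beta_latitude=0.01,
            intercept=0.0, admixture_range=(0.0, 0.0), latitude_range=(10, 60), seed=1,
        )
        t = simulate_cline_table(cfg)
        assert np.allclose(t["proportion"], 0.01 * t["latitude"])

    def test_no_effects_gives_constant_proportion(self):
        cfg = ClineSimConfig(noise_sd=0.0, beta_latitude=0.0, beta_admixture=0.0,
                             intercept=0.4, seed=1)
        t = simulate_cline_table(cfg)
        assert np.allclose(t["proportion"], 0.4)

    def test_proportions_clipped_to_unit_interval(self):
        cfg = ClineSimConfig(noise_sd=0.5, seed=3)
        t = simulate_cline_table(cfg)
        assert t["proportion"].between(0, 1).all()

    def test_same_seed_reproduces_table(self):
        cfg = ClineSimConfig(seed=6)
        assert simulate_cline_table(cfg).equals(simulate_cline_table(cfg))
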