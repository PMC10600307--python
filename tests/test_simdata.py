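"""Synthetic study generator: markers, genetic values, trials, spectra."""

import numpy as np
import pandas as pd
import pytest

from phenosel.simdata import (
    BandSpec,
    GeneticArchitecture,
    PRepLayout,
    TraitSpec,
    default_architecture,
    scenario_default,
    simulate_field_trial,
    simulate_genetic_values,
    simulate_markers,
    simulate_spectra,
)
from phenosel.spectra import snv_normalize


class TestMarkers:
    def test_even_chromosome_allocation(self):
        m = simulate_markers(10, 21, n_chrom=21, missing_rate=0.0, seed=0)
        assert m.chrom.value_counts().eq(1).all()
        assert not m.values.isna().any().any()

    def test_mean_maf_at_half(self):
        m = simulate_markers(5000, 300, n_chrom=3, maf_range=(0.5, 0.5),
                             seed=1)
        assert 0.48 <= m.maf.mean() <= 0.52

    def test_seed_determinism(self):
        a = simulate_markers(30, 50, n_chrom=5, missing_rate=0.1, seed=42)
        b = simulate_markers(30, 50, n_chrom=5, missing_rate=0.1, seed=42)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_missing_rate_realized(self):
        m = simulate_markers(200, 200, n_chrom=4, missing_rate=0.1, seed=2)
        assert m.missing_rate == pytest.approx(0.1, abs=0.01)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError, match="per chromosome"):
            simulate_markers(10, 5, n_chrom=10)
        with pytest.raises(ValueError, match="maf_range"):
            simulate_markers(10, 20, n_chrom=2, maf_range=(0.4, 0.2))
        with pytest.raises(ValueError, match="maf_range"):
            simulate_markers(10, 20, n_chrom=2, maf_range=(0.0, 0.3))


def two_trait_arch(rho, n_qtl=400):
    specs = [TraitSpec("A", 0.5, 0.0, 1.0, 0.0, 0.0, 0.5),
             TraitSpec("B", 0.5, 0.0, 1.0, 0.0, 0.0, 0.5)]
    R = np.array([[1.0, rho], [rho, 1.0]])
    return GeneticArchitecture(specs, R, n_qtl_per_trait=n_qtl)


class TestGeneticValues:
    def test_identity_correlation_stays_small(self):
        vals = []
        for seed in range(20):
            m = simulate_markers(500, 1000, n_chrom=21, seed=seed)
            truth = simulate_genetic_values(m, two_trait_arch(0.0), seed=seed)
            vals.append(abs(truth.realized_rho_G[0, 1]))
        assert np.mean(vals) < 0.15

    def test_target_correlation_recovered(self):
        vals = []
        for seed in range(20):
            m = simulate_markers(500, 1000, n_chrom=21, seed=seed)
            truth = simulate_genetic_values(m, two_trait_arch(-0.5), seed=seed)
            vals.append(truth.realized_rho_G[0, 1])
        assert np.mean(vals) == pytest.approx(-0.5, abs=0.1)

    def test_correlation_error_shrinks_with_size(self):
        def mean_abs_err(n_geno, n_markers, seeds):
            errs = []
            for seed in seeds:
                m = simulate_markers(n_geno, n_markers, n_chrom=5, seed=seed)
                t = simulate_genetic_values(m, two_trait_arch(-0.5, 150),
                                            seed=seed)
                errs.append(abs(t.realized_rho_G[0, 1] + 0.5))
            return np.mean(errs)

        small = mean_abs_err(60, 150, range(12))
        large = mean_abs_err(600, 1500, range(12))
        assert large < small

    def test_single_marker_single_trait(self):
        m = simulate_markers(40, 1, n_chrom=1, maf_range=(0.4, 0.5), seed=3)
        spec = TraitSpec("A", 0.5, 0.0, 2.0, 0.0, 0.0, 0.5)
        arch = GeneticArchitecture([spec], np.eye(1), n_qtl_per_trait=1)
        truth = simulate_genetic_values(m, arch, seed=3)
        col = m.values.iloc[:, 0].to_numpy(dtype=float)
        r = np.corrcoef(truth.true_breeding_values["A"], col)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert truth.true_breeding_values["A"].std(ddof=0) == pytest.approx(2.0)

    def test_non_psd_rho_rejected_with_hint(self):
        specs = [TraitSpec(n, 0.5, 0.0, 1.0, 0.0, 0.0, 0.5)
                 for n in ("A", "B", "C")]
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="nearest PSD"):
            GeneticArchitecture(specs, R)

    def test_missing_markers_rejected(self):
        m = simulate_markers(30, 40, n_chrom=2, missing_rate=0.1, seed=4)
        with pytest.raises(ValueError, match="complete"):
            simulate_genetic_values(m, two_trait_arch(0.0), seed=0)


class TestFieldTrial:
    def test_noise_free_plot_values_equal_truth(self):
        spec = TraitSpec("A", 0.99, 5.0, 1.0, 0.0, 0.0, 0.0, gxe_sd=0.0)
        m = simulate_markers(30, 60, n_chrom=2, maf_range=(0.3, 0.5), seed=5)
        arch = GeneticArchitecture([spec], np.eye(1), n_qtl_per_trait=30)
        truth = simulate_genetic_values(m, arch, seed=5)
        layout = PRepLayout(7, 6, rep_fraction=0.25)
        trial = simulate_field_trial(truth, layout, "2020", "L",
                                     trait_specs=[spec], spatial_amplitude=0.0,
                                     row_sd_frac=0.0, col_sd_frac=0.0, seed=6)
        tbv = truth.true_breeding_values["A"]
        np.testing.assert_allclose(
            trial.data["A"], 5.0 + tbv.loc[trial.data["genotype"]], atol=1e-12)

    def test_prep_plot_counts(self):
        spec = TraitSpec("A", 0.5, 0.0, 1.0, 0.0, 0.0, 1.0)
        m = simulate_markers(100, 60, n_chrom=2, seed=7)
        arch = GeneticArchitecture([spec], np.eye(1), n_qtl_per_trait=30)
        truth = simulate_genetic_values(m, arch, seed=7)
        trial = simulate_field_trial(truth, PRepLayout(12, 11, 0.25), "2020",
                                     "L", trait_specs=[spec], seed=8)
        assert trial.n_plots == 125
        counts = trial.genotype_counts()
        assert (counts == 2).sum() == 25
        assert (counts == 1).sum() == 75

    def test_layout_capacity_checked(self):
        spec = TraitSpec("A", 0.5, 0.0, 1.0, 0.0, 0.0, 1.0)
        m = simulate_markers(100, 60, n_chrom=2, seed=7)
        arch = GeneticArchitecture([spec], np.eye(1), n_qtl_per_trait=30)
        truth = simulate_genetic_values(m, arch, seed=7)
        with pytest.raises(ValueError, match="too small"):
            simulate_field_trial(truth, PRepLayout(5, 5, 0.25), "2020", "L",
                                 trait_specs=[spec], seed=8)

    def test_bad_rep_fraction_rejected(self):
        with pytest.raises(ValueError, match="replicated fraction"):
            PRepLayout(5, 5, rep_fraction=1.5)


class TestSpectra:
    @staticmethod
    def pc_trial(noise=0.0, scatter=0.0, seed=9):
        spec = TraitSpec("PC", 0.99, 14.0, 1.0, 0.0, 0.0, 0.0, gxe_sd=0.0)
        m = simulate_markers(30, 60, n_chrom=2, maf_range=(0.3, 0.5),
                             seed=seed)
        arch = GeneticArchitecture([spec], np.eye(1), n_qtl_per_trait=30)
        truth = simulate_genetic_values(m, arch, seed=seed)
        trial = simulate_field_trial(truth, PRepLayout(7, 6, 0.25), "2020",
                                     "L", trait_specs=[spec],
                                     spatial_amplitude=0.0, row_sd_frac=0.0,
                                     col_sd_frac=0.0, seed=seed)
        grid = np.linspace(4000, 8000, 50)
        s = simulate_spectra(trial, truth,
                             bands=[BandSpec(6000.0, 300.0, 1.0, "PC")],
                             grid=grid, scatter_sd=scatter, noise_sd=noise,
                             seed=seed)
        return trial, s

    def test_band_center_affine_in_driver(self):
        trial, s = self.pc_trial()
        j = np.argmin(np.abs(s.grid - 6000.0))
        r = np.corrcoef(s.values[:, j], trial.data["PC"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_snv_removes_scatter(self):
        t0, clean = self.pc_trial(scatter=0.0)
        t1, scat = self.pc_trial(scatter=0.4)
        np.testing.assert_allclose(snv_normalize(scat).values,
                                   snv_normalize(clean).values, atol=1e-8)

    def test_off_grid_band_rejected(self):
        trial, _ = self.pc_trial()
        with pytest.raises(ValueError, match="outside grid"):
            simulate_spectra(trial, None,
                             bands=[BandSpec(3000.0, 100.0, 1.0, "noise")],
                             grid=np.linspace(4000, 8000, 20), seed=0)

    def test_unknown_driver_rejected(self):
        trial, _ = self.pc_trial()
        with pytest.raises(ValueError, match="driver"):
            simulate_spectra(trial, None,
                             bands=[BandSpec(6000.0, 100.0, 1.0, "XX")],
                             grid=np.linspace(4000, 8000, 20), seed=0)


class TestScenarioDefault:
    def test_structure(self, tiny_study):
        assert len(tiny_study.trials) == 12
        assert tiny_study.locations == ("DOE", "PRO", "WEI")
        assert tiny_study.years == ("2019", "2020", "2021", "2022")
        assert len(tiny_study.genotypes) == 60
        for t in tiny_study.trials:
            assert t.spectra is not None
            assert [p[0] for p in t.spectra.provenance][-1] == "snv"

    def test_seed_determinism(self):
        a = scenario_default(seed=5, n_geno=25, n_markers=60, grid_points=12)
        b = scenario_default(seed=5, n_geno=25, n_markers=60, grid_points=12)
        pd.testing.assert_frame_equal(a.trials[0].data, b.trials[0].data)
        np.testing.assert_array_equal(a.trials[3].spectra.values,
                                      b.trials[3].spectra.values)
        np.testing.assert_array_equal(a.truth.realized_rho_G,
                                      b.truth.realized_rho_G)

    def test_default_architecture_valid(self):
        arch = default_architecture()
        assert arch.rho_G[0, 1] < 0          # GY-PC trade-off
        w = np.linalg.eigvalsh(arch.rho_G)
        assert w.min() > 0
        # heritability targets keep the PC > GY ordering
        h2 = {t.name: t.h2_target for t in arch.trait_specs}
        assert h2["PC"] > h2["GY"]
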