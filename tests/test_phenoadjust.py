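"""Two-stage spatial adjustment, repeatability and heritability."""

import numpy as np
import pandas as pd
import pytest

from phenosel.mixedmodel import VarianceComponents
from phenosel.phenoadjust import (
    FieldTrial,
    adjust_spectra,
    effective_replication,
    fit_stage1,
    fit_stage2,
    heritability,
    repeatability,
    spectra_repeatability,
    stage1_design,
)
from phenosel.simdata import (
    BandSpec,
    GeneticArchitecture,
    PRepLayout,
    TraitSpec,
    simulate_field_trial,
    simulate_genetic_values,
    simulate_markers,
    simulate_spectra,
)
from phenosel.spectra import snv_normalize

QUIET = TraitSpec("T", h2_target=0.99, mean=10.0, genetic_sd=2.0, year_sd=0.0,
                  location_sd=0.0, residual_sd=0.0, gxe_sd=0.0)


def quiet_truth(n_geno=40, n_markers=100, seed=0, spec=QUIET):
    markers = simulate_markers(n_geno, n_markers, n_chrom=3,
                               maf_range=(0.3, 0.5), seed=seed)
    arch = GeneticArchitecture([spec], rho_G=np.eye(1), n_qtl_per_trait=60)
    return simulate_genetic_values(markers, arch, seed=seed)


def make_trial(truth, spec=QUIET, **kw):
    n = len(truth.true_breeding_values)
    n_plots = n + int(round(0.25 * n))
    rows = int(np.ceil(np.sqrt(n_plots)))
    cols = int(np.ceil(n_plots / rows))
    layout = PRepLayout(rows, cols, 0.25)
    kw.setdefault("spatial_amplitude", 0.0)
    kw.setdefault("row_sd_frac", 0.0)
    kw.setdefault("col_sd_frac", 0.0)
    return simulate_field_trial(truth, layout, year=kw.pop("year", "2020"),
                                location=kw.pop("location", "L"),
                                trait_specs=[spec], **kw)


class TestEffectiveReplication:
    def test_all_duplicated(self):
        assert effective_replication([2, 2, 2]) == pytest.approx(2.0)

    def test_half_and_half_harmonic(self):
        assert effective_replication([1, 2]) == pytest.approx(4 / 3)

    def test_single_unreplicated(self):
        assert effective_replication([1]) == pytest.approx(1.0)

    def test_arithmetic_option(self):
        assert effective_replication([1, 2], "arithmetic") == pytest.approx(1.5)


class TestRatios:
    def test_formula(self):
        vc = VarianceComponents(sigma2_g=1.0, sigma2_e=1.0, r_bar=2.0)
        assert repeatability(vc) == pytest.approx(2 / 3)

    def test_zero_genetic_variance(self):
        vc = VarianceComponents(sigma2_g=0.0, sigma2_e=1.0, r_bar=1.0)
        assert repeatability(vc) == 0.0

    def test_both_zero_undefined(self):
        vc = VarianceComponents(sigma2_g=0.0, sigma2_e=0.0)
        with pytest.raises(ValueError):
            repeatability(vc)

    def test_infinite_replication_limit(self):
        vc = VarianceComponents(sigma2_g=0.35, sigma2_e=5.0, r_bar=1e9)
        assert heritability(vc) == pytest.approx(1.0, abs=1e-6)

    def test_inversion(self):
        # sigma2_e chosen so that H2 = 0.35 exactly
        vc = VarianceComponents(sigma2_g=0.35, sigma2_e=0.65, r_bar=1.0)
        assert heritability(vc) == pytest.approx(0.35)


class TestStage1:
    def test_noise_free_blues_recover_truth_exactly(self):
        truth = quiet_truth()
        trial = make_trial(truth, seed=1)
        res = fit_stage1(trial, "T", "fixed")
        expect = 10.0 + truth.true_breeding_values["T"]
        got = res.means.blues.loc[expect.index]
        np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_small_noise_blues_within_3se(self):
        spec = TraitSpec("T", 0.99, 10.0, 2.0, 0.0, 0.0, residual_sd=0.1,
                         gxe_sd=0.0)
        truth = quiet_truth(spec=spec)
        trial = make_trial(truth, spec=spec, seed=2)
        res = fit_stage1(trial, "T", "fixed")
        expect = 10.0 + truth.true_breeding_values["T"]
        z = (res.means.blues.loc[expect.index] - expect) / res.means.se
        assert (np.abs(z) < 3).mean() > 0.95

    def test_spline_variance_near_zero_without_surface(self):
        spec = TraitSpec("T", 0.5, 10.0, 2.0, 0.0, 0.0, residual_sd=2.0,
                         gxe_sd=0.0)
        ratios = []
        for seed in range(7):
            truth = quiet_truth(n_geno=60, seed=seed, spec=spec)
            trial = make_trial(truth, spec=spec, seed=seed)
            res = fit_stage1(trial, "T", "random")
            ratios.append(res.reml.sigma2["spline"] / res.reml.sigma2_e)
        assert np.median(ratios) < 0.10

    def test_injected_surface_recovered(self):
        spec = TraitSpec("T", 0.99, 10.0, 2.0, 0.0, 0.0, residual_sd=1.0,
                         gxe_sd=0.0)
        cors = []
        for seed in range(10):
            truth = quiet_truth(n_geno=80, seed=seed, spec=spec)
            trial = make_trial(truth, spec=spec, seed=seed,
                               spatial_amplitude=2.0)
            res = fit_stage1(trial, "T", "random")
            reml = None
            # recompute with access to the fitted surface at plots
            model, _ = stage1_design(trial, "random")
            model.set_response(trial.data["T"].to_numpy(float))
            reml = model.fit()
            surf = truth.spatial_fields[("L", "2020")]
            at_plots = surf[trial.data["row"] - 1, trial.data["col"] - 1]
            fitted = reml.fitted_random("spline")
            cors.append(np.corrcoef(fitted, at_plots)[0, 1])
        assert np.mean(cors) > 0.8

    def test_spline_improves_loglik_when_surface_present(self):
        spec = TraitSpec("T", 0.99, 10.0, 2.0, 0.0, 0.0, residual_sd=0.5,
                         gxe_sd=0.0)
        truth = quiet_truth(n_geno=60, seed=3, spec=spec)
        trial = make_trial(truth, spec=spec, seed=3, spatial_amplitude=3.0)
        full = fit_stage1(trial, "T", "random")
        from phenosel.mixedmodel import MixedREML, RandomTerm
        from phenosel.phenoadjust import _onehot

        df = trial.data
        Zg, _ = _onehot(df["genotype"])
        Zr, _ = _onehot(df["row"])
        Zc, _ = _onehot(df["col"])
        reduced = MixedREML(df["T"].to_numpy(float), np.ones((len(df), 1)),
                            [RandomTerm("genotype", Zg), RandomTerm("row", Zr),
                             RandomTerm("col", Zc)]).fit()
        assert full.reml.loglik > reduced.loglik

    def test_perfect_replication_repeatability_one(self):
        truth = quiet_truth(n_geno=20)
        tbv = truth.true_breeding_values["T"]
        rows, cols, vals, genos = [], [], [], []
        k = 0
        for g, v in tbv.items():
            for _ in range(2):
                rows.append(k // 8 + 1)
                cols.append(k % 8 + 1)
                genos.append(g)
                vals.append(10.0 + v)
                k += 1
        trial = FieldTrial(data=pd.DataFrame({
            "plot_id": [f"p{i}" for i in range(k)], "genotype": genos,
            "row": rows, "col": cols, "replicate": 1, "T": vals}),
            year="2020", location="L")
        res = fit_stage1(trial, "T", "random")
        assert res.varcomp.r_bar == pytest.approx(2.0)
        assert repeatability(res.varcomp) > 0.999

    def test_scale_equivariance_of_repeatability(self):
        spec = TraitSpec("T", 0.5, 10.0, 2.0, 0.0, 0.0, residual_sd=2.0,
                         gxe_sd=0.0)
        truth = quiet_truth(spec=spec)
        trial = make_trial(truth, spec=spec, seed=5)
        r1 = repeatability(fit_stage1(trial, "T", "random").varcomp)
        trial.data["T"] *= 37.0
        r2 = repeatability(fit_stage1(trial, "T", "random").varcomp)
        assert r2 == pytest.approx(r1, abs=1e-3)

    def test_missing_response_plots_dropped(self):
        truth = quiet_truth()
        trial = make_trial(truth, seed=6)
        trial.data.loc[3, "T"] = np.nan
        res = fit_stage1(trial, "T", "fixed")
        kept = trial.data.dropna(subset=["T"])["genotype"].nunique()
        assert len(res.means.blues) == kept

    def test_one_genotype_is_singular(self):
        df = pd.DataFrame({"plot_id": ["a", "b", "c", "d"],
                           "genotype": ["g1"] * 4,
                           "row": [1, 1, 2, 2], "col": [1, 2, 1, 2],
                           "replicate": [1, 2, 3, 4],
                           "T": [1.0, 2.0, 3.0, 4.0]})
        trial = FieldTrial(data=df, year="y", location="L")
        with pytest.raises(ValueError, match="genotypes"):
            fit_stage1(trial, "T", "random")


class TestStage2:
    def test_identical_years_give_zero_residual(self):
        blues = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        res = fit_stage2({"2019": blues, "2020": blues}, "fixed")
        np.testing.assert_allclose(res.means.blues.loc[["a", "b", "c"]],
                                   blues, atol=1e-8)
        vcr = fit_stage2({"2019": blues, "2020": blues}, "random")
        assert vcr.varcomp.sigma2_e < 1e-6

    def test_matches_two_way_anova_oracle(self):
        rng = np.random.default_rng(20)
        g, yno = 40, 4
        geff = rng.normal(0, 2.0, g)
        yeff = rng.normal(0, 3.0, yno)
        tbl = geff[:, None] + yeff[None, :] + rng.normal(0, 1.0, (g, yno))
        blues = {f"y{j}": pd.Series(tbl[:, j],
                                    index=[f"g{i}" for i in range(g)])
                 for j in range(yno)}
        vc = fit_stage2(blues, "random").varcomp
        # balanced two-way ANOVA method-of-moments oracle
        gm = tbl.mean()
        msa = yno * np.sum((tbl.mean(1) - gm) ** 2) / (g - 1)
        msb = g * np.sum((tbl.mean(0) - gm) ** 2) / (yno - 1)
        mse = np.sum((tbl - tbl.mean(1)[:, None] - tbl.mean(0)[None, :]
                      + gm) ** 2) / ((g - 1) * (yno - 1))
        assert vc.sigma2_g == pytest.approx((msa - mse) / yno, abs=1e-3)
        assert vc.extra["sigma2_y"] == pytest.approx((msb - mse) / g,
                                                     rel=1e-3, abs=1e-3)
        assert vc.sigma2_e == pytest.approx(mse, abs=1e-3)

    def test_plus_minus_five_year_effects(self):
        rng = np.random.default_rng(21)
        g = 30
        geff = rng.normal(0, 1.0, g)
        tbl = geff[:, None] + np.array([5.0, -5.0])[None, :] \
            + rng.normal(0, 0.3, (g, 2))
        blues = {f"y{j}": pd.Series(tbl[:, j],
                                    index=[f"g{i}" for i in range(g)])
                 for j in range(2)}
        vc = fit_stage2(blues, "random").varcomp
        gm = tbl.mean()
        msb = g * np.sum((tbl.mean(0) - gm) ** 2) / 1
        mse = np.sum((tbl - tbl.mean(1)[:, None] - tbl.mean(0)[None, :]
                      + gm) ** 2) / (g - 1)
        assert vc.extra["sigma2_y"] == pytest.approx((msb - mse) / g,
                                                     rel=1e-2)

    def test_single_year_random_rejected(self):
        blues = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="2 years"):
            fit_stage2({"2019": blues}, "random")


class TestSpectraAdjustment:
    def quiet_spectral_trials(self, seed=0, noise=0.0, scatter=0.0):
        spec = TraitSpec("PC", 0.99, 14.0, 1.0, 0.0, 0.0, residual_sd=0.0,
                         gxe_sd=0.0)
        truth = quiet_truth(n_geno=25, seed=seed, spec=spec)
        grid = np.linspace(4000.0, 7000.0, 25)
        trials = []
        for year in ("2019", "2020"):
            bands = [BandSpec(5000.0, 300.0, 1.0, "PC")]
            if noise > 0 or scatter > 0:
                bands.append(BandSpec(6200.0, 250.0, 0.6, "noise"))
            t = make_trial(truth, spec=spec, year=year, seed=seed + int(year))
            simulate_spectra(t, truth, bands=bands, grid=grid,
                             scatter_sd=scatter, noise_sd=noise, seed=seed)
            t.spectra = snv_normalize(t.spectra)
            trials.append(t)
        return truth, trials

    def test_noise_free_blues_equal_genotype_means(self):
        truth, trials = self.quiet_spectral_trials()
        adj = adjust_spectra(trials)
        blues = adj.blues["L"]
        # oracle: mean of SNV plot spectra per genotype, averaged over years
        frames = []
        for t in trials:
            f = pd.DataFrame(t.spectra.values, columns=t.spectra.grid)
            f["genotype"] = t.data["genotype"].to_numpy()
            frames.append(f.groupby("genotype").mean())
        oracle = (frames[0] + frames[1]) / 2
        np.testing.assert_allclose(
            blues.loc[oracle.index].to_numpy(), oracle.to_numpy(), atol=1e-6)

    def test_requires_snv(self):
        truth, trials = self.quiet_spectral_trials()
        trials[0].spectra.provenance = []
        with pytest.raises(ValueError, match="SNV"):
            adjust_spectra(trials)

    def test_degenerate_wavenumber_substituted_and_logged(self):
        truth, trials = self.quiet_spectral_trials(noise=0.01)
        for t in trials:
            t.spectra.values[:, 5] = 0.123     # constant injected column
        adj = adjust_spectra(trials)
        wav = trials[0].spectra.grid[5]
        stage1_subs = [s for s in adj.substitutions
                       if s[1] == "stage1" and s[3] == pytest.approx(wav)]
        assert len(stage1_subs) == len(trials)
        assert np.allclose(adj.blues["L"].iloc[:, 5], 0.123)

    def test_spectral_repeatability_spans_wide_range(self):
        truth, trials = self.quiet_spectral_trials(noise=0.05, scatter=0.1)
        rep = spectra_repeatability(trials[0])
        vals = rep.dropna()
        # composition-driven wavenumbers ~1, pure-noise regions ~0
        assert vals.max() > 0.9
        assert vals.min() < 0.4
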