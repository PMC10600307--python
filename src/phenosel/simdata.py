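"""Synthetic wheat-breeding study generator.

Emulates the statistical structure of a multi-year, multi-location
winter-wheat advanced-yield-trial series so every downstream stage of the
pipeline can be tested against a known truth:

* biallelic markers on 21 chromosomes for a panel of (nearly) inbred
  lines, coded {-1, 0, 1};
* additive polygenic traits whose effects are drawn jointly across
  traits with a genetic correlation matrix rho_G, so that trait
  correlations (notably the negative grain yield / protein content
  correlation) emerge through shared loci;
* partially replicated (p-rep) field trials per location-year with
  random row/column effects and a smooth two-dimensional fertility
  surface, plus genotype-by-environment deviations that are themselves
  correlated across traits (rho_E);
* grain NIR spectra per plot built from Gaussian absorption bands driven
  by grain-composition traits (protein content above all), year effects
  and noise, wrapped in per-plot affine scatter (what SNV removes).
  Grain yield is never a direct spectral driver: any yield signal in the
  spectra arises only through the GY-PC correlation, which is exactly
  the mechanism behind the predictor-bias analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .kinship import MarkerMatrix, impute_markers, maf_filter
from .phenoadjust import FieldTrial
from .spectra import SpectraSet, snv_normalize

__all__ = [
    "TraitSpec",
    "GeneticArchitecture",
    "BandSpec",
    "SimTruth",
    "PRepLayout",
    "SyntheticStudy",
    "simulate_markers",
    "simulate_genetic_values",
    "simulate_field_trial",
    "simulate_spectra",
    "scenario_default",
    "default_trait_specs",
    "default_architecture",
    "default_bands",
    "default_grid",
]

#: years and locations of the emulated study design
DEFAULT_YEARS = ("2019", "2020", "2021", "2022")
DEFAULT_LOCATIONS = ("DOE", "PRO", "WEI")


@dataclass
class TraitSpec:
    """Generative parameters of one trait.

    ``gxe_sd`` is the standard deviation of the genotype-by-environment
    deviation per location-year; by default it is calibrated from
    ``h2_target`` so that the across-year broad-sense heritability of the
    simulated trials lands near the target (see ``calibrated_gxe_sd``).
    """

    name: str
    h2_target: float
    mean: float
    genetic_sd: float
    year_sd: float
    location_sd: float
    residual_sd: float
    gxe_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.h2_target <= 1:
            raise ValueError("h2_target must be in (0, 1]")
        for f in ("genetic_sd", "year_sd", "location_sd", "residual_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def calibrated_gxe_sd(self, n_years: int = 4, r_bar: float = 1.25) -> float:
        """GxE standard deviation implied by the heritability target.

        H2 = s2_g / (s2_g + s2_e2 / n_years) with the stage-2 residual
        s2_e2 ~ gxe^2 + residual^2 / r_bar (BLUE error), solved for gxe.
        """
        if self.gxe_sd is not None:
            return self.gxe_sd
        g2 = self.genetic_sd**2
        target = g2 * (1 / self.h2_target - 1) * n_years
        blue_err = self.residual_sd**2 / r_bar
        return float(np.sqrt(max(target - blue_err, 0.0)))


@dataclass
class GeneticArchitecture:
    """Joint genetic model of the trait set.

    ``rho_G`` is the genetic correlation matrix (traits x traits);
    ``rho_E`` the correlation of the GxE deviations (default: rho_G
    shrunk most of the way toward the identity — environmental
    correlations are far weaker than genetic ones).
    """

    trait_specs: list
    rho_G: np.ndarray
    n_qtl_per_trait: int = 300
    rho_E: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rho_G = np.asarray(self.rho_G, dtype=float)
        k = len(self.trait_specs)
        if self.rho_G.shape != (k, k):
            raise ValueError("rho_G shape must match number of traits")
        if not np.allclose(self.rho_G, self.rho_G.T):
            raise ValueError("rho_G must be symmetric")
        if not np.allclose(np.diag(self.rho_G), 1.0):
            raise ValueError("rho_G must have unit diagonal")
        w = np.linalg.eigvalsh(self.rho_G)
        if w.min() < -1e-8:
            raise ValueError(
                "rho_G is not positive semi-definite; project it to the "
                "nearest PSD matrix (e.g. clip negative eigenvalues and "
                "rescale the diagonal) before use")
        if self.rho_E is None:
            # the GY-PC trade-off is predominantly genetic; GxE deviations
            # carry only a faint echo of it
            self.rho_E = 0.1 * self.rho_G + 0.9 * np.eye(k)

    @property
    def trait_names(self) -> list:
        return [t.name for t in self.trait_specs]


@dataclass
class BandSpec:
    """One Gaussian absorption band: amplitude * driver * N(center, width)."""

    center: float
    width: float
    amplitude: float
    driver: str

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated study."""

    true_breeding_values: pd.DataFrame     # genotype x trait
    realized_rho_G: np.ndarray
    qtl_effects: pd.DataFrame              # marker x trait
    arch: GeneticArchitecture
    spatial_fields: dict = field(default_factory=dict)  # (loc, year) -> 2-D array
    gxe_values: dict = field(default_factory=dict)      # (loc, year) -> DataFrame


@dataclass
class PRepLayout:
    """Partially replicated layout: a fraction of entries appears twice."""

    n_rows: int
    n_cols: int
    rep_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.rep_fraction <= 1:
            raise ValueError("replicated fraction must be in [0, 1]")

    def n_plots(self, n_geno: int) -> int:
        return n_geno + int(round(self.rep_fraction * n_geno))


def simulate_markers(n_geno: int, n_markers: int, n_chrom: int = 21,
                     maf_range: tuple[float, float] = (0.05, 0.5),
                     missing_rate: float = 0.0, seed: int = 0) -> MarkerMatrix:
    """Independent biallelic markers for inbred lines, coded {-1, 1}
    (heterozygotes can only arise downstream of imputation rounding).

    Allele frequencies are drawn uniformly on ``maf_range`` and assigned
    to either allele at random; markers are allocated to chromosomes
    near-evenly.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if n_markers < n_chrom:
        raise ValueError("need at least one marker per chromosome")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a non-empty subset of (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_markers)
    p = np.where(rng.random(n_markers) < 0.5, maf, 1 - maf)
    calls = np.where(rng.random((n_geno, n_markers)) < p[None, :], 1.0, -1.0)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan
    geno_ids = [f"G{i + 1:04d}" for i in range(n_geno)]
    marker_ids = [f"M{j + 1:05d}" for j in range(n_markers)]
    per_chrom = np.array_split(np.arange(n_markers), n_chrom)
    chrom = np.empty(n_markers, dtype=object)
    for c, idx in enumerate(per_chrom):
        chrom[idx] = f"chr{c + 1:02d}"
    values = pd.DataFrame(calls, index=geno_ids, columns=marker_ids)
    return MarkerMatrix(values=values,
                        chrom=pd.Series(chrom, index=marker_ids, name="chrom"))


def simulate_genetic_values(markers: MarkerMatrix, arch: GeneticArchitecture,
                            seed: int = 0) -> SimTruth:
    """Additive polygenic breeding values with target genetic correlations.

    A shared set of QTL is sampled among the markers and per-trait effects
    are drawn jointly from N(0, rho_G); breeding values M beta are then
    rescaled so each trait's genetic standard deviation matches its spec.
    """
    v = markers.values.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError("markers must be complete (imputed) for genetic values")
    rng = np.random.default_rng(seed)
    k = len(arch.trait_specs)
    n_qtl = min(arch.n_qtl_per_trait, markers.n_markers)
    qtl_idx = np.sort(rng.choice(markers.n_markers, size=n_qtl, replace=False))
    # eigen square root copes with merely PSD rho_G
    w, U = np.linalg.eigh(arch.rho_G)
    root = U * np.sqrt(np.clip(w, 0, None))
    beta = rng.standard_normal((n_qtl, k)) @ root.T
    Zc = v[:, qtl_idx] - v[:, qtl_idx].mean(axis=0)
    raw = Zc @ beta
    scale = np.ones(k)
    for t in range(k):
        sd = raw[:, t].std(ddof=0)
        if sd > 0:
            scale[t] = arch.trait_specs[t].genetic_sd / sd
    tbv = (raw - raw.mean(axis=0)) * scale
    effects = np.zeros((markers.n_markers, k))
    effects[qtl_idx] = beta * scale
    if k > 1 and np.all(tbv.std(axis=0) > 0):
        realized = np.corrcoef(tbv, rowvar=False)
    else:
        realized = np.eye(k)
    names = arch.trait_names
    return SimTruth(
        true_breeding_values=pd.DataFrame(tbv, index=markers.genotypes,
                                          columns=names),
        realized_rho_G=realized,
        qtl_effects=pd.DataFrame(effects, index=markers.values.columns,
                                 columns=names),
        arch=arch)


def _smooth_surface(n_rows: int, n_cols: int, rng) -> np.ndarray:
    """Smooth standardized 2-D fertility surface (Gaussian-filtered noise)."""
    raw = rng.standard_normal((n_rows + 8, n_cols + 8))
    sm = gaussian_filter(raw, sigma=max(min(n_rows, n_cols) / 5.0, 1.5))
    sm = sm[4:4 + n_rows, 4:4 + n_cols]
    sd = sm.std()
    return (sm - sm.mean()) / (sd if sd > 0 else 1.0)


def simulate_field_trial(truth: SimTruth, layout: PRepLayout, year: str,
                         location: str, trait_specs: Sequence[TraitSpec] | None = None,
                         spatial_amplitude: float = 1.0,
                         row_sd_frac: float = 0.4, col_sd_frac: float = 0.4,
                         seed: int = 0,
                         env_offsets: dict | None = None,
                         n_years_ref: int = 4) -> FieldTrial:
    """One p-rep trial: plot value = mean + env offset + breeding value +
    GxE deviation + row + column + smooth surface + residual.

    The spatial surface (shared shape across traits, scaled per trait by
    ``spatial_amplitude * residual_sd``) and the GxE draws are stored on
    ``truth`` for recovery tests.
    """
    arch = truth.arch
    specs = list(trait_specs) if trait_specs is not None else arch.trait_specs
    names = [s.name for s in specs]
    tbv = truth.true_breeding_values[names]
    genos = tbv.index.to_numpy()
    n_geno = len(genos)
    n_plots = layout.n_plots(n_geno)
    if layout.n_rows * layout.n_cols < n_plots:
        raise ValueError(
            f"layout {layout.n_rows}x{layout.n_cols} too small for "
            f"{n_plots} plots")
    rng = np.random.default_rng(seed)
    n_rep = n_plots - n_geno
    rep_geno = rng.choice(genos, size=n_rep, replace=False)
    entries = np.concatenate([genos, rep_geno])
    rng.shuffle(entries)
    # serpentine row-major assignment of plots to field cells
    cells = []
    for r in range(layout.n_rows):
        cs = range(layout.n_cols) if r % 2 == 0 else range(layout.n_cols - 1, -1, -1)
        cells.extend((r + 1, c + 1) for c in cs)
    cells = cells[:n_plots]
    rows = np.array([rc[0] for rc in cells])
    cols = np.array([rc[1] for rc in cells])

    surface = _smooth_surface(layout.n_rows, layout.n_cols, rng)
    truth.spatial_fields[(location, year)] = surface
    k = len(specs)
    gxe_sds = np.array([s.calibrated_gxe_sd(n_years=n_years_ref) for s in specs])
    names_arch = arch.trait_names
    if all(s.name in names_arch for s in specs):
        idx = [names_arch.index(s.name) for s in specs]
        sub = arch.rho_E[np.ix_(idx, idx)]
    else:
        sub = np.eye(k)
    w, U = np.linalg.eigh(sub)
    rootE = U * np.sqrt(np.clip(w, 0, None))
    gxe = (rng.standard_normal((n_geno, k)) @ rootE.T) * gxe_sds[None, :]
    gxe_df = pd.DataFrame(gxe, index=genos, columns=names)
    truth.gxe_values[(location, year)] = gxe_df

    data = {"plot_id": [f"{location}_{year}_{i + 1:04d}" for i in range(n_plots)],
            "genotype": entries, "row": rows, "col": cols}
    seen: dict = {}
    reps = []
    for g in entries:
        seen[g] = seen.get(g, 0) + 1
        reps.append(seen[g])
    data["replicate"] = reps
    df = pd.DataFrame(data)
    for j, s in enumerate(specs):
        if env_offsets is not None and s.name in env_offsets:
            off = float(env_offsets[s.name])
        else:
            off = (rng.normal(0, s.year_sd) if s.year_sd > 0 else 0.0) + \
                  (rng.normal(0, s.location_sd) if s.location_sd > 0 else 0.0)
        row_eff = rng.normal(0, row_sd_frac * s.residual_sd, layout.n_rows)
        col_eff = rng.normal(0, col_sd_frac * s.residual_sd, layout.n_cols)
        resid = rng.normal(0, s.residual_sd, n_plots) if s.residual_sd > 0 \
            else np.zeros(n_plots)
        vals = (s.mean + off
                + tbv[s.name].loc[entries].to_numpy()
                + gxe_df[s.name].loc[entries].to_numpy()
                + row_eff[rows - 1] + col_eff[cols - 1]
                + spatial_amplitude * s.residual_sd * surface[rows - 1, cols - 1]
                + resid)
        df[s.name] = vals
    return FieldTrial(data=df, year=str(year), location=location,
                      trait_names=names)


def default_grid(n_points: int = 700, lo: float = 4000.0,
                 hi: float = 12500.0) -> np.ndarray:
    """Default wavenumber grid (cm^-1), ascending."""
    return np.linspace(lo, hi, n_points)


def default_bands() -> list[BandSpec]:
    """Default absorption-band set: protein content dominates, grain
    characteristics (TW, TKW) contribute, plus year- and noise-driven
    regions.  Grain yield is deliberately absent."""
    return [
        BandSpec(4600.0, 120.0, 1.8, "PC"),
        BandSpec(4870.0, 100.0, 1.2, "PC"),
        BandSpec(6000.0, 200.0, 0.75, "PC"),
        BandSpec(5200.0, 150.0, 0.5, "TW"),
        BandSpec(6900.0, 180.0, 0.4, "TKW"),
        BandSpec(5600.0, 300.0, 0.6, "year"),
        BandSpec(8200.0, 400.0, 0.5, "year"),
        BandSpec(7500.0, 250.0, 0.3, "noise"),
    ]


def _year_driver_value(year: str) -> float:
    """Deterministic standard-normal year effect shared across locations."""
    import zlib
    h = zlib.crc32(str(year).encode()) % (2**31)
    return float(np.random.default_rng(h).standard_normal())


def simulate_spectra(trial: FieldTrial, truth: SimTruth,
                     bands: list[BandSpec] | None = None,
                     grid: np.ndarray | None = None,
                     scatter_sd: float = 0.15, noise_sd: float = 0.01,
                     seed: int = 0) -> SpectraSet:
    """Per-plot grain spectra for a trial; also attached to ``trial``.

    spectrum = a + b * (background + sum_bands amp * driver * gauss) + noise,
    with per-plot affine scatter (a, b).  Trait drivers are z-scored plot
    values; the 'year' driver is a per-year scalar; 'noise' is a per-plot
    standard normal.
    """
    if bands is None:
        bands = default_bands()
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = trial.n_plots
    for b in bands:
        if not (grid[0] <= b.center <= grid[-1]):
            raise ValueError(f"band center {b.center} outside grid "
                             f"[{grid[0]}, {grid[-1]}]")
    background = (0.8 * np.exp(-0.5 * ((grid - 6500.0) / 2500.0) ** 2)
                  + 0.4 * np.exp(-0.5 * ((grid - 10500.0) / 1800.0) ** 2))
    comp = np.tile(background, (n, 1))
    for b in bands:
        prof = np.exp(-0.5 * ((grid - b.center) / b.width) ** 2)
        if b.driver == "year":
            drv = np.full(n, _year_driver_value(trial.year))
        elif b.driver == "noise":
            drv = rng.standard_normal(n)
        elif b.driver in trial.data.columns:
            x = trial.data[b.driver].to_numpy(dtype=float)
            sd = x.std()
            drv = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        else:
            raise ValueError(f"band driver {b.driver!r} not found on trial")
        comp += b.amplitude * drv[:, None] * prof[None, :]
    a = rng.normal(0, scatter_sd, n)
    bmul = 1.0 + rng.normal(0, scatter_sd, n)
    values = a[:, None] + bmul[:, None] * comp
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, values.shape)
    spec = SpectraSet(values=values, grid=grid,
                      sample_ids=trial.data["plot_id"].to_numpy())
    trial.spectra = spec
    return spec


def default_trait_specs() -> list[TraitSpec]:
    """The emulated trait set: grain yield (GY, dt/ha), protein content
    (PC, %), heading date (HD, day of year), plant height (PH, cm), test
    weight (TW, kg/hl) and thousand-kernel weight (TKW, g), with
    heritability targets in the ranges of routine winter-wheat trials."""
    return [
        TraitSpec("GY", 0.35, 80.0, 3.0, 6.0, 4.0, 4.0),
        TraitSpec("PC", 0.50, 14.0, 0.7, 0.8, 0.5, 0.35),
        TraitSpec("HD", 0.85, 150.0, 3.0, 3.0, 2.0, 1.2),
        TraitSpec("PH", 0.72, 95.0, 6.0, 5.0, 4.0, 3.0),
        TraitSpec("TW", 0.74, 78.0, 2.0, 1.5, 1.0, 1.0),
        TraitSpec("TKW", 0.75, 45.0, 3.0, 2.0, 1.5, 1.5),
    ]


def default_architecture(n_qtl_per_trait: int = 300) -> GeneticArchitecture:
    """Default joint architecture.

    The GY-PC genetic correlation is strongly negative (the starch/protein
    trade-off is genetically entrenched), while their GxE deviations are
    weakly *positively* correlated: a favourable season or nitrogen status
    lifts both yield and protein.  The net phenotypic correlation of
    across-year means then lands in the weak-to-moderate negative range
    typical of winter-wheat breeding trials.
    """
    #          GY     PC     HD     PH     TW    TKW
    rho = np.array([
        [1.00, -0.80, -0.10, 0.00, 0.10, 0.10],
        [-0.80, 1.00, 0.00, 0.20, 0.10, 0.10],
        [-0.10, 0.00, 1.00, 0.10, 0.00, 0.00],
        [0.00, 0.20, 0.10, 1.00, 0.00, 0.10],
        [0.10, 0.10, 0.00, 0.00, 1.00, 0.30],
        [0.10, 0.10, 0.00, 0.10, 0.30, 1.00],
    ])
    rho_e = 0.1 * rho + 0.9 * np.eye(6)
    rho_e[0, 1] = rho_e[1, 0] = 0.10
    return GeneticArchitecture(trait_specs=default_trait_specs(), rho_G=rho,
                               n_qtl_per_trait=n_qtl_per_trait, rho_E=rho_e)


@dataclass
class SyntheticStudy:
    """Bundle of a complete simulated study."""

    markers: MarkerMatrix            # raw (may contain missing calls)
    markers_filtered: MarkerMatrix   # imputed + MAF-filtered
    truth: SimTruth
    trials: list
    years: tuple
    locations: tuple
    grid: np.ndarray

    @property
    def genotypes(self) -> np.ndarray:
        return self.truth.true_breeding_values.index.to_numpy()

    def trials_at(self, location: str) -> list:
        return [t for t in self.trials if t.location == location]


def scenario_default(seed: int = 0, n_geno: int = 461, n_markers: int = 6722,
                     n_chrom: int = 21,
                     years: Sequence[str] = DEFAULT_YEARS,
                     locations: Sequence[str] = DEFAULT_LOCATIONS,
                     rep_fraction: float = 0.25,
                     grid_points: int = 700,
                     marker_missing_rate: float = 0.02,
                     arch: GeneticArchitecture | None = None,
                     spatial_amplitude: float = 1.0,
                     scatter_sd: float = 0.15, noise_sd: float = 0.01,
                     snv: bool = True) -> SyntheticStudy:
    """The default synthetic study: a p-rep trial per location-year with
    plot spectra, matching the scale and structure of a four-year,
    three-location breeding series (sizes configurable for tests).

    Year and location offsets per trait are drawn once and shared across
    trials so that year effects are consistent between locations.  Plot
    spectra are SNV-normalized when ``snv`` is True (the plot-level
    normalization the adjustment stage expects).
    """
    rng = np.random.default_rng(seed)
    if arch is None:
        arch = default_architecture()
    markers = simulate_markers(n_geno, n_markers, n_chrom,
                               missing_rate=marker_missing_rate,
                               seed=int(rng.integers(2**31)))
    filtered = maf_filter(impute_markers(markers, "column_mode"))
    truth = simulate_genetic_values(filtered, arch,
                                    seed=int(rng.integers(2**31)))
    n_plots = n_geno + int(round(rep_fraction * n_geno))
    n_rows = int(np.ceil(np.sqrt(n_plots)))
    n_cols = int(np.ceil(n_plots / n_rows))
    layout = PRepLayout(n_rows=n_rows, n_cols=n_cols, rep_fraction=rep_fraction)
    year_off = {y: {s.name: rng.normal(0, s.year_sd) for s in arch.trait_specs}
                for y in years}
    loc_off = {L: {s.name: rng.normal(0, s.location_sd) for s in arch.trait_specs}
               for L in locations}
    grid = default_grid(grid_points)
    trials = []
    for L in locations:
        for y in years:
            offs = {s.name: year_off[y][s.name] + loc_off[L][s.name]
                    for s in arch.trait_specs}
            trial = simulate_field_trial(
                truth, layout, year=y, location=L,
                spatial_amplitude=spatial_amplitude,
                seed=int(rng.integers(2**31)), env_offsets=offs,
                n_years_ref=len(years))
            simulate_spectra(trial, truth, grid=grid, scatter_sd=scatter_sd,
                             noise_sd=noise_sd,
                             seed=int(rng.integers(2**31)))
            if snv:
                trial.spectra = snv_normalize(trial.spectra)
            trials.append(trial)
    return SyntheticStudy(markers=markers, markers_filtered=filtered,
                          truth=truth, trials=trials, years=tuple(years),
                          locations=tuple(locations), grid=grid)
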