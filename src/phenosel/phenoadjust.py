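"""Two-stage adjustment of plot-level field-trial data.

Stage 1, per trial (one location-year): a spatial mixed model

    y_ijk = mu + g_i + r_j + c_k + sp_jk + e_ijk

with random row and column effects and a two-dimensional tensor-product
B-spline surface sp_jk (single isotropic variance).  With genotypes
fixed it yields per-trial BLUEs; with genotypes random it yields the
variance components behind single-trial repeatability

    rep2 = sigma2_G / (sigma2_G + sigma2_e / r_bar)

where r_bar is the effective replication of the p-rep design (harmonic
mean of per-genotype plot counts by default).

Stage 2, per location: the per-year BLUEs enter

    y_ij = mu + g_i + y_j + e_ij

with random year effects; genotypes random give broad-sense heritability
H2 (same algebra, r_bar now the effective number of years per genotype),
genotypes fixed give across-year location BLUEs.  The same machinery is
applied independently to every spectral wavenumber; wavenumbers whose
fit does not converge fall back to the mean over all entries and the
substitution is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .mixedmodel import MixedREML, MixedREMLResults, RandomTerm, VarianceComponents
from .spectra import SpectraSet

__all__ = [
    "FieldTrial",
    "AdjustedMeans",
    "Stage1Result",
    "Stage2Result",
    "fit_stage1",
    "fit_stage2",
    "effective_replication",
    "repeatability",
    "heritability",
    "adjust_spectra",
    "two_stage_adjust",
    "SpectraAdjustment",
    "TwoStageResult",
]

logger = logging.getLogger(__name__)

PLOT_COLUMNS = ("plot_id", "genotype", "row", "col", "replicate")


@dataclass
class FieldTrial:
    """Plot-level records for one trial (one location in one year).

    ``data`` holds the design columns (plot_id, genotype, row, col,
    replicate) plus one column per trait; ``spectra`` optionally holds the
    per-plot NIR spectra aligned with ``data['plot_id']``.
    """

    data: pd.DataFrame
    year: str
    location: str
    trait_names: list = field(default_factory=list)
    spectra: SpectraSet | None = None

    def __post_init__(self) -> None:
        missing = [c for c in PLOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"plot table is missing columns {missing}")
        dup = self.data.duplicated(subset=["row", "col"])
        if dup.any():
            ids = self.data.loc[dup, "plot_id"].tolist()[:5]
            raise ValueError(f"duplicate (row, col) coordinates, e.g. plots {ids}")
        if not self.trait_names:
            self.trait_names = [c for c in self.data.columns
                                if c not in PLOT_COLUMNS]
        if self.spectra is not None:
            if self.spectra.n_samples != len(self.data):
                raise ValueError("spectra rows must match plot count")

    @property
    def n_plots(self) -> int:
        return len(self.data)

    @property
    def genotypes(self) -> np.ndarray:
        return self.data["genotype"].unique()

    def genotype_counts(self) -> pd.Series:
        return self.data["genotype"].value_counts()


@dataclass
class AdjustedMeans:
    """Genotype BLUEs (per trial, or per location across years)."""

    blues: pd.DataFrame | pd.Series
    level: str
    se: pd.DataFrame | pd.Series | None = None


@dataclass
class Stage1Result:
    varcomp: VarianceComponents | None
    means: AdjustedMeans | None
    reml: MixedREMLResults


@dataclass
class Stage2Result:
    varcomp: VarianceComponents | None
    means: AdjustedMeans | None
    reml: MixedREMLResults


def effective_replication(counts, method: str = "harmonic") -> float:
    """Effective average replication factor r_bar from per-genotype
    observation counts (harmonic mean by default)."""
    if isinstance(counts, FieldTrial):
        counts = counts.genotype_counts()
    c = np.asarray(counts, dtype=float)
    if len(c) == 0:
        raise ValueError("no genotypes")
    if method == "harmonic":
        return float(len(c) / np.sum(1.0 / c))
    if method == "arithmetic":
        return float(np.mean(c))
    raise ValueError(f"unknown method {method!r}")


def repeatability(vc: VarianceComponents) -> float:
    """Single-trial repeatability rep2 = s2_G / (s2_G + s2_e / r_bar)."""
    if vc.sigma2_g == 0 and vc.sigma2_e == 0:
        raise ValueError("both variance components are zero; rep2 undefined")
    return vc.sigma2_g / (vc.sigma2_g + vc.sigma2_e / vc.r_bar)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H2 on an entry-mean basis; the same
    algebra as repeatability with r_bar the effective number of years."""
    return repeatability(vc)


def _bspline_basis(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Clamped B-spline basis evaluated at x, with n_basis functions."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        hi = lo + 1.0
    n_basis = max(n_basis, degree + 1)
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    xx = np.clip(x, lo, hi - 1e-9 * (hi - lo))
    return BSpline.design_matrix(xx, t, degree, extrapolate=False).toarray()


def _spline_design(rows: np.ndarray, cols: np.ndarray,
                   spline_basis: tuple[int, int] | None) -> np.ndarray:
    if spline_basis is None:
        nr = min(10, int(np.ceil(len(np.unique(rows)) / 2)))
        nc = min(10, int(np.ceil(len(np.unique(cols)) / 2)))
        spline_basis = (nr, nc)
    Br = _bspline_basis(rows.astype(float), spline_basis[0])
    Bc = _bspline_basis(cols.astype(float), spline_basis[1])
    # row-wise tensor product
    return np.einsum("ij,ik->ijk", Br, Bc).reshape(len(rows), -1)


def _onehot(codes: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    cat = pd.Categorical(codes)
    Z = np.zeros((len(cat), len(cat.categories)))
    Z[np.arange(len(cat)), cat.codes] = 1.0
    return Z, np.asarray(cat.categories)


def stage1_design(trial: FieldTrial, genotype_role: str = "fixed",
                  spline_basis: tuple[int, int] | None = None,
                  mask: np.ndarray | None = None):
    """Build the stage-1 spatial REML design (reusable across responses).

    Returns ``(model, genotype_labels)`` where ``model`` is a
    :class:`MixedREML` with no response set.
    """
    df = trial.data if mask is None else trial.data.loc[mask]
    rows = df["row"].to_numpy()
    cols = df["col"].to_numpy()
    if len(np.unique(rows)) < 2 or len(np.unique(cols)) < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    Zg, genos = _onehot(df["genotype"])
    if len(genos) < 2:
        raise ValueError("singular design: need at least 2 genotypes")
    Zr, _ = _onehot(df["row"])
    Zc, _ = _onehot(df["col"])
    Zs = _spline_design(rows, cols, spline_basis)
    if genotype_role == "fixed":
        X = Zg
        terms = [RandomTerm("row", Zr), RandomTerm("col", Zc),
                 RandomTerm("spline", Zs)]
    elif genotype_role == "random":
        X = np.ones((len(df), 1))
        terms = [RandomTerm("genotype", Zg), RandomTerm("row", Zr),
                 RandomTerm("col", Zc), RandomTerm("spline", Zs)]
    else:
        raise ValueError("genotype_role must be 'fixed' or 'random'")
    return MixedREML(None, X, terms), genos


def fit_stage1(trial: FieldTrial, response: str,
               genotype_role: str = "fixed",
               spline_basis: tuple[int, int] | None = None) -> Stage1Result:
    """Stage-1 spatial fit of one trait on one trial."""
    if response not in trial.data.columns:
        raise ValueError(f"response {response!r} not on plot table")
    y_all = trial.data[response]
    mask = y_all.notna().to_numpy()
    dropped = int((~mask).sum())
    if dropped:
        logger.info("stage1 %s/%s %s: dropped %d plots with missing response",
                    trial.location, trial.year, response, dropped)
    model, genos = stage1_design(trial, genotype_role, spline_basis,
                                 mask=mask if dropped else None)
    model.set_response(y_all.to_numpy(dtype=float)[mask])
    res = model.fit()
    counts = trial.data.loc[mask, "genotype"].value_counts()
    r_bar = effective_replication(counts)
    if genotype_role == "random":
        vc = res.variance_components(r_bar=r_bar)
        return Stage1Result(varcomp=vc, means=None, reml=res)
    blues = pd.Series(res.beta, index=genos, name=response)
    se = pd.Series(res.beta_se(), index=genos, name=response)
    return Stage1Result(
        varcomp=None,
        means=AdjustedMeans(blues=blues, level="trial", se=se),
        reml=res)


def _stage2_table(trial_blues: dict) -> pd.DataFrame:
    frames = []
    for year, s in trial_blues.items():
        f = pd.DataFrame({"genotype": s.index, "value": np.asarray(s)})
        f["year"] = str(year)
        frames.append(f)
    long = pd.concat(frames, ignore_index=True).dropna(subset=["value"])
    return long


def fit_stage2(trial_blues: dict, genotype_role: str = "fixed") -> Stage2Result:
    """Across-year fit per location from per-year genotype BLUEs.

    ``trial_blues`` maps year -> Series of genotype BLUEs.
    """
    long = _stage2_table(trial_blues)
    n_years = long["year"].nunique()
    if genotype_role == "random" and n_years < 2:
        raise ValueError("need >= 2 years to separate year variance")
    Zg, genos = _onehot(long["genotype"])
    Zy, _ = _onehot(long["year"])
    y = long["value"].to_numpy(dtype=float)
    counts = long.groupby("genotype").size()
    r_bar = effective_replication(counts)
    if genotype_role == "random":
        model = MixedREML(y, np.ones((len(y), 1)),
                          [RandomTerm("genotype", Zg), RandomTerm("year", Zy)])
        res = model.fit()
        vc = res.variance_components(r_bar=r_bar)
        vc.extra["sigma2_y"] = vc.extra.pop("year")
        return Stage2Result(varcomp=vc, means=None, reml=res)
    model = MixedREML(y, Zg, [RandomTerm("year", Zy)])
    res = model.fit()
    blues = pd.Series(res.beta, index=genos)
    se = pd.Series(res.beta_se(), index=genos)
    return Stage2Result(
        varcomp=None,
        means=AdjustedMeans(blues=blues, level="location-across-years", se=se),
        reml=res)


# ---------------------------------------------------------------------------
# Whole-pipeline helpers: traits and spectra
# ---------------------------------------------------------------------------


@dataclass
class TwoStageResult:
    """Adjusted means and variance summaries for a set of traits."""

    location_blues: dict            # location -> DataFrame genotype x trait
    repeatability: pd.DataFrame     # location, year, trait, rep2, converged
    heritability: pd.DataFrame      # location, trait, H2, sigma2_g, sigma2_y, sigma2_e


def two_stage_adjust(trials: list[FieldTrial], traits: list[str] | None = None,
                     spline_basis: tuple[int, int] | None = None
                     ) -> TwoStageResult:
    """Run the full two-stage trait adjustment over a list of trials."""
    if traits is None:
        traits = trials[0].trait_names
    by_loc: dict[str, list[FieldTrial]] = {}
    for t in trials:
        by_loc.setdefault(t.location, []).append(t)
    rep_rows, h2_rows, loc_blues = [], [], {}
    for loc, loc_trials in by_loc.items():
        blues_frames = {}
        for trait in traits:
            per_year = {}
            for trial in loc_trials:
                if trial.data[trait].notna().sum() == 0:
                    continue
                r1f = fit_stage1(trial, trait, "fixed", spline_basis)
                per_year[trial.year] = r1f.means.blues
                r1r = fit_stage1(trial, trait, "random", spline_basis)
                rep_rows.append({
                    "location": loc, "year": trial.year, "trait": trait,
                    "rep2": repeatability(r1r.varcomp),
                    "sigma2_g": r1r.varcomp.sigma2_g,
                    "sigma2_e": r1r.varcomp.sigma2_e,
                    "r_bar": r1r.varcomp.r_bar,
                    "converged": r1r.varcomp.converged})
            r2r = fit_stage2(per_year, "random")
            h2_rows.append({
                "location": loc, "trait": trait,
                "H2": heritability(r2r.varcomp),
                "sigma2_g": r2r.varcomp.sigma2_g,
                "sigma2_y": r2r.varcomp.extra.get("sigma2_y", np.nan),
                "sigma2_e": r2r.varcomp.sigma2_e,
                "r_bar": r2r.varcomp.r_bar,
                "converged": r2r.varcomp.converged})
            r2f = fit_stage2(per_year, "fixed")
            blues_frames[trait] = r2f.means.blues
        loc_blues[loc] = pd.DataFrame(blues_frames)
    return TwoStageResult(location_blues=loc_blues,
                          repeatability=pd.DataFrame(rep_rows),
                          heritability=pd.DataFrame(h2_rows))


@dataclass
class SpectraAdjustment:
    """Per-location genotype x wavenumber spectral BLUEs with a log of
    mean-substituted wavenumbers."""

    blues: dict                     # location -> DataFrame genotype x wavenumber
    grid: np.ndarray
    substitutions: list             # (location, stage, year-or-'across', wavenumber)

    def spectra_set(self, location: str) -> SpectraSet:
        f = self.blues[location]
        return SpectraSet(values=f.to_numpy(), grid=self.grid,
                          sample_ids=f.index.to_numpy(),
                          provenance=[("snv", {}),
                                      ("adjusted", {"location": location})])


def spectra_repeatability(trial: FieldTrial,
                          spline_basis: tuple[int, int] | None = None,
                          wavenumber_stride: int = 1) -> pd.Series:
    """Per-wavenumber single-trial repeatability from random-genotype
    stage-1 fits (non-converged wavenumbers yield NaN)."""
    if trial.spectra is None:
        raise ValueError("trial has no spectra")
    model, _ = stage1_design(trial, "random", spline_basis)
    counts = trial.genotype_counts()
    r_bar = effective_replication(counts)
    grid = trial.spectra.grid[::wavenumber_stride]
    vals = []
    theta = None
    for w, wav in enumerate(grid):
        y = trial.spectra.values[:, w * wavenumber_stride]
        if np.ptp(y) < 1e-12:
            vals.append(np.nan)
            continue
        res = model.refit(y, start=theta, xatol=2e-3, fatol=1e-7)
        if not res.converged:
            vals.append(np.nan)
            continue
        theta = res.theta
        vc = res.variance_components(r_bar=r_bar)
        vals.append(repeatability(vc))
    return pd.Series(vals, index=grid, name="rep2")


def adjust_spectra(trials: list[FieldTrial],
                   spline_basis: tuple[int, int] | None = None
                   ) -> SpectraAdjustment:
    """Per-wavenumber two-stage adjustment of plot-level spectra.

    Expects SNV-normalized plot spectra on every trial (checked via
    provenance).  Non-converged or degenerate wavenumber fits fall back to
    the plain mean over all entries, and each substitution is logged.
    """
    by_loc: dict[str, list[FieldTrial]] = {}
    grid = None
    for t in trials:
        if t.spectra is None:
            raise ValueError(f"trial {t.location}/{t.year} has no spectra")
        if "snv" not in [s[0] for s in t.spectra.provenance]:
            raise ValueError("plot spectra must be SNV-normalized first")
        if grid is None:
            grid = t.spectra.grid
        elif not np.array_equal(grid, t.spectra.grid):
            raise ValueError("all trials must share a wavenumber grid")
        by_loc.setdefault(t.location, []).append(t)
    subs = []
    out = {}
    for loc, loc_trials in by_loc.items():
        per_year_blues = {}
        for trial in loc_trials:
            model, genos = stage1_design(trial, "fixed", spline_basis)
            V = trial.spectra.values
            blues = np.empty((len(genos), V.shape[1]))
            theta = None
            for w in range(V.shape[1]):
                y = V[:, w]
                if np.ptp(y) < 1e-12:
                    blues[:, w] = y.mean()
                    subs.append((loc, "stage1", trial.year, float(grid[w])))
                    continue
                res = model.refit(y, start=theta, xatol=2e-3, fatol=1e-7)
                if res.converged:
                    theta = res.theta
                    blues[:, w] = res.beta
                else:
                    blues[:, w] = y.mean()
                    subs.append((loc, "stage1", trial.year, float(grid[w])))
            per_year_blues[trial.year] = pd.DataFrame(
                blues, index=genos, columns=grid)
        # stage 2 across years, per wavenumber
        long0 = pd.concat(
            [f.assign(year=yr, genotype=f.index)
             for yr, f in per_year_blues.items()], ignore_index=True)
        Zg, genos2 = _onehot(long0["genotype"])
        Zy, _ = _onehot(long0["year"])
        model2 = MixedREML(None, Zg, [RandomTerm("year", Zy)])
        blues2 = np.empty((len(genos2), len(grid)))
        theta = None
        for w, wav in enumerate(grid):
            y = long0[wav].to_numpy(dtype=float)
            if np.ptp(y) < 1e-12:
                blues2[:, w] = y.mean()
                subs.append((loc, "stage2", "across", float(wav)))
                continue
            res = model2.refit(y, start=theta, xatol=2e-3, fatol=1e-7)
            if res.converged:
                theta = res.theta
                blues2[:, w] = res.beta
            else:
                blues2[:, w] = y.mean()
                subs.append((loc, "stage2", "across", float(wav)))
        out[loc] = pd.DataFrame(blues2, index=genos2, columns=grid)
        for s in subs:
            logger.info("mean-substituted wavenumber: %s", s)
    return SpectraAdjustment(blues=out, grid=np.asarray(grid), substitutions=subs)
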