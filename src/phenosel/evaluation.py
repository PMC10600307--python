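"""Cross-validated prediction ability, predictor bias, and selection
indices.

The experimental design: for each sampled population size, draw a random
subset of genotypes, split it into five folds, train the prediction
model (kernel BLUP on G or H, ridge-regression BLUP, or PLSR) on four
folds and predict the fifth, rotating until every fold was validated
once; repeat the sampling ``n_reps`` times.

Prediction ability is the Pearson correlation of predicted and observed
values in the validation fold.  Predictor bias is the correlation of the
predictions with a *secondary* trait (grain protein content), compared
with the phenotypic correlation of target and secondary trait on the
complete set — a predictor is biased when its predictions correlate with
the secondary trait more strongly than the phenotypes themselves do.

Selection indices: GYD (grain yield deviation, the residual of GY
regressed on PC), PY (protein yield, GY * PC / 100), and EWPY (the
per-location sum of z-scores of GY and PC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import KernelBLUP, PredictionSet, plsr, rr_blup

__all__ = [
    "CVDesign",
    "CVBiasReport",
    "IndexSet",
    "make_cv_design",
    "run_cv",
    "prediction_ability",
    "bias_correlation",
    "compute_indices",
    "index_bias_analysis",
    "summarize_cv",
]

logger = logging.getLogger(__name__)


@dataclass
class CVDesign:
    """Fold assignments for repeated, size-stratified five-fold CV."""

    k: int
    sizes: list
    n_reps: int
    seed: int
    assignments: dict   # (size, rep) -> Series genotype -> fold

    def folds(self, size: int, rep: int):
        s = self.assignments[(size, rep)]
        for f in range(self.k):
            val = s.index[s == f]
            train = s.index[s != f]
            yield f, list(train), list(val)


@dataclass
class CVBiasReport:
    """Per-fold CV records plus the complete-set phenotypic references."""

    records: pd.DataFrame
    reference: dict = field(default_factory=dict)

    def aggregate(self, by=("model", "size")) -> pd.DataFrame:
        g = self.records.groupby(list(by))
        out = g["ability"].agg(["mean", "min", "max"])
        for col in ("bias", "bias_abs", "cor_gy", "cor_pc"):
            if col in self.records.columns:
                out[f"{col}_mean"] = g[col].mean()
        return out.reset_index()


@dataclass
class IndexSet:
    """Selection indices per location with their fitting constants."""

    values: pd.DataFrame            # genotype x {GYD, PY, EWPY}
    alpha: float
    beta: float
    mu_gy: float
    sigma_gy: float
    mu_pc: float
    sigma_pc: float


def make_cv_design(genotypes, sizes=(100, 200, 300, 400), n_reps: int = 20,
                   k: int = 5, seed: int = 0) -> CVDesign:
    """Random size-stratified fold assignments.

    Each (size, rep) samples ``size`` genotypes without replacement and
    partitions them into k folds whose sizes differ by at most one.
    """
    genotypes = np.asarray(genotypes)
    sizes = list(sizes)
    if max(sizes) > len(genotypes):
        raise ValueError("largest size exceeds population")
    if min(sizes) < k:
        raise ValueError("size must be >= number of folds")
    rng = np.random.default_rng(seed)
    assignments = {}
    for size in sizes:
        for rep in range(n_reps):
            sample = rng.choice(genotypes, size=size, replace=False)
            folds = np.resize(np.arange(k), size)
            rng.shuffle(folds)
            assignments[(size, rep)] = pd.Series(folds, index=sample)
    return CVDesign(k=k, sizes=sizes, n_reps=n_reps, seed=seed,
                    assignments=assignments)


def _fit_predict(model: str, y: pd.Series, train, val, K=None, Z=None,
                 X=None, seed: int = 0):
    y_tr = y.loc[train].to_numpy(dtype=float)
    if model == "kernel_blup":
        K_tt = K.loc[train, train].to_numpy()
        fit = KernelBLUP(y_tr, K_tt).fit()
        return fit.predict(K.loc[val, train].to_numpy())
    if model == "rrblup":
        Z_tr = Z.loc[train].to_numpy(dtype=float)
        mu = Z_tr.mean(axis=0)
        fit = KernelBLUP(y_tr, (Z_tr - mu) @ (Z_tr - mu).T / Z_tr.shape[1]).fit()
        lam_m = fit.lam * Z_tr.shape[1]
        _, preds = rr_blup(y_tr, Z_tr - mu, lam_m,
                           Z_new=Z.loc[val].to_numpy(dtype=float) - mu)
        return preds.predicted
    if model == "plsr":
        p, _ = plsr(X.loc[train].to_numpy(dtype=float), y_tr,
                    X.loc[val].to_numpy(dtype=float), seed=seed)
        return p
    raise ValueError(f"unknown model {model!r}")


def run_cv(design: CVDesign, y: pd.Series, K=None, model: str = "kernel_blup",
           Z=None, X=None, tag: str | None = None) -> list[PredictionSet]:
    """Run the CV design: one PredictionSet per (size, rep, fold).

    Degenerate folds (constant predictions/observations) are kept in the
    output but flagged and excluded later by the correlation helpers;
    fitting failures are logged and the fold skipped.
    """
    missing = set()
    for (size, rep), s in design.assignments.items():
        missing |= set(s.index) - set(y.index)
    if missing:
        raise ValueError(f"response missing for designed genotypes: "
                         f"{sorted(missing)[:5]}")
    out = []
    tag = tag or model
    for size in design.sizes:
        for rep in range(design.n_reps):
            for f, train, val in design.folds(size, rep):
                try:
                    pred = _fit_predict(model, y, train, val, K=K, Z=Z, X=X,
                                        seed=design.seed + 31 * rep + f)
                except Exception as exc:   # noqa: BLE001 - logged, fold skipped
                    logger.warning("fold skipped (size=%s rep=%s fold=%s): %s",
                                   size, rep, f, exc)
                    continue
                out.append(PredictionSet(
                    ids=np.asarray(val), predicted=pred,
                    observed=y.loc[val].to_numpy(dtype=float),
                    model=tag, fold=f, rep=rep, size=size))
    return out


def prediction_ability(preds: PredictionSet) -> float:
    """Pearson correlation of predicted vs observed in a validation fold."""
    if preds.observed is None:
        raise ValueError("prediction set has no observed values")
    if len(preds.predicted) < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(preds.predicted) == 0 or np.ptp(preds.observed) == 0:
        raise ValueError("degenerate fold: constant predictions or observations")
    return float(stats.pearsonr(preds.predicted, preds.observed)[0])


def bias_correlation(preds: PredictionSet, secondary: pd.Series) -> float:
    """Correlation of the fold's predictions with a secondary trait."""
    sec = secondary.loc[preds.ids].to_numpy(dtype=float)
    if np.ptp(preds.predicted) == 0 or np.ptp(sec) == 0:
        raise ValueError("degenerate fold: constant predictions or secondary")
    return float(stats.pearsonr(preds.predicted, sec)[0])


def cv_bias_report(pred_sets: list[PredictionSet], secondary: pd.Series,
                   primary_full: pd.Series, secondary_full: pd.Series,
                   location: str = "", trait: str = "") -> CVBiasReport:
    """Assemble per-fold ability and bias records with the complete-set
    phenotypic reference correlation."""
    common = primary_full.index.intersection(secondary_full.index)
    ref = float(stats.pearsonr(primary_full.loc[common],
                               secondary_full.loc[common])[0])
    rows = []
    dropped = 0
    for p in pred_sets:
        try:
            ability = prediction_ability(p)
            bias = bias_correlation(p, secondary)
        except ValueError:
            dropped += 1
            continue
        rows.append({"model": p.model, "trait": trait, "location": location,
                     "size": p.size, "rep": p.rep, "fold": p.fold,
                     "ability": ability, "bias": bias, "bias_abs": abs(bias),
                     "reference": ref})
    if dropped:
        logger.info("dropped %d degenerate folds", dropped)
    return CVBiasReport(records=pd.DataFrame(rows),
                        reference={"phenotypic": ref, "dropped_folds": dropped})


def compute_indices(gy: pd.Series, pc: pd.Series) -> IndexSet:
    """Selection indices from paired GY and PC BLUEs of one location.

    GYD: residuals of the OLS regression of GY on PC (orthogonal to PC on
    the fitting set).  PY: GY * PC / 100 (dt/ha with PC in percent).
    EWPY: z(GY) + z(PC), mean zero by construction.
    """
    common = gy.index.intersection(pc.index)
    g = gy.loc[common].to_numpy(dtype=float)
    p = pc.loc[common].to_numpy(dtype=float)
    if np.ptp(p) == 0:
        raise ValueError("constant PC: GYD regression undefined")
    if np.ptp(g) == 0:
        raise ValueError("constant GY")
    beta, alpha = np.polyfit(p, g, 1)
    gyd = g - (alpha + beta * p)
    py = g * p / 100.0
    mu_g, sd_g = g.mean(), g.std(ddof=0)
    mu_p, sd_p = p.mean(), p.std(ddof=0)
    ewpy = (g - mu_g) / sd_g + (p - mu_p) / sd_p
    vals = pd.DataFrame({"GYD": gyd, "PY": py, "EWPY": ewpy}, index=common)
    return IndexSet(values=vals, alpha=float(alpha), beta=float(beta),
                    mu_gy=float(mu_g), sigma_gy=float(sd_g),
                    mu_pc=float(mu_p), sigma_pc=float(sd_p))


def index_bias_analysis(pred_sets: list[PredictionSet], gy: pd.Series,
                        pc: pd.Series, location: str = "",
                        index_name: str = "") -> CVBiasReport:
    """Per-fold correlations of index predictions with GY and PC, with
    complete-set phenotypic references."""
    common = gy.index.intersection(pc.index)
    rows = []
    dropped = 0
    for p in pred_sets:
        if np.ptp(p.predicted) == 0:
            dropped += 1
            continue
        gyv = gy.loc[p.ids].to_numpy(dtype=float)
        pcv = pc.loc[p.ids].to_numpy(dtype=float)
        if np.ptp(gyv) == 0 or np.ptp(pcv) == 0:
            dropped += 1
            continue
        rows.append({
            "model": p.model, "trait": index_name, "location": location,
            "size": p.size, "rep": p.rep, "fold": p.fold,
            "ability": prediction_ability(p),
            "cor_gy": float(stats.pearsonr(p.predicted, gyv)[0]),
            "cor_pc": float(stats.pearsonr(p.predicted, pcv)[0])})
    # phenotypic reference: correlations of the index itself with GY / PC
    idx = compute_indices(gy, pc).values[index_name] if index_name in \
        ("GYD", "PY", "EWPY") else None
    ref = {}
    if idx is not None:
        ref = {"cor_gy": float(stats.pearsonr(idx.loc[common],
                                              gy.loc[common])[0]),
               "cor_pc": float(stats.pearsonr(idx.loc[common],
                                              pc.loc[common])[0]),
               "dropped_folds": dropped}
    return CVBiasReport(records=pd.DataFrame(rows), reference=ref)


def summarize_cv(reports: list[CVBiasReport]) -> pd.DataFrame:
    """Tidy long-format summary across reports (mean/min/max by model and
    size, with references attached)."""
    frames = []
    for r in reports:
        agg = r.aggregate()
        for k, v in r.reference.items():
            if isinstance(v, float):
                agg[f"ref_{k}"] = v
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)
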