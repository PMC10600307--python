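"""Chemometric pretreatment of NIR spectra and the spectral kernel H.

The pretreatments are the standard chemometric set: SNV (standard normal
variate, per-sample centering/scaling that removes affine light-scatter),
polynomial detrending, and Savitzky-Golay derivative filtering.  From
pretreated, doubly standardized genotype spectra S (one row per genotype,
l wavenumbers) the spectral relationship matrix is

    H = S S' / l

which, because rows are standardized with the population-sd convention,
has unit diagonal and off-diagonal entries equal to Pearson correlations
of genotype spectra — the NIRS analogue of a genomic relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

__all__ = [
    "SpectraSet",
    "RelationshipMatrix",
    "snv_normalize",
    "detrend",
    "savitzky_golay",
    "standardize_for_kernel",
    "build_h_matrix",
    "pretreat",
    "PRETREATMENTS",
]

PRETREATMENTS = ("means", "detrend", "sg1", "sg2")


@dataclass
class SpectraSet:
    """Sample x wavenumber spectra with pretreatment provenance.

    ``grid`` must be strictly monotone increasing (a descending instrument
    grid is reversed on construction and the reversal recorded).
    """

    values: np.ndarray
    grid: np.ndarray
    sample_ids: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x wavenumbers)")
        if len(self.grid) != self.values.shape[1]:
            raise ValueError("grid length must equal column count")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids must match row count")
        d = np.diff(self.grid)
        if np.all(d < 0):
            self.grid = self.grid[::-1].copy()
            self.values = self.values[:, ::-1].copy()
            self.provenance = list(self.provenance) + [("reverse_grid", {})]
        elif not np.all(d > 0):
            raise ValueError("wavenumber grid must be strictly monotone")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.values.shape[1]

    def _derive(self, values, grid=None, step=None) -> "SpectraSet":
        return SpectraSet(
            values=values,
            grid=self.grid if grid is None else grid,
            sample_ids=self.sample_ids.copy(),
            provenance=list(self.provenance) + ([step] if step else []))

    def to_frame(self) -> pd.DataFrame:
        f = pd.DataFrame(self.values, columns=self.grid)
        f.insert(0, "sample_id", self.sample_ids)
        return f


@dataclass
class RelationshipMatrix:
    """Symmetric PSD genotype relationship matrix (G from markers, H from
    spectra) with its provenance and predictor count."""

    values: np.ndarray
    labels: np.ndarray
    source: str
    n_predictors: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if len(set(map(str, self.labels))) != n:
            raise ValueError("labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric (1e-10)")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError(
                f"relationship matrix is not PSD (min eigenvalue {w.min():.3g})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())


def snv_normalize(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: each sample scaled to mean 0, variance 1
    (sample-variance convention, divisor n-1)."""
    v = spectra.values
    sd = v.std(axis=1, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        ids = ", ".join(map(str, spectra.sample_ids[bad][:5]))
        raise ValueError(f"zero variance sample(s), cannot SNV-normalize: {ids}")
    out = (v - v.mean(axis=1, keepdims=True)) / sd[:, None]
    return spectra._derive(out, step=("snv", {}))


def detrend(spectra: SpectraSet, poly_order: int = 2) -> SpectraSet:
    """Remove, per sample, the OLS polynomial fit of the spectrum on the
    wavenumber grid (default quadratic)."""
    if poly_order >= spectra.n_wavenumbers:
        raise ValueError("poly_order must be < number of wavenumbers")
    x = spectra.grid
    # orthonormal polynomial basis for numerical stability
    B = np.vander((x - x.mean()) / (x.std() + 1e-30), poly_order + 1,
                  increasing=True)
    Q, _ = np.linalg.qr(B)
    v = spectra.values
    out = v - (v @ Q) @ Q.T
    return spectra._derive(out, step=("detrend", {"poly_order": poly_order}))


def savitzky_golay(spectra: SpectraSet, window: int = 37,
                   deriv_order: int = 1,
                   poly_order: int | None = None) -> SpectraSet:
    """Savitzky-Golay derivative filter on a uniform grid.

    Local least-squares polynomial of order ``poly_order`` (default
    deriv_order + 1) in a centred window; output trimmed to the
    (n - window + 1) interior positions where the full window fits, and
    the grid shortened accordingly.
    """
    if poly_order is None:
        poly_order = deriv_order + 1
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > spectra.n_wavenumbers:
        raise ValueError("window exceeds grid length")
    if deriv_order > poly_order:
        raise ValueError("derivative order must be <= polynomial order")
    steps = np.diff(spectra.grid)
    delta = steps.mean()
    if not np.allclose(steps, delta, rtol=1e-6, atol=1e-9 * abs(delta)):
        raise ValueError("Savitzky-Golay requires a uniform wavenumber grid")
    c = savgol_coeffs(window, poly_order, deriv=deriv_order, delta=delta,
                      use="conv")
    out = np.apply_along_axis(
        lambda r: np.convolve(r, c, mode="valid"), 1, spectra.values)
    half = window // 2
    grid = spectra.grid[half:spectra.n_wavenumbers - half]
    tag = f"sg{deriv_order}"
    return spectra._derive(out, grid=grid,
                           step=(tag, {"window": window,
                                       "poly_order": poly_order}))


def standardize_for_kernel(spectra: SpectraSet) -> SpectraSet:
    """Double standardization before the kernel: columns (wavenumbers)
    centred/scaled with sample sd, then rows (genotypes) with population
    sd so that diag(H) = 1 exactly."""
    v = spectra.values
    csd = v.std(axis=0, ddof=1)
    badc = np.nonzero(csd == 0)[0]
    if badc.size:
        raise ValueError(f"constant column(s) at grid indices {badc[:10].tolist()}")
    v = (v - v.mean(axis=0)) / csd
    rsd = v.std(axis=1, ddof=0)
    badr = np.nonzero(rsd == 0)[0]
    if badr.size:
        ids = spectra.sample_ids[badr][:10].tolist()
        raise ValueError(f"constant row(s) after column pass: {ids}")
    v = (v - v.mean(axis=1, keepdims=True)) / rsd[:, None]
    return spectra._derive(v, step=("standardize", {"order": "columns_then_rows"}))


def build_h_matrix(spectra: SpectraSet, source: str = "spectra"
                   ) -> RelationshipMatrix:
    """Spectral relationship matrix H = S S' / l from standardized spectra
    (one row per genotype)."""
    steps = [s[0] for s in spectra.provenance]
    if "standardize" not in steps:
        raise ValueError("spectra must pass standardize_for_kernel first")
    l = spectra.n_wavenumbers
    if l < 2:
        raise ValueError("need at least 2 predictors (wavenumbers)")
    S = spectra.values
    H = (S @ S.T) / l
    H = 0.5 * (H + H.T)
    pre = ":".join(s for s in steps if s != "standardize") or "raw"
    return RelationshipMatrix(values=H, labels=spectra.sample_ids,
                              source=f"spectra:{pre}:{source}",
                              n_predictors=l)


def pretreat(spectra: SpectraSet, method: str = "means", window: int = 37,
             poly_order: int = 2) -> SpectraSet:
    """Apply one of the named pretreatment variants to SNV-normalized
    spectra: 'means' (none beyond SNV), 'detrend', 'sg1' or 'sg2'."""
    if method not in PRETREATMENTS:
        raise ValueError(f"unknown pretreatment {method!r}; "
                         f"choose from {PRETREATMENTS}")
    if method == "means":
        return spectra
    if method == "detrend":
        return detrend(spectra, poly_order=poly_order)
    m = 1 if method == "sg1" else 2
    return savitzky_golay(spectra, window=window, deriv_order=m)
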