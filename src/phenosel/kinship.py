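"""Marker QC, the VanRaden genomic relationship matrix, and diagnostics
for comparing relationship matrices (Mantel correlation, PCA profiles).

Markers are coded on the trinary {-1, 0, 1} scale (homozygous aa / het /
homozygous AA).  With allele frequency p_k of the "+1" allele estimated
from the data, the genomic relationship matrix is

    Z = M - P,  P_ik = 2 p_k - 1,   G = Z Z' / (2 sum_k p_k (1 - p_k))

the VanRaden (2008) construction on the trinary coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import RelationshipMatrix

__all__ = [
    "MarkerMatrix",
    "MatrixComparison",
    "impute_markers",
    "maf_filter",
    "vanraden_g",
    "mantel_correlation",
    "pc_variance_profile",
]

_TRINARY = (-1.0, 0.0, 1.0)


@dataclass
class MarkerMatrix:
    """Genotype x marker matrix in {-1, 0, 1} (NaN = missing) plus a
    chromosome label per marker."""

    values: pd.DataFrame
    chrom: pd.Series

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        ok = np.isnan(v) | np.isin(v, _TRINARY)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"non-trinary marker value {v[i, j]!r} at genotype "
                f"{self.values.index[i]!r}, marker {self.values.columns[j]!r}")
        if not self.values.columns.equals(pd.Index(self.chrom.index)):
            self.chrom = self.chrom.reindex(self.values.columns)
            if self.chrom.isna().any():
                missing = self.chrom.index[self.chrom.isna()][:5].tolist()
                raise ValueError(f"chromosome labels missing for markers {missing}")

    @property
    def genotypes(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def n_geno(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_rate(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    def allele_freq(self) -> pd.Series:
        """Frequency of the '+1' allele: (count(1) + 0.5*count(0)) / n over
        non-missing calls."""
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            n = np.sum(~np.isnan(v), axis=0)
            p = (np.nansum(v == 1, axis=0) + 0.5 * np.nansum(v == 0, axis=0)) / n
        return pd.Series(p, index=self.values.columns, name="p")

    @property
    def maf(self) -> pd.Series:
        p = self.allele_freq()
        return pd.concat([p, 1 - p], axis=1).min(axis=1).rename("maf")


@dataclass
class MatrixComparison:
    """Mantel correlation between two relationship matrices."""

    mantel_r: float
    mantel_p: float
    n_perm: int

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.mantel_r <= 1 + 1e-12:
            raise ValueError("mantel_r out of [-1, 1]")


def impute_markers(m: MarkerMatrix, method: str = "column_mode",
                   knn_k: int = 5) -> MarkerMatrix:
    """Fill missing calls. ``column_mode`` / ``column_mean_rounded`` work
    per marker; ``knn`` takes a majority vote among the k nearest
    genotypes, computed chromosome-wise on mean-filled distances."""
    v = m.values.to_numpy(dtype=float).copy()
    miss = np.isnan(v)
    if not miss.any():
        return MarkerMatrix(values=m.values.copy(), chrom=m.chrom.copy())
    fully = np.nonzero(miss.all(axis=0))[0]
    if fully.size:
        ids = m.values.columns[fully][:10].tolist()
        raise ValueError(f"fully missing marker(s): {ids}")
    if method == "column_mode":
        for j in np.nonzero(miss.any(axis=0))[0]:
            col = v[:, j]
            obs = col[~np.isnan(col)]
            codes, counts = np.unique(obs, return_counts=True)
            col[np.isnan(col)] = codes[np.argmax(counts)]
    elif method == "column_mean_rounded":
        for j in np.nonzero(miss.any(axis=0))[0]:
            col = v[:, j]
            mean = np.nanmean(col)
            col[np.isnan(col)] = np.clip(np.round(mean), -1, 1)
    elif method == "knn":
        chrom = m.chrom.to_numpy()
        for c in pd.unique(chrom):
            sel = np.nonzero(chrom == c)[0]
            block = v[:, sel]
            bmiss = np.isnan(block)
            if not bmiss.any():
                continue
            filled = block.copy()
            colmean = np.nanmean(block, axis=0)
            filled[bmiss] = np.take(colmean, np.nonzero(bmiss)[1])
            # genotype-genotype distance on the mean-filled block
            d2 = (np.sum(filled**2, axis=1)[:, None]
                  + np.sum(filled**2, axis=1)[None, :]
                  - 2 * filled @ filled.T)
            np.fill_diagonal(d2, np.inf)
            order = np.argsort(d2, axis=1)
            for i in np.nonzero(bmiss.any(axis=1))[0]:
                for jj in np.nonzero(bmiss[i])[0]:
                    donors = [g for g in order[i] if not bmiss[g, jj]][:knn_k]
                    codes, counts = np.unique(block[donors, jj],
                                              return_counts=True)
                    block[i, jj] = codes[np.argmax(counts)]
            v[:, sel] = block
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    out = pd.DataFrame(v, index=m.values.index, columns=m.values.columns)
    return MarkerMatrix(values=out, chrom=m.chrom.copy())


def maf_filter(m: MarkerMatrix, threshold: float = 0.05) -> MarkerMatrix:
    """Drop markers with minor-allele frequency below ``threshold``
    (markers at exactly the threshold are retained)."""
    if m.values.isna().any().any():
        raise ValueError("impute before MAF filtering")
    keep = m.maf >= threshold
    if not keep.any():
        raise ValueError("MAF filter removed all markers")
    return MarkerMatrix(values=m.values.loc[:, keep],
                        chrom=m.chrom.loc[keep])


def vanraden_g(m: MarkerMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from a complete, MAF-filtered
    trinary marker matrix."""
    v = m.values.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError("marker matrix has missing calls; impute first")
    p = m.allele_freq().to_numpy()
    mono = np.nonzero((p <= 0) | (p >= 1))[0]
    if mono.size:
        ids = m.values.columns[mono][:10].tolist()
        raise ValueError(f"monomorphic marker(s) present, filter first: {ids}")
    Z = v - (2 * p - 1)[None, :]
    denom = 2.0 * np.sum(p * (1 - p))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(values=G, labels=m.genotypes, source="markers",
                              n_predictors=m.n_markers)


def _as_frame(M) -> pd.DataFrame:
    if isinstance(M, RelationshipMatrix):
        return M.to_frame()
    if isinstance(M, pd.DataFrame):
        return M
    raise TypeError("expected RelationshipMatrix or labelled DataFrame")


def _aligned(A, B):
    fa, fb = _as_frame(A), _as_frame(B)
    la = set(map(str, fa.index))
    lb = set(map(str, fb.index))
    if la != lb:
        raise ValueError(
            f"label mismatch: only in first {sorted(la - lb)[:5]}, "
            f"only in second {sorted(lb - la)[:5]}")
    order = [str(x) for x in fa.index]
    fb = fb.copy()
    fb.index = fb.index.map(str)
    fb.columns = fb.columns.map(str)
    return fa.to_numpy(), fb.loc[order, order].to_numpy()


def mantel_correlation(A, B, n_perm: int = 999, seed: int = 0
                       ) -> MatrixComparison:
    """Mantel correlation of two relationship matrices (or labelled square
    DataFrames): Pearson r over the strictly-lower-triangle entries, with a
    permutation p-value obtained by simultaneous row/column permutation of
    the second matrix."""
    a, b = _aligned(A, B)
    n = a.shape[0]
    il = np.tril_indices(n, k=-1)
    x = a[il]
    r_obs = _pearson(x, b[il])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if abs(_pearson(x, bp[il])) >= abs(r_obs) - 1e-15:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MatrixComparison(mantel_r=float(r_obs), mantel_p=float(p),
                            n_perm=n_perm)


def _pearson(x, y):
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        raise ValueError("constant off-diagonal entries; Mantel r undefined")
    return (x @ y) / denom


def pc_variance_profile(K: RelationshipMatrix, n_components: int = 10
                        ) -> np.ndarray:
    """Cumulative fractions of variance explained by the leading principal
    components (eigenvalues clipped at zero)."""
    w = np.clip(np.linalg.eigvalsh(K.values), 0.0, None)[::-1]
    total = w.sum()
    if total <= 0:
        raise ValueError("matrix has no positive eigenvalues")
    frac = np.cumsum(w) / total
    out = np.ones(n_components)
    k = min(n_components, len(frac))
    out[:k] = frac[:k]
    if len(frac) < n_components:
        out[len(frac):] = frac[-1]
    return out
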