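"""Mixed-model machinery: REML variance components and kernel BLUP.

Two model families live here.

``KernelBLUP`` fits the single-kernel model

    y = 1 mu + g + e,   g ~ N(0, K sigma2_g),   e ~ N(0, I sigma2_e)

by restricted maximum likelihood, using the eigendecomposition of the
kernel K so the restricted likelihood is a one-dimensional function of
the variance ratio lambda = sigma2_e / sigma2_g.  The kernel K is a
genomic (G) or spectral (H) relationship matrix.

``MixedREML`` is a generic multi-component REML model

    y = X beta + sum_u Z_u u_u + e,   u_u ~ N(0, I sigma2_u)

used for the spatial field-trial models (random row, column and a
tensor-product spline surface) and the across-year models.  The
restricted likelihood is profiled over the residual variance and the
fixed effects, leaving a search over the log variance ratios
gamma_u = sigma2_u / sigma2_e.  All linear algebra goes through the
Woodbury identity on the stacked random-effect design, so a likelihood
evaluation costs O(q^3) in the total number of random-effect levels q,
independent of the number of observations; designs can be reused across
many responses (e.g. one response per spectral wavenumber).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = [
    "VarianceComponents",
    "KernelBLUP",
    "KernelBLUPResults",
    "MixedREML",
    "MixedREMLResults",
    "RandomTerm",
    "PredictionSet",
    "reml_single_kernel",
    "kblup_predict",
    "rr_blup",
    "plsr",
    "reml_multi",
]

logger = logging.getLogger(__name__)

_LOG_GAMMA_LO = np.log(1e-8)
_LOG_GAMMA_HI = np.log(1e8)
_LOG_LAMBDA_BOUNDS = (-8.0, 8.0)


@dataclass
class VarianceComponents:
    """REML variance components with the bookkeeping needed for
    repeatability / heritability (sigma2_g / (sigma2_g + sigma2_e / r_bar))."""

    sigma2_g: float
    sigma2_e: float
    extra: dict = field(default_factory=dict)
    r_bar: float = 1.0
    converged: bool = True
    loglik: float = np.nan

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if self.r_bar < 1:
            raise ValueError("effective replication r_bar must be >= 1")


@dataclass
class PredictionSet:
    """Aligned predicted/observed values for a validation set."""

    ids: np.ndarray
    predicted: np.ndarray
    observed: np.ndarray | None = None
    model: str = ""
    fold: int = -1
    rep: int = -1
    size: int = -1

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=float)
            if len(self.observed) != len(self.predicted):
                raise ValueError("predicted and observed must align")

    def to_frame(self) -> pd.DataFrame:
        d = {"genotype": self.ids, "predicted": self.predicted}
        if self.observed is not None:
            d["observed"] = self.observed
        f = pd.DataFrame(d)
        f["model"] = self.model
        f["fold"] = self.fold
        f["rep"] = self.rep
        f["size"] = self.size
        return f


# ---------------------------------------------------------------------------
# Single-kernel REML (GBLUP / HBLUP)
# ---------------------------------------------------------------------------


class KernelBLUP:
    """Single-kernel mixed model ``y = 1 mu + g + e`` with g ~ N(0, K s2g).

    Parameters
    ----------
    y : array-like
        Response vector (e.g. across-year genotype BLUEs).
    K : ndarray or DataFrame
        Symmetric PSD relationship matrix aligned with ``y``.
    ids : sequence, optional
        Genotype labels; taken from ``K``'s index when it is a DataFrame.
    """

    def __init__(self, y, K, ids: Sequence | None = None):
        if isinstance(K, pd.DataFrame):
            if ids is None:
                ids = K.index.to_numpy()
            K = K.to_numpy()
        y = np.asarray(y, dtype=float)
        K = np.asarray(K, dtype=float)
        if y.ndim != 1 or K.shape != (len(y), len(y)):
            raise ValueError("K must be square and match len(y)")
        if np.ptp(y) == 0:
            raise ValueError("response is constant; variance ratio unidentifiable")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        self.y = y
        self.K = K
        self.ids = np.asarray(ids) if ids is not None else np.arange(len(y))
        self.nobs = len(y)

    def _profile(self):
        d, U = eigh(self.K)
        d = np.clip(d, 0.0, None)
        yt = U.T @ self.y
        xt = U.T @ np.ones(self.nobs)
        n = self.nobs
        df = n - 1

        def neg_reml(loglam):
            lam = np.exp(loglam)
            v = d + lam
            w = 1.0 / v
            sxx = np.sum(w * xt * xt)
            beta = np.sum(w * xt * yt) / sxx
            r = yt - beta * xt
            s2g = np.sum(w * r * r) / df
            s2g = max(s2g, 1e-300)
            return 0.5 * (
                df * (np.log(2 * np.pi * s2g) + 1)
                + np.sum(np.log(v))
                + np.log(sxx)
                - np.log(n)
            )

        return d, U, yt, xt, neg_reml

    def fit(self, n_grid: int = 81, bounds: tuple[float, float] = _LOG_LAMBDA_BOUNDS
            ) -> "KernelBLUPResults":
        """REML fit: coarse grid over log(lambda) then local refinement."""
        d, U, yt, xt, neg_reml = self._profile()
        lo, hi = bounds
        grid = np.linspace(lo, hi, n_grid)
        vals = np.array([neg_reml(g) for g in grid])
        i = int(np.argmin(vals))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            neg_reml, bounds=(a, b), method="bounded",
            options={"xatol": 1e-8})
        loglam = float(res.x)
        converged = bool(res.success) and (loglam > lo + 1e-3) and (loglam < hi - 1e-3)
        lam = np.exp(loglam)

        n = self.nobs
        v = d + lam
        w = 1.0 / v
        sxx = np.sum(w * xt * xt)
        mu = float(np.sum(w * xt * yt) / sxx)
        r = yt - mu * xt
        s2g = float(np.sum(w * r * r) / (n - 1))
        s2e = float(lam * s2g)
        # alpha = (K + lam I)^{-1} (y - mu) in the original basis
        alpha = U @ (w * r)
        gblup = self.K @ alpha
        return KernelBLUPResults(
            model=self, mu=mu, sigma2_g=s2g, sigma2_e=s2e, lam=float(lam),
            loglik=float(-neg_reml(loglam)), gblup=gblup, alpha=alpha,
            converged=converged)


@dataclass
class KernelBLUPResults:
    """Fitted single-kernel model: variance components, BLUPs, predictions."""

    model: KernelBLUP
    mu: float
    sigma2_g: float
    sigma2_e: float
    lam: float
    loglik: float
    gblup: np.ndarray
    alpha: np.ndarray
    converged: bool

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.mu + self.gblup

    def predict(self, K_cross: np.ndarray) -> np.ndarray:
        """Predict for new genotypes from their kernel rows against the
        training set: ``mu + K_vt (K_tt + lam I)^{-1} (y_t - mu)``."""
        K_cross = np.asarray(K_cross, dtype=float)
        if K_cross.ndim == 1:
            K_cross = K_cross[None, :]
        if K_cross.shape[1] != len(self.alpha):
            raise ValueError("K_cross columns must match training set size")
        return self.mu + K_cross @ self.alpha

    def summary(self) -> str:
        lines = [
            "Kernel BLUP (REML)",
            "=" * 40,
            f"n obs           {self.model.nobs:>12d}",
            f"mu              {self.mu:>12.5g}",
            f"sigma2_g        {self.sigma2_g:>12.5g}",
            f"sigma2_e        {self.sigma2_e:>12.5g}",
            f"lambda (e/g)    {self.lam:>12.5g}",
            f"REML loglik     {self.loglik:>12.5g}",
            f"converged       {str(self.converged):>12s}",
        ]
        return "\n".join(lines)


def reml_single_kernel(y, K, ids=None) -> KernelBLUPResults:
    """Functional wrapper: REML fit of the single-kernel model."""
    return KernelBLUP(y, K, ids=ids).fit()


def kblup_predict(fit: KernelBLUPResults, K, train_ids, val_ids,
                  observed=None, **tags) -> PredictionSet:
    """Kernel-BLUP prediction of validation genotypes from a training fit.

    ``fit`` must come from ``KernelBLUP`` on the training subset; ``K`` is
    the full labelled relationship matrix containing both sets.
    """
    if not isinstance(K, pd.DataFrame):
        raise TypeError("K must be a labelled DataFrame for id-based prediction")
    train_ids = list(train_ids)
    val_ids = list(val_ids)
    if set(train_ids) & set(val_ids):
        raise ValueError("train and validation sets overlap")
    K_vt = K.loc[val_ids, train_ids].to_numpy()
    pred = fit.predict(K_vt)
    obs = None
    if observed is not None:
        obs = pd.Series(observed).loc[val_ids].to_numpy()
    return PredictionSet(ids=np.asarray(val_ids), predicted=pred,
                         observed=obs, **tags)


def rr_blup(y, Z, lambda_m: float, Z_new=None):
    """Ridge-regression BLUP of marker effects.

    beta_hat = Z' (Z Z' + lambda_m I)^{-1} (y - mu_hat) with mu_hat the GLS
    intercept under V = Z Z' + lambda_m I.  Returns ``(beta, PredictionSet)``
    with predictions ``mu + Z beta`` for ``Z_new`` (default: training rows).
    Equivalent to kernel BLUP with K = Z Z' / c and lambda_m = c * lambda.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n = len(y)
    if Z.shape[0] != n:
        raise ValueError("Z rows must match len(y)")
    V = Z @ Z.T + lambda_m * np.eye(n)
    cV = cho_factor(V)
    ones = np.ones(n)
    Vi1 = cho_solve(cV, ones)
    mu = float((Vi1 @ y) / (Vi1 @ ones))
    alpha = cho_solve(cV, y - mu)
    beta = Z.T @ alpha
    Zp = Z if Z_new is None else np.asarray(Z_new, dtype=float)
    pred = mu + Zp @ beta
    return beta, PredictionSet(ids=np.arange(len(pred)), predicted=pred,
                               model="rrblup")


def plsr(X_train, y_train, X_val, n_components: int | None = None,
         max_components: int = 20, cv_folds: int = 5, seed: int = 0):
    """Partial least squares regression (NIPALS) for spectral prediction.

    When ``n_components`` is None the count is chosen by inner k-fold CV
    over 1..max_components with the one-standard-error rule.
    Returns ``(predictions, n_components_used)``.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    rank = np.linalg.matrix_rank(X_train - X_train.mean(axis=0))
    if n_components is not None:
        if n_components > rank:
            raise ValueError(
                f"n_components={n_components} exceeds rank {rank} of centered X")
        ncomp = n_components
    else:
        cmax = int(min(max_components, rank, len(y_train) - 2))
        kf = KFold(n_splits=min(cv_folds, len(y_train)), shuffle=True,
                   random_state=seed)
        mse = np.full((cmax, kf.get_n_splits()), np.nan)
        for j, (tr, va) in enumerate(kf.split(X_train)):
            for c in range(1, cmax + 1):
                m = PLSRegression(n_components=c, scale=False)
                m.fit(X_train[tr], y_train[tr])
                p = m.predict(X_train[va]).ravel()
                mse[c - 1, j] = np.mean((p - y_train[va]) ** 2)
        mean = mse.mean(axis=1)
        se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
        best = int(np.argmin(mean))
        thresh = mean[best] + se[best]
        ncomp = int(np.nonzero(mean <= thresh)[0][0]) + 1
    m = PLSRegression(n_components=ncomp, scale=False)
    m.fit(X_train, y_train)
    return m.predict(X_val).ravel(), ncomp


# ---------------------------------------------------------------------------
# Generic multi-component REML
# ---------------------------------------------------------------------------


@dataclass
class RandomTerm:
    """A random effect u ~ N(0, cov * sigma2) entering as Z u.

    ``cov`` (level covariance) defaults to the identity; a non-identity
    covariance is absorbed into Z via its symmetric square root.
    """

    name: str
    Z: np.ndarray
    cov: np.ndarray | None = None

    def effective_design(self) -> np.ndarray:
        Z = np.asarray(self.Z, dtype=float)
        if self.cov is None:
            return Z
        C = np.asarray(self.cov, dtype=float)
        d, U = eigh(C)
        d = np.clip(d, 0.0, None)
        return Z @ (U * np.sqrt(d))


class MixedREML:
    """Multi-component linear mixed model fitted by REML.

    y = X beta + sum_u Z_u u_u + e.  The restricted likelihood is profiled
    over beta and sigma2_e and maximised over the log variance ratios by
    Nelder-Mead.  The design part (cross-products of X and the stacked Z)
    is precomputed once, so many responses sharing a design can be fitted
    cheaply via :meth:`refit`.
    """

    def __init__(self, y, X, terms: Sequence[RandomTerm]):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1:
            X = X.T
        n = X.shape[0]
        if not terms:
            raise ValueError("at least one random term is required")
        self.term_names = [t.name for t in terms]
        Zs = [t.effective_design() for t in terms]
        for nm, Z in zip(self.term_names, Zs):
            if Z.shape[0] != n:
                raise ValueError(f"term {nm!r}: design rows != n obs")
        self._identical = None
        for i in range(len(Zs)):
            for j in range(i + 1, len(Zs)):
                if Zs[i].shape == Zs[j].shape and np.allclose(Zs[i], Zs[j]):
                    self._identical = (self.term_names[i], self.term_names[j])
        self.X = X
        self.nobs = n
        self.rank_x = np.linalg.matrix_rank(X)
        if self.rank_x < X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")
        self.Z = np.hstack(Zs)
        self.blocks = np.concatenate(
            [np.full(Z.shape[1], i) for i, Z in enumerate(Zs)])
        # design-level cross-products, shared across responses
        self.ZtZ = self.Z.T @ self.Z
        self.ZtX = self.Z.T @ X
        self.XtX = X.T @ X
        _, ld = np.linalg.slogdet(self.XtX)
        self.logdet_xtx = ld
        # one-hot fixed designs (genotype incidence) give a diagonal X'X,
        # which unlocks an O(q^3) likelihood evaluation via the matrix
        # determinant lemma regardless of the number of fixed levels
        self._xtx_diag = np.allclose(
            self.XtX, np.diag(np.diag(self.XtX)), atol=1e-12)
        self.y = None
        if y is not None:
            self.set_response(y)

    def set_response(self, y) -> None:
        y = np.asarray(y, dtype=float)
        if len(y) != self.nobs:
            raise ValueError("len(y) != n obs")
        self.y = y
        self.Zty = self.Z.T @ y
        self.Xty = self.X.T @ y
        self.yty = float(y @ y)

    def _eval(self, log_gamma: np.ndarray):
        """Profiled negative restricted log-likelihood at gamma, plus the
        quantities needed to assemble estimates."""
        lg = np.clip(log_gamma, _LOG_GAMMA_LO, _LOG_GAMMA_HI)
        gamma = np.exp(lg)
        g = np.sqrt(gamma[self.blocks])
        q = len(g)
        n, p = self.nobs, self.X.shape[1]
        W = np.eye(q) + (g[:, None] * self.ZtZ) * g[None, :]
        cW = cho_factor(W, lower=True)
        U = g[:, None] * self.ZtX
        zy = g * self.Zty
        Wizy = cho_solve(cW, zy)
        b = self.Xty - U.T @ Wizy           # X' V0^-1 y
        yVy = self.yty - zy @ Wizy
        logdet_w = 2.0 * np.sum(np.log(np.diag(cW[0])))
        aux = {"cW": cW, "g": g}
        if self._xtx_diag:
            # A = D - U' W^-1 U with D diagonal; Woodbury keeps all dense
            # algebra q x q:  A^-1 = D^-1 + D^-1 U' S^-1 U D^-1,
            # det A = det D * det S / det W,  S = W - U D^-1 U'
            D = np.diag(self.XtX)
            U_D = U / D[None, :]
            S = W - U_D @ U.T
            try:
                cS = cho_factor(S, lower=True)
            except np.linalg.LinAlgError:
                cS = None
            if cS is not None:
                t = U @ (b / D)
                beta = b / D + U_D.T @ cho_solve(cS, t)
                logdet_a = (np.sum(np.log(D))
                            + 2.0 * np.sum(np.log(np.diag(cS[0])))
                            - logdet_w)
                aux.update(D=D, cS=cS, U_D=U_D, cA=None)
            else:
                cS = None
        if not self._xtx_diag or aux.get("cA", "missing") == "missing":
            WiU = cho_solve(cW, U)
            A = self.XtX - U.T @ WiU        # X' V0^-1 X
            cA = cho_factor(A, lower=True)
            beta = cho_solve(cA, b)
            logdet_a = 2.0 * np.sum(np.log(np.diag(cA[0])))
            aux.update(cA=cA, D=None, cS=None, U_D=None)
        aux["U"] = U
        qf = max(yVy - beta @ b, 1e-12 * max(self.yty, 1.0) / n)
        s2e = qf / (n - p)
        nll = 0.5 * (
            (n - p) * (np.log(2 * np.pi * s2e) + 1)
            + logdet_w + logdet_a - self.logdet_xtx
        )
        return nll, gamma, beta, s2e, aux

    def fit(self, start: np.ndarray | None = None, max_iter: int = 200,
            xatol: float = 1e-6, fatol: float = 1e-9) -> "MixedREMLResults":
        if self.y is None:
            raise ValueError("no response set")
        k = len(self.term_names)
        if self._identical is not None:
            a, bname = self._identical
            nll0, gamma, beta, s2e, _ = self._eval(np.zeros(k))
            return MixedREMLResults(
                model=self, gamma=gamma, sigma2_e=s2e, beta=beta,
                loglik=-nll0, converged=False,
                message=f"random terms {a!r} and {bname!r} have identical "
                        "designs; variance components are not identifiable")
        x0 = np.zeros(k) if start is None else np.asarray(start, dtype=float)

        def obj(t):
            return self._eval(t)[0]

        res = optimize.minimize(
            obj, x0, method="Nelder-Mead",
            options={"maxiter": max_iter * k, "xatol": xatol, "fatol": fatol})
        nll, gamma, beta, s2e, _ = self._eval(res.x)
        at_bound = bool(np.any(res.x >= _LOG_GAMMA_HI - 1e-6))
        converged = bool(res.success) and not at_bound
        out = MixedREMLResults(
            model=self, gamma=gamma, sigma2_e=s2e, beta=beta,
            loglik=float(-nll), converged=converged,
            message="" if converged else "optimizer did not converge",
            theta=np.clip(res.x, _LOG_GAMMA_LO, _LOG_GAMMA_HI))
        out._y = self.y.copy()
        return out

    def refit(self, y, start: np.ndarray | None = None, max_iter: int = 200,
              xatol: float = 1e-6, fatol: float = 1e-9) -> "MixedREMLResults":
        """Fit a new response on the same design (warm-startable)."""
        self.set_response(y)
        return self.fit(start=start, max_iter=max_iter, xatol=xatol,
                        fatol=fatol)


@dataclass
class MixedREMLResults:
    """REML estimates for a multi-component mixed model."""

    model: MixedREML
    gamma: np.ndarray
    sigma2_e: float
    beta: np.ndarray
    loglik: float
    converged: bool
    message: str = ""
    theta: np.ndarray | None = None
    _y: np.ndarray | None = None

    @property
    def sigma2(self) -> dict:
        """Per-term variance components sigma2_u = gamma_u * sigma2_e."""
        return {nm: float(g * self.sigma2_e)
                for nm, g in zip(self.model.term_names, self.gamma)}

    def _solve_pieces(self):
        # restore this result's own response in case the shared design has
        # since been refitted on another one
        m = self.model
        if self._y is not None and (m.y is None or not np.array_equal(m.y, self._y)):
            m.set_response(self._y)
        lg = np.log(self.gamma)
        _, _, _, _, aux = m._eval(lg)
        return aux

    def beta_se(self) -> np.ndarray:
        """Standard errors of the fixed effects (GLS covariance)."""
        aux = self._solve_pieces()
        p = self.model.X.shape[1]
        if aux["cA"] is not None:
            diag = np.diag(cho_solve(aux["cA"], np.eye(p)))
        else:
            V = cho_solve(aux["cS"], aux["U_D"])
            diag = 1.0 / aux["D"] + np.einsum("qp,qp->p", aux["U_D"], V)
        return np.sqrt(self.sigma2_e * diag)

    def blup(self, term: str) -> np.ndarray:
        """BLUP of a random term's levels: gamma_u Z_u' V0^{-1} r."""
        m = self.model
        if term not in m.term_names:
            raise KeyError(term)
        aux = self._solve_pieces()
        cW, g = aux["cW"], aux["g"]
        r = m.y - m.X @ self.beta
        Ztr = m.Z.T @ r
        V0ir_proj = Ztr - m.ZtZ @ (g * cho_solve(cW, g * Ztr))
        idx = m.blocks == m.term_names.index(term)
        return self.gamma[m.term_names.index(term)] * V0ir_proj[idx]

    def fitted_random(self, term: str) -> np.ndarray:
        """Fitted contribution Z_u u_hat at the observations."""
        m = self.model
        idx = m.blocks == m.term_names.index(term)
        return m.Z[:, idx] @ self.blup(term)

    def variance_components(self, r_bar: float = 1.0,
                            genotype_term: str = "genotype"
                            ) -> VarianceComponents:
        s2 = self.sigma2
        if genotype_term not in s2:
            raise KeyError(genotype_term)
        extra = {k: v for k, v in s2.items() if k != genotype_term}
        return VarianceComponents(
            sigma2_g=s2[genotype_term], sigma2_e=self.sigma2_e, extra=extra,
            r_bar=r_bar, converged=self.converged, loglik=self.loglik)

    def summary(self) -> str:
        lines = ["Mixed model (REML)", "=" * 44,
                 f"n obs {self.model.nobs}, fixed rank {self.model.rank_x}",
                 f"REML loglik  {self.loglik:.5g}",
                 f"converged    {self.converged}" + (
                     f"  ({self.message})" if self.message else ""),
                 "-" * 44, "variance components"]
        for nm, v in self.sigma2.items():
            lines.append(f"  {nm:<14s} {v:>12.5g}")
        lines.append(f"  {'residual':<14s} {self.sigma2_e:>12.5g}")
        return "\n".join(lines)


def reml_multi(y, random_designs: Sequence[tuple], X=None,
               names: Sequence[str] | None = None,
               r_bar: float = 1.0) -> VarianceComponents:
    """REML variance components for ``y = X beta + sum Z_u u_u + e``.

    ``random_designs`` is a list of ``(Z, cov)`` pairs (cov=None for
    identity).  The first term is reported as ``sigma2_g``; the rest land
    in ``extra``.  X defaults to an intercept.
    """
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((len(y), 1))
    if names is None:
        names = ["genotype"] + [f"term{i}" for i in range(1, len(random_designs))]
    terms = [RandomTerm(nm, Z, cov) for nm, (Z, cov) in zip(names, random_designs)]
    res = MixedREML(y, X, terms).fit()
    if not res.converged and res.message.startswith("random terms"):
        vc = VarianceComponents(sigma2_g=0.0, sigma2_e=res.sigma2_e,
                                extra={}, r_bar=r_bar, converged=False,
                                loglik=res.loglik)
        vc.extra["message"] = res.message
        return vc
    return res.variance_components(r_bar=r_bar, genotype_term=names[0])
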