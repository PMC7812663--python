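"""REML estimation of additive, dominance and residual variances for the
mixed model y = X beta + a + d + e with Cov(a) = G sigma2_a,
Cov(d) = D sigma2_d, Cov(e) = I sigma2_e.

Fixed effects are removed exactly by projecting the data onto an orthonormal
basis of the null space of X' (error contrasts), after which REML is plain
maximum likelihood of the projected Gaussian. The three variances are
optimized on the log scale with L-BFGS-B and analytic gradients, from three
start points (equal split, additive-heavy, dominance-heavy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .grm import RelationshipMatrix

__all__ = [
    "PhenotypeData",
    "VarCompFit",
    "AdditiveDominanceREML",
    "reml_fit",
    "variance_ratios",
    "design_from_table",
]


@dataclass
class PhenotypeData:
    """Trait values and a full-column-rank fixed-effect design."""

    ids: np.ndarray
    y: np.ndarray
    fixed_design: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        self.fixed_design = np.atleast_2d(np.asarray(self.fixed_design, dtype=float))
        if self.fixed_design.shape[0] != len(self.y):
            raise ValueError("design and trait lengths differ")
        if np.linalg.matrix_rank(self.fixed_design) < self.fixed_design.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")


@dataclass
class VarCompFit:
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    h2: float
    d2: float
    loglik_reml: float
    converged: bool
    n_iter: int
    beta: np.ndarray | None = None


def design_from_table(
    df: pd.DataFrame, fixed: tuple[str, ...] = (), id_col: str = "id", y_col: str = "y"
) -> PhenotypeData:
    """Build PhenotypeData from a table with an intercept plus treatment-coded
    factors for each column named in ``fixed``."""
    n = len(df)
    cols = [np.ones((n, 1))]
    for name in fixed:
        dummies = pd.get_dummies(df[name].astype("category"), drop_first=True)
        if dummies.shape[1]:
            cols.append(dummies.to_numpy(dtype=float))
    X = np.hstack(cols)
    return PhenotypeData(ids=df[id_col].to_numpy(), y=df[y_col].to_numpy(), fixed_design=X)


def _values(M) -> np.ndarray:
    return M.values if isinstance(M, RelationshipMatrix) else np.asarray(M, dtype=float)


class AdditiveDominanceREML(BaseEstimator):
    """REML estimator of (sigma2_a, sigma2_d, sigma2_e).

    Parameters
    ----------
    fit_dominance : bool
        When False the dominance component is dropped (forced to zero) and
        only (sigma2_a, sigma2_e) are estimated.
    max_iter, tol : optimizer budget and relative log-likelihood tolerance.
    floor_frac : variances are bounded below by ``floor_frac * var(y)``;
        estimates under ``1e-6 * var(y)`` are reported as exact zeros.

    Fitted attributes: ``sigma2_a_``, ``sigma2_d_``, ``sigma2_e_``, ``h2_``,
    ``d2_``, ``loglik_``, ``converged_``, ``n_iter_``, ``beta_``.
    """

    def __init__(
        self,
        fit_dominance: bool = True,
        max_iter: int = 200,
        tol: float = 1e-8,
        floor_frac: float = 1e-10,
    ):
        self.fit_dominance = fit_dominance
        self.max_iter = max_iter
        self.tol = tol
        self.floor_frac = floor_frac

    # -- internals -----------------------------------------------------

    def _project(self, X: np.ndarray, y: np.ndarray, mats: list[np.ndarray]):
        n, p = X.shape
        Qfull, _ = qr(X, mode="full")
        K = Qfull[:, p:]  # orthonormal basis of the error-contrast space
        ystar = K.T @ y
        mstar = [K.T @ M @ K for M in mats]
        return ystar, mstar

    @staticmethod
    def _nll_grad(theta: np.ndarray, ystar: np.ndarray, mstar: list[np.ndarray]):
        """-2x restricted log-likelihood (up to constant) and its gradient
        with respect to log-variances."""
        s = np.exp(theta)
        q = len(ystar)
        V = s[-1] * np.eye(q)
        for sk, Mk in zip(s[:-1], mstar):
            V += sk * Mk
        try:
            c = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        logdet = 2.0 * np.log(np.diag(c[0])).sum()
        alpha = cho_solve(c, ystar)
        nll = 0.5 * (logdet + ystar @ alpha + q * np.log(2.0 * np.pi))
        Vinv = cho_solve(c, np.eye(q))
        grad = np.empty_like(theta)
        for k, Mk in enumerate(mstar):
            grad[k] = 0.5 * s[k] * ((Vinv * Mk).sum() - alpha @ Mk @ alpha)
        grad[-1] = 0.5 * s[-1] * (np.trace(Vinv) - alpha @ alpha)
        return nll, grad

    # -- API -----------------------------------------------------------

    def fit(self, X, y, G=None, D=None):
        """Fit with fixed-effect design ``X`` (n x p), trait ``y`` and
        relationship matrices ``G`` (and ``D`` unless fit_dominance=False)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed-effect design is rank deficient")
        if G is None:
            raise ValueError("an additive relationship matrix G is required")
        Gv = _values(G)
        mats = [Gv]
        if self.fit_dominance:
            if D is None:
                raise ValueError("a dominance relationship matrix D is required")
            Dv = _values(D)
            mats.append(Dv)
        if n < p + 3:
            raise ValueError("too few records for the fixed-effect design")

        identifiable = True
        if self.fit_dominance and np.abs(Gv - mats[1]).max() < 1e-10:
            warnings.warn(
                "G and D are numerically identical; additive and dominance "
                "variances are not separately identifiable",
                UserWarning,
            )
            identifiable = False

        ystar, mstar = self._project(X, y, mats)
        vary = max(float(np.var(ystar)), np.finfo(float).tiny)
        lo, hi = np.log(self.floor_frac * vary), np.log(10.0 * vary)
        n_comp = len(mats) + 1
        if self.fit_dominance:
            splits = [(1 / 3, 1 / 3, 1 / 3), (0.6, 0.1, 0.3), (0.1, 0.6, 0.3)]
        else:
            splits = [(0.5, 0.5), (0.8, 0.2), (0.2, 0.8)]
        best = None
        n_iter = 0
        ok = False
        for split in splits:
            theta0 = np.clip(np.log(np.array(split) * vary), lo, hi)
            res = minimize(
                self._nll_grad,
                theta0,
                args=(ystar, mstar),
                jac=True,
                method="L-BFGS-B",
                bounds=[(lo, hi)] * n_comp,
                options={"maxiter": self.max_iter, "ftol": self.tol},
            )
            n_iter += res.nit
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            ok = ok or bool(res.success)

        s = np.exp(best.x)
        zero_tol = 1e-6 * vary
        s = np.where(s < zero_tol, 0.0, s)
        sigma2_a = float(s[0])
        sigma2_d = float(s[1]) if self.fit_dominance else 0.0
        sigma2_e = float(s[-1])
        total = sigma2_a + sigma2_d + sigma2_e
        self.sigma2_a_, self.sigma2_d_, self.sigma2_e_ = sigma2_a, sigma2_d, sigma2_e
        self.h2_ = sigma2_a / total if total > 0 else float("nan")
        self.d2_ = sigma2_d / total if total > 0 else float("nan")
        self.loglik_ = -float(best.fun)
        self.converged_ = bool(ok and identifiable)
        self.n_iter_ = int(n_iter)
        # GLS fixed effects at the estimates
        sv = np.exp(best.x)
        V = sv[-1] * np.eye(n)
        for sk, Mk in zip(sv[:-1], mats):
            V += sk * Mk
        c = cho_factor(V, lower=True)
        XtVi = cho_solve(c, X).T
        self.beta_ = np.linalg.solve(XtVi @ X, XtVi @ y)
        self._ystar, self._mstar = ystar, mstar
        return self

    def predict(self, X) -> np.ndarray:
        """Fixed-effect part X beta at the GLS estimates."""
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.beta_

    def restricted_loglik(self, sigma2: np.ndarray) -> float:
        """Restricted log-likelihood at arbitrary non-negative variances
        (same data as the last fit); used for profiling and diagnostics."""
        sigma2 = np.asarray(sigma2, dtype=float)
        theta = np.log(np.maximum(sigma2, np.finfo(float).tiny))
        nll, _ = self._nll_grad(theta, self._ystar, self._mstar)
        return -float(nll)


def reml_fit(
    ph: PhenotypeData,
    G,
    D=None,
    fit_dominance: bool = True,
    **kwargs,
) -> VarCompFit:
    """Functional wrapper around :class:`AdditiveDominanceREML`."""
    for M in (G, D):
        if isinstance(M, RelationshipMatrix) and not np.array_equal(
            M.ids.astype(str), ph.ids.astype(str)
        ):
            raise ValueError("relationship matrix ids do not align with phenotypes")
    est = AdditiveDominanceREML(fit_dominance=fit_dominance, **kwargs)
    est.fit(ph.fixed_design, ph.y, G=G, D=D)
    return VarCompFit(
        sigma2_a=est.sigma2_a_,
        sigma2_d=est.sigma2_d_,
        sigma2_e=est.sigma2_e_,
        h2=est.h2_,
        d2=est.d2_,
        loglik_reml=est.loglik_,
        converged=est.converged_,
        n_iter=est.n_iter_,
        beta=est.beta_,
    )


def variance_ratios(fit: VarCompFit) -> tuple[float, float, float]:
    """(h2, d2, phenotypic variance) from a fit; NaN ratios when all
    components are zero."""
    total = fit.sigma2_a + fit.sigma2_d + fit.sigma2_e
    if total <= 0:
        return float("nan"), float("nan"), 0.0
    return fit.sigma2_a / total, fit.sigma2_d / total, total
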