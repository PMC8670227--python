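"""Multi-kernel variance components, whitening and the ML likelihood-ratio engine.

The polygenic model for a vector of hybrid phenotypes is

    y = X beta + xi_a + xi_d + xi_aa + xi_ad + xi_dd + eps,

with xi_x ~ N(0, K_x sigma2_x) for the five kernels of a KinshipSet and
eps ~ N(0, I sigma2).  Writing lambda_x = sigma2_x / sigma2 and
K = sum_x K_x lambda_x, var(y) = (K + I) sigma2.  Eigendecomposing
K = U D U^T and premultiplying the model by (D + I)^{-1/2} U^T turns it into
an ordinary regression with homoscedastic residuals, so genome scans reduce
to least squares on the whitened data and likelihood-ratio tests of added
marker columns.  The LRT is reported on the LOD scale, LOD = LRT / 4.61.

Variance components can be estimated by a seeded Gibbs sampler with
scaled-inverse-chi-square priors (the default: 15,000 iterations, 5,000
burn-in) or by profiled REML, which is deterministic and is the natural
backend for tests and closed-form comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from ._reml import RemlResult, mixture_chi2_pvalue, reml_fit
from .kinship import GENETIC_COMPONENTS, KinshipSet

__all__ = [
    "PolygenicModel",
    "PolygenicResults",
    "WhitenedData",
    "estimate_polygenic_varcomps",
    "compose_background",
    "whiten",
    "ml_lrt",
    "LOD_SCALE",
]

# LRT -> LOD conversion constant, 2 * ln(10) rounded as conventionally printed
LOD_SCALE = 4.61


@dataclass
class PolygenicResults:
    """Estimated variance components of the multi-kernel polygenic model.

    variances maps component name ('a', 'd', 'aa', 'ad', 'dd', 'residual')
    to its sigma2 estimate; lambdas are ratios to the residual variance;
    proportions are shares of the total variance (genetic + residual).
    """

    variances: dict
    lambdas: dict
    proportions: dict
    method: str
    components: tuple
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)
    beta: np.ndarray | None = None

    @property
    def sigma2(self) -> float:
        return self.variances["residual"]

    def background_lambdas(self) -> dict:
        return {k: v for k, v in self.lambdas.items() if k != "residual"}

    def summary(self) -> str:
        lines = [
            f"Polygenic variance components ({self.method})",
            f"{'component':>10} {'sigma2':>12} {'lambda':>10} {'proportion':>11}",
        ]
        for name in (*self.components, "residual"):
            lam = self.lambdas.get(name, float("nan"))
            lines.append(
                f"{name:>10} {self.variances[name]:>12.5g} "
                f"{lam:>10.4g} {self.proportions[name]:>11.4f}"
            )
        return "\n".join(lines)


@dataclass
class WhitenedData:
    """Data transformed by (D + I)^{-1/2} U^T so residuals are i.i.d.

    The stored transform can be applied to any further design column via
    ``transform_columns``; ``sigma2`` records the residual scale of the null
    variance fit that produced the background K.
    """

    y_star: np.ndarray
    X_star: np.ndarray
    columns_star: dict
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    sigma2: float = 1.0

    @property
    def transform(self) -> np.ndarray:
        return (self.eigenvectors / np.sqrt(self.eigenvalues + 1.0)).T

    def transform_columns(self, M: np.ndarray) -> np.ndarray:
        return self.transform @ np.asarray(M, dtype=float)


class PolygenicModel:
    """Five-kernel mixed model for hybrid phenotypes.

    Parameters
    ----------
    y : (n,) array
        Phenotypes (hybrid performance or midparent heterosis).
    X : (n, p) array or None
        Fixed-effect design; defaults to an intercept.  For the pooled
        TC-TM population this is [1, population indicator].
    kinships : KinshipSet or mapping name -> kernel
        The polygenic covariance kernels to include.  Single-population
        analyses typically use {'a', 'aa'}; the pooled hybrid analysis all
        five.
    """

    def __init__(self, y, X=None, kinships=None, components=None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.shape[0]
        if X is None:
            X = np.ones((n, 1))
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != n:
            raise ValueError("X rows do not match y")
        if isinstance(kinships, KinshipSet):
            names = components or GENETIC_COMPONENTS
            self.kernels = {name: kinships[name] for name in names}
        elif kinships is not None:
            self.kernels = dict(kinships)
        else:
            raise ValueError("kinships required")
        for name, K in self.kernels.items():
            K = np.asarray(K, dtype=float)
            if K.shape != (n, n):
                raise ValueError(f"kernel {name} has shape {K.shape}, n={n}")
            wmin = float(np.linalg.eigvalsh(K).min())
            if wmin < -1e-6 * max(1.0, float(np.abs(K).max())):
                raise ValueError(f"kernel {name} is not PSD (min eigenvalue {wmin:.3g})")
            self.kernels[name] = K
        self.components = tuple(self.kernels)

    # -- estimation ---------------------------------------------------------

    def fit(self, method="gibbs", n_iter=15000, burn_in=5000, seed=None) -> PolygenicResults:
        if method == "reml":
            return self._fit_reml()
        if method == "gibbs":
            return self._fit_gibbs(n_iter=n_iter, burn_in=burn_in, seed=seed)
        raise ValueError(f"unknown method {method!r}")

    def _fit_reml(self) -> PolygenicResults:
        res: RemlResult = reml_fit(
            self.y, self.X, list(self.kernels.values()), names=list(self.components)
        )
        return self._package(res.variances, "reml", diagnostics={
            "loglik": res.loglik, "converged": res.converged, "n_evals": res.n_evals,
        }, beta=res.beta)

    def _fit_gibbs(self, n_iter, burn_in, seed) -> PolygenicResults:
        if burn_in >= n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        rng = np.random.default_rng(seed)
        y, X = self.y, self.X
        n = y.shape[0]
        # eigenbasis representation xi_x = U_x alpha_x, alpha ~ N(0, diag(s) s2_x):
        # with orthonormal U the conditional posterior of alpha_x is diagonal.
        bases = {}
        for name, K in self.kernels.items():
            w, U = np.linalg.eigh(K)
            keep = w > 1e-10 * max(1.0, w.max())
            bases[name] = (U[:, keep], w[keep])
        XtX = X.T @ X
        XtX_chol = linalg.cho_factor(XtX)
        L_beta = np.linalg.cholesky(np.linalg.inv(XtX))
        # weakly informative scaled-inverse-chi-square priors splitting half
        # the phenotypic variance across the genetic terms
        df0 = 5.0
        vy = float(np.var(y))
        n_terms = max(len(bases), 1)
        S0_g = {name: vy * 0.5 / n_terms * (df0 + 2.0) for name in bases}
        S0_e = vy * 0.5 * (df0 + 2.0)

        beta = np.zeros(X.shape[1])
        alpha = {name: np.zeros(U.shape[1]) for name, (U, _) in bases.items()}
        xi = {name: np.zeros(n) for name in bases}
        s2 = {name: vy * 0.5 / n_terms for name in bases}
        s2e = vy * 0.5

        keep_iters = n_iter - burn_in
        draws = {name: np.zeros(keep_iters) for name in bases}
        draws_e = np.zeros(keep_iters)
        total_xi = np.zeros(n)
        for it in range(n_iter):
            # fixed effects (flat prior)
            r = y - total_xi
            mean_b = linalg.cho_solve(XtX_chol, X.T @ r)
            beta = mean_b + np.sqrt(s2e) * (L_beta @ rng.standard_normal(X.shape[1]))
            resid = y - X @ beta - total_xi
            for name, (U, s) in bases.items():
                resid += xi[name]
                t = U.T @ resid
                prec = 1.0 / s2e + 1.0 / (s * s2[name])
                mu = (t / s2e) / prec
                alpha[name] = mu + rng.standard_normal(mu.shape) / np.sqrt(prec)
                new_xi = U @ alpha[name]
                total_xi += new_xi - xi[name]
                xi[name] = new_xi
                resid -= new_xi
                ss = float(np.sum(alpha[name] ** 2 / s))
                s2[name] = (ss + S0_g[name]) / rng.chisquare(df0 + len(s))
            rss = float(resid @ resid)
            s2e = (rss + S0_e) / rng.chisquare(df0 + n)
            if it >= burn_in:
                j = it - burn_in
                for name in bases:
                    draws[name][j] = s2[name]
                draws_e[j] = s2e
        variances = {name: float(draws[name].mean()) for name in bases}
        variances["residual"] = float(draws_e.mean())
        diagnostics = {
            "n_iter": n_iter,
            "burn_in": burn_in,
            "posterior_sd": {name: float(draws[name].std()) for name in bases}
            | {"residual": float(draws_e.std())},
        }
        return self._package(variances, "gibbs", diagnostics=diagnostics,
                             seed=seed, beta=beta)

    def _package(self, variances, method, diagnostics=None, seed=None, beta=None):
        s2e = variances["residual"]
        lambdas = {
            name: (variances[name] / s2e if s2e > 0 else float("inf"))
            for name in self.components
        }
        total = sum(variances[name] for name in self.components) + s2e
        proportions = {name: variances[name] / total for name in self.components}
        proportions["residual"] = s2e / total
        return PolygenicResults(
            variances=dict(variances),
            lambdas=lambdas,
            proportions=proportions,
            method=method,
            components=self.components,
            seed=seed,
            diagnostics=diagnostics or {},
            beta=beta,
        )

    # -- whitening ----------------------------------------------------------

    def whitened(self, results: PolygenicResults, extra_columns=None) -> WhitenedData:
        K = compose_background(self.kernels, results.background_lambdas())
        return whiten(self.y, self.X, extra_columns or {}, K, sigma2=results.sigma2)


def estimate_polygenic_varcomps(
    y, X, kinships, components=None, method="gibbs", n_iter=15000, burn_in=5000, seed=None
) -> PolygenicResults:
    """Functional wrapper over PolygenicModel.fit."""
    model = PolygenicModel(y, X, kinships, components=components)
    return model.fit(method=method, n_iter=n_iter, burn_in=burn_in, seed=seed)


def compose_background(kernels, lambdas) -> np.ndarray:
    """K = sum_x lambda_x K_x for non-negative ratios lambda_x."""
    if isinstance(kernels, KinshipSet):
        kernels = dict(kernels.items())
    names = list(lambdas)
    for name, lam in lambdas.items():
        if lam < 0:
            raise ValueError(f"negative variance ratio for {name}: {lam}")
    n = np.asarray(kernels[names[0]]).shape[0] if names else None
    if n is None:
        raise ValueError("no components to compose")
    K = np.zeros((n, n))
    for name in names:
        K += lambdas[name] * np.asarray(kernels[name], dtype=float)
    return K


def whiten(y, X, extra_columns, K, sigma2=1.0) -> WhitenedData:
    """Transform y, X and design columns by (D + I)^{-1/2} U^T.

    K = U D U^T is the composed polygenic background; after the transform
    the model residual covariance is I sigma2, so ordinary least squares is
    exact.  A zero background yields the identity transform (U = I, D = 0).
    """
    y = np.asarray(y, dtype=float).ravel()
    K = np.asarray(K, dtype=float)
    n = y.shape[0]
    if K.shape != (n, n):
        raise ValueError("K shape does not match y")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("K must be symmetric")
    if np.allclose(K, 0):
        D = np.zeros(n)
        U = np.eye(n)
    else:
        D, U = np.linalg.eigh(K)
        if D.min() < -1e-8 * max(1.0, D.max()):
            raise ValueError(f"K is not PSD (min eigenvalue {D.min():.3g})")
        D = np.clip(D, 0.0, None)
    T = (U / np.sqrt(D + 1.0)).T
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    cols = {}
    if extra_columns:
        for name, M in dict(extra_columns).items():
            cols[name] = T @ np.asarray(M, dtype=float)
    return WhitenedData(
        y_star=T @ y,
        X_star=T @ X,
        columns_star=cols,
        eigenvalues=D,
        eigenvectors=U,
        sigma2=sigma2,
    )


def _ols_rss(A, y):
    """Residual sum of squares and coefficients of an OLS fit."""
    coef, rss, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rss.size == 0:  # rank-deficient or saturated: recompute explicitly
        r = y - A @ coef
        rss_val = float(r @ r)
    else:
        rss_val = float(rss[0])
    return coef, rss_val, rank


def ml_lrt(whitened, null_columns=None, full_columns=None):
    """Likelihood-ratio test of added design columns on whitened data.

    The null design is [X*, null_columns]; the full design additionally
    carries ``full_columns`` (the tested marker or interaction columns).
    With i.i.d. Gaussian residuals the ML likelihood ratio is
    LRT = n * ln(RSS_null / RSS_full); LOD = LRT / 4.61.  The regression
    coefficients of the tested columns are returned as effect estimates.
    If the tested columns add no rank (collinear with the null design) the
    effect is inestimable and LRT = LOD = 0.
    """
    if isinstance(whitened, WhitenedData):
        y, X = whitened.y_star, whitened.X_star
    else:
        y, X = whitened
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    parts_null = [np.atleast_2d(np.asarray(X, dtype=float))]
    if parts_null[0].shape[0] != n:
        parts_null[0] = parts_null[0].T
    if null_columns is not None and np.size(null_columns):
        C = np.asarray(null_columns, dtype=float)
        parts_null.append(C.reshape(n, -1))
    A0 = np.hstack(parts_null)
    if full_columns is None or not np.size(full_columns):
        raise ValueError("full model must add at least one tested column")
    C1 = np.asarray(full_columns, dtype=float).reshape(n, -1)
    A1 = np.hstack([A0, C1])
    _, rss0, rank0 = _ols_rss(A0, y)
    coef1, rss1, rank1 = _ols_rss(A1, y)
    n_tested = C1.shape[1]
    if rank1 <= rank0 or rss1 <= 0 or rss0 <= 0:
        return {
            "lrt": 0.0,
            "lod": 0.0,
            "effects": np.full(n_tested, np.nan),
            "rss_null": rss0,
            "rss_full": rss1,
            "estimable": rank1 > rank0,
        }
    lrt = max(0.0, n * np.log(rss0 / rss1))
    return {
        "lrt": float(lrt),
        "lod": float(lrt / LOD_SCALE),
        "effects": coef1[-n_tested:],
        "rss_null": rss0,
        "rss_full": rss1,
        "estimable": True,
    }
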