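"""Mixed-model association, heritability and genetic correlation.

The single-random-effect linear mixed model y = W a + x b + u + e with
u ~ N(0, sg2 K), e ~ N(0, se2 I) is fitted exactly by rotating into the
eigenbasis of K, which reduces REML/ML to a one-dimensional optimization
over the variance ratio lambda = sg2/se2 (the EMMA trick, as used by
GEMMA). The model object / results object split follows statsmodels:
:class:`MixedLMM` holds data and structure, ``fit()`` returns a
:class:`MixedLMMResults` with estimates, standard errors and a summary
table. GWAS, h2 and genetic-correlation estimation are thin layers on top.

The kinship matrix is GEMMA's standardized ("-gk 2") form by default:
K = (1/m) sum_j (x_j - 2 f_j 1)(x_j - 2 f_j 1)^T / (2 f_j (1 - f_j)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import MISSING, ConfigError, GenotypeMatrix

_LOG_LAMBDA_BOUNDS = (-11.5129, 11.5129)  # lambda in [1e-5, 1e5]


# ---------------------------------------------------------------------------
# Kinship and PCA
# ---------------------------------------------------------------------------

def _imputed_dosage(g: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with per-site mean imputation of missing calls."""
    X = g.G.astype(float)
    X[X == MISSING] = np.nan
    f = np.nanmean(X, axis=0)
    return np.where(np.isnan(X), f[None, :], X)


def kinship(g: GenotypeMatrix, method: str = "standardized") -> tuple[np.ndarray, int]:
    """Genomic relatedness matrix.

    ``standardized``: per-site centering by 2f and scaling by
    sqrt(2 f (1-f)), monomorphic sites skipped; ``centered``: centering
    only. Missing genotypes are mean-imputed per site first. Returns
    (K, m_used).
    """
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    X = _imputed_dosage(g)
    f = X.mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    if method == "standardized":
        if not poly.any():
            raise ValueError("all sites monomorphic")
        Z = (X[:, poly] - 2 * f[poly]) / np.sqrt(2 * f[poly] * (1 - f[poly]))
        m = int(poly.sum())
    elif method == "centered":
        Z = X - 2 * f
        m = g.n_variants
        if m == 0:
            raise ValueError("no sites")
    else:
        raise ConfigError(f"unknown kinship method {method!r}")
    K = Z @ Z.T / m
    return (K + K.T) / 2.0, m


def pca(g: GenotypeMatrix, k: int, standardize: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of the genotype matrix.

    Returns (scores: n x k, explained variance fractions). Missing calls
    are mean-imputed; sites are centered (and optionally standardized).
    The sign of each component is fixed by making its largest-magnitude
    variant loading positive.
    """
    if k >= g.n_samples:
        raise ValueError("k must be < number of samples")
    X = _imputed_dosage(g)
    f = X.mean(axis=0) / 2.0
    Z = X - 2 * f
    if standardize:
        sd = np.sqrt(2 * f * (1 - f))
        poly = sd > 0
        Z = Z[:, poly] / sd[poly]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    total = (S ** 2).sum()
    scores = U[:, :k] * S[:k]
    explained = S[:k] ** 2 / total if total > 0 else np.zeros(k)
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] *= -1
    return scores, explained


# ---------------------------------------------------------------------------
# Univariate mixed model (EMMA rotation)
# ---------------------------------------------------------------------------

@dataclass
class MixedLMMResults:
    """Fit results of a :class:`MixedLMM`.

    Attributes mirror statsmodels results: ``params``/``bse`` for the fixed
    effects, variance components, the REML variance ratio ``lambda_hat``,
    and ``h2`` on the K-as-given scale.
    """

    model: "MixedLMM"
    lambda_hat: float
    sigma_g2: float
    sigma_e2: float
    params: np.ndarray
    bse: np.ndarray
    loglike_reml: float
    loglike_ml: float
    boundary: bool
    h2_se: float | None = None

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else 0.0

    def summary(self) -> str:
        lines = [
            "Mixed linear model (single genetic random effect, REML)",
            "=" * 56,
            f"n = {self.model.n}   fixed effects = {self.model.X.shape[1]}",
            f"sigma_g^2 = {self.sigma_g2:.6g}   sigma_e^2 = {self.sigma_e2:.6g}",
            f"lambda = sigma_g^2/sigma_e^2 = {self.lambda_hat:.6g}"
            + ("   [boundary]" if self.boundary else ""),
            f"h2 = {self.h2:.4f}" + (f" (se {self.h2_se:.4f})" if self.h2_se else ""),
            f"REML loglike = {self.loglike_reml:.4f}",
            "-" * 56,
            f"{'coef':>12} {'se':>12}",
        ]
        for b, s in zip(self.params, self.bse):
            lines.append(f"{b:12.5g} {s:12.5g}")
        return "\n".join(lines)


class MixedLMM:
    """Linear mixed model y = X beta + u + e with u ~ N(0, sg2 K).

    Parameters
    ----------
    y : array (n,)
        Phenotype; no missing values (drop samples beforehand).
    K : array (n, n)
        Positive semidefinite kinship matrix for the same samples.
    X : array (n, c), optional
        Fixed-effect design; defaults to an intercept.
    """

    def __init__(self, y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None):
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if np.isnan(y).any():
            raise ValueError("missing phenotypes: drop those samples first")
        if K.shape != (n, n):
            raise ValueError("K shape mismatch")
        if X is None:
            X = np.ones((n, 1))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            raise ValueError("X shape mismatch")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # name the first collinear column for the error message
            for j in range(1, X.shape[1]):
                if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                    raise ValueError(f"collinear covariate column {j}")
            raise ValueError("collinear covariates")
        w, U = np.linalg.eigh((K + K.T) / 2.0)
        if w.min() < -1e-6 * max(w.max(), 1.0):
            raise ValueError("K is not positive semidefinite beyond tolerance")
        self.n = n
        self.y = y
        self.K = K
        self.X = X
        self.eigenvalues = np.clip(w, 0.0, None)
        self.U = U
        self.yt = U.T @ y
        self.Xt = U.T @ X

    # -- likelihoods at fixed lambda ------------------------------------
    def _gls(self, lam: float, Xt: np.ndarray | None = None):
        """GLS at fixed lambda on the rotated data.

        Returns (beta, XtDX_inv, rss, d) with d the rotated variances/se2.
        """
        Xt = self.Xt if Xt is None else Xt
        d = lam * self.eigenvalues + 1.0
        w = 1.0 / d
        XtDX = (Xt * w[:, None]).T @ Xt
        XtDy = (Xt * w[:, None]).T @ self.yt
        XtDX_inv = np.linalg.inv(XtDX)
        beta = XtDX_inv @ XtDy
        resid = self.yt - Xt @ beta
        rss = float((resid * w * resid).sum())
        return beta, XtDX_inv, rss, d

    def loglike_reml(self, lam: float, Xt: np.ndarray | None = None) -> float:
        Xt = self.Xt if Xt is None else Xt
        n, c = self.n, Xt.shape[1]
        beta, XtDX_inv, rss, d = self._gls(lam, Xt)
        sign, logdet_XtDX = np.linalg.slogdet(np.linalg.inv(XtDX_inv))
        nc = n - c
        return float(
            0.5 * (nc * np.log(nc / (2 * np.pi)) - nc - nc * np.log(rss)
                   - np.log(d).sum() - logdet_XtDX
                   + np.linalg.slogdet(Xt.T @ Xt)[1])
        )

    def loglike_ml(self, lam: float, Xt: np.ndarray | None = None) -> float:
        Xt = self.Xt if Xt is None else Xt
        n = self.n
        _, _, rss, d = self._gls(lam, Xt)
        return float(0.5 * (n * np.log(n / (2 * np.pi)) - n - n * np.log(rss)
                            - np.log(d).sum()))

    def _optimize(self, objective) -> tuple[float, bool]:
        """Grid pre-scan + bounded Brent on log-lambda."""
        lo, hi = _LOG_LAMBDA_BOUNDS
        grid = np.linspace(lo, hi, 80)
        vals = np.array([objective(np.exp(t)) for t in grid])
        i = int(np.argmax(vals))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -objective(np.exp(t)), bounds=(a, b), method="bounded",
            options={"xatol": 1e-8},
        )
        best_t = res.x if -res.fun >= vals[i] else grid[i]
        boundary = bool(best_t <= lo + 1e-3 or best_t >= hi - 1e-3)
        return float(np.exp(best_t)), boundary

    def fit(self, method: str = "reml", se_h2: bool = False) -> MixedLMMResults:
        """Estimate lambda by REML (or ML), then the fixed effects by GLS."""
        obj = self.loglike_reml if method == "reml" else self.loglike_ml
        lam, boundary = self._optimize(obj)
        beta, XtDX_inv, rss, d = self._gls(lam)
        nc = self.n - self.X.shape[1]
        se2 = rss / nc if method == "reml" else rss / self.n
        sg2 = lam * se2
        bse = np.sqrt(np.diag(XtDX_inv) * se2)
        h2_se = None
        if se_h2:
            h2_se = self._h2_se(lam, obj)
        return MixedLMMResults(
            model=self, lambda_hat=lam, sigma_g2=sg2, sigma_e2=se2,
            params=beta, bse=bse,
            loglike_reml=self.loglike_reml(lam),
            loglike_ml=self.loglike_ml(lam),
            boundary=boundary, h2_se=h2_se,
        )

    def _h2_se(self, lam: float, obj) -> float | None:
        """Delta-method SE of h2 from the numerical curvature in log-lambda."""
        t = np.log(lam)
        eps = 1e-3
        f0, fp, fm = obj(np.exp(t)), obj(np.exp(t + eps)), obj(np.exp(t - eps))
        curv = (fp - 2 * f0 + fm) / eps ** 2
        if curv >= 0:
            return None
        var_t = -1.0 / curv
        # h2 = lam/(1+lam); dh2/dt = lam/(1+lam)^2
        grad = lam / (1.0 + lam) ** 2
        return float(np.sqrt(var_t) * grad)


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

def lmm_assoc(
    y: np.ndarray,
    g: GenotypeMatrix,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact single-variant LMM association (Wald, LRT and score tests).

    Per variant, lambda is re-optimized by REML for the Wald test (GEMMA
    "-lmm 4" convention: Wald uses REML, LRT uses ML with the null ML fit,
    score uses the null REML fit). Missing genotypes are mean-imputed.
    Returns a DataFrame aligned with ``g.variants``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != g.n_samples:
        raise ValueError("phenotype / genotype sample mismatch")
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    null = MixedLMM(y, K, W)
    lam0_reml, _ = null._optimize(null.loglike_reml)
    lam0_ml, _ = null._optimize(null.loglike_ml)
    ll0_ml = null.loglike_ml(lam0_ml)

    # score-test ingredients at the null REML fit
    d0 = lam0_reml * null.eigenvalues + 1.0
    w0 = 1.0 / d0
    Wt = null.Xt
    WtDW_inv = np.linalg.inv((Wt * w0[:, None]).T @ Wt)
    alpha0 = WtDW_inv @ (Wt * w0[:, None]).T @ null.yt
    r0 = null.yt - Wt @ alpha0
    se2_0 = float((r0 * w0 * r0).sum()) / (n - W.shape[1])

    X = _imputed_dosage(g)
    f = X.mean(axis=0) / 2.0
    maf = np.minimum(f, 1 - f)
    Xt_all = null.U.T @ X

    rows = np.empty((g.n_variants, 6))
    c = W.shape[1] + 1
    for j in range(g.n_variants):
        xt = Xt_all[:, j]
        if X[:, j].std() == 0:
            rows[j] = (0.0, np.nan, np.nan, np.nan, np.nan, lam0_reml)
            continue
        Xt = np.column_stack([Wt, xt])
        m = MixedLMM.__new__(MixedLMM)
        m.n, m.y, m.K = n, y, K
        m.X = np.column_stack([W, X[:, j]])
        m.eigenvalues, m.U = null.eigenvalues, null.U
        m.yt, m.Xt = null.yt, Xt
        lam, _ = m._optimize(m.loglike_reml)
        beta, XtDX_inv, rss, _ = m._gls(lam)
        se2 = rss / (n - c)
        b = beta[-1]
        se = np.sqrt(XtDX_inv[-1, -1] * se2)
        f_stat = (b / se) ** 2
        p_wald = stats.f.sf(f_stat, 1, n - c)
        lam_ml, _ = m._optimize(m.loglike_ml)
        lrt = 2.0 * (m.loglike_ml(lam_ml) - ll0_ml)
        p_lrt = stats.chi2.sf(max(lrt, 0.0), 1)
        # score test at the null REML lambda
        xproj = xt - Wt @ (WtDW_inv @ (Wt * w0[:, None]).T @ xt)
        denom = float((xproj * w0 * xproj).sum())
        if denom <= 0:
            p_score = np.nan
        else:
            u = float((xproj * w0 * r0).sum())
            t_stat = u ** 2 / (se2_0 * denom)
            p_score = stats.chi2.sf(t_stat, 1)
        rows[j] = (b, se, p_wald, p_lrt, p_score, lam)

    out = g.variants[["chrom", "pos", "id", "vclass"]].copy()
    out[["beta", "se", "p_wald", "p_lrt", "p_score", "lambda_hat"]] = rows
    out["maf"] = maf
    return out


def significance_thresholds(n_tests: int) -> dict:
    """Bonferroni 0.05/n and the fixed genome-wide 1e-8 threshold."""
    if n_tests < 1:
        raise ConfigError("n_tests must be >= 1")
    return {"bonferroni": 0.05 / n_tests, "genomewide": 1e-8}


# ---------------------------------------------------------------------------
# Heritability and genetic correlation
# ---------------------------------------------------------------------------

def reml_h2(
    y: np.ndarray,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
) -> MixedLMMResults:
    """REML heritability of one trait: h2 = lambda/(1+lambda) on the
    K-as-given scale, with a delta-method standard error."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    return MixedLMM(y, K, W).fit(se_h2=True)


@dataclass
class BivariateResults:
    """Bivariate REML fit: variance components, r_g and the HE cross-check."""

    sigma_g1: float
    sigma_g2: float
    sigma_g12: float
    sigma_e1: float
    sigma_e2: float
    sigma_e12: float
    converged: bool
    he_r_g: float
    clamped: bool = False

    @property
    def r_g(self) -> float:
        denom = np.sqrt(self.sigma_g1 * self.sigma_g2)
        if denom <= 0:
            return np.nan
        return float(np.clip(self.sigma_g12 / denom, -1.0, 1.0))

    @property
    def r_e(self) -> float:
        denom = np.sqrt(self.sigma_e1 * self.sigma_e2)
        return float(self.sigma_e12 / denom) if denom > 0 else np.nan

    @property
    def h2(self) -> tuple[float, float]:
        return (
            self.sigma_g1 / (self.sigma_g1 + self.sigma_e1),
            self.sigma_g2 / (self.sigma_g2 + self.sigma_e2),
        )

    def summary(self) -> str:
        return "\n".join([
            "Bivariate mixed model (REML, log-Cholesky parameterization)",
            "=" * 58,
            f"Vg = [[{self.sigma_g1:.4g}, {self.sigma_g12:.4g}], "
            f"[{self.sigma_g12:.4g}, {self.sigma_g2:.4g}]]",
            f"Ve = [[{self.sigma_e1:.4g}, {self.sigma_e12:.4g}], "
            f"[{self.sigma_e12:.4g}, {self.sigma_e2:.4g}]]",
            f"r_g = {self.r_g:.4f}   (Haseman-Elston: {self.he_r_g:.4f})",
            f"h2 = ({self.h2[0]:.4f}, {self.h2[1]:.4f})   converged: {self.converged}",
        ])


def he_regression(y1: np.ndarray, y2: np.ndarray, K: np.ndarray) -> dict:
    """Haseman-Elston cross-product regression (method of moments).

    Off-diagonal products y_i y_j are regressed on K_ij; slopes estimate
    genetic (co)variances on centered traits.
    """
    y1 = y1 - y1.mean()
    y2 = y2 - y2.mean()
    n = y1.size
    iu = np.triu_indices(n, k=1)
    kk = K[iu]
    denom = (kk ** 2).sum()
    sg1 = float((kk * (y1[iu[0]] * y1[iu[1]])).sum() / denom)
    sg2 = float((kk * (y2[iu[0]] * y2[iu[1]])).sum() / denom)
    sg12 = float((kk * 0.5 * (y1[iu[0]] * y2[iu[1]] + y2[iu[0]] * y1[iu[1]])).sum()
                 / denom)
    d = np.sqrt(max(sg1, 1e-12) * max(sg2, 1e-12))
    return {"sigma_g1": sg1, "sigma_g2": sg2, "sigma_g12": sg12,
            "r_g": sg12 / d if d > 0 else np.nan}


def _chol_to_cov(theta: np.ndarray) -> np.ndarray:
    """(log l11, l21, log l22) -> 2x2 PD covariance via Cholesky."""
    L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    return L @ L.T


def _cov_to_chol(V: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(V)
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


def reml_rg(
    y1: np.ndarray,
    y2: np.ndarray,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    max_iter: int = 500,
) -> BivariateResults:
    """Bivariate REML genetic correlation.

    The two traits share the genetic covariance structure sigma_g12 * K and
    a residual covariance; the six (co)variance parameters are optimized by
    L-BFGS on the K-rotated restricted likelihood, positive-definiteness
    enforced through a log-Cholesky parameterization. A Haseman-Elston
    cross-product estimate initializes the search and is reported as an
    independent method-of-moments cross-check.
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    n = y1.size
    if y2.size != n:
        raise ValueError("trait length mismatch")
    ok = ~(np.isnan(y1) | np.isnan(y2))
    if ok.sum() < 30:
        raise ValueError("need >= 30 jointly observed samples")
    y1, y2 = y1[ok], y2[ok]
    K = K[np.ix_(ok, ok)]
    n = y1.size
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates)[ok]])
    c = W.shape[1]

    w_eig, U = np.linalg.eigh((K + K.T) / 2.0)
    w_eig = np.clip(w_eig, 0.0, None)
    Y = U.T @ np.column_stack([y1, y2])  # n x 2
    Wt = U.T @ W  # n x c

    he = he_regression(y1, y2, K)
    v1, v2 = y1.var(ddof=1), y2.var(ddof=1)
    sg1 = min(max(he["sigma_g1"], 0.05 * v1), 0.95 * v1)
    sg2 = min(max(he["sigma_g2"], 0.05 * v2), 0.95 * v2)
    rg0 = np.clip(he["r_g"] if np.isfinite(he["r_g"]) else 0.0, -0.9, 0.9)
    Vg0 = np.array([[sg1, rg0 * np.sqrt(sg1 * sg2)],
                    [rg0 * np.sqrt(sg1 * sg2), sg2]])
    Ve0 = np.array([[v1 - sg1, 0.0], [0.0, v2 - sg2]])
    Ve0 += np.eye(2) * 1e-3 * (v1 + v2)

    def neg_restricted_ll(theta):
        Vg = _chol_to_cov(theta[:3])
        Ve = _chol_to_cov(theta[3:])
        # per-eigencomponent 2x2 covariances
        S = w_eig[:, None, None] * Vg[None] + Ve[None]
        det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
        if (det <= 0).any() or (S[:, 0, 0] <= 0).any():
            return 1e12
        inv = np.empty_like(S)
        inv[:, 0, 0] = S[:, 1, 1] / det
        inv[:, 1, 1] = S[:, 0, 0] / det
        inv[:, 0, 1] = inv[:, 1, 0] = -S[:, 0, 1] / det
        # F = sum_i X_i' S_i^-1 X_i with X_i = I_2 (x) w_i-row
        ww = np.einsum("ic,id->icd", Wt, Wt)  # n x c x c
        F = np.zeros((2 * c, 2 * c))
        F[:c, :c] = np.einsum("i,icd->cd", inv[:, 0, 0], ww)
        F[c:, c:] = np.einsum("i,icd->cd", inv[:, 1, 1], ww)
        F[:c, c:] = np.einsum("i,icd->cd", inv[:, 0, 1], ww)
        F[c:, :c] = F[:c, c:].T
        b = np.concatenate([
            np.einsum("ic,i->c", Wt, inv[:, 0, 0] * Y[:, 0] + inv[:, 0, 1] * Y[:, 1]),
            np.einsum("ic,i->c", Wt, inv[:, 1, 0] * Y[:, 0] + inv[:, 1, 1] * Y[:, 1]),
        ])
        try:
            alpha = np.linalg.solve(F, b)
        except np.linalg.LinAlgError:
            return 1e12
        mu1 = Wt @ alpha[:c]
        mu2 = Wt @ alpha[c:]
        r1 = Y[:, 0] - mu1
        r2 = Y[:, 1] - mu2
        Q = float((r1 * (inv[:, 0, 0] * r1 + inv[:, 0, 1] * r2)
                   + r2 * (inv[:, 1, 0] * r1 + inv[:, 1, 1] * r2)).sum())
        sign, logdetF = np.linalg.slogdet(F)
        if sign <= 0:
            return 1e12
        return 0.5 * (np.log(det).sum() + logdetF + Q)

    theta0 = np.concatenate([_cov_to_chol(Vg0), _cov_to_chol(Ve0)])
    res = optimize.minimize(neg_restricted_ll, theta0, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": 1e-12})
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(
            f"bivariate REML did not converge; Haseman-Elston fallback: {he}")
    Vg = _chol_to_cov(res.x[:3])
    Ve = _chol_to_cov(res.x[3:])
    denom = np.sqrt(Vg[0, 0] * Vg[1, 1])
    clamped = bool(denom > 0 and abs(Vg[0, 1] / denom) > 1.0)
    return BivariateResults(
        sigma_g1=float(Vg[0, 0]), sigma_g2=float(Vg[1, 1]),
        sigma_g12=float(Vg[0, 1]),
        sigma_e1=float(Ve[0, 0]), sigma_e2=float(Ve[1, 1]),
        sigma_e12=float(Ve[0, 1]),
        converged=bool(res.success), he_r_g=float(he["r_g"]), clamped=clamped,
    )
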