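"""Single-random-effect linear mixed model fitted by REML.

The model is y = X b + u + e with u ~ N(0, sigma2_u * K) and
e ~ N(0, sigma2_e * I). Writing lambda = sigma2_e / sigma2_u, the covariance
is sigma2_u * (K + lambda I), so a one-time eigendecomposition K = U S U'
reduces every restricted-likelihood evaluation to O(n) diagonal algebra
(the EMMA trick). The variance ratio is profiled: for each candidate lambda
the GLS fixed effects and sigma2_u have closed forms, leaving a 1-D
maximization over log10(lambda) done by grid search plus golden-section
refinement. This solver is shared by GWAS (per-marker scans), genomic
prediction, and heritability estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .kinship import KinshipMatrix

#: search window for the variance ratio, log10(lambda)
LOG10_LAMBDA_RANGE = (-5.0, 5.0)
GRID_POINTS = 100
#: relative tolerance of the golden-section refinement (on log10 lambda)
REFINE_XTOL = 1e-8
#: diagonal ridge used inside linear solves only, never stored in K
SOLVE_RIDGE = 1e-6


@dataclass
class LmmFit:
    """REML fit: fixed effects, BLUPs, variance components, restricted log-likelihood."""

    beta: np.ndarray
    beta_se: np.ndarray
    u: np.ndarray
    sigma2_u: float
    sigma2_e: float
    lam: float
    loglik_restricted: float

    @property
    def h2(self) -> float:
        tot = self.sigma2_u + self.sigma2_e
        return float(self.sigma2_u / tot) if tot > 0 else 0.0

    def to_dict(self) -> dict:
        return {"beta": self.beta.tolist(), "beta_se": self.beta_se.tolist(),
                "u": self.u.tolist(), "sigma2_u": self.sigma2_u,
                "sigma2_e": self.sigma2_e, "lambda": self.lam,
                "loglik_restricted": self.loglik_restricted}


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    h2: float


class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix.

    Built once per kinship and reused across fits that share K but differ in
    X (a GWAS tests one extra column per marker against the same K).
    """

    def __init__(self, K: KinshipMatrix | np.ndarray):
        values = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        if not np.all(np.isfinite(values)):
            raise ValueError("kinship contains non-finite entries")
        s, U = np.linalg.eigh(values)
        self.s = np.clip(s, 0.0, None)  # clip numerical negatives of a PSD matrix
        self.U = U
        self.n = values.shape[0]

    def rotate(self, a: np.ndarray) -> np.ndarray:
        """U' @ a for a vector or matrix aligned to K's rows."""
        return self.U.T @ a


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of columns that are linear combinations of earlier ones."""
    bad = []
    cols: list[np.ndarray] = []
    for j in range(X.shape[1]):
        trial = np.column_stack(cols + [X[:, j]]) if cols else X[:, [j]]
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            bad.append(j)
        else:
            cols.append(X[:, j])
    return bad


def _profile(lam: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profiled REML quantities at a fixed variance ratio.

    Returns (restricted loglik up to an additive constant, beta, XtDiX, q)
    where q = weighted residual sum of squares and XtDiX = X' V^-1 X without
    the sigma2_u factor.
    """
    n, p = Xt.shape
    d = s + lam
    w = 1.0 / d
    XtDiX = (Xt * w[:, None]).T @ Xt
    XtDiy = (Xt * w[:, None]).T @ yt
    try:
        beta = np.linalg.solve(XtDiX, XtDiy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtDiX, XtDiy, rcond=None)[0]
    r = yt - Xt @ beta
    q = float(np.sum(r * r * w))
    df = n - p
    sign, logdet_x = np.linalg.slogdet(XtDiX)
    if sign <= 0:
        return -np.inf, beta, XtDiX, q
    if q <= 0:
        q = np.finfo(float).tiny
    ll = -0.5 * (df * np.log(q / df) + np.sum(np.log(d)) + logdet_x + df)
    return ll, beta, XtDiX, q


def reml_profile_loglik(lam: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """Restricted log-likelihood profile in lambda (additive constant dropped)."""
    return _profile(lam, s, yt, Xt)[0]


def _optimize_lambda(s, yt, Xt, grid_points: int = GRID_POINTS):
    lo, hi = LOG10_LAMBDA_RANGE
    grid = np.logspace(lo, hi, grid_points)
    lls = np.array([reml_profile_loglik(l, s, yt, Xt) for l in grid])
    i = int(np.argmax(lls))
    a = np.log10(grid[max(i - 1, 0)])
    b = np.log10(grid[min(i + 1, grid_points - 1)])
    if a == b:
        return grid[i], lls[i]
    res = optimize.minimize_scalar(
        lambda x: -reml_profile_loglik(10.0 ** x, s, yt, Xt),
        bounds=(a, b), method="bounded",
        options={"xatol": REFINE_XTOL * max(1.0, abs(a), abs(b))})
    lam = float(10.0 ** res.x)
    ll = -float(res.fun)
    if lls[i] > ll:  # grid point was already the optimum
        return float(grid[i]), float(lls[i])
    return lam, ll


def fit_lmm_reml(y: np.ndarray, X: np.ndarray, K: KinshipMatrix | np.ndarray,
                 eigen: KinshipEigen | None = None) -> LmmFit:
    """REML fit of y = X b + u + e with var(u) = sigma2_u * K.

    ``eigen`` may carry a precomputed eigendecomposition of K (reused across
    calls that share K). X must be full column rank; y finite.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype vector contains non-finite values")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"design shape {X.shape} does not match n={y.size}")
    bad = _collinear_columns(X)
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns {bad}")
    if X.shape[1] >= y.size:
        raise ValueError("more fixed-effect columns than observations")
    eig = eigen if eigen is not None else KinshipEigen(K)
    if eig.n != y.size:
        raise ValueError("kinship dimension does not match phenotype length")
    yt = eig.rotate(y)
    Xt = eig.rotate(X)
    lam, ll = _optimize_lambda(eig.s, yt, Xt)
    _, beta, XtDiX, q = _profile(lam, eig.s, yt, Xt)
    df = y.size - X.shape[1]
    sigma2_u = q / df
    sigma2_e = lam * sigma2_u
    cov_beta = sigma2_u * np.linalg.inv(XtDiX)
    beta_se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    # BLUP E[u|y] = K (K + lam I)^-1 (y - X beta), via the eigenbasis
    rt = yt - Xt @ beta
    u = eig.U @ (eig.s / (eig.s + lam) * rt)
    return LmmFit(beta=beta, beta_se=beta_se, u=u, sigma2_u=float(sigma2_u),
                  sigma2_e=float(sigma2_e), lam=float(lam),
                  loglik_restricted=float(ll))


def estimate_h2(line_means: np.ndarray, K: KinshipMatrix) -> VarianceComponents:
    """Narrow-sense heritability from line means and a genomic relationship matrix.

    Fits an intercept-only mixed model and returns
    h2 = sigma2_u / (sigma2_u + sigma2_e), i.e. additive genetic variance over
    total phenotypic variance.
    """
    y = np.asarray(line_means, dtype=np.float64).ravel()
    if y.size != K.n_lines:
        raise ValueError("one value per line required")
    if np.var(y) <= 0:
        raise ValueError("zero phenotypic variance; heritability undefined")
    fit = fit_lmm_reml(y, np.ones((y.size, 1)), K)
    # The additive variance among lines is var(u_i) = sigma2_u * G_ii, so the
    # population-level additive variance carries the mean diagonal of G (≈2
    # for fully inbred lines under VanRaden scaling, ≈1 for outbred panels).
    add_var = fit.sigma2_u * float(np.mean(np.diag(K.values)))
    h2 = add_var / (add_var + fit.sigma2_e) if (add_var + fit.sigma2_e) > 0 else 0.0
    return VarianceComponents(fit.sigma2_u, fit.sigma2_e, float(h2))


def gls_wald(fit: LmmFit, column_index: int) -> tuple[float, float]:
    """Wald test of one fixed-effect column: ((beta/se)^2, chi-square(1) p)."""
    if not (0 <= column_index < fit.beta.size):
        raise IndexError(f"column {column_index} outside design of {fit.beta.size}")
    se = fit.beta_se[column_index]
    if se == 0.0:
        raise ZeroDivisionError(f"degenerate design column {column_index}: zero standard error")
    stat = float((fit.beta[column_index] / se) ** 2)
    p = float(stats.chi2.sf(stat, df=1))
    return stat, max(p, np.finfo(float).tiny)
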