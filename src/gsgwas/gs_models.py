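"""Prediction engines: RR-BLUP with optional fixed-effect markers, and the
multiple-linear-regression (MLR) non-GS control.

RR-BLUP / GBLUP: y = X b + u + e with u ~ N(0, sigma2_u G), G the VanRaden
genomic relationship matrix. With no fixed markers X is the intercept alone
and the model is standard RR-BLUP. When up to four markers are fit as fixed
effects, their raw allele-dosage columns join X and those markers are removed
from the calculation of G. Genome-estimated breeding values for unphenotyped
lines come from the conditional expectation of u under the joint
(training + target) kinship; an algebraically equivalent marker-effect ridge
formulation is also provided and the two are held to agree by test.

MLR: single-marker regressions rank markers by F-test P-value; OLS models on
the top 1..100 markers are compared by training-data fit (adjusted R^2) and
the winner predicts directly from its coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fixed_selection import FixedEffectSet
from .genotype_io import GenotypeMatrix
from .kinship import KinshipMatrix, compute_grm
from .mixed_model import LmmFit, SOLVE_RIDGE, fit_lmm_reml

DEFAULT_MLR_MAX_MARKERS = 100


@dataclass
class GsModel:
    """A fitted prediction model (rrblup, rrblup_fe, or mlr)."""

    method: str
    train_line_ids: list[str]
    fit: LmmFit | None = None
    fixed_set: FixedEffectSet | None = None
    kinship_spec: list[str] | None = None  # marker ids G was built from
    joint_kinship: KinshipMatrix | None = None
    fixed_marker_ids: list[str] | None = None
    _alpha: np.ndarray | None = None  # (K_train + lam I)^-1 residual, for BLUP
    _resid: np.ndarray | None = None  # y - X beta on the training lines
    # ridge-dual state (shares centering with the kinship)
    _W_train: np.ndarray | None = None
    _center: np.ndarray | None = None
    _denom: float | None = None
    _kin_marker_idx: np.ndarray | None = None
    # MLR state
    mlr_marker_ids: list[str] | None = None
    mlr_coef: np.ndarray | None = None
    mlr_models_tested: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("rrblup", "rrblup_fe", "mlr"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "rrblup_fe":
            if self.fixed_set is None:
                raise ValueError("rrblup_fe requires a fixed-effect set")
            overlap = set(self.fixed_set.marker_ids) & set(self.kinship_spec or [])
            if overlap:
                raise ValueError(f"fixed markers {sorted(overlap)} must not enter the kinship")


def fit_rrblup_fe(y_train: np.ndarray, g_train: GenotypeMatrix,
                  fixed_set: FixedEffectSet | None = None,
                  g_joint: GenotypeMatrix | None = None,
                  joint_kinship: KinshipMatrix | None = None) -> GsModel:
    """Fit RR-BLUP, with the fixed-effect markers (if any) moved into X and
    excluded from G.

    ``g_joint`` may carry additional (future target) lines; the relationship
    matrix is then computed jointly over all its lines, which is what makes
    kinship-based prediction of those lines possible later. With
    ``fixed_set=None`` the result is the plain RR-BLUP model.
    """
    y = np.asarray(y_train, dtype=np.float64).ravel()
    if y.size != g_train.n_lines:
        raise ValueError("phenotype length does not match training lines")
    gj = g_joint if g_joint is not None else g_train
    if set(g_train.line_ids) - set(gj.line_ids):
        raise ValueError("g_joint must contain all training lines")
    fixed_ids = list(fixed_set.marker_ids) if fixed_set is not None else []
    train_rows = gj.line_index(g_train.line_ids)

    if fixed_ids:
        fx_cols = gj.dosage[np.ix_(train_rows, gj.marker_index(fixed_ids))]
        mono = [m for m, c in zip(fixed_ids, fx_cols.T) if c.std() == 0.0]
        if mono:
            raise ValueError(
                f"fixed markers monomorphic in training data: {mono}; reselect candidates")
        X_train = np.column_stack([np.ones(y.size), fx_cols])
    else:
        X_train = np.ones((y.size, 1))

    if joint_kinship is not None:
        if (list(joint_kinship.line_ids) != list(gj.line_ids)
                or set(joint_kinship.excluded_markers) != set(fixed_ids)):
            raise ValueError("precomputed joint kinship does not match lines/exclusions")
        joint_K = joint_kinship
    else:
        joint_K = compute_grm(gj, exclude=fixed_ids)
    K_train = joint_K.subset(g_train.line_ids)
    fit = fit_lmm_reml(y, X_train, K_train)

    resid = y - X_train @ fit.beta
    n = y.size
    alpha = np.linalg.solve(K_train.values + (fit.lam + SOLVE_RIDGE) * np.eye(n), resid)

    kin_mask = ~gj.markers["marker_id"].isin(fixed_ids).to_numpy()
    kin_idx = np.flatnonzero(kin_mask)
    Xk = gj.dosage[:, kin_idx]
    p = Xk.mean(axis=0) / 2.0
    center = 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))

    return GsModel(
        method="rrblup_fe" if fixed_ids else "rrblup",
        train_line_ids=list(g_train.line_ids),
        fit=fit,
        fixed_set=fixed_set if fixed_ids else None,
        kinship_spec=gj.markers.loc[kin_mask, "marker_id"].tolist(),
        joint_kinship=joint_K,
        fixed_marker_ids=fixed_ids,
        _alpha=alpha,
        _resid=resid,
        _W_train=Xk[train_rows] - center[None, :],
        _center=center,
        _denom=denom,
        _kin_marker_idx=kin_idx,
    )


def predict_gebv(model: GsModel, target_lines: list[str], g_all: GenotypeMatrix,
                 path: str = "kinship") -> np.ndarray:
    """Genome-estimated breeding values for the target lines.

    ``path='kinship'`` uses the joint relationship matrix stored at fit time:
    u_target = G[target, train] (G[train, train] + lam I)^-1 (y - X beta).
    ``path='ridge'`` back-solves marker effects
    a = (W'W + lam c I)^-1 W' (y - X beta) on the centered training dosages
    and applies them to the target dosages; the two are algebraically
    identical and both are exposed so the agreement can be verified.
    """
    if model.method == "mlr":
        return _predict_mlr(model, target_lines, g_all)
    missing = [l for l in target_lines if l not in set(g_all.line_ids)]
    if missing:
        raise KeyError(f"target lines not genotyped: {missing[:10]}")
    rows = g_all.line_index(target_lines)
    if model.fixed_marker_ids:
        fx = g_all.dosage[np.ix_(rows, g_all.marker_index(model.fixed_marker_ids))]
        X_t = np.column_stack([np.ones(len(target_lines)), fx])
    else:
        X_t = np.ones((len(target_lines), 1))
    fixed_part = X_t @ model.fit.beta

    if path == "kinship":
        known = set(model.joint_kinship.line_ids)
        if not set(target_lines) <= known:
            raise KeyError(
                "targets absent from the joint kinship built at fit time; "
                "refit with g_joint covering them or use path='ridge'")
        G_tt = model.joint_kinship.block(target_lines, model.train_line_ids)
        u_t = G_tt @ model._alpha
    elif path == "ridge":
        Xk_t = g_all.dosage[np.ix_(rows, g_all.marker_index(model.kinship_spec))]
        W_t = Xk_t - model._center[None, :]
        W = model._W_train
        m = W.shape[1]
        a = np.linalg.solve(W.T @ W + (model.fit.lam + SOLVE_RIDGE) * model._denom * np.eye(m),
                            W.T @ model._resid)
        u_t = (W_t @ a)
    else:
        raise ValueError("path must be 'kinship' or 'ridge'")
    return fixed_part + u_t


def fit_mlr(y_train: np.ndarray, g_train: GenotypeMatrix,
            max_markers: int = DEFAULT_MLR_MAX_MARKERS) -> GsModel:
    """Multiple linear regression on the top single-marker-regression SNPs.

    Markers are ranked by the F-test P of a simple regression of the
    phenotype on each dosage column; OLS models on the top k markers for
    k = 1..min(max_markers, markers available) are compared by adjusted R^2
    on the training data, and the best one is returned.
    """
    if max_markers < 1:
        raise ValueError("max_markers must be >= 1")
    y = np.asarray(y_train, dtype=np.float64).ravel()
    n = y.size
    if n != g_train.n_lines:
        raise ValueError("phenotype length does not match training lines")
    if np.isnan(g_train.dosage).any():
        raise ValueError("genotypes contain missing values; impute first")
    D = g_train.dosage
    sd = D.std(axis=0)
    poly = sd > 0.0
    if not poly.any():
        raise ValueError("no polymorphic markers in training data")
    yc = y - y.mean()
    y_sd = yc.std()
    if y_sd == 0.0:
        raise ValueError("constant training phenotype")
    Dc = D[:, poly] - D[:, poly].mean(axis=0)
    r = (Dc.T @ yc) / (n * sd[poly] * y_sd)
    r2 = np.clip(r ** 2, 0.0, 1.0 - 1e-15)
    f = (n - 2) * r2 / (1.0 - r2)
    pvals = stats.f.sf(f, 1, n - 2)
    order = np.argsort(pvals, kind="mergesort")
    marker_ids = g_train.markers.loc[poly, "marker_id"].to_numpy()[order]
    cols = D[:, poly][:, order]

    k_max = min(max_markers, cols.shape[1], n - 2)
    if k_max < 1:
        raise ValueError(f"too few training lines (n={n}) to fit any MLR model")
    best = None  # (adj R2, -k)
    sst = float(np.sum(yc ** 2))
    for k in range(1, k_max + 1):
        X = np.column_stack([np.ones(n), cols[:, :k]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        r2_k = 1.0 - rss / sst
        adj = 1.0 - (1.0 - r2_k) * (n - 1) / (n - k - 1)
        key = (round(adj, 12), -k)
        if best is None or key > best[0]:
            best = (key, k, coef)
    _, k, coef = best
    return GsModel(method="mlr", train_line_ids=list(g_train.line_ids),
                   mlr_marker_ids=list(marker_ids[:k]), mlr_coef=coef,
                   mlr_models_tested=k_max)


def _predict_mlr(model: GsModel, target_lines: list[str], g_all: GenotypeMatrix) -> np.ndarray:
    rows = g_all.line_index(target_lines)
    cols = g_all.dosage[np.ix_(rows, g_all.marker_index(model.mlr_marker_ids))]
    X = np.column_stack([np.ones(len(target_lines)), cols])
    return X @ model.mlr_coef
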