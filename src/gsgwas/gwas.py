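"""Single-marker mixed-model GWAS, FDR correction, and peak binning.

Each marker is tested as one extra fixed-effect column in the kinship mixed
model (Wald test on its allele-substitution effect). Two modes are offered:

- ``exact_per_marker``: the variance ratio is re-optimized by REML for every
  marker (the GEMMA default behaviour);
- ``p3d``: the ratio is estimated once under the null model and held fixed
  across markers (EMMAX/P3D), which lets the whole scan run as vectorized
  weighted least squares.

P-values are Benjamini-Hochberg corrected over all tested SNPs, then binned
into fixed-width windows per chromosome (default 500 kb) keeping the lowest
P-value SNP per bin — in breeding populations with long-range LD an
association peak typically spans an entire bin, so the bin representative
stands in for the peak.

Results use a fixed tabular schema (marker_id, chromosome, position_bp, beta,
se, p_wald, q_fdr), and externally produced association tables in the same
schema can be fed to the downstream fixed-effect selection (the
"historical GWAS" route).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix
from .kinship import KinshipMatrix
from .mixed_model import KinshipEigen, _optimize_lambda, _profile

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ["marker_id", "chromosome", "position_bp", "beta", "se", "p_wald", "q_fdr"]
PEAK_COLUMNS = ["chromosome", "bin_start_bp", "bin_end_bp", "marker_id", "p_wald", "q_fdr"]

DEFAULT_BIN_BP = 500_000


def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{k >= i} p_(k) * m / k, capped at 1. All p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_lmm_gwas(g: GenotypeMatrix, y: np.ndarray, K: KinshipMatrix,
                 covariates: np.ndarray | None = None,
                 mode: str = "exact_per_marker") -> pd.DataFrame:
    """Mixed-model association scan over all markers of ``g``.

    ``y`` must align with ``g.line_ids`` and ``K`` must be built on the same
    lines. ``covariates`` defaults to an intercept-only design; a supplied
    matrix must already contain the intercept column. Markers monomorphic in
    the current line subset are skipped (logged count). Returns the GWAS
    table with BH q-values included.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = g.n_lines
    if y.size != n:
        raise ValueError(f"phenotype length {y.size} != {n} genotyped lines")
    if K.n_lines != n or list(K.line_ids) != list(g.line_ids):
        raise ValueError("kinship line ids do not match genotype line ids")
    if np.isnan(g.dosage).any():
        raise ValueError("genotypes contain missing values; impute first")
    if mode not in ("exact_per_marker", "p3d"):
        raise ValueError(f"mode must be 'exact_per_marker' or 'p3d', got {mode!r}")
    X0 = np.ones((n, 1)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=np.float64))
    if X0.shape[0] != n:
        raise ValueError("covariate rows do not match lines")

    poly = g.dosage.std(axis=0) > 0.0
    n_skipped = int((~poly).sum())
    if n_skipped:
        logger.info("GWAS: skipped %d markers monomorphic in the current lines", n_skipped)
    if not poly.any():
        raise ValueError("all markers monomorphic in the tested lines")

    eig = KinshipEigen(K)
    yt = eig.rotate(y)
    X0t = eig.rotate(X0)
    Mt = eig.rotate(g.dosage[:, poly])

    if mode == "exact_per_marker":
        beta, se, pvals = _scan_exact(eig.s, yt, X0t, Mt)
    else:
        beta, se, pvals = _scan_p3d(eig.s, yt, X0t, Mt)

    out = g.markers.loc[poly, ["marker_id", "chromosome", "position_bp"]].reset_index(drop=True)
    out["beta"] = beta
    out["se"] = se
    out["p_wald"] = np.clip(pvals, np.finfo(float).tiny, 1.0)
    out["q_fdr"] = fdr_correct(out["p_wald"].to_numpy())
    return out[GWAS_COLUMNS]


def _scan_exact(s, yt, X0t, Mt):
    """Per-marker REML: re-optimize the variance ratio for every marker."""
    n, p0 = X0t.shape
    m = Mt.shape[1]
    beta = np.empty(m)
    se = np.empty(m)
    pvals = np.empty(m)
    for j in range(m):
        Xt = np.column_stack([X0t, Mt[:, j]])
        lam, _ = _optimize_lambda(s, yt, Xt)
        _, b, XtDiX, q = _profile(lam, s, yt, Xt)
        sigma2 = q / (n - p0 - 1)
        cov = sigma2 * np.linalg.inv(XtDiX)
        beta[j] = b[-1]
        se_j = np.sqrt(max(cov[-1, -1], 0.0))
        se[j] = se_j
        if se_j > 0:
            stat = (b[-1] / se_j) ** 2
        else:  # zero residual variance: a perfect fit is infinitely significant
            stat = np.inf if b[-1] != 0 else 0.0
        pvals[j] = stats.chi2.sf(stat, df=1)
    return beta, se, pvals


def _scan_p3d(s, yt, X0t, Mt):
    """Null-model variance ratio held fixed; the scan is vectorized WLS.

    Frisch-Waugh: residualize the rotated phenotype and every rotated marker
    column against the rotated covariates under weights 1/(s + lambda), then
    each marker effect is a weighted simple regression.
    """
    n, p0 = X0t.shape
    lam, _ = _optimize_lambda(s, yt, X0t)
    w = 1.0 / (s + lam)
    XtW = X0t * w[:, None]
    A = XtW.T @ X0t
    yr = yt - X0t @ np.linalg.solve(A, XtW.T @ yt)
    Mr = Mt - X0t @ np.linalg.solve(A, XtW.T @ Mt)
    s_xx = np.einsum("ij,ij->j", Mr * w[:, None], Mr)
    s_xy = (Mr * w[:, None]).T @ yr
    q_y = float(np.sum(yr * yr * w))
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = s_xy / s_xx
        rss = q_y - s_xy ** 2 / s_xx
        sigma2 = rss / (n - p0 - 1)
        var_b = sigma2 / s_xx
    se = np.sqrt(np.clip(var_b, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, (beta / se) ** 2,
                        np.where(np.abs(beta) > 0, np.inf, 0.0))
    pvals = stats.chi2.sf(stat, df=1)
    return beta, se, pvals


def bin_peaks(res: pd.DataFrame, bin_size_bp: int = DEFAULT_BIN_BP) -> pd.DataFrame:
    """Lowest-P SNP per half-open window [k*B, (k+1)*B) on each chromosome.

    Ties inside a bin go to the lower position, then the lexicographically
    smaller marker id. Empty bins are omitted; the output is sorted by q_fdr
    then p_wald ascending.
    """
    if bin_size_bp < 1:
        raise ValueError("bin_size_bp must be >= 1")
    req = set(GWAS_COLUMNS) - {"beta", "se"}
    if not req.issubset(res.columns):
        raise ValueError(f"GWAS table lacks columns {sorted(req - set(res.columns))}")
    df = res.copy()
    df["_bin"] = df["position_bp"].to_numpy(dtype=np.int64) // int(bin_size_bp)
    df = df.sort_values(["p_wald", "position_bp", "marker_id"], kind="mergesort")
    top = df.groupby(["chromosome", "_bin"], sort=False).head(1).copy()
    top["bin_start_bp"] = top["_bin"] * int(bin_size_bp)
    top["bin_end_bp"] = (top["_bin"] + 1) * int(bin_size_bp)
    top = top.sort_values(["q_fdr", "p_wald", "chromosome", "bin_start_bp"],
                          kind="mergesort").reset_index(drop=True)
    return top[PEAK_COLUMNS]


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------

_TSV_RENAME = {"chromosome": "chr", "position_bp": "pos"}


def write_gwas_tsv(res: pd.DataFrame, path) -> None:
    res.rename(columns=_TSV_RENAME).to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path) -> pd.DataFrame:
    """Read a GWAS table (ours or externally produced in the same schema)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str, "chromosome": str})
    df = df.rename(columns={v: k for k, v in _TSV_RENAME.items()})
    missing = [c for c in GWAS_COLUMNS if c not in df.columns and c not in ("beta", "se")]
    if missing:
        raise ValueError(f"GWAS TSV lacks required columns {missing}")
    for c in ("beta", "se"):
        if c not in df.columns:
            df[c] = np.nan
    df["chromosome"] = df["chromosome"].astype(str)
    return df[GWAS_COLUMNS]


def write_peaks_tsv(peaks: pd.DataFrame, path) -> None:
    peaks.rename(columns=_TSV_RENAME).to_csv(path, sep="\t", index=False)
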