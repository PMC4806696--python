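"""Cluster-aware cross-validation for genomic prediction.

Breeding populations contain nests of close relatives (full sibs, parents and
offspring). Randomly scattering such relatives across folds lets the model
"predict" a line from its sib and inflates accuracy, so folds are built from
k-medoids (PAM) clusters of the genotype matrix: the number of clusters is
chosen by the largest average silhouette width, and every cluster is assigned
whole to one of the folds, balancing only fold size.

Cross-validation follows the CV1 scheme: the validation cell's phenotypes
(minus the validation individuals) may join the training data. Training
phenotypes are per-line adjusted values (within-cell least-squares means over
reps), averaged across the cells included in the training composition. For
the de novo GWAS method the association scan, peak binning, and fixed-effect
selection are redone per fold on training-fold lines only. Accuracy is the
Pearson correlation between predicted GEBVs and the adjusted phenotype of the
validation cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import pairwise_distances, silhouette_score

from . import gwas as gwas_mod
from .fixed_selection import (FixedEffectSet, applicability_score,
                              select_best_combination, select_candidates,
                              DEFAULT_FDR_THRESHOLD, DEFAULT_MAX_PRIMARY)
from .genotype_io import GenotypeMatrix, PhenotypeTable
from .gs_models import fit_mlr, fit_rrblup_fe, predict_gebv
from .kinship import compute_grm

logger = logging.getLogger(__name__)

Cell = tuple[str, int, str]  # (site, year, season)

CV_METHODS = ("rrblup", "rrblup_fe_denovo", "rrblup_fe_external", "mlr")


# ---------------------------------------------------------------------------
# k-medoids (PAM) and fold construction
# ---------------------------------------------------------------------------

def _pam(D: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Greedy BUILD initialization followed by best-improvement SWAP steps
    (each step evaluates every (medoid, candidate) replacement using the
    nearest/second-nearest decomposition). Deterministic.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    for _ in range(1, k):
        d_near = D[:, medoids].min(axis=1)
        gains = np.maximum(d_near[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    med = np.array(medoids)
    for _ in range(max_iter):
        dm = D[:, med]
        order = np.argsort(dm, axis=1, kind="mergesort")
        nearest = order[:, 0]
        d1 = dm[np.arange(n), nearest]
        d2 = dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        for ii in range(k):
            mask = nearest == ii
            t = np.minimum(D[~mask] - d1[~mask, None], 0.0).sum(axis=0)
            if mask.any():
                t = t + (np.minimum(D[mask], d2[mask, None]) - d1[mask, None]).sum(axis=0)
            t[med] = np.inf
            j = int(np.argmin(t))
            if t[j] < best_delta:
                best_delta, best_swap = t[j], (ii, j)
        if best_swap is None:
            break
        med[best_swap[0]] = best_swap[1]
    return med


def _pam_labels(D: np.ndarray, med: np.ndarray) -> np.ndarray:
    return np.argmin(D[:, med], axis=1)


@dataclass
class FoldAssignment:
    """Cluster and fold membership of every line, plus the silhouette-chosen k."""

    cluster_of: dict[str, int]
    fold_of: dict[str, int]
    k_chosen: int
    silhouette: float
    seed: int
    n_folds: int

    def lines_in_fold(self, fold: int) -> list[str]:
        return [l for l, f in self.fold_of.items() if f == fold]

    @property
    def line_ids(self) -> list[str]:
        return list(self.fold_of)


def default_k_candidates(n_lines: int) -> list[int]:
    """Coarse silhouette scan grid: 2..min(150, n-1) in steps of 5."""
    hi = min(150, n_lines - 1)
    return list(range(2, hi + 1, 5))


def build_folds(g: GenotypeMatrix, n_folds: int = 5,
                k_candidates: list[int] | None = None,
                seed: int = 0, refine: bool = True) -> FoldAssignment:
    """Silhouette-optimal PAM clustering followed by whole-cluster fold assignment.

    Distances are Euclidean on the (imputed) dosage matrix. Each candidate k
    is clustered by PAM and scored by average silhouette width; the best k
    (ties -> smaller) wins, and with ``refine`` the scan is repeated at step 1
    within +/-4 of the coarse optimum. Clusters are then assigned whole to
    folds in decreasing size order, each onto the currently smallest fold,
    shuffling equal-size clusters and breaking fold-size ties randomly under
    ``seed``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if np.isnan(g.dosage).any():
        raise ValueError("impute genotypes before fold construction")
    n = g.n_lines
    D = pairwise_distances(g.dosage, metric="euclidean")
    cands = sorted(set(k_candidates)) if k_candidates is not None else default_k_candidates(n)
    if any(k < 2 or k > n - 1 for k in cands):
        raise ValueError(f"k candidates must lie in [2, {n - 1}]")

    def score(k: int):
        med = _pam(D, k)
        labels = _pam_labels(D, med)
        uniq, labels = np.unique(labels, return_inverse=True)
        if len(uniq) < 2:
            return -np.inf, labels
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sil = float(silhouette_score(D, labels, metric="precomputed"))
        return sil, labels

    results = {k: score(k) for k in cands}
    k_best = max(results, key=lambda k: (results[k][0], -k))
    if refine:
        extra = [k for k in range(max(2, k_best - 4), min(n - 1, k_best + 4) + 1)
                 if k not in results]
        for k in extra:
            results[k] = score(k)
        k_best = max(results, key=lambda k: (results[k][0], -k))
    sil_best, labels = results[k_best]

    rng = np.random.default_rng(seed)
    clusters: dict[int, list[str]] = {}
    for line, lab in zip(g.line_ids, labels):
        clusters.setdefault(int(lab), []).append(line)
    sizes = {c: len(v) for c, v in clusters.items()}
    max_size = max(sizes.values())
    if max_size > 2 * n / n_folds:
        logger.warning("largest cluster (%d lines) exceeds 2*n/n_folds; "
                       "fold balance will be poor", max_size)
    order = list(clusters)
    rng.shuffle(order)  # randomizes the order of equal-size clusters
    order.sort(key=lambda c: -sizes[c])  # stable: keeps shuffle within ties
    fold_sizes = np.zeros(n_folds, dtype=int)
    fold_of: dict[str, int] = {}
    for c in order:
        smallest = np.flatnonzero(fold_sizes == fold_sizes.min())
        f = int(rng.choice(smallest))
        for line in clusters[c]:
            fold_of[line] = f + 1
        fold_sizes[f] += sizes[c]
    cluster_of = {line: int(lab) for line, lab in zip(g.line_ids, labels)}
    return FoldAssignment(cluster_of=cluster_of, fold_of=fold_of,
                          k_chosen=int(k_best), silhouette=sil_best,
                          seed=seed, n_folds=n_folds)


# ---------------------------------------------------------------------------
# Adjusted phenotypes
# ---------------------------------------------------------------------------

def adjust_phenotypes(p: PhenotypeTable, cell: Cell, trait: str) -> pd.Series:
    """Per-line adjusted value within one site x year x season cell.

    Least-squares means from the two-way fixed-effects model
    value ~ line + rep; with a single rep (or no rep structure) this is the
    plain line mean. Lines absent from the cell are simply absent from the
    returned Series (logged).
    """
    site, year, season = cell
    df = p.cell(site, year, season, trait).dropna(subset=["value"])
    if len(df) == 0:
        raise ValueError(f"no records for trait {trait!r} in cell {cell}")
    reps = df["rep"].dropna().unique()
    lines = sorted(df["line_id"].unique())
    per_line_count = df.groupby("line_id").size()
    if len(reps) < 2 or (per_line_count <= 1).all():
        out = df.groupby("line_id")["value"].mean()
        return out.reindex(lines)
    # LS-means: solve value ~ line + rep by least squares, then evaluate each
    # line averaged over all rep levels.
    line_idx = {l: i for i, l in enumerate(lines)}
    rep_levels = sorted(reps)
    rep_idx = {r: i for i, r in enumerate(rep_levels)}
    n = len(df)
    X = np.zeros((n, len(lines) + len(rep_levels) - 1))
    for row, (l, r) in enumerate(zip(df["line_id"], df["rep"])):
        X[row, line_idx[l]] = 1.0
        if pd.notna(r) and rep_idx[r] > 0:  # first rep level is the reference
            X[row, len(lines) + rep_idx[r] - 1] = 1.0
    coef, *_ = np.linalg.lstsq(X, df["value"].to_numpy(dtype=float), rcond=None)
    rep_effects = np.concatenate([[0.0], coef[len(lines):]])
    lsmean = coef[:len(lines)] + rep_effects.mean()
    return pd.Series(lsmean, index=pd.Index(lines, name="line_id"))


@dataclass
class TrainingComposition:
    """Which site x year x season cells feed the training data (CV1)."""

    included: list[Cell]
    validation_cell: Cell
    scheme: str = "cv1"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.scheme != "cv1":
            raise ValueError("only the cv1 scheme is supported")
        self.included = [(s, int(y), se) for s, y, se in self.included]
        s, y, se = self.validation_cell
        self.validation_cell = (s, int(y), se)
        if self.name is None:
            self.name = "+".join(f"{s}-{y}-{se}" for s, y, se in self.included)


# ---------------------------------------------------------------------------
# Cross-validated prediction
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Per-fold and mean prediction accuracies with provenance."""

    folds: pd.DataFrame  # fold, n_test, accuracy (+ fixed-effect columns)
    mean_accuracy: float
    method: str
    trait: str
    composition: TrainingComposition
    seed: int
    fold_assignment: FoldAssignment
    fixed_sets: dict[int, FixedEffectSet] = field(default_factory=dict)
    audit: dict = field(default_factory=dict)


def _composite_training_values(adjusted: dict[Cell, pd.Series],
                               cells: list[Cell], lines: list[str]) -> pd.Series:
    """Average adjusted values across cells, per line; lines with no data dropped."""
    frames = [adjusted[c].rename(str(c)) for c in cells]
    wide = pd.concat(frames, axis=1)
    means = wide.mean(axis=1)
    return means.loc[means.index.intersection(lines)].dropna()


def run_cv(g: GenotypeMatrix, p: PhenotypeTable, trait: str,
           composition: TrainingComposition, method: str, folds: FoldAssignment,
           gwas_source_cell: Cell | None = None, seed: int = 0, *,
           external_gwas: pd.DataFrame | None = None,
           aux_trait: str | None = None,
           fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
           bin_size_bp: int = gwas_mod.DEFAULT_BIN_BP,
           max_primary: int = DEFAULT_MAX_PRIMARY,
           gwas_mode: str = "exact_per_marker",
           mlr_max_markers: int = 100,
           min_test_lines: int = 3) -> CvResult:
    """Cross-validated genomic prediction under CV1 semantics.

    For each fold: training phenotypes are composite adjusted values over the
    composition cells, restricted to training-fold lines; for
    ``rrblup_fe_denovo`` the GWAS is re-run per fold on training-fold lines
    using the ``gwas_source_cell`` phenotypes and fixed effects re-selected
    per fold; GEBVs are predicted for the validation-fold lines and scored
    against the validation cell's adjusted phenotype.
    """
    if method not in CV_METHODS:
        raise ValueError(f"method must be one of {CV_METHODS}")
    if method == "rrblup_fe_denovo" and gwas_source_cell is None:
        raise ValueError("rrblup_fe_denovo requires gwas_source_cell")
    if method == "rrblup_fe_external" and external_gwas is None:
        raise ValueError("rrblup_fe_external requires an external GWAS table")

    fold_lines = folds.line_ids
    g = g.take_lines([l for l in g.line_ids if l in set(fold_lines)])
    if np.isnan(g.dosage).any():
        raise ValueError("impute genotypes before cross-validation")

    cells = list(composition.included)
    if composition.validation_cell not in cells:
        logger.info("CV1: validation cell %s added to the training composition "
                    "(validation individuals stay excluded)", composition.validation_cell)
        cells = cells + [composition.validation_cell]
    adjusted = {c: adjust_phenotypes(p, c, trait) for c in cells}
    gwas_adjusted = None
    if method == "rrblup_fe_denovo":
        gwas_adjusted = adjust_phenotypes(p, gwas_source_cell, trait)
    aux_adjusted = None
    if aux_trait is not None and aux_trait != trait and method in (
            "rrblup_fe_denovo",):
        src = gwas_source_cell if gwas_source_cell is not None else composition.validation_cell
        aux_adjusted = adjust_phenotypes(p, src, aux_trait)
    val_pheno = adjusted[composition.validation_cell]

    rows = []
    fixed_sets: dict[int, FixedEffectSet] = {}
    audit: dict = {"leakage_checked": True, "folds": {}}
    grm_cache: dict[tuple, object] = {}

    def cached_grm(gm, exclude):
        key = (tuple(gm.line_ids), tuple(sorted(exclude)))
        if key not in grm_cache:
            grm_cache[key] = compute_grm(gm, exclude=list(exclude))
        return grm_cache[key]
    for f in range(1, folds.n_folds + 1):
        test_lines = [l for l in g.line_ids if folds.fold_of[l] == f]
        train_lines = [l for l in g.line_ids if folds.fold_of[l] != f]
        y_train_s = _composite_training_values(adjusted, cells, train_lines)
        train_ph_lines = list(y_train_s.index)
        if len(train_ph_lines) < 10:
            raise ValueError(f"fold {f}: only {len(train_ph_lines)} phenotyped training lines")
        g_train = g.take_lines(train_ph_lines)
        g_joint = g.take_lines(train_ph_lines + test_lines)
        y_train = y_train_s.to_numpy(dtype=float)

        fes = None
        if method in ("rrblup_fe_denovo", "rrblup_fe_external"):
            if method == "rrblup_fe_denovo":
                gl = [l for l in train_ph_lines if l in gwas_adjusted.index
                      and pd.notna(gwas_adjusted[l])]
                g_gwas = g.take_lines(gl)
                y_gwas = gwas_adjusted.loc[gl].to_numpy(dtype=float)
                K_gwas = compute_grm(g_gwas)
                res = gwas_mod.run_lmm_gwas(g_gwas, y_gwas, K_gwas, mode=gwas_mode)
                gwas_lines = set(gl)
            else:
                res = external_gwas
                gwas_lines = set()
            peaks = gwas_mod.bin_peaks(res, bin_size_bp)
            aux_peaks = None
            if aux_adjusted is not None:
                al = [l for l in train_ph_lines if l in aux_adjusted.index
                      and pd.notna(aux_adjusted[l])]
                g_aux = g.take_lines(al)
                res_aux = gwas_mod.run_lmm_gwas(
                    g_aux, aux_adjusted.loc[al].to_numpy(dtype=float),
                    compute_grm(g_aux), mode=gwas_mode)
                aux_peaks = gwas_mod.bin_peaks(res_aux, bin_size_bp)
                gwas_lines |= set(al)
            cands = select_candidates(peaks, fdr_threshold, max_primary, aux_peaks)
            fes = select_best_combination(cands, g_train, y_train)
            fixed_sets[f] = fes
        else:
            gwas_lines = set()

        # leakage audit: no validation-fold line contributes a phenotype to
        # training or to the fold GWAS
        assert not (set(train_ph_lines) & set(test_lines))
        assert not (gwas_lines & set(test_lines))
        audit["folds"][f] = {
            "n_train_pheno": len(train_ph_lines),
            "n_gwas_lines": len(gwas_lines),
            "train_test_overlap": 0,
            "gwas_test_overlap": 0,
        }

        if method == "mlr":
            model = fit_mlr(y_train, g_train, max_markers=mlr_max_markers)
        else:
            fixed_ids = fes.marker_ids if fes is not None else []
            model = fit_rrblup_fe(y_train, g_train, fes, g_joint=g_joint,
                                  joint_kinship=cached_grm(g_joint, fixed_ids))
        gebv = predict_gebv(model, test_lines, g_joint)

        have = [i for i, l in enumerate(test_lines)
                if l in val_pheno.index and pd.notna(val_pheno[l])]
        dropped = len(test_lines) - len(have)
        if dropped:
            logger.info("fold %d: %d test lines lack validation phenotypes; dropped",
                        f, dropped)
        if len(have) < min_test_lines:
            raise ValueError(f"fold {f}: only {len(have)} test lines with validation "
                             f"phenotypes; accuracy undefined")
        y_val = val_pheno.loc[[test_lines[i] for i in have]].to_numpy(dtype=float)
        acc = float(sps.pearsonr(gebv[have], y_val)[0])
        row = {"fold": f, "n_test": len(have), "accuracy": acc}
        if fes is not None:
            score, rec = applicability_score(fes)
            row.update(marker_ids=",".join(fes.marker_ids),
                       mean_q_fdr=fes.mean_q_fdr, min_q_fdr=fes.min_q_fdr,
                       applicability_score=score, recommended=rec,
                       fallback_used=fes.fallback_used)
        rows.append(row)

    fold_df = pd.DataFrame(rows)
    return CvResult(folds=fold_df, mean_accuracy=float(fold_df["accuracy"].mean()),
                    method=method, trait=trait, composition=composition, seed=seed,
                    fold_assignment=folds, fixed_sets=fixed_sets, audit=audit)


def multi_environment_sweep(g: GenotypeMatrix, p: PhenotypeTable, trait: str,
                            compositions: list[TrainingComposition],
                            methods: list[str], folds: FoldAssignment,
                            seed: int = 0, **run_cv_kwargs) -> pd.DataFrame:
    """Cartesian execution of training compositions x methods with shared folds.

    Returns a tidy table (composition, validation cell, method, fold,
    accuracy) with per-composition mean rows flagged by ``is_mean``.
    """
    if not compositions:
        raise ValueError("no training compositions given")
    out = []
    for comp in compositions:
        for method in methods:
            res = run_cv(g, p, trait, comp, method, folds, seed=seed, **run_cv_kwargs)
            for r in res.folds.itertuples():
                out.append({"composition": comp.name, "validation_cell": str(comp.validation_cell),
                            "method": method, "fold": r.fold, "n_test": r.n_test,
                            "accuracy": r.accuracy, "is_mean": False})
            out.append({"composition": comp.name, "validation_cell": str(comp.validation_cell),
                        "method": method, "fold": None, "n_test": int(res.folds["n_test"].sum()),
                        "accuracy": res.mean_accuracy, "is_mean": True})
    return pd.DataFrame(out)


def write_cv_results_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
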