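"""Choosing the markers to fit as fixed effects in the prediction model.

From the binned GWAS peaks of the focal trait, up to three SNPs passing an
FDR threshold (default q <= 0.1) are kept as candidates; if none pass, the
single lowest-P peak is carried forward as a fallback. Optionally the single
most significant SNP for a secondary trait (flowering time, whose variation
shifts most other agronomic traits) is added as a fourth candidate. All
non-empty subsets of the candidates are then scored by ordinary least squares
on the training data only, and the subset whose fitted values correlate best
with the training phenotype becomes the fixed-effect set. The average of the
selected SNPs' FDR-corrected P-values is reported alongside; a model is
recommended for use when -log10 of the best corrected P-value is >= 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.1
DEFAULT_MAX_PRIMARY = 3
#: -log10(q) at or above which the fixed-effect model is recommended
RECOMMEND_SCORE = 2.0
#: training-fit correlations closer than this are treated as tied (in-sample
#: correlation never decreases when a marker is added, so exact comparison
#: would always select the full candidate set even for pure numerical noise)
CORR_TIE = 1e-9


@dataclass
class CandidateSet:
    """Candidate fixed-effect SNPs: up to three for the focal trait plus an
    optional one from a secondary trait."""

    primary: list[tuple[str, float]]
    auxiliary: tuple[str, float] | None = None
    fallback_used: bool = False

    def all_markers(self) -> list[str]:
        ids = [m for m, _ in self.primary]
        if self.auxiliary is not None:
            ids.append(self.auxiliary[0])
        return ids

    def q_of(self, marker_id: str) -> float:
        for m, q in self.primary:
            if m == marker_id:
                return q
        if self.auxiliary is not None and self.auxiliary[0] == marker_id:
            return self.auxiliary[1]
        raise KeyError(marker_id)


@dataclass
class FixedEffectSet:
    """The selected fixed-effect markers and their training-fit summary."""

    marker_ids: list[str]
    design_columns: np.ndarray
    mean_q_fdr: float
    min_q_fdr: float
    training_fit_corr: float
    fallback_used: bool = False
    candidate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= len(self.marker_ids) <= 4):
            raise ValueError("fixed-effect set must hold 1-4 markers")


def select_candidates(peaks: pd.DataFrame,
                      fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                      max_primary: int = DEFAULT_MAX_PRIMARY,
                      auxiliary_peaks: pd.DataFrame | None = None) -> CandidateSet:
    """Candidate SNPs from binned peaks under the FDR rule.

    Primary = the lowest-q peaks with q <= threshold (at most ``max_primary``);
    if no peak passes, the single lowest-P peak with ``fallback_used`` set.
    Auxiliary = the single most significant peak of ``auxiliary_peaks`` when
    given; it is dropped if it duplicates a primary candidate.
    """
    if peaks is None or len(peaks) == 0:
        raise ValueError("empty peak table")
    ranked = peaks.sort_values(["q_fdr", "p_wald", "marker_id"], kind="mergesort")
    passing = ranked[ranked["q_fdr"] <= fdr_threshold]
    if len(passing) > 0:
        primary = [(r.marker_id, float(r.q_fdr))
                   for r in passing.head(max_primary).itertuples()]
        fallback = False
    else:
        top = ranked.sort_values(["p_wald", "q_fdr", "marker_id"], kind="mergesort").iloc[0]
        primary = [(top["marker_id"], float(top["q_fdr"]))]
        fallback = True
    auxiliary = None
    if auxiliary_peaks is not None and len(auxiliary_peaks) > 0:
        aux = auxiliary_peaks.sort_values(
            ["q_fdr", "p_wald", "marker_id"], kind="mergesort").iloc[0]
        if aux["marker_id"] not in {m for m, _ in primary}:
            auxiliary = (aux["marker_id"], float(aux["q_fdr"]))
    return CandidateSet(primary=primary, auxiliary=auxiliary, fallback_used=fallback)


def select_best_combination(cands: CandidateSet, g_train: GenotypeMatrix,
                            y_train: np.ndarray) -> FixedEffectSet:
    """Exhaustive search over candidate subsets for the best training-data fit.

    Every non-empty subset of the candidates is fit by OLS (subset dosage
    columns plus intercept) on the training data; the score is the Pearson
    correlation between fitted values and the training phenotype. Ties prefer
    fewer markers, then lower mean q. Collinear candidate columns are dropped
    (later-ranked duplicate loses) with a warning.
    """
    y = np.asarray(y_train, dtype=np.float64).ravel()
    if y.size != g_train.n_lines:
        raise ValueError("training phenotype does not align with training genotypes")
    markers = cands.all_markers()
    cols = g_train.dosage[:, g_train.marker_index(markers)]
    if np.isnan(cols).any():
        raise ValueError("candidate dosage columns contain missing values; impute first")
    # drop all-constant columns outright, and later-ranked collinear duplicates
    keep: list[int] = []
    for j in range(cols.shape[1]):
        if cols[:, j].std() == 0.0:
            logger.warning("candidate %s constant in training data; dropped", markers[j])
            continue
        trial = cols[:, keep + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), trial])) < trial.shape[1] + 1:
            logger.warning("candidate %s collinear with earlier candidates; dropped", markers[j])
            continue
        keep.append(j)
    if not keep:
        raise ValueError("all candidate columns constant or collinear in training data")
    markers = [markers[j] for j in keep]
    cols = cols[:, keep]

    scored = []  # (subset, corr, mean_q)
    for size in range(1, len(markers) + 1):
        for subset in combinations(range(len(markers)), size):
            X = np.column_stack([np.ones(y.size), cols[:, list(subset)]])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            fitted = X @ coef
            if fitted.std() == 0.0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(fitted, y)[0, 1])
            mean_q = float(np.mean([cands.q_of(markers[j]) for j in subset]))
            scored.append((subset, corr, mean_q))
    # correlations within CORR_TIE of the maximum count as tied; ties prefer
    # fewer markers, then lower mean q
    c_max = max(c for _, c, _ in scored)
    tied = [s for s in scored if s[1] >= c_max - CORR_TIE]
    subset, corr, mean_q = min(tied, key=lambda s: (len(s[0]), s[2], s[0]))
    chosen = [markers[j] for j in subset]
    qs = [cands.q_of(m) for m in chosen]
    return FixedEffectSet(
        marker_ids=chosen,
        design_columns=cols[:, list(subset)],
        mean_q_fdr=mean_q,
        min_q_fdr=float(min(qs)),
        training_fit_corr=corr,
        fallback_used=cands.fallback_used,
        candidate_ids=markers,
    )


def applicability_score(fes: FixedEffectSet) -> tuple[float, bool]:
    """-log10 of the best (lowest) corrected P among the selected markers.

    The fixed-effect model is recommended over plain RR-BLUP when the score
    is >= 2.0, i.e. when the best SNP is convincingly significant after
    multiple-test correction.
    """
    score = float(-np.log10(fes.min_q_fdr))
    return score, bool(score >= RECOMMEND_SCORE)


def write_fixed_sets_tsv(rows: list[dict], path) -> None:
    """Serialize per-fold fixed-effect sets (fold, markers, q stats, fit)."""
    pd.DataFrame(rows, columns=["fold", "marker_ids", "mean_q_fdr", "min_q_fdr",
                                "training_fit_corr", "fallback_used"]).to_csv(
        path, sep="\t", index=False)
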