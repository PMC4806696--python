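"""Genomic relationship matrix (VanRaden method 1).

G = W W' / (2 * sum_j p_j (1 - p_j)), where W is the dosage matrix with each
column centered by twice its observed alternate-allele frequency. G serves as
the covariance of the random line effects in GBLUP / RR-BLUP; markers fit as
fixed effects in the prediction model can be excluded from its computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix


@dataclass
class KinshipMatrix:
    """Symmetric lines x lines genomic relationship matrix."""

    line_ids: list[str]
    values: np.ndarray
    excluded_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kinship shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kinship contains non-finite entries")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("kinship is not symmetric")
        # enforce exact symmetry for downstream eigendecompositions
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset(self, line_ids) -> "KinshipMatrix":
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        idx = np.array([lookup[l] for l in line_ids], dtype=np.intp)
        return KinshipMatrix(list(line_ids), self.values[np.ix_(idx, idx)],
                             list(self.excluded_markers))

    def block(self, rows, cols) -> np.ndarray:
        """Rectangular sub-block (e.g. target x training relationships)."""
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        ri = np.array([lookup[l] for l in rows], dtype=np.intp)
        ci = np.array([lookup[l] for l in cols], dtype=np.intp)
        return self.values[np.ix_(ri, ci)]


def compute_grm(g: GenotypeMatrix, exclude: list[str] | None = None) -> KinshipMatrix:
    """VanRaden method-1 G from a complete (imputed) dosage matrix.

    Columns are centered by 2*p_j with p_j the observed alt-allele frequency;
    the denominator is 2*sum_j p_j(1-p_j) over the markers actually used.
    Markers listed in ``exclude`` contribute nothing. Monomorphic markers add
    zero to both numerator and denominator, but a matrix with no polymorphic
    marker after exclusion is an error (denominator would vanish).
    """
    exclude = list(exclude or [])
    if np.isnan(g.dosage).any():
        raise ValueError("genotypes contain missing values; impute before compute_grm")
    if exclude:
        g.marker_index(exclude)  # validate ids
        keep = ~g.markers["marker_id"].isin(exclude).to_numpy()
    else:
        keep = np.ones(g.n_markers, dtype=bool)
    if not keep.any():
        raise ValueError("no markers remain after exclusion")
    X = g.dosage[:, keep]
    if not (X.std(axis=0) > 0.0).any():
        raise ZeroDivisionError(
            "all markers monomorphic after exclusion; G would be identically zero")
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    W = X - 2.0 * p[None, :]
    G = (W @ W.T) / denom
    return KinshipMatrix(list(g.line_ids), G, exclude)


def write_kinship_tsv(k: KinshipMatrix, path) -> None:
    df = pd.DataFrame(k.values, index=k.line_ids, columns=k.line_ids)
    df.index.name = "line_id"
    df.to_csv(path, sep="\t")


def read_kinship_tsv(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("kinship TSV row and column line ids differ")
    return KinshipMatrix([str(l) for l in df.index], df.to_numpy(dtype=np.float64))
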