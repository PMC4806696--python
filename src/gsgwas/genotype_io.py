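"""Genotype and phenotype I/O: reading, validation, filtering, imputation, subsetting.

Genotypes are held as an allele-dosage matrix (lines x markers, entries 0/1/2
counting copies of the alternate allele, NaN for missing) together with a marker
map of genomic coordinates. Phenotypes are a long-format table keyed by
(line, trait, site, year, season, rep), the shape in which multi-environment
breeding-trial data usually arrives.

Supported genotype formats: VCF (biallelic SNPs, GT field), HapMap
(tab-delimited, allele-pair or IUPAC diploid calls), and a plain dosage TSV
(header = marker ids, first column = line id, cells in {0,1,2,NA}).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_ref", "allele_alt"]

#: IUPAC ambiguity codes for heterozygous diploid calls in HapMap files.
_IUPAC_HET = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}


class FormatError(ValueError):
    """A file does not parse under the named standard."""


class EmptyResultError(ValueError):
    """An operation removed every marker or line."""


def build_marker_map(marker_id, chromosome, position_bp,
                     allele_ref=None, allele_alt=None) -> pd.DataFrame:
    """Assemble and validate a marker map DataFrame.

    Positions are 1-based as in VCF/HapMap. Marker ids must be unique and
    positions >= 1; markers need not arrive sorted but must be sortable by
    (chromosome, position).
    """
    n = len(marker_id)
    mm = pd.DataFrame({
        "marker_id": pd.array(marker_id, dtype="str"),
        "chromosome": pd.array(chromosome, dtype="str"),
        "position_bp": np.asarray(position_bp, dtype=np.int64),
        "allele_ref": pd.array(allele_ref if allele_ref is not None else [None] * n, dtype="str"),
        "allele_alt": pd.array(allele_alt if allele_alt is not None else [None] * n, dtype="str"),
    })
    if mm["marker_id"].duplicated().any():
        dups = mm.loc[mm["marker_id"].duplicated(), "marker_id"].tolist()[:5]
        raise ValueError(f"duplicate marker ids: {dups}")
    if (mm["position_bp"] < 1).any():
        raise ValueError("marker positions must be >= 1 (1-based coordinates)")
    return mm


@dataclass
class GenotypeMatrix:
    """Lines x markers allele-dosage matrix with marker map and provenance.

    ``dosage`` is float64 with NaN marking missing calls; non-missing raw calls
    are in {0, 1, 2} (imputation introduces fractional values, recorded in
    provenance).
    """

    line_ids: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if self.dosage.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.markers)} markers")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def line_index(self, line_ids) -> np.ndarray:
        """Row indices for the given line ids (error on unknown ids)."""
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in lookup]
        if missing:
            raise KeyError(f"lines not genotyped: {missing[:10]}")
        return np.array([lookup[l] for l in line_ids], dtype=np.intp)

    def marker_index(self, marker_ids) -> np.ndarray:
        lookup = {m: j for j, m in enumerate(self.markers["marker_id"])}
        missing = [m for m in marker_ids if m not in lookup]
        if missing:
            raise KeyError(f"unknown markers: {missing[:10]}")
        return np.array([lookup[m] for m in marker_ids], dtype=np.intp)

    def take_lines(self, line_ids, note: str | None = None) -> "GenotypeMatrix":
        idx = self.line_index(line_ids)
        prov = self.provenance + ([note] if note else [])
        return GenotypeMatrix(list(line_ids), self.markers.reset_index(drop=True),
                              self.dosage[idx], prov)

    def take_markers(self, marker_ids, note: str | None = None) -> "GenotypeMatrix":
        idx = self.marker_index(marker_ids)
        prov = self.provenance + ([note] if note else [])
        return GenotypeMatrix(list(self.line_ids),
                              self.markers.iloc[idx].reset_index(drop=True),
                              self.dosage[:, idx], prov)


@dataclass
class PhenotypeTable:
    """Long-format trait observations keyed by (line, trait, site, year, season, rep)."""

    records: pd.DataFrame

    COLUMNS = ["line_id", "trait", "value", "site", "year", "season", "rep"]

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        missing = [c for c in self.COLUMNS if c not in df.columns and c != "rep"]
        if missing:
            raise ValueError(f"phenotype table lacks columns: {missing}")
        if "rep" not in df.columns:
            df["rep"] = pd.NA
        df["year"] = df["year"].astype(int)
        bad_season = set(df["season"].unique()) - {"dry", "wet"}
        if bad_season:
            raise ValueError(f"season must be 'dry' or 'wet', got {sorted(bad_season)}")
        vals = pd.to_numeric(df["value"], errors="raise")
        if np.isinf(vals.dropna()).any():
            raise ValueError("phenotype values must be finite")
        df["value"] = vals
        key = ["line_id", "trait", "site", "year", "season", "rep"]
        if df.duplicated(subset=key).any():
            raise ValueError("duplicate (line, trait, site, year, season, rep) records")
        self.records = df[self.COLUMNS].reset_index(drop=True)

    def cell(self, site: str, year: int, season: str, trait: str) -> pd.DataFrame:
        """All records for one trait in one site x year x season cell."""
        r = self.records
        return r[(r["site"] == site) & (r["year"] == int(year))
                 & (r["season"] == season) & (r["trait"] == trait)]

    def cells(self, trait: str | None = None) -> list[tuple[str, int, str]]:
        """Distinct (site, year, season) cells, optionally for one trait."""
        r = self.records
        if trait is not None:
            r = r[r["trait"] == trait]
        return sorted({(s, int(y), se) for s, y, se in
                       zip(r["site"], r["year"], r["season"])})


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str) -> GenotypeMatrix:
    """Read a genotype file into a dosage matrix.

    ``fmt`` is one of ``vcf``, ``hapmap``, ``dosage_tsv``. Dosages count
    copies of the alternate allele. Multi-allelic sites are skipped with a
    logged count; an input yielding zero markers is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"vcf": _read_vcf, "hapmap": _read_hapmap, "dosage_tsv": _read_dosage_tsv}
    if fmt not in readers:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(readers)}")
    g = readers[fmt](path)
    if g.n_markers == 0:
        raise EmptyResultError(f"no biallelic SNP markers parsed from {path}")
    return g


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "nan", ""])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse dosage TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise EmptyResultError(f"no marker columns in {path}")
    mat = df.to_numpy(dtype=np.float64)
    obs = mat[~np.isnan(mat)]
    if obs.size and not np.all(np.isin(obs, [0.0, 1.0, 2.0])):
        bad = obs[~np.isin(obs, [0.0, 1.0, 2.0])][0]
        raise FormatError(f"dosage TSV {path}: cell value {bad!r} not in {{0,1,2,NA}}")
    marker_ids = [str(c) for c in df.columns]
    # No coordinates in a bare dosage file: place markers on a single dummy
    # chromosome at consecutive positions so downstream code stays usable.
    mm = build_marker_map(marker_ids, ["0"] * len(marker_ids),
                          np.arange(1, len(marker_ids) + 1))
    return GenotypeMatrix([str(i) for i in df.index], mm, mat,
                          [f"read dosage_tsv {path.name}: {df.shape[0]} lines x {df.shape[1]} markers"])


def read_marker_map(path) -> pd.DataFrame:
    """Read a marker map TSV (marker_id, chromosome, position_bp[, alleles])."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return build_marker_map(
        df["marker_id"].astype(str), df["chromosome"], df["position_bp"],
        df.get("allele_ref"), df.get("allele_alt"))


def attach_marker_map(g: GenotypeMatrix, mm: pd.DataFrame) -> GenotypeMatrix:
    """Replace a GenotypeMatrix's marker map (e.g. after a bare dosage TSV read)."""
    mm = mm.set_index("marker_id").loc[g.markers["marker_id"]].reset_index()
    return GenotypeMatrix(g.line_ids, build_marker_map(
        mm["marker_id"], mm["chromosome"], mm["position_bp"],
        mm["allele_ref"], mm["allele_alt"]), g.dosage,
        g.provenance + ["attached marker map"])


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    line_ids = list(vcf.samples)
    ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = rec.genotype.array()[:, :2].astype(np.float64)
        gt[gt < 0] = np.nan  # missing alleles coded -1 by cyvcf2
        dos = gt.sum(axis=1)
        dos[np.isnan(gt).any(axis=1)] = np.nan
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        cols.append(dos)
    if n_skipped:
        logger.info("VCF %s: skipped %d non-biallelic-SNP records", path.name, n_skipped)
    mat = np.column_stack(cols) if cols else np.empty((len(line_ids), 0))
    mm = build_marker_map(ids, chroms, poss if poss else [], refs, alts)
    prov = [f"read vcf {path.name}: {len(line_ids)} lines x {len(ids)} markers, "
            f"{n_skipped} non-biallelic records skipped"]
    return GenotypeMatrix(line_ids, mm, mat, prov)


_HAPMAP_META_COLS = 11  # rs#, alleles, chrom, pos, strand, assembly, center, protLSID, assayLSID, panelLSID, QCcode


def _read_hapmap(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) <= _HAPMAP_META_COLS or not header[0].lower().startswith("rs"):
            raise FormatError(f"{path}: not a HapMap header (first record: {header[:3]})")
        line_ids = header[_HAPMAP_META_COLS:]
        ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
        n_skipped = 0
        for lineno, raw in enumerate(fh, start=2):
            f = raw.rstrip("\n").split("\t")
            if len(f) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(f)}")
            alleles = f[1].split("/")
            if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
                n_skipped += 1
                continue
            ref, alt = alleles
            dos = np.empty(len(line_ids))
            for i, call in enumerate(f[_HAPMAP_META_COLS:]):
                d = _hapmap_call_dosage(call, ref, alt)
                if d is False:
                    raise FormatError(f"{path}:{lineno}: bad call {call!r} for alleles {ref}/{alt}")
                dos[i] = np.nan if d is None else d
            ids.append(f[0]); chroms.append(f[2]); poss.append(int(f[3]))
            refs.append(ref); alts.append(alt); cols.append(dos)
    if n_skipped:
        logger.info("HapMap %s: skipped %d non-biallelic records", path.name, n_skipped)
    mat = np.column_stack(cols) if cols else np.empty((len(line_ids), 0))
    mm = build_marker_map(ids, chroms, poss, refs, alts)
    return GenotypeMatrix(line_ids, mm, mat,
                          [f"read hapmap {path.name}: {len(line_ids)} lines x {len(ids)} markers, "
                           f"{n_skipped} non-biallelic records skipped"])


def _hapmap_call_dosage(call: str, ref: str, alt: str):
    """Dosage of ``alt`` for a HapMap genotype call; None = missing, False = malformed."""
    call = call.strip().upper()
    if call in ("NN", "N", "--", "-", "./.", ""):
        return None
    if len(call) == 1:
        if call in _IUPAC_HET:
            pair = _IUPAC_HET[call]
            if set(pair) == {ref, alt}:
                return 1.0
            return False
        call = call + call  # homozygous single-letter call
    if len(call) != 2:
        return False
    d = 0.0
    for a in call:
        if a == alt:
            d += 1.0
        elif a != ref:
            return False
    return d


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def marker_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate, alt-allele frequency, MAF, and observed-value count."""
    obs = ~g.missing_mask
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(g.dosage, axis=0) / np.where(n_obs > 0, 2.0 * n_obs, np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    n_distinct = np.array([len(np.unique(col[o])) for col, o in
                           zip(g.dosage.T, obs.T)])
    return pd.DataFrame({
        "marker_id": g.markers["marker_id"].to_numpy(),
        "call_rate": n_obs / g.n_lines,
        "p_alt": p_alt,
        "maf": maf,
        "n_distinct_obs": n_distinct,
    })


def filter_markers(g: GenotypeMatrix, min_call_rate: float = 0.75,
                   min_maf: float = 0.0, drop_monomorphic: bool = True) -> GenotypeMatrix:
    """Drop markers failing call-rate, MAF, or polymorphism requirements.

    Call rate and MAF are computed on non-missing entries; the monomorphic test
    requires >= 2 distinct observed dosage values. Attrition per filter is
    recorded in provenance (counts attributed in the order call rate, MAF,
    monomorphism; a marker is charged to the first filter it fails).
    """
    if not (0.0 <= min_call_rate <= 1.0):
        raise ValueError("min_call_rate must be in [0, 1]")
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    st = marker_stats(g)
    fail_cr = (st["call_rate"] < min_call_rate).to_numpy()
    fail_maf = (~fail_cr) & (st["maf"].fillna(0.0).to_numpy() < min_maf)
    fail_mono = np.zeros(g.n_markers, dtype=bool)
    if drop_monomorphic:
        fail_mono = (~fail_cr) & (~fail_maf) & (st["n_distinct_obs"].to_numpy() < 2)
    keep = ~(fail_cr | fail_maf | fail_mono)
    note = (f"filter_markers(min_call_rate={min_call_rate}, min_maf={min_maf}, "
            f"drop_monomorphic={drop_monomorphic}): removed "
            f"{int(fail_cr.sum())} by call rate, {int(fail_maf.sum())} by MAF, "
            f"{int(fail_mono.sum())} monomorphic; {int(keep.sum())} retained")
    if not keep.any():
        raise EmptyResultError("all markers removed: " + note)
    logger.info(note)
    return GenotypeMatrix(
        g.line_ids, g.markers.loc[keep].reset_index(drop=True),
        g.dosage[:, keep], g.provenance + [note])


def filter_lines(g: GenotypeMatrix, max_missing: float = 0.6) -> GenotypeMatrix:
    """Drop lines with a missing-call fraction strictly above ``max_missing``."""
    if not (0.0 < max_missing <= 1.0):
        raise ValueError("max_missing must be in (0, 1]")
    frac = g.missing_mask.mean(axis=1)
    keep = frac <= max_missing
    dropped = [l for l, k in zip(g.line_ids, keep) if not k]
    if not keep.any():
        raise EmptyResultError(f"all {g.n_lines} lines exceed {max_missing:.0%} missing data")
    note = f"filter_lines(max_missing={max_missing}): dropped {len(dropped)} lines {dropped[:10]}"
    logger.info(note)
    return GenotypeMatrix(
        [l for l, k in zip(g.line_ids, keep) if k],
        g.markers.reset_index(drop=True), g.dosage[keep], g.provenance + [note])


def impute_missing(g: GenotypeMatrix, method: str = "marker_mean") -> GenotypeMatrix:
    """Fill missing dosages with the per-marker mean of observed calls.

    Observed entries are untouched; imputed values are real-valued. Requires
    every marker to have at least one observed call (run filter_markers first).
    """
    if method != "marker_mean":
        raise ValueError(f"unknown imputation method {method!r}")
    mask = g.missing_mask
    if not mask.any():
        return g
    n_obs = (~mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = g.markers.loc[n_obs == 0, "marker_id"].tolist()[:5]
        raise ValueError(
            f"markers with zero observed calls (e.g. {bad}); apply filter_markers first")
    means = np.nansum(g.dosage, axis=0) / n_obs
    dosage = np.where(mask, means[None, :], g.dosage)
    note = f"impute_missing(marker_mean): filled {int(mask.sum())} cells"
    return GenotypeMatrix(g.line_ids, g.markers.reset_index(drop=True),
                          dosage, g.provenance + [note])


# ---------------------------------------------------------------------------
# Marker subsetting (genotyping-density experiments)
# ---------------------------------------------------------------------------

def subset_markers(g: GenotypeMatrix, n: int, mode: str, seed: int) -> GenotypeMatrix:
    """Take ``n`` markers either uniformly at random or evenly spaced in bp.

    Distributed mode allocates bins of equal bp width per chromosome, with the
    per-chromosome bin count proportional to chromosome length
    (largest-remainder rounding), and takes the not-yet-chosen marker nearest
    each bin midpoint (ties -> lower position, then marker id). Deterministic
    given (g, n, mode, seed).
    """
    if not (1 <= n <= g.n_markers):
        raise ValueError(f"n={n} outside [1, {g.n_markers}]")
    if mode == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(g.n_markers, size=n, replace=False))
    elif mode == "distributed":
        idx = _distributed_indices(g.markers, n)
    else:
        raise ValueError(f"mode must be 'distributed' or 'random', got {mode!r}")
    ids = g.markers["marker_id"].iloc[idx].tolist()
    return g.take_markers(ids, note=f"subset_markers(n={n}, mode={mode}, seed={seed})")


def _distributed_indices(mm: pd.DataFrame, n: int) -> np.ndarray:
    chroms = sorted(mm["chromosome"].unique())
    lengths = {c: int(mm.loc[mm["chromosome"] == c, "position_bp"].max()) for c in chroms}
    counts = {c: int((mm["chromosome"] == c).sum()) for c in chroms}
    total = sum(lengths.values())
    # Largest-remainder allocation of n bins over chromosomes, capped at the
    # number of markers actually present on each chromosome.
    quota = {c: n * lengths[c] / total for c in chroms}
    alloc = {c: min(int(np.floor(quota[c])), counts[c]) for c in chroms}
    while sum(alloc.values()) < n:
        # order by remainder, breaking ties by chromosome name for determinism
        order = sorted(chroms, key=lambda c: (-(quota[c] - np.floor(quota[c])), c))
        for c in order:
            if alloc[c] < counts[c]:
                alloc[c] += 1
                break
        else:  # pragma: no cover - guarded by n <= total markers
            raise RuntimeError("cannot allocate requested marker count")
    chosen: list[int] = []
    for c in chroms:
        b = alloc[c]
        if b == 0:
            continue
        sub = mm[mm["chromosome"] == c].sort_values(["position_bp", "marker_id"])
        pos = sub["position_bp"].to_numpy(dtype=float)
        rows = sub.index.to_numpy()
        width = lengths[c] / b
        centers = (np.arange(b) + 0.5) * width
        used = np.zeros(len(pos), dtype=bool)
        for ctr in centers:
            dist = np.abs(pos - ctr)
            dist[used] = np.inf
            j = int(np.argmin(dist))  # argmin takes the first = lowest position on ties
            used[j] = True
            chosen.append(int(rows[j]))
    return np.sort(np.array(chosen, dtype=np.intp))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_dosage_tsv(g: GenotypeMatrix, path, sidecar: bool = True) -> None:
    """Write a dosage TSV plus a JSON provenance sidecar (``<path>.provenance.json``)."""
    path = Path(path)
    df = pd.DataFrame(g.dosage, index=g.line_ids,
                      columns=g.markers["marker_id"].to_numpy())
    df.index.name = "line_id"
    df.to_csv(path, sep="\t", na_rep="NA")
    if sidecar:
        meta = {"n_lines": g.n_lines, "n_markers": g.n_markers,
                "provenance": g.provenance}
        Path(str(path) + ".provenance.json").write_text(json.dumps(meta, indent=2))


def write_marker_map(g: GenotypeMatrix, path) -> None:
    g.markers.to_csv(path, sep="\t", index=False)


def read_phenotypes_csv(path) -> PhenotypeTable:
    """Read a long-format phenotype CSV with the PhenotypeTable columns."""
    return PhenotypeTable(pd.read_csv(path))


def write_phenotypes_csv(p: PhenotypeTable, path) -> None:
    p.records.to_csv(path, index=False)
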