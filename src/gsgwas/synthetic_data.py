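"""Simulation of an inbred breeding population with controlled trait architecture.

Genotypes: inbred founder haplotypes drawn at alternate-allele frequencies
U(0.05, 0.5); biparental families from founder crosses; single-seed descent
for a configurable number of selfing generations with recombination under
the Haldane map (no interference), so residual heterozygosity halves each
generation (~2^-6 after six generations, matching F6-F7 breeding lines).
Family structure plus limited recombination gives the long-range LD blocks
typical of such populations.

Phenotypes: each trait mixes a few large-effect QTL (each explaining a set
fraction of phenotypic variance), an exchangeable polygenic component over
the remaining markers, and residual noise filling the line-level phenotypic
variance to 1 — so variance fractions read directly as heritability
contributions. Traits are replicated over multi-environment cells with a
specified genetic correlation across environments, replicate noise within
cells, and unbalancedness created by masking whole line x cell blocks (the
way typhoons or pest outbreaks wipe out a site-season, not random cells).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PhenotypeTable, build_marker_map

Cell = tuple[str, int, str]


@dataclass
class TraitSpec:
    """Architecture of one simulated trait across environments."""

    name: str
    n_large_qtl: int = 0
    pve_per_qtl: float = 0.0
    polygenic_pve: float = 0.3
    n_environments: int = 1
    genetic_correlation: float | np.ndarray = 0.9
    reps: int = 1
    missing_cell_fraction: float = 0.0
    rep_noise_sd: float = 0.5
    cells: list[Cell] | None = None

    @property
    def total_pve(self) -> float:
        return self.n_large_qtl * self.pve_per_qtl + self.polygenic_pve

    def correlation_matrix(self) -> np.ndarray:
        e = self.n_environments
        if np.isscalar(self.genetic_correlation):
            R = np.full((e, e), float(self.genetic_correlation))
            np.fill_diagonal(R, 1.0)
        else:
            R = np.asarray(self.genetic_correlation, dtype=float)
        if R.shape != (e, e):
            raise ValueError(f"correlation matrix shape {R.shape} != ({e}, {e})")
        return R

    def cell_list(self) -> list[Cell]:
        if self.cells is not None:
            if len(self.cells) != self.n_environments:
                raise ValueError("cells length must equal n_environments")
            return [(s, int(y), se) for s, y, se in self.cells]
        return [(f"S{e + 1}", 2012, "dry") for e in range(self.n_environments)]


@dataclass
class SimConfig:
    """Population design and trait architectures for one simulated study."""

    n_founders: int = 40
    n_families: int = 80
    lines_per_family: int = 4
    selfing_generations: int = 6
    n_chromosomes: int = 12
    chrom_length_bp: int = 30_000_000
    n_markers: int = 3_000
    recomb_rate: float = 1.5  # expected crossovers per chromosome per meiosis
    traits: list[TraitSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_founders", "n_families", "lines_per_family",
                     "n_chromosomes", "chrom_length_bp", "n_markers"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.n_founders < 2:
            problems.append("n_founders must be >= 2 (families need two parents)")
        if self.selfing_generations < 0:
            problems.append("selfing_generations must be >= 0")
        if self.recomb_rate < 0:
            problems.append("recomb_rate must be >= 0")
        for t in self.traits:
            if not (0.0 <= t.total_pve <= 1.0):
                problems.append(f"trait {t.name}: total variance explained "
                                f"{t.total_pve:.3f} outside [0, 1]")
            if not (0.0 <= t.missing_cell_fraction < 1.0):
                problems.append(f"trait {t.name}: missing_cell_fraction outside [0, 1)")
            if t.reps < 1:
                problems.append(f"trait {t.name}: reps must be >= 1")
            R = t.correlation_matrix()
            if np.linalg.eigvalsh(R).min() < -1e-8:
                problems.append(f"trait {t.name}: genetic correlation matrix not PSD")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


def default_config(seed: int = 0) -> SimConfig:
    """The reference simulated study: ~320 F6 lines in 80 biparental families,
    12 chromosomes, and three traits mirroring the canonical architectures —
    few large QTL (flowering-time-like), purely polygenic (yield-like), and
    mixed (plant-height-like) — with moderately correlated multi-environment
    phenotypes, two reps, and 10% whole-block missingness.
    """
    cells = [("LB", 2011, "dry"), ("LB", 2011, "wet"),
             ("LB", 2012, "dry"), ("LB", 2012, "wet")]
    traits = [
        TraitSpec("FLW", n_large_qtl=2, pve_per_qtl=0.15, polygenic_pve=0.10,
                  n_environments=4, genetic_correlation=0.7, reps=2,
                  missing_cell_fraction=0.10, cells=cells),
        TraitSpec("YLD", n_large_qtl=0, pve_per_qtl=0.0, polygenic_pve=0.25,
                  n_environments=4, genetic_correlation=0.7, reps=2,
                  missing_cell_fraction=0.10, cells=cells),
        TraitSpec("PH", n_large_qtl=1, pve_per_qtl=0.10, polygenic_pve=0.20,
                  n_environments=4, genetic_correlation=0.7, reps=2,
                  missing_cell_fraction=0.10, cells=cells),
    ]
    return SimConfig(traits=traits, seed=seed)


@dataclass
class SimTruth:
    """Ground truth of a simulated study, for recovery tests."""

    qtl: dict[str, pd.DataFrame]  # trait -> (marker_id, chromosome, position_bp, effect)
    breeding_values: dict[str, pd.DataFrame]  # trait -> lines x cells true genetic values
    realized_h2: dict[str, dict[str, float]]  # trait -> cell label -> realized h2

    def to_json(self) -> str:
        return json.dumps({
            "qtl": {t: df.to_dict(orient="list") for t, df in self.qtl.items()},
            "breeding_values": {t: {"line_id": list(df.index),
                                    "cells": list(df.columns),
                                    "values": df.to_numpy().tolist()}
                                for t, df in self.breeding_values.items()},
            "realized_h2": self.realized_h2,
        }, indent=1)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _marker_positions(cfg: SimConfig, rng: np.random.Generator):
    per = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per[: cfg.n_markers % cfg.n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(cfg.n_chromosomes):
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=per[c]))
        while len(pos) < per[c]:  # top up the rare collision
            extra = rng.integers(1, cfg.chrom_length_bp + 1, size=per[c] - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        pos.sort()
        chroms.extend([f"chr{c + 1:02d}"] * per[c])
        positions.extend(pos.tolist())
    return np.array(chroms), np.array(positions, dtype=np.int64), per


def _adjacent_recomb_fractions(cfg: SimConfig, positions, per) -> np.ndarray:
    """Recombination fraction between each marker and its predecessor.

    Haldane: r = 0.5 (1 - exp(-2 d)) with d in Morgans proportional to bp
    spacing; the first marker of each chromosome gets r = 0.5 (independent
    assortment across chromosomes, and a random phase at the chromosome start).
    """
    r = np.empty(len(positions))
    start = 0
    for m_c in per:
        seg = positions[start:start + m_c]
        d = cfg.recomb_rate * np.diff(seg) / cfg.chrom_length_bp  # Morgans
        r[start] = 0.5
        r[start + 1:start + m_c] = 0.5 * (1.0 - np.exp(-2.0 * d))
        start += m_c
    return r


def _meiosis(hapA: np.ndarray, hapB: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per line, vectorized over lines (rows) and markers (cols)."""
    switches = rng.random(hapA.shape) < r[None, :]
    selector = np.cumsum(switches, axis=1) % 2
    return np.where(selector == 0, hapA, hapB)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Simulate the breeding-population dosage matrix and its pedigree.

    Returns the genotype matrix (complete, no missing data) and a mapping of
    line id to family id. Deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms, positions, per = _marker_positions(cfg, rng)
    m = len(positions)
    r = _adjacent_recomb_fractions(cfg, positions, per)

    p_alt = rng.uniform(0.05, 0.5, size=m)
    founders = (rng.random((cfg.n_founders, m)) < p_alt[None, :]).astype(np.float64)

    n_lines = cfg.n_families * cfg.lines_per_family
    parents = np.empty((cfg.n_families, 2), dtype=int)
    for fam in range(cfg.n_families):
        parents[fam] = rng.choice(cfg.n_founders, size=2, replace=False)
    fam_of_line = np.repeat(np.arange(cfg.n_families), cfg.lines_per_family)
    hapA = founders[parents[fam_of_line, 0]].copy()
    hapB = founders[parents[fam_of_line, 1]].copy()
    for _ in range(cfg.selfing_generations):
        g1 = _meiosis(hapA, hapB, r, rng)
        g2 = _meiosis(hapA, hapB, r, rng)
        hapA, hapB = g1, g2
    dosage = hapA + hapB

    line_ids = [f"F{fam + 1:03d}_L{i + 1}" for fam, i in
                zip(fam_of_line, np.tile(np.arange(cfg.lines_per_family), cfg.n_families))]
    pedigree = {l: f"F{fam + 1:03d}" for l, fam in zip(line_ids, fam_of_line)}
    mm = build_marker_map([f"m{j + 1:05d}" for j in range(m)], chroms, positions)
    g = GenotypeMatrix(line_ids, mm, dosage,
                       [f"simulated: {n_lines} lines, {cfg.n_families} families, "
                        f"{cfg.selfing_generations} selfing generations, seed={cfg.seed}"])
    return g, pedigree


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate multi-environment phenotypes for every configured trait.

    Per environment cell, the line-level phenotypic variance is normalized to
    1 so that QTL and polygenic variance fractions are heritabilities.
    """
    cfg.validate()
    if np.isnan(g.dosage).any():
        raise ValueError("genotypes must be complete")
    rng = np.random.default_rng(cfg.seed + 1)
    n = g.n_lines
    records = []
    qtl_truth: dict[str, pd.DataFrame] = {}
    bv_truth: dict[str, pd.DataFrame] = {}
    h2_truth: dict[str, dict[str, float]] = {}

    maf = np.minimum(g.dosage.mean(axis=0) / 2.0, 1.0 - g.dosage.mean(axis=0) / 2.0)
    for spec in cfg.traits:
        cells = spec.cell_list()
        E = spec.n_environments
        R = spec.correlation_matrix()
        L = np.linalg.cholesky(R + 1e-10 * np.eye(E))

        eligible = np.flatnonzero(maf >= 0.1)
        if spec.n_large_qtl > len(eligible):
            raise ValueError(f"trait {spec.name}: not enough common markers for "
                             f"{spec.n_large_qtl} QTL")
        qtl_idx = rng.choice(eligible, size=spec.n_large_qtl, replace=False) \
            if spec.n_large_qtl else np.array([], dtype=int)

        # large-effect QTL: effect magnitude set so each explains pve_per_qtl
        # of the unit phenotypic variance; sign random, stable across envs
        G_env = np.zeros((n, E))
        qtl_effects = []
        for qi in qtl_idx:
            x = g.dosage[:, qi]
            beta = np.sqrt(spec.pve_per_qtl / np.var(x)) * rng.choice([-1.0, 1.0])
            qtl_effects.append(beta)
            G_env += np.outer(x - x.mean(), np.ones(E)) * beta

        # polygenic background: exchangeable small effects on the remaining
        # markers, correlated across environments per R, rescaled empirically
        if spec.polygenic_pve > 0:
            poly_idx = np.setdiff1d(np.arange(g.n_markers), qtl_idx)
            W = g.dosage[:, poly_idx] - g.dosage[:, poly_idx].mean(axis=0)
            B = rng.standard_normal((len(poly_idx), E)) @ L.T
            U = W @ B
            sd = U.std(axis=0)
            sd[sd == 0] = 1.0
            U = U / sd[None, :] * np.sqrt(spec.polygenic_pve)
            G_env += U

        resid_sd = np.sqrt(max(1.0 - spec.total_pve, 0.0))
        Y_line = G_env + rng.standard_normal((n, E)) * resid_sd

        # whole line x cell blocks go missing, mimicking lost site-seasons
        mask = np.zeros((n, E), dtype=bool)
        n_miss = int(np.floor(spec.missing_cell_fraction * n))
        for e in range(E):
            if n_miss:
                mask[rng.choice(n, size=n_miss, replace=False), e] = True

        h2_cells = {}
        for e, cell in enumerate(cells):
            gv, yv = G_env[:, e], Y_line[:, e]
            h2_cells[str(cell)] = float(np.corrcoef(gv, yv)[0, 1] ** 2) \
                if gv.std() > 0 else 0.0
            for rep in range(1, spec.reps + 1):
                noise = rng.standard_normal(n) * (spec.rep_noise_sd if spec.reps > 1 else 0.0)
                vals = yv + noise
                for i, line in enumerate(g.line_ids):
                    if mask[i, e]:
                        continue
                    records.append((line, spec.name, vals[i],
                                    cell[0], cell[1], cell[2], rep))

        qtl_truth[spec.name] = pd.DataFrame({
            "marker_id": g.markers["marker_id"].to_numpy()[qtl_idx],
            "chromosome": g.markers["chromosome"].to_numpy()[qtl_idx],
            "position_bp": g.markers["position_bp"].to_numpy()[qtl_idx],
            "effect": qtl_effects,
        })
        bv_truth[spec.name] = pd.DataFrame(G_env, index=g.line_ids,
                                           columns=[str(c) for c in cells])
        h2_truth[spec.name] = h2_cells

    p = PhenotypeTable(pd.DataFrame(
        records, columns=["line_id", "trait", "value", "site", "year", "season", "rep"]))
    return p, SimTruth(qtl=qtl_truth, breeding_values=bv_truth, realized_h2=h2_truth)


def write_fixture(outdir, g: GenotypeMatrix, p: PhenotypeTable, truth: SimTruth | None = None,
                  prefix: str = "sim") -> dict[str, Path]:
    """Emit genotype dosage TSV + marker map + phenotype CSV + truth JSON."""
    from .genotype_io import write_dosage_tsv, write_marker_map, write_phenotypes_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / f"{prefix}_genotypes.tsv",
        "marker_map": outdir / f"{prefix}_markers.tsv",
        "phenotypes": outdir / f"{prefix}_phenotypes.csv",
    }
    write_dosage_tsv(g, paths["genotypes"])
    write_marker_map(g, paths["marker_map"])
    write_phenotypes_csv(p, paths["phenotypes"])
    if truth is not None:
        paths["truth"] = outdir / f"{prefix}_truth.json"
        paths["truth"].write_text(truth.to_json())
    return paths
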