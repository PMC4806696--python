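import numpy as np
import pandas as pd
import pytest

from gsgwas.genotype_io import GenotypeMatrix, PhenotypeTable, build_marker_map
from gsgwas.synthetic_data import SimConfig, TraitSpec, simulate_genotypes, simulate_phenotypes


def make_genotypes(dosage, positions=None, chromosomes=None, line_ids=None,
                   marker_ids=None) -> GenotypeMatrix:
    """Small in-memory genotype matrix for unit tests."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    marker_ids = marker_ids or [f"m{j + 1}" for j in range(m)]
    positions = positions if positions is not None else np.arange(1, m + 1) * 1000
    chromosomes = chromosomes if chromosomes is not None else ["1"] * m
    mm = build_marker_map(marker_ids, chromosomes, positions)
    return GenotypeMatrix(line_ids or [f"L{i + 1}" for i in range(n)], mm, dosage)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1,length=1000000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\tL2\tL3\n"
)


@pytest.fixture
def vcf_file(tmp_path):
    def _write(records):
        path = tmp_path / "test.vcf"
        path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
        return path
    return _write


HAPMAP_HEADER = ("rs#\talleles\tchrom\tpos\tstrand\tassembly#\tcenter\tprotLSID\t"
                 "assayLSID\tpanelLSID\tQCcode\tL1\tL2\tL3\n")


@pytest.fixture
def hapmap_file(tmp_path):
    def _write(records):
        path = tmp_path / "test.hmp.txt"
        path.write_text(HAPMAP_HEADER + "".join(r + "\n" for r in records))
        return path
    return _write


@pytest.fixture(scope="session")
def sim_population():
    """A moderately sized simulated breeding population shared across tests:
    ~200 F6 lines in 50 families, one mixed-architecture trait."""
    cfg = SimConfig(n_families=50, lines_per_family=4, n_markers=1000,
                    n_chromosomes=5,
                    traits=[TraitSpec("T", n_large_qtl=1, pve_per_qtl=0.2,
                                      polygenic_pve=0.2)],
                    seed=42)
    g, ped = simulate_genotypes(cfg)
    p, truth = simulate_phenotypes(g, cfg)
    return {"cfg": cfg, "g": g, "pedigree": ped, "p": p, "truth": truth}


def pheno_from_values(line_ids, values, trait="T", site="S1", year=2012,
                      season="dry", rep=1) -> PhenotypeTable:
    return PhenotypeTable(pd.DataFrame({
        "line_id": line_ids, "trait": trait, "value": values,
        "site": site, "year": year, "season": season, "rep": rep}))
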