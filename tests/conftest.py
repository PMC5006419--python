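"""Shared fixtures: programmatic VCF / BED / phenotype toy data.

The toy cohort has 40 samples (20 cases, 20 controls) and a small genome of
five genes on one chromosome.  Each gene carries one rare singleton variant,
two rare variants sit between genes (one 50 kb intergenic window), and two
common variants are present to be removed by the NMAF threshold — so a
gene-level run with 50 kb intergenic bins yields exactly 5 gene bins + 1
intergenic bin.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from rarebin.variant_io import Phenotype

N_SAMPLES = 40
SAMPLES = [f"T{i:02d}" for i in range(N_SAMPLES)]

# gene name -> 0-based half-open interval on chr1
GENES = {
    "GENE_A": (1000, 2000),
    "GENE_B": (6000, 8000),
    "GENE_C": (11000, 12500),
    "GENE_D": (20000, 22000),
    "GENE_E": (30000, 31000),
}

# (pos0, genotypes) — rare singletons inside each gene: carrier varies
RARE_IN_GENES = [
    ("GENE_A", 1500, 0),
    ("GENE_B", 7000, 1),
    ("GENE_C", 12000, 2),
    ("GENE_D", 21000, 3),
    ("GENE_E", 30500, 4),
]
RARE_INTERGENIC_POS = [4000, 15000]  # both in window [0, 50000) at 50 kb
COMMON_POS = [1600, 25000]  # NMAF ~ 0.5, removed by the threshold


def write_vcf(path: Path, samples: list[str], records: list[tuple]) -> Path:
    """records: (chrom, pos1, ref, alt_string, [GT strings])."""
    lines = [
        "##fileformat=VCFv4.2",
        *(f"##contig=<ID={c}>" for c in dict.fromkeys(r[0] for r in records)),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                   "FORMAT", *samples]),
    ]
    for chrom, pos1, ref, alt, gts in records:
        lines.append(
            "\t".join([chrom, str(pos1), ".", ref, alt, ".", ".", ".", "GT", *gts])
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def toy_records() -> list[tuple]:
    records = []
    for _, pos0, carrier in RARE_IN_GENES:
        gts = ["0/0"] * N_SAMPLES
        gts[carrier] = "0/1"
        records.append(("chr1", pos0 + 1, "A", "C", gts))
    for j, pos0 in enumerate(RARE_INTERGENIC_POS):
        gts = ["0/0"] * N_SAMPLES
        gts[10 + j] = "0/1"
        records.append(("chr1", pos0 + 1, "G", "T", gts))
    for pos0 in COMMON_POS:
        gts = ["0/1" if i % 2 else "1/1" for i in range(N_SAMPLES)]
        records.append(("chr1", pos0 + 1, "C", "G", gts))
    return sorted(records, key=lambda r: r[1])


@pytest.fixture()
def toy_dataset(tmp_path: Path) -> dict:
    vcf = write_vcf(tmp_path / "toy.vcf", SAMPLES, toy_records())
    bed = tmp_path / "toy_genes.bed"
    bed.write_text(
        "# toy gene models\n"
        + "".join(f"chr1\t{a}\t{b}\t{name}\n" for name, (a, b) in GENES.items())
    )
    groups = tmp_path / "toy_groups.tsv"
    groups.write_text(
        "PATH_1\ttoy\tregion\tGENE_A\n"
        "PATH_1\ttoy\tregion\tGENE_B\n"
        "PATH_2\ttoy\tregion\tGENE_C\n"
        "PATH_2\ttoy\tgroup\tPATH_1\n"
    )
    phen = tmp_path / "toy_phen.tsv"
    phen.write_text(
        "".join(f"{s}\t{1 if i < 20 else 0}\n" for i, s in enumerate(SAMPLES))
    )
    return {
        "vcf": vcf,
        "bed": bed,
        "groups": groups,
        "phenotype": phen,
        "n_rare_gene": len(RARE_IN_GENES),
        "n_rare_intergenic": len(RARE_INTERGENIC_POS),
        "n_common": len(COMMON_POS),
        "tmp_path": tmp_path,
    }


@pytest.fixture()
def toy_phenotype() -> Phenotype:
    return Phenotype(SAMPLES, np.array([1] * 20 + [0] * 20))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250927)
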