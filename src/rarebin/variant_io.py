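"""VCF ingest, allele frequencies, NMAF, and disease-model genotype encoding.

Internally everything is 0-based: VCF's 1-based POS is shifted on read.
Genotype calls are stored as an ``(n_samples, n_loci, 2)`` array of allele
indices (ref = 0), with -1 marking a missing call; phased and unphased calls
are treated identically as unordered allele pairs.

The quantity driving variant selection is the non-major allele frequency
(NMAF): one minus the frequency of the most common allele.  At biallelic
sites NMAF coincides with the classical minor allele frequency; at
multi-allelic sites it pools every allele other than the major one, so it is
bounded by (k-1)/k for k observed alleles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Locus",
    "GenotypeMatrix",
    "Phenotype",
    "DiseaseModel",
    "MISSING",
    "read_vcf",
    "read_phenotype_file",
    "compute_allele_freqs",
    "compute_nmaf",
    "nmaf_vector",
    "encode_genotype",
    "encode_genotypes",
]

MISSING = -1


class DiseaseModel(str, enum.Enum):
    """How a genotype contributes to a bin score.

    additive: count of non-major alleles (0, 1, 2);
    dominant: 1 if any non-major allele is carried;
    recessive: 1 only for a homozygous non-major call.
    """

    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


@dataclass(frozen=True)
class Locus:
    """One variant site: position, allele list (ref first), stable id."""

    locus_id: str
    chrom: str
    pos: int  # 0-based
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 2:
            raise ValueError(f"locus {self.locus_id!r}: need >= 2 alleles")

    @classmethod
    def from_site(cls, chrom: str, pos: int, ref: str, alts: Sequence[str]) -> "Locus":
        alleles = (ref, *alts)
        return cls(f"{chrom}:{pos + 1}:{ref}:{','.join(alts)}", chrom, pos, alleles)


class GenotypeMatrix:
    """Aligned samples x loci diploid call matrix.

    ``calls[i, j]`` is the unordered allele-index pair of sample i at locus j,
    or ``(-1, -1)`` when missing.
    """

    def __init__(self, samples: Sequence[str], loci: Sequence[Locus], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int16)
        if calls.shape != (len(samples), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(samples)}, {len(loci)}, 2)"
            )
        self.samples = list(samples)
        self.loci = list(loci)
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._locus_index = {l.locus_id: j for j, l in enumerate(self.loci)}
        self._major: np.ndarray | None = None
        self._cache: dict = {}  # memo for per-matrix derived arrays

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_indices(self, samples: Sequence[str] | None) -> np.ndarray:
        if samples is None:
            return np.arange(self.n_samples)
        try:
            return np.array([self._sample_index[s] for s in samples], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from None

    def locus_index(self, locus_id: str) -> int:
        return self._locus_index[locus_id]

    def allele_counts(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-locus allele counts over non-missing calls, shape (n_loci, max_alleles)."""
        key = ("allele_counts", None if sample_idx is None else sample_idx.tobytes())
        if key in self._cache:
            return self._cache[key]
        calls = self.calls if sample_idx is None else self.calls[sample_idx]
        n_alleles = max(len(l.alleles) for l in self.loci) if self.loci else 0
        counts = np.zeros((self.n_loci, n_alleles), dtype=np.int64)
        for a in range(n_alleles):
            counts[:, a] = (calls == a).sum(axis=(0, 2))
        self._cache[key] = counts
        return counts

    def major_alleles(self) -> np.ndarray:
        """Most frequent allele index per locus over the full loaded cohort.

        Fixed once per matrix: the same reference orientation is used for
        every encoding and weighting step.  Monomorphic-missing loci and ties
        fall back to the lowest allele index (the reference).
        """
        if self._major is None:
            self._major = np.argmax(self.allele_counts(), axis=1).astype(np.int16)
        return self._major


@dataclass
class Phenotype:
    """Binary case/control status (1 = case) with optional covariates."""

    samples: list[str]
    status: np.ndarray
    covariates: np.ndarray | None = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.shape != (len(self.samples),):
            raise ValueError("status length != number of samples")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0 (control) or 1 (case)")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != len(self.samples):
                raise ValueError("covariate rows != number of samples")
        self._index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def aligned_to(self, gm: GenotypeMatrix) -> "Phenotype":
        """Reorder to the genotype matrix's sample order (must be a subset)."""
        missing = [s for s in self.samples if s not in gm._sample_index]
        if missing:
            raise KeyError(f"phenotype samples absent from genotypes: {missing}")
        order = sorted(range(len(self.samples)), key=lambda i: gm._sample_index[self.samples[i]])
        cov = self.covariates[order] if self.covariates is not None else None
        return Phenotype([self.samples[i] for i in order], self.status[order], cov)

    def aligned_to_samples(self, samples: Sequence[str]) -> "Phenotype":
        """Subset/reorder to an explicit sample-id order."""
        missing = [s for s in samples if s not in self._index]
        if missing:
            raise KeyError(f"samples without phenotype: {missing}")
        idx = [self._index[s] for s in samples]
        cov = self.covariates[idx] if self.covariates is not None else None
        return Phenotype(list(samples), self.status[idx], cov)

    def case_control_masks(self, gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Boolean case / control masks over ``gm``'s sample axis."""
        case = np.zeros(gm.n_samples, dtype=bool)
        ctrl = np.zeros(gm.n_samples, dtype=bool)
        for s, st in zip(self.samples, self.status):
            i = gm._sample_index.get(s)
            if i is None:
                raise KeyError(f"phenotype sample {s!r} absent from genotypes")
            (case if st else ctrl)[i] = True
        return case, ctrl


def read_vcf(path: str | Path, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a VCF 4.x (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Every record becomes one locus; multi-allelic records are kept as a
    single locus carrying all ALT alleles.  Positions are converted to
    0-based.  Missing genotypes become ``(-1, -1)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    if sample_subset is not None:
        absent = [s for s in sample_subset if s not in vcf_samples]
        if absent:
            raise ValueError(f"samples not in VCF: {', '.join(absent)}")
        keep = [vcf_samples.index(s) for s in sample_subset]
        samples = list(sample_subset)
    else:
        keep = list(range(len(vcf_samples)))
        samples = vcf_samples

    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    for record in vcf:
        gts = record.genotype.array() if record.genotype is not None else None
        if gts is None:
            raise ValueError(f"{path}: record {record.CHROM}:{record.POS} has no GT field")
        pair = np.asarray(gts)[:, :2].astype(np.int16)  # drop phase column
        pair[(pair < 0).any(axis=1)] = MISSING  # half-missing -> fully missing
        loci.append(Locus.from_site(record.CHROM, record.POS - 1, record.REF, record.ALT))
        rows.append(pair[keep])
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0, 2), dtype=np.int16)
    )
    return GenotypeMatrix(samples, loci, calls)


def read_phenotype_file(path: str | Path) -> Phenotype:
    """Tab-delimited ``sample_id  status(0/1)  [covariate ...]``, '#' comments."""
    samples: list[str] = []
    status: list[int] = []
    covs: list[list[float]] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample status [covariates]'")
            samples.append(fields[0])
            if fields[1] not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: status must be 0 or 1")
            status.append(int(fields[1]))
            covs.append([float(x) for x in fields[2:]])
    ncov = {len(c) for c in covs}
    if len(ncov) > 1:
        raise ValueError(f"{path}: inconsistent covariate counts {sorted(ncov)}")
    covariates = np.array(covs) if covs and covs[0] else None
    return Phenotype(samples, np.array(status), covariates)


def compute_allele_freqs(
    gm: GenotypeMatrix, locus_id: str, subset: Sequence[str] | None = None
) -> np.ndarray | None:
    """Observed allele frequencies at one locus over a sample subset.

    Only non-missing calls enter the denominator.  Returns ``None`` ("no
    data") when every call in the subset is missing.
    """
    j = gm.locus_index(locus_id)
    idx = gm.sample_indices(subset)
    if idx.size == 0:
        raise ValueError("empty sample subset")
    calls = gm.calls[idx, j, :].ravel()
    calls = calls[calls >= 0]
    if calls.size == 0:
        return None
    k = len(gm.loci[j].alleles)
    counts = np.bincount(calls, minlength=k).astype(float)
    return counts / counts.sum()


def compute_nmaf(
    gm: GenotypeMatrix, locus_id: str, subset: Sequence[str] | None = None
) -> float | None:
    """Non-major allele frequency: 1 - max allele frequency; None if no data."""
    freqs = compute_allele_freqs(gm, locus_id, subset)
    if freqs is None:
        return None
    return float(1.0 - freqs.max())


def nmaf_vector(gm: GenotypeMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """Vectorized NMAF for every locus over a boolean sample mask.

    Loci with no non-missing call in the mask get NaN ("no data").
    """
    idx = np.nonzero(mask)[0] if mask is not None else None
    counts = gm.allele_counts(idx).astype(float)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nmaf = 1.0 - counts.max(axis=1) / total
    nmaf[total == 0] = np.nan
    return nmaf


def encode_genotype(
    call: tuple[int, int] | None, major_allele: int, model: DiseaseModel
) -> int:
    """Contribution of a single call under a disease model.

    ``m`` = number of non-major alleles in the call; additive -> m,
    dominant -> m >= 1, recessive -> m == 2.  Missing calls contribute 0.
    At multi-allelic loci every non-major allele pools into m.
    """
    if call is None or call[0] < 0 or call[1] < 0:
        return 0
    m = int(call[0] != major_allele) + int(call[1] != major_allele)
    model = DiseaseModel(model)
    if model is DiseaseModel.ADDITIVE:
        return m
    if model is DiseaseModel.DOMINANT:
        return int(m >= 1)
    return int(m == 2)


def encode_genotypes(gm: GenotypeMatrix, model: DiseaseModel) -> np.ndarray:
    """(n_samples, n_loci) contribution matrix; missing calls encode as 0."""
    model = DiseaseModel(model)
    key = ("encode", model.value)
    if key in gm._cache:
        return gm._cache[key]
    major = gm.major_alleles()[np.newaxis, :, np.newaxis]
    nonmajor = (gm.calls != major) & (gm.calls >= 0)
    m = nonmajor.sum(axis=2, dtype=np.int8)
    if model is DiseaseModel.ADDITIVE:
        out = m
    elif model is DiseaseModel.DOMINANT:
        out = (m >= 1).astype(np.int8)
    else:
        out = (m == 2).astype(np.int8)
    gm._cache[key] = out
    return out
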