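"""The collapsing engine: NMAF-based locus selection, multi-level bin
assignment, Madsen-Browning-style variant weighting, and per-sample bin
scores.

A bin collapses the selected low-frequency variants inside one biological
feature (gene, pathway/group, or fixed-width intergenic window) into a single
per-sample score

    s_i = sum_j  w_j * g_ij

where g_ij is the disease-model encoding of sample i's genotype at locus j
and w_j an optional locus weight.  With unit weights and additive encoding
the score is simply the sample's non-major allele count inside the feature.

Weights follow the weighted-sum form of Madsen & Browning:

    w_j = 1 / sqrt(n_j * q_j * (1 - q_j)),     q_j = (m_j + 1) / (2 * n_pop + 2)

with m_j the non-major allele count in the *weighting population* (controls
only, cases only, or everyone, depending on the scheme), n_pop the genotyped
individuals in that population, and n_j the genotyped individuals at the
locus in the full cohort.  Rarer variants get larger weights.  The scheme
decides which population supplies q: ``control`` uses controls only (the
original proposal), ``overall`` everyone, ``minimum``/``maximum`` take the
smaller/larger of the case-based and control-based weights per locus,
``none`` sets every weight to 1, and ``custom`` reads a user table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .variant_io import (
    DiseaseModel,
    GenotypeMatrix,
    Locus,
    Phenotype,
    encode_genotypes,
    nmaf_vector,
)
from .knowledge_store import KnowledgeBase, expand_group

__all__ = [
    "FilterMode",
    "WeightScheme",
    "LocusWeight",
    "BinDefinition",
    "BinScoreMatrix",
    "RoleFilter",
    "select_loci",
    "apply_role_filter",
    "assign_loci_to_features",
    "make_intergenic_bins",
    "compute_weights",
    "score_bins",
    "write_bin_report",
    "read_score_file",
    "load_role_file",
    "load_weight_file",
    "DEFAULT_NMAF_THRESHOLD",
]

DEFAULT_NMAF_THRESHOLD = 0.05


class FilterMode(str, enum.Enum):
    """Which NMAF estimate the selection threshold applies to.

    overall: pooled-cohort NMAF below the threshold;
    either:  NMAF below the threshold in at least one of cases / controls
             (min of the stratum NMAFs), the default — keeps variants that
             are rare on one side only, capturing risk and protective sites;
    both:    NMAF below the threshold in both strata (max of stratum NMAFs),
             the conservative option.
    """

    OVERALL = "overall"
    EITHER = "either"
    BOTH = "both"


class WeightScheme(str, enum.Enum):
    NONE = "none"
    CONTROL = "control"
    MINIMUM = "minimum"
    MAXIMUM = "maximum"
    OVERALL = "overall"
    CUSTOM = "custom"


@dataclass(frozen=True)
class LocusWeight:
    locus_id: str
    q: float  # frequency estimate used, pseudo-counted into (0, 1)
    n: int  # genotyped individuals at the locus (full cohort)
    w: float

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(f"weight for {self.locus_id} must be > 0, got {self.w}")


@dataclass
class BinDefinition:
    """A named bin: the feature it represents and its member loci (id-sorted)."""

    bin_id: str
    level: str  # gene | group | intergenic | custom
    member_loci: list[str]
    feature_ref: str = ""

    def __post_init__(self) -> None:
        if len(set(self.member_loci)) != len(self.member_loci):
            raise ValueError(f"bin {self.bin_id}: duplicate member loci")
        self.member_loci = sorted(self.member_loci)

    @property
    def n_loci(self) -> int:
        return len(self.member_loci)


@dataclass
class BinScoreMatrix:
    """Collapsed per-sample scores, one column per bin."""

    samples: list[str]
    bins: list[BinDefinition]
    scores: np.ndarray  # (n_samples, n_bins)
    capacity: np.ndarray  # per-bin max possible unweighted score
    allele_totals: np.ndarray  # per-bin total non-major allele count

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.samples), len(self.bins)):
            raise ValueError("score matrix shape mismatch")
        if (self.scores < 0).any():
            raise ValueError("bin scores must be non-negative")


@dataclass
class RoleFilter:
    """Keep (include) or drop (exclude) loci carrying a role annotation,
    e.g. predicted-damaging tags from an annotation tool."""

    mode: str  # include | exclude
    annotations: Mapping[str, set[str]]

    def __post_init__(self) -> None:
        if self.mode not in ("include", "exclude"):
            raise ValueError(f"role filter mode must be include|exclude, got {self.mode!r}")


def select_loci(
    gm: GenotypeMatrix,
    phen: Phenotype,
    mode: FilterMode | str = FilterMode.EITHER,
    threshold: float = DEFAULT_NMAF_THRESHOLD,
) -> list[str]:
    """Locus ids whose NMAF falls strictly below ``threshold`` under ``mode``.

    Stratified modes require at least one case and one control; loci with no
    genotype data in a required stratum are excluded.  Ids return sorted.
    """
    mode = FilterMode(mode)
    if not 0 < threshold < 1:
        raise ValueError(f"NMAF threshold must be in (0, 1), got {threshold}")
    if mode is FilterMode.OVERALL:
        stat = nmaf_vector(gm)
    else:
        case_mask, ctrl_mask = phen.case_control_masks(gm)
        if not case_mask.any() or not ctrl_mask.any():
            raise ValueError(f"mode {mode.value!r} needs at least one case and one control")
        nm_case = nmaf_vector(gm, case_mask)
        nm_ctrl = nmaf_vector(gm, ctrl_mask)
        stat = np.fmin(nm_case, nm_ctrl) if mode is FilterMode.EITHER else np.fmax(nm_case, nm_ctrl)
        stat[np.isnan(nm_case) | np.isnan(nm_ctrl)] = np.nan
    keep = np.nonzero(stat < threshold)[0]  # NaN compares False: "no data" excluded
    return sorted(gm.loci[j].locus_id for j in keep)


def apply_role_filter(loci: Sequence[str], rf: RoleFilter) -> list[str]:
    """Include mode keeps only annotated loci; exclude mode drops them."""
    annotated = {l for l in loci if rf.annotations.get(l)}
    if rf.mode == "include":
        return sorted(annotated)
    return sorted(set(loci) - annotated)


def assign_loci_to_features(
    loci: Sequence[Locus],
    kb: KnowledgeBase,
    level: str = "gene",
    group_ids: Sequence[str] | None = None,
) -> tuple[list[BinDefinition], list[Locus]]:
    """Map selected loci onto knowledge features, one bin per hit feature.

    gene level: one bin per region containing >= 1 locus.  group level: one
    bin per group, members pooled over the group's transitive region closure.
    A locus inside several overlapping features contributes to each of them.
    Loci covered by no feature come back as the unassigned remainder (in
    input order), ready for intergenic binning.
    """
    if level not in ("gene", "group"):
        raise ValueError(f"level must be gene|group, got {level!r}")
    region_hits: dict[str, list[str]] = {}
    locus_assigned: dict[str, bool] = {}
    for locus in loci:
        hits = kb.regions.at(locus.chrom, locus.pos)
        locus_assigned[locus.locus_id] = False
        for region in hits:
            region_hits.setdefault(region.region_id, []).append(locus.locus_id)

    bins: list[BinDefinition] = []
    if level == "gene":
        for region_id in sorted(region_hits):
            members = region_hits[region_id]
            bins.append(BinDefinition(region_id, "gene", members, feature_ref=region_id))
            for lid in members:
                locus_assigned[lid] = True
    else:
        if group_ids is None:
            group_ids = sorted(g.group_id for g in kb.groups)
        else:
            unknown = sorted(set(group_ids) - {g.group_id for g in kb.groups})
            if unknown:
                raise ValueError(f"unknown group ids: {', '.join(unknown)}")
        for gid in sorted(group_ids):
            members: set[str] = set()
            for rid in expand_group(kb, gid):
                members.update(region_hits.get(rid, ()))
            if members:
                bins.append(BinDefinition(gid, "group", sorted(members), feature_ref=gid))
                for lid in members:
                    locus_assigned[lid] = True
    unassigned = [l for l in loci if not locus_assigned[l.locus_id]]
    return bins, unassigned


def make_intergenic_bins(unassigned: Sequence[Locus], width_kb: int) -> list[BinDefinition]:
    """Collapse feature-less loci into fixed-width genomic windows.

    Each locus goes to window ``floor(pos / (width_kb * 1000))`` on its
    chromosome; empty windows are never emitted.
    """
    if width_kb < 1:
        raise ValueError(f"width_kb must be >= 1, got {width_kb}")
    width = width_kb * 1000
    windows: dict[tuple[str, int], list[str]] = {}
    for locus in unassigned:
        windows.setdefault((locus.chrom, locus.pos // width), []).append(locus.locus_id)
    bins = []
    for (chrom, idx), members in windows.items():
        span = (idx * width, (idx + 1) * width)
        bin_id = f"intergenic:{chrom}:{span[0]}-{span[1]}"
        bins.append(BinDefinition(bin_id, "intergenic", members, feature_ref=bin_id))
    return sorted(bins, key=lambda b: b.bin_id)


def _stratum_counts(
    gm: GenotypeMatrix, mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """(non-major allele count, genotyped individual count) per locus."""
    key = ("stratum_counts", None if mask is None else mask.tobytes())
    if key in gm._cache:
        return gm._cache[key]
    calls = gm.calls if mask is None else gm.calls[mask]
    major = gm.major_alleles()[np.newaxis, :, np.newaxis]
    observed = calls >= 0
    m = ((calls != major) & observed).sum(axis=(0, 2))
    n = observed.all(axis=2).sum(axis=0)
    gm._cache[key] = (m, n)
    return m, n


def _mb_weight(m: np.ndarray, n_pop: np.ndarray, n_total: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q = (m + 1.0) / (2.0 * n_pop + 2.0)
    w = 1.0 / np.sqrt(n_total * q * (1.0 - q))
    return q, w


def compute_weights(
    gm: GenotypeMatrix,
    phen: Phenotype,
    loci: Sequence[str],
    scheme: WeightScheme | str = WeightScheme.NONE,
    custom: Mapping[str, float] | None = None,
) -> list[LocusWeight]:
    """Per-locus weights under a weighting-population scheme (see module doc).

    ``n`` (the genotyped-individual count inside the square root) is always
    taken from the full cohort so that the minimum / overall / maximum
    weights are ordered at every locus.
    """
    scheme = WeightScheme(scheme)
    if scheme is WeightScheme.CUSTOM and custom is None:
        raise ValueError("custom scheme requires a weight table")
    if scheme is not WeightScheme.CUSTOM and custom is not None:
        raise ValueError("weight table given but scheme is not custom")

    cols = np.array([gm.locus_index(l) for l in loci], dtype=int)
    _, n_total_all = _stratum_counts(gm, None)
    n_total = n_total_all[cols]

    if scheme is WeightScheme.NONE:
        # q is unused for unit/custom weights; 0.5 keeps the (0,1) invariant
        return [LocusWeight(l, 0.5, int(n_total[i]), 1.0) for i, l in enumerate(loci)]
    if scheme is WeightScheme.CUSTOM:
        return [
            LocusWeight(l, 0.5, int(n_total[i]), float(custom.get(l, 1.0)))
            for i, l in enumerate(loci)
        ]

    case_mask, ctrl_mask = phen.case_control_masks(gm)
    if scheme is WeightScheme.CONTROL and not ctrl_mask.any():
        raise ValueError("control weighting scheme requires at least one control")

    if scheme is WeightScheme.OVERALL:
        m, n_pop = _stratum_counts(gm, None)  # everyone, regardless of status
        q, w = _mb_weight(m[cols], n_pop[cols], n_total)
    elif scheme is WeightScheme.CONTROL:
        m, n_pop = _stratum_counts(gm, ctrl_mask)
        q, w = _mb_weight(m[cols], n_pop[cols], n_total)
    else:  # minimum / maximum over the case- and control-based weights
        if not case_mask.any() or not ctrl_mask.any():
            raise ValueError(f"{scheme.value} weighting needs both cases and controls")
        m_ca, n_ca = _stratum_counts(gm, case_mask)
        m_co, n_co = _stratum_counts(gm, ctrl_mask)
        q_ca, w_ca = _mb_weight(m_ca[cols], n_ca[cols], n_total)
        q_co, w_co = _mb_weight(m_co[cols], n_co[cols], n_total)
        if scheme is WeightScheme.MINIMUM:
            take_case = w_ca <= w_co
        else:
            take_case = w_ca >= w_co
        q = np.where(take_case, q_ca, q_co)
        w = np.where(take_case, w_ca, w_co)
    return [
        LocusWeight(l, float(q[i]), int(n_total[i]), float(w[i])) for i, l in enumerate(loci)
    ]


def score_bins(
    bins: Sequence[BinDefinition],
    gm: GenotypeMatrix,
    model: DiseaseModel | str,
    weights: Sequence[LocusWeight],
) -> BinScoreMatrix:
    """Collapse genotypes into the per-sample weighted bin scores."""
    model = DiseaseModel(model)
    wmap = {lw.locus_id: lw.w for lw in weights}
    enc = encode_genotypes(gm, model).astype(float)
    additive = (
        enc if model is DiseaseModel.ADDITIVE else encode_genotypes(gm, DiseaseModel.ADDITIVE)
    )
    per_locus_cap = 2 if model is DiseaseModel.ADDITIVE else 1
    scores = np.zeros((gm.n_samples, len(bins)))
    capacity = np.zeros(len(bins))
    allele_totals = np.zeros(len(bins))
    for b, bin_def in enumerate(bins):
        missing_w = [l for l in bin_def.member_loci if l not in wmap]
        if missing_w:
            raise ValueError(f"bin {bin_def.bin_id}: no weight for loci {missing_w}")
        cols = np.array([gm.locus_index(l) for l in bin_def.member_loci], dtype=int)
        wvec = np.array([wmap[l] for l in bin_def.member_loci])
        scores[:, b] = enc[:, cols] @ wvec
        capacity[b] = per_locus_cap * len(cols)
        allele_totals[b] = additive[:, cols].sum()
    return BinScoreMatrix(list(gm.samples), list(bins), scores, capacity, allele_totals)


def write_bin_report(bsm: BinScoreMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_scores.tsv`` (samples x bins) and ``<prefix>_bins.tsv``
    (bin_id, level, n_loci, non_major_alleles, capacity)."""
    prefix = Path(prefix)
    scores_path = prefix.parent / f"{prefix.name}_scores.tsv"
    bins_path = prefix.parent / f"{prefix.name}_bins.tsv"
    with open(scores_path, "w") as handle:
        handle.write("sample\t" + "\t".join(b.bin_id for b in bsm.bins) + "\n")
        for i, sample in enumerate(bsm.samples):
            vals = "\t".join(repr(float(v)) for v in bsm.scores[i])
            handle.write(f"{sample}\t{vals}\n" if bsm.bins else f"{sample}\n")
    with open(bins_path, "w") as handle:
        handle.write("bin_id\tlevel\tn_loci\tnon_major_alleles\tcapacity\n")
        for b, bin_def in enumerate(bsm.bins):
            handle.write(
                f"{bin_def.bin_id}\t{bin_def.level}\t{bin_def.n_loci}\t"
                f"{int(bsm.allele_totals[b])}\t{int(bsm.capacity[b])}\n"
            )
    return scores_path, bins_path


def read_score_file(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a ``*_scores.tsv`` back: (samples, bin ids, score matrix)."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        bin_ids = header[1:]
        samples, rows = [], []
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            samples.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
    return samples, bin_ids, np.array(rows).reshape(len(samples), len(bin_ids))


def load_role_file(path: str | Path) -> dict[str, set[str]]:
    """Tab-delimited ``locus_id  role_tag`` annotations, one per line."""
    annotations: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'locus_id role_tag'")
            annotations.setdefault(fields[0], set()).add(fields[1])
    return annotations


def load_weight_file(path: str | Path) -> dict[str, float]:
    """Tab-delimited ``locus_id  weight`` custom weight table."""
    weights: dict[str, float] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'locus_id weight'")
            w = float(fields[1])
            if w <= 0 or math.isnan(w):
                raise ValueError(f"{path}:{lineno}: weight must be positive")
            weights[fields[0]] = w
    return weights
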