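"""Locus selection, bin assignment, variant weighting, and bin scoring."""

import numpy as np
import pytest

from rarebin.binning import (
    BinDefinition,
    FilterMode,
    RoleFilter,
    WeightScheme,
    apply_role_filter,
    assign_loci_to_features,
    compute_weights,
    make_intergenic_bins,
    read_score_file,
    score_bins,
    select_loci,
    write_bin_report,
)
from rarebin.knowledge_store import KnowledgeBase, Group, GroupSet, Region, RegionSet
from rarebin.variant_io import GenotypeMatrix, Locus, Phenotype

from test_variant_io import biallelic_matrix


def matrix_with_freqs(case_dos, ctrl_dos):
    """Matrix with cases first, then controls, one phenotype to match."""
    dos = np.vstack([case_dos, ctrl_dos])
    gm = biallelic_matrix(dos)
    status = np.r_[np.ones(len(case_dos), dtype=int), np.zeros(len(ctrl_dos), dtype=int)]
    return gm, Phenotype(list(gm.samples), status)


class TestSelectLoci:
    def make(self, nm_case, nm_ctrl, n=50):
        """One locus with the requested per-stratum non-major dosage fractions."""
        case = np.zeros((n, 1), dtype=int)
        ctrl = np.zeros((n, 1), dtype=int)
        case[: int(round(nm_case * 2 * n))] = 1  # het carriers
        ctrl[: int(round(nm_ctrl * 2 * n))] = 1
        return matrix_with_freqs(case, ctrl)

    def test_either_vs_both_straddling_threshold(self):
        gm, phen = self.make(0.04, 0.06)
        assert select_loci(gm, phen, "either", 0.05) == ["L0"]
        assert select_loci(gm, phen, "both", 0.05) == []

    def test_boundary_is_strict(self):
        gm, phen = self.make(0.05, 0.05)
        assert select_loci(gm, phen, "overall", 0.05) == []
        assert select_loci(gm, phen, "either", 0.05) == []

    def test_common_variant_excluded_everywhere(self):
        gm, phen = self.make(0.30, 0.30)
        for mode in FilterMode:
            assert select_loci(gm, phen, mode, 0.05) == []

    def test_rare_everywhere_selected_everywhere(self):
        gm, phen = self.make(0.01, 0.02)
        for mode in FilterMode:
            assert select_loci(gm, phen, mode, 0.05) == ["L0"]

    def test_stratified_mode_requires_both_classes(self):
        gm = biallelic_matrix(np.zeros((4, 1), dtype=int))
        phen = Phenotype(list(gm.samples), np.ones(4, dtype=int))
        with pytest.raises(ValueError, match="control"):
            select_loci(gm, phen, "either", 0.05)


class TestRoleFilter:
    def test_include_keeps_only_annotated(self):
        rf = RoleFilter("include", {"L1": {"damaging"}})
        assert apply_role_filter(["L1", "L2"], rf) == ["L1"]

    def test_exclude_with_empty_table_is_identity(self):
        rf = RoleFilter("exclude", {})
        assert apply_role_filter(["L1", "L2"], rf) == ["L1", "L2"]

    def test_include_then_exclude_empties(self):
        ann = {"L1": {"x"}, "L2": {"y"}}
        kept = apply_role_filter(["L1", "L2"], RoleFilter("include", ann))
        assert apply_role_filter(kept, RoleFilter("exclude", ann)) == []


def loci_at(positions, chrom="chr1"):
    return [Locus(f"L{p:06d}", chrom, p, ("A", "C")) for p in positions]


class TestAssignment:
    kb = KnowledgeBase(
        RegionSet([
            Region("GENE_A", "GENE_A", "chr1", 1000, 2000),
            Region("GENE_B", "GENE_B", "chr1", 1800, 3000),  # overlaps GENE_A
        ]),
        GroupSet([Group("PW", member_region_ids={"GENE_A", "GENE_B"})]),
    )

    def test_gene_bins_and_unassigned(self):
        loci = loci_at([1100, 1200, 1900, 5000])
        bins, unassigned = assign_loci_to_features(loci, self.kb, "gene")
        by_id = {b.bin_id: b for b in bins}
        assert by_id["GENE_A"].member_loci == ["L001100", "L001200", "L001900"]
        assert [l.pos for l in unassigned] == [5000]

    def test_overlapping_genes_double_assign(self):
        loci = loci_at([1900])
        bins, _ = assign_loci_to_features(loci, self.kb, "gene")
        assert [b.bin_id for b in bins] == ["GENE_A", "GENE_B"]
        assert all(b.member_loci == ["L001900"] for b in bins)

    def test_group_level_pools_member_regions(self):
        loci = loci_at([1100, 2500, 9999])
        bins, unassigned = assign_loci_to_features(loci, self.kb, "group")
        assert [b.bin_id for b in bins] == ["PW"]
        assert bins[0].member_loci == ["L001100", "L002500"]
        assert [l.pos for l in unassigned] == [9999]

    def test_unknown_group_ids_error(self):
        with pytest.raises(ValueError, match="NOPE"):
            assign_loci_to_features(loci_at([1100]), self.kb, "group", group_ids=["NOPE"])

    def test_membership_matches_brute_force(self, rng):
        regions = []
        for i in range(40):
            start = int(rng.integers(0, 20000))
            regions.append(Region(f"R{i:02d}", f"R{i:02d}", "chr1",
                                  start, start + int(rng.integers(100, 3000))))
        kb = KnowledgeBase(RegionSet(regions))
        loci = loci_at(sorted(rng.choice(25000, size=120, replace=False)))
        bins, unassigned = assign_loci_to_features(loci, kb, "gene")
        membership = {b.bin_id: set(b.member_loci) for b in bins}
        for r in regions:
            expected = {l.locus_id for l in loci if r.contains(l.chrom, l.pos)}
            assert membership.get(r.region_id, set()) == expected
        hit = set().union(*membership.values()) if membership else set()
        assert {l.locus_id for l in unassigned} == {l.locus_id for l in loci} - hit


class TestIntergenic:
    def test_floor_division_window(self):
        bins = make_intergenic_bins(loci_at([123456]), width_kb=50)
        assert bins[0].bin_id == "intergenic:chr1:100000-150000"

    def test_same_window_shares_bin(self):
        bins = make_intergenic_bins(loci_at([10001, 49999]), width_kb=50)
        assert len(bins) == 1 and bins[0].n_loci == 2

    def test_width_validation(self):
        with pytest.raises(ValueError):
            make_intergenic_bins([], width_kb=0)


class TestWeights:
    def test_madsen_browning_reference_value(self):
        # 500 controls, 4 non-major alleles among them, 1000 genotyped total
        ctrl = np.zeros((500, 1), dtype=int)
        ctrl[:4] = 1
        case = np.zeros((500, 1), dtype=int)
        gm, phen = matrix_with_freqs(case, ctrl)
        (lw,) = compute_weights(gm, phen, ["L0"], WeightScheme.CONTROL)
        assert lw.q == pytest.approx(5 / 1002, abs=1e-9)
        assert lw.n == 1000
        assert lw.w == pytest.approx(0.4488, abs=1e-4)

    def test_none_scheme_is_unit_weights(self, rng):
        gm, phen = matrix_with_freqs(rng.integers(0, 2, (20, 5)), rng.integers(0, 2, (20, 5)))
        weights = compute_weights(gm, phen, [l.locus_id for l in gm.loci], "none")
        assert all(w.w == 1.0 for w in weights)

    def test_identical_strata_collapse_stratum_schemes(self, rng):
        dos = rng.integers(0, 2, (30, 6))
        gm, phen = matrix_with_freqs(dos, dos.copy())
        ids = [l.locus_id for l in gm.loci]
        w_ctrl = [w.w for w in compute_weights(gm, phen, ids, "control")]
        w_min = [w.w for w in compute_weights(gm, phen, ids, "minimum")]
        w_max = [w.w for w in compute_weights(gm, phen, ids, "maximum")]
        w_all = [w.w for w in compute_weights(gm, phen, ids, "overall")]
        assert w_ctrl == w_min == w_max
        # the pooled estimate differs only through the shared pseudo-count
        np.testing.assert_allclose(w_all, w_ctrl, rtol=0.15)

    def test_weight_monotone_decreasing_in_frequency(self):
        # fixed n: rarer variant -> strictly larger weight
        ctrl = np.zeros((100, 3), dtype=int)
        ctrl[:1, 0] = 1
        ctrl[:10, 1] = 1
        ctrl[:40, 2] = 1
        gm, phen = matrix_with_freqs(np.zeros((100, 3), dtype=int), ctrl)
        ws = compute_weights(gm, phen, ["L0", "L1", "L2"], "control")
        assert ws[0].w > ws[1].w > ws[2].w
        assert ws[0].q < ws[1].q < ws[2].q < 0.5

    def test_sandwich_when_pooled_q_is_between_stratum_qs(self, rng):
        # betweenness of the pooled estimate is what orders the schemes
        case = rng.binomial(2, 0.05, (200, 40))
        ctrl = rng.binomial(2, 0.12, (200, 40))
        gm, phen = matrix_with_freqs(case, ctrl)
        ids = [l.locus_id for l in gm.loci]
        w_min = np.array([w.w for w in compute_weights(gm, phen, ids, "minimum")])
        w_max = np.array([w.w for w in compute_weights(gm, phen, ids, "maximum")])
        over = compute_weights(gm, phen, ids, "overall")
        q_min = np.array([w.q for w in compute_weights(gm, phen, ids, "maximum")])
        q_max = np.array([w.q for w in compute_weights(gm, phen, ids, "minimum")])
        w_over = np.array([w.w for w in over])
        q_over = np.array([w.q for w in over])
        between = (q_min <= q_over) & (q_over <= q_max)
        assert between.mean() > 0.5  # generically true away from monomorphic loci
        assert (w_min[between] <= w_over[between] + 1e-12).all()
        assert (w_over[between] <= w_max[between] + 1e-12).all()
        assert (w_min <= w_max + 1e-12).all()

    def test_custom_scheme_lookup_with_default(self, rng):
        gm, phen = matrix_with_freqs(rng.integers(0, 2, (10, 2)), rng.integers(0, 2, (10, 2)))
        ws = compute_weights(gm, phen, ["L0", "L1"], "custom", custom={"L0": 2.5})
        assert [w.w for w in ws] == [2.5, 1.0]
        with pytest.raises(ValueError, match="weight table"):
            compute_weights(gm, phen, ["L0"], "custom")


class TestScoring:
    def test_two_locus_weighted_het(self):
        gm = biallelic_matrix(np.array([[1, 1], [0, 0]]))
        from rarebin.binning import LocusWeight

        weights = [LocusWeight("L0", 0.1, 2, 1.0), LocusWeight("L1", 0.1, 2, 0.5)]
        bsm = score_bins([BinDefinition("B", "gene", ["L0", "L1"])], gm, "additive", weights)
        np.testing.assert_allclose(bsm.scores[:, 0], [1.5, 0.0])
        assert bsm.capacity[0] == 4

    def test_all_reference_sample_scores_zero(self, rng):
        dos = rng.integers(0, 2, (10, 4))
        dos[0] = 0
        gm = biallelic_matrix(dos)
        phen = Phenotype(list(gm.samples), np.r_[np.ones(5, dtype=int), np.zeros(5, dtype=int)])
        ids = [l.locus_id for l in gm.loci]
        bsm = score_bins([BinDefinition("B", "gene", ids)], gm, "additive",
                         compute_weights(gm, phen, ids, "none"))
        assert bsm.scores[0, 0] == 0.0

    def test_matches_naive_double_loop(self, rng):
        from rarebin.binning import LocusWeight
        from rarebin.variant_io import encode_genotype

        dos = rng.integers(-1, 3, size=(20, 10))
        gm = biallelic_matrix(dos)
        ids = [l.locus_id for l in gm.loci]
        weights = [LocusWeight(l, 0.1, 20, float(w)) for l, w in
                   zip(ids, rng.uniform(0.2, 3.0, 10))]
        wmap = {w.locus_id: w.w for w in weights}
        bins = [BinDefinition("B1", "gene", ids[:6]), BinDefinition("B2", "gene", ids[4:])]
        for model in ("additive", "dominant", "recessive"):
            bsm = score_bins(bins, gm, model, weights)
            major = gm.major_alleles()
            for b, bin_def in enumerate(bins):
                for i in range(gm.n_samples):
                    expected = 0.0
                    for lid in bin_def.member_loci:
                        j = gm.locus_index(lid)
                        call = tuple(gm.calls[i, j])
                        expected += wmap[lid] * encode_genotype(call, major[j], model)
                    assert bsm.scores[i, b] == pytest.approx(expected)

    def test_missing_weight_errors(self):
        gm = biallelic_matrix(np.array([[1]]))
        with pytest.raises(ValueError, match="no weight"):
            score_bins([BinDefinition("B", "gene", ["L0"])], gm, "additive", [])

    def test_unit_additive_scores_are_allele_counts(self, rng):
        dos = rng.integers(0, 3, (15, 6))
        gm = biallelic_matrix(dos)
        phen = Phenotype(list(gm.samples), np.r_[np.ones(7, dtype=int), np.zeros(8, dtype=int)])
        ids = [l.locus_id for l in gm.loci]
        bsm = score_bins([BinDefinition("B", "gene", ids)], gm, "additive",
                         compute_weights(gm, phen, ids, "none"))
        major = gm.major_alleles()
        # with allele 1 the majority somewhere, "non-major" flips to the ref count
        expected = np.where(major[None, :] == 0, dos, 2 - dos).sum(axis=1)
        np.testing.assert_allclose(bsm.scores[:, 0], expected)
        assert np.allclose(bsm.scores[:, 0] % 1, 0)


class TestReport:
    def test_round_trip_and_summary(self, tmp_path, rng):
        dos = rng.integers(0, 2, (2, 3))
        gm = biallelic_matrix(dos)
        phen = Phenotype(list(gm.samples), np.array([1, 0]))
        ids = [l.locus_id for l in gm.loci]
        bsm = score_bins([BinDefinition("B", "gene", ids)], gm, "additive",
                         compute_weights(gm, phen, ids, "overall"))
        scores_path, bins_path = write_bin_report(bsm, tmp_path / "toy")
        assert len(scores_path.read_text().splitlines()) == 3  # header + 2 samples
        samples, bin_ids, scores = read_score_file(scores_path)
        assert samples == bsm.samples and bin_ids == ["B"]
        np.testing.assert_allclose(scores, bsm.scores, atol=1e-9)
        summary = bins_path.read_text().splitlines()[1].split("\t")
        assert summary[2] == "3"  # n_loci column equals |member_loci|
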