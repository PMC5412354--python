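"""Synthetic panel world: intervals, planting, pedigree genotypes, reads."""

import numpy as np
import pytest

from paneldepth import (
    CapacityError,
    ConsistencyError,
    InvalidParameterError,
    Member,
    Pedigree,
    assign_pedigree_genotypes,
    build_panel,
    left_normalize,
    plant_variants,
    simulate_reads,
    transmission_consistent,
)
from paneldepth.panel_synth import PanelRegion, total_padded_length
from paneldepth.pedigree import AFFECTED, UNAFFECTED
from paneldepth.variants import GT_HET, GT_HOM_ALT, GT_HOM_REF
from paneldepth.example_cases import case1_pedigree, case2_pedigree


def interval_union_length(regions):
    """Independent oracle: total padded length via a per-chromosome boolean mask."""
    total = 0
    for r in regions:
        hi = max(e for _, e in r.padded_intervals)
        mask = np.zeros(hi, dtype=bool)
        for s, e in r.padded_intervals:
            mask[s:e] = True
        total += int(mask.sum())
    return total


class TestBuildPanel:
    def test_padded_length_matches_interval_union_oracle(self):
        regions, reference = build_panel(27, 5, 200, pad_bp=100, seed=3)
        assert len(regions) == 27
        # gap 300 > 2*100 so pads never merge: 27 genes x 5 exons x (200+200)
        assert total_padded_length(regions) == 27 * 5 * 400
        assert total_padded_length(regions) == interval_union_length(regions)
        for r in regions:
            assert len(reference[r.chromosome]) >= r.padded_intervals[-1][1]

    def test_single_unpadded_exon(self):
        regions, _ = build_panel(1, 1, 100, pad_bp=0, seed=1)
        assert regions[0].padded_intervals == [regions[0].exons[0]]
        assert total_padded_length(regions) == 100

    def test_close_exons_merge_after_padding(self):
        # pad 100 on each side of exons 150 apart: 100+100 >= 150 forces a merge
        regions, _ = build_panel(2, 4, 200, pad_bp=100, seed=5, exon_gap=150)
        for r in regions:
            assert len(r.padded_intervals) == 1
            assert r.padded_length == 4 * 200 + 3 * 150 + 200
        assert total_padded_length(regions) == interval_union_length(regions)

    def test_deterministic_for_fixed_seed(self):
        a = build_panel(4, 3, 120, 50, seed=42)
        b = build_panel(4, 3, 120, 50, seed=42)
        assert a[1] == b[1]
        assert [r.padded_intervals for r in a[0]] == [r.padded_intervals for r in b[0]]

    @pytest.mark.parametrize("kwargs", [
        dict(n_genes=0, exons_per_gene=1, exon_len=100, pad_bp=0),
        dict(n_genes=1, exons_per_gene=1, exon_len=5, pad_bp=0),
        dict(n_genes=1, exons_per_gene=1, exon_len=100, pad_bp=-1),
    ])
    def test_invalid_sizes_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            build_panel(seed=0, **kwargs)

    def test_region_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            PanelRegion("g", "c", [(10, 5)], 0)
        with pytest.raises(InvalidParameterError):
            PanelRegion("g", "c", [(0, 10), (5, 20)], 0)


class TestPlantVariants:
    def test_exact_counts_and_classes(self):
        regions, reference = build_panel(27, 5, 200, 100, seed=1)
        variants = plant_variants(regions, reference, 162, 42, seed=2)
        assert sum(v.var_class == "snp" for v in variants) == 162
        assert sum(v.var_class == "indel" for v in variants) == 42

    def test_variants_left_normalized_and_sorted(self):
        regions, reference = build_panel(6, 4, 150, 100, seed=7)
        variants = plant_variants(regions, reference, 20, 20, seed=8)
        keys = [v.key for v in variants]
        assert keys == sorted(keys)
        for v in variants:
            seq = reference[v.chrom]
            assert seq[v.pos - 1 : v.pos - 1 + len(v.ref)] == v.ref
            assert left_normalize(seq, v.pos, v.ref, v.alt) == (v.pos, v.ref, v.alt)

    def test_zero_requested_gives_empty_set(self):
        regions, reference = build_panel(2, 2, 100, 50, seed=1)
        assert plant_variants(regions, reference, 0, 0, seed=1) == []

    def test_determinism(self):
        regions, reference = build_panel(5, 3, 150, 100, seed=9)
        a = plant_variants(regions, reference, 15, 5, seed=10)
        b = plant_variants(regions, reference, 15, 5, seed=10)
        assert [v.key for v in a] == [v.key for v in b]

    def test_capacity_error_when_panel_too_small(self):
        regions, reference = build_panel(1, 1, 200, 0, seed=1)
        with pytest.raises(CapacityError):
            plant_variants(regions, reference, 50, 0, seed=1)


class TestLeftNormalize:
    def test_deletion_shifts_left_through_homopolymer(self):
        #     123456789
        seq = "GAAAATCGT"
        # deleting one A reported at pos 4 normalizes to the anchor G at pos 1
        assert left_normalize(seq, 4, "AA", "A") == (1, "GA", "G")

    def test_snp_unchanged(self):
        assert left_normalize("ACGT", 3, "G", "T") == (3, "G", "T")

    def test_shared_leading_base_trimmed_for_mnp(self):
        assert left_normalize("ACGTACGT", 2, "CG", "CT") == (3, "G", "T")


class TestPedigreeGenotypes:
    def _causal(self, variants):
        return next(v for v in variants if v.var_class == "snp").key

    def test_ar_family_affected_hom_parents_het(self):
        regions, reference = build_panel(4, 3, 150, 100, seed=20)
        variants = plant_variants(regions, reference, 10, 2, seed=21)
        ped = case1_pedigree()
        causal = self._causal(variants)
        out = assign_pedigree_genotypes(variants, ped, causal, seed=22)
        cv = next(v for v in out if v.key == causal)
        assert cv.genotypes["II-1"] == GT_HOM_ALT
        assert cv.genotypes["II-2"] == GT_HOM_ALT
        assert cv.genotypes["I-1"] == GT_HET and cv.genotypes["I-2"] == GT_HET
        for sib in ("II-3", "II-4", "II-5"):
            assert cv.genotypes[sib] in (GT_HET, GT_HOM_REF)
        for v in out:
            assert transmission_consistent(v.genotypes, ped)

    def test_ad_incomplete_penetrance_allows_unaffected_carrier(self):
        regions, reference = build_panel(3, 2, 150, 100, seed=30)
        variants = plant_variants(regions, reference, 5, 1, seed=31)
        ped = case2_pedigree()  # penetrance 0.5
        causal = self._causal(variants)
        out = assign_pedigree_genotypes(variants, ped, causal, seed=32)
        cv = next(v for v in out if v.key == causal)
        assert cv.genotypes["II-1"] in (GT_HET, GT_HOM_ALT)  # affected proband carries
        assert cv.genotypes["I-1"] in (GT_HET, GT_HOM_ALT)   # affected aunt carries
        # the proband's carrier parent is unaffected: only possible with penetrance < 1
        assert cv.genotypes["I-2"] in (GT_HET, GT_HOM_ALT) or cv.genotypes["I-3"] in (GT_HET, GT_HOM_ALT)

    def test_ad_full_penetrance_with_unaffected_parents_is_impossible(self):
        regions, reference = build_panel(3, 2, 150, 100, seed=33)
        variants = plant_variants(regions, reference, 4, 0, seed=34)
        ped = case2_pedigree()
        ped.penetrance = 1.0
        with pytest.raises(ConsistencyError):
            assign_pedigree_genotypes(variants, ped, self._causal(variants), seed=35)

    def test_single_founder_zero_maf_all_hom_ref(self):
        regions, reference = build_panel(2, 2, 150, 100, seed=36)
        variants = plant_variants(regions, reference, 5, 0, seed=37)
        ped = Pedigree([Member("F1", "female", None, None, UNAFFECTED)])
        out = assign_pedigree_genotypes(variants, ped, None, seed=38, founder_maf=0.0)
        assert all(v.genotypes["F1"] == GT_HOM_REF for v in out)


class TestSimulateReads:
    def test_realized_coverage_within_5pct(self, small_world):
        from paneldepth import coverage_metrics

        m = coverage_metrics(small_world.reads, small_world.regions)
        assert abs(m.mean_target_coverage - 150.0) / 150.0 < 0.05

    def test_error_free_hom_ref_reads_match_reference(self):
        regions, reference = build_panel(2, 2, 150, 100, seed=40)
        reads = simulate_reads(reference, regions, 30.0, error_rate=0.0, seed=41)
        from paneldepth._util import decode_seq

        for i in range(reads.n_reads):
            chrom = reads.chroms[reads.chrom_idx[i]]
            s = int(reads.start[i])
            assert decode_seq(reads.seq[i]) == reference[chrom][s : s + reads.read_len]

    def test_het_site_allele_fraction_binomial(self):
        from paneldepth import build_pileup
        from paneldepth.variants import PlantedVariant

        regions, reference = build_panel(1, 1, 400, 100, seed=50)
        r = regions[0]
        pos0 = (r.padded_intervals[0][0] + r.padded_intervals[0][1]) // 2
        ref_base = reference[r.chromosome][pos0]
        alt = "A" if ref_base != "A" else "C"
        v = PlantedVariant(r.chromosome, pos0 + 1, ref_base, alt, {"s": GT_HET})
        reads = simulate_reads(reference, regions, 200.0, 0.0, member_id="s",
                               capture_cv=0.0, seed=51, variants=[v])
        col = next(c for c in build_pileup(reads, reference, regions) if c.pos == pos0 + 1)
        depth = col.depth
        frac = col.base_counts.get(alt, 0) / depth
        assert abs(frac - 0.5) < 3 * (0.25 / depth) ** 0.5

    def test_homopolymer_slip_creates_spurious_deletion_evidence(self):
        # a poly-A tract of 12 inside the target; otherwise run-free sequence
        body = ("ACGT" * 200)[:600]
        seq = body[:300] + "A" * 12 + body[312:]
        reference = {"panel_chr1": seq}
        regions = [PanelRegion("g", "panel_chr1", [(250, 400)], 0)]
        reads = simulate_reads(reference, regions, 80.0, error_rate=0.0,
                               capture_cv=0.0, seed=70, homopolymer_slip_rate=0.5)
        events = set(reads.indel_events.values())
        assert events, "expected spurious slip events at the poly-A tract"
        assert all(pos == 300 and ref[1] == "A" and ref[0] == alt
                   for pos, ref, alt in events)

    def test_parameter_validation(self):
        regions, reference = build_panel(1, 1, 100, 0, seed=1)
        with pytest.raises(InvalidParameterError):
            simulate_reads(reference, regions, 0.0, 0.01)
        with pytest.raises(InvalidParameterError):
            simulate_reads(reference, regions, 10.0, 0.5)
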