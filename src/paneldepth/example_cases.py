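"""Bundled worked example: two diagnosed CMT families from a 27-gene panel.

Two index patients sequenced on a Charcot-Marie-Tooth gene panel serve as
the package's reference walkthrough.  Case 1 is a consanguineous family with
autosomal recessive disease resolved to a homozygous HSPB1 p.G84R variant;
Case 2 is an autosomal dominant family with incomplete penetrance resolved
to a heterozygous GDAP1 p.R120W variant.  This module encodes their
published annotated shortlists (frequencies, MutationTaster and KGGSeq
outputs), cascade-screening pedigree genotypes, the known-mutation lookup
table, and the summary statistics of each sequencing run (mean target
coverage, truth-set sizes, low-coverage recall means), so the cascade and
the depth arithmetic can be exercised end to end without any external data.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .pedigree import AFFECTED, UNAFFECTED, Member, Pedigree
from .prioritize import (
    KGG_BENIGN,
    KGG_DISEASE,
    KGG_FILTERED,
    KGG_NONE,
    MT_DISEASE,
    MT_POLY,
    AnnotatedVariant,
)
from .variants import GT_HET, GT_HOM_ALT, GT_HOM_REF

#: HGMD-style local known-mutation table keyed by (gene, HGVS cDNA).
KNOWN_MUTATIONS: Dict[Tuple[str, str], str] = {
    ("HSPB1", "c.250G>A"): "CM084860",
    ("GDAP1", "c.358C>T"): "CM032927",
}

#: Published per-run summary statistics used in the depth arithmetic.
CASE_SUMMARIES = {
    "case1": {
        "mean_target_coverage": 213.4,
        "n_snps": 162,
        "n_indels": 42,
        "snp_mean_count_at_5pct": 115.0,
        "indel_mean_count_at_5pct": 11.4,
        "coverage_pcts": {"ge_2x": 99.09, "ge_10x": 98.64, "ge_50x": 90.98},
    },
    "case2": {
        "mean_target_coverage": 184.2,
        "n_snps": 160,
        "n_indels": 33,
        "snp_mean_count_at_5pct": 118.0,
        "indel_mean_count_at_5pct": 8.6,
        "coverage_pcts": {"ge_2x": 99.29, "ge_10x": 98.85, "ge_50x": 89.50},
    },
}


def case1_pedigree() -> Pedigree:
    """AR consanguineous family: two affected sibs, carrier parents."""
    members = [
        Member("I-1", "male", None, None, UNAFFECTED),
        Member("I-2", "female", None, None, UNAFFECTED),
        Member("II-1", "female", "I-1", "I-2", AFFECTED),
        Member("II-2", "male", "I-1", "I-2", AFFECTED),   # proband
        Member("II-3", "male", "I-1", "I-2", UNAFFECTED),
        Member("II-4", "female", "I-1", "I-2", UNAFFECTED),
        Member("II-5", "male", "I-1", "I-2", UNAFFECTED),
    ]
    return Pedigree(members, inheritance_model="AR", penetrance=1.0)


def case1_genotypes() -> Dict[str, str]:
    """Cascade-screening genotypes for the HSPB1 c.250G>A variant."""
    return {
        "I-1": GT_HET, "I-2": GT_HET,
        "II-1": GT_HOM_ALT, "II-2": GT_HOM_ALT,
        "II-3": GT_HOM_REF, "II-4": GT_HOM_REF, "II-5": GT_HOM_REF,
    }


def case2_pedigree() -> Pedigree:
    """AD family with incomplete penetrance: affected aunt and proband,
    unaffected carrier father."""
    members = [
        Member("I-1", "female", None, None, AFFECTED),    # paternal aunt
        Member("I-2", "male", None, None, UNAFFECTED),    # father, carrier
        Member("I-3", "female", None, None, UNAFFECTED),  # mother
        Member("II-1", "female", "I-2", "I-3", AFFECTED), # proband
    ]
    return Pedigree(members, inheritance_model="AD", penetrance=0.5)


def case2_genotypes() -> Dict[str, str]:
    """Cascade-screening genotypes for the GDAP1 c.358C>T variant."""
    return {
        "I-1": GT_HET, "I-2": GT_HET, "I-3": GT_HOM_REF, "II-1": GT_HET,
    }


def case1_annotated_variants():
    """Case 1's annotated shortlist table (four rows)."""
    return [
        AnnotatedVariant(
            variant_id="chr1:156109095delA", gene="LMNA", hgvs="cDNA.2405delA",
            function_class="utr_indel", genotype=GT_HET,
            genotype_quality=99.0, site_depth=210,
            overall_mafs={}, subpop_mafs={},
            predictor_mt=(MT_DISEASE, 0.999), predictor_kgg=(KGG_NONE, None),
            is_indel=True, homopolymer_run=8, multiallelic_pileup=True,
        ),
        AnnotatedVariant(
            variant_id="chr7:75932279G>A", gene="HSPB1", hgvs="c.250G>A",
            function_class="nonsynonymous_snp", genotype=GT_HOM_ALT,
            genotype_quality=99.0, site_depth=220,
            overall_mafs={}, subpop_mafs={},
            predictor_mt=(MT_DISEASE, 0.999), predictor_kgg=(KGG_DISEASE, 0.681),
        ),
        AnnotatedVariant(
            variant_id="chr11:9861208G>C", gene="SBF2", hgvs="c.3292C>G",
            function_class="nonsynonymous_snp", genotype=GT_HET,
            genotype_quality=99.0, site_depth=200,
            overall_mafs={"exac": 0.0209}, subpop_mafs={},
            predictor_mt=(MT_POLY, 0.054), predictor_kgg=(KGG_BENIGN, 3.46e-4),
        ),
        AnnotatedVariant(
            variant_id="chr11:95595177A>G", gene="MTMR2", hgvs="c.447T>C",
            function_class="synonymous_snp", genotype=GT_HET,
            genotype_quality=99.0, site_depth=190,
            overall_mafs={"exac": 2.527e-5}, subpop_mafs={"sas": 2.527e-5},
            predictor_mt=(MT_DISEASE, 1.0), predictor_kgg=(KGG_NONE, None),
        ),
    ]


def case2_annotated_variants():
    """Case 2's annotated shortlist table (five rows)."""
    return [
        AnnotatedVariant(
            variant_id="chr1:10342522G>A", gene="KIF1B", hgvs="c.1227G>A",
            function_class="synonymous_snp", genotype=GT_HET,
            genotype_quality=99.0, site_depth=180,
            overall_mafs={"exac": 0.0328}, subpop_mafs={"eas": 0.08},
            predictor_mt=(MT_POLY, 2.98e-17), predictor_kgg=(KGG_FILTERED, None),
        ),
        AnnotatedVariant(
            variant_id="chr1:10397567A>G", gene="KIF1B", hgvs="c.3260A>G",
            function_class="nonsynonymous_snp", genotype=GT_HET,
            genotype_quality=99.0, site_depth=185,
            overall_mafs={"exac": 0.0325}, subpop_mafs={},
            predictor_mt=(MT_POLY, 5.41e-11), predictor_kgg=(KGG_BENIGN, 0.039),
        ),
        AnnotatedVariant(
            variant_id="chr1:156109095delA", gene="LMNA", hgvs="cDNA.2405delA",
            function_class="utr_indel", genotype=GT_HET,
            genotype_quality=99.0, site_depth=175,
            overall_mafs={}, subpop_mafs={},
            predictor_mt=(MT_DISEASE, 0.999), predictor_kgg=(KGG_NONE, None),
            is_indel=True, homopolymer_run=8, multiallelic_pileup=True,
        ),
        AnnotatedVariant(
            variant_id="chr8:75272419C>T", gene="GDAP1", hgvs="c.358C>T",
            function_class="nonsynonymous_snp", genotype=GT_HET,
            genotype_quality=99.0, site_depth=170,
            overall_mafs={}, subpop_mafs={},
            predictor_mt=(MT_DISEASE, 0.999), predictor_kgg=(KGG_DISEASE, 0.500),
        ),
        AnnotatedVariant(
            variant_id="chr11:9990017G>A", gene="SBF2", hgvs="c.1471C>T",
            function_class="nonsynonymous_snp", genotype=GT_HET,
            genotype_quality=99.0, site_depth=165,
            overall_mafs={}, subpop_mafs={},
            predictor_mt=(MT_DISEASE, 0.999), predictor_kgg=(KGG_BENIGN, 0.044),
        ),
    ]
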