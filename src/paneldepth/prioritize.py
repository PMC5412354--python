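"""Variant-prioritization cascade and pedigree segregation checks.

The cascade reproduces the clinical shortlist logic of a Mendelian panel
workup over an annotated variant table: population-frequency filters
(overall and sub-population MAF < 0.05), genotype quality control (GQ >= 20,
depth >= 4), a functional-class eligibility flag (non-synonymous and
splice-site variants can carry a diagnosis; synonymous and UTR variants are
retained in the report but flagged), a two-predictor consensus (a
MutationTaster-style classifier and a KGGSeq-style Mendelian ensemble whose
label/probability are *inputs*, not re-implemented here), a known-mutation
lookup, and an inheritance-mode shortlist (AR keeps homozygous variants, AD
keeps carriers).

The final candidate diagnosis requires a strong predictor consensus plus
inheritance compatibility; ties are ranked by consensus then disease
probability.  A segregation check grades observed family genotypes as
consistent, consistent-with-incomplete-penetrance (unaffected carriers
under AD), or inconsistent (Mendelian impossibility or an affected
non-carrier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._util import InvalidParameterError
from .pedigree import AFFECTED, UNAFFECTED, Pedigree, transmission_consistent
from .variants import GT_HET, GT_HOM_ALT, GT_HOM_REF

FUNCTION_CLASSES = ("nonsynonymous_snp", "synonymous_snp", "splice_site", "utr_indel", "other")
DIAGNOSIS_ELIGIBLE_CLASSES = ("nonsynonymous_snp", "splice_site")

MT_DISEASE = "disease_causing"
MT_POLY = "polymorphism"
KGG_DISEASE = "disease_causing"
KGG_BENIGN = "non_disease_causing"
KGG_NONE = "no_prediction"
KGG_FILTERED = "filtered"

PASS, FAIL, NA = "pass", "fail", "not_applicable"

#: Homopolymer-slip artifact rule: an indel at the end of a base run at least
#: this long, with a multi-allelic pileup, is flagged suspected-artifact.
ARTIFACT_MIN_HOMOPOLYMER = 6


@dataclass
class QCThresholds:
    min_genotype_quality: float = 20.0
    min_depth: int = 4
    max_overall_maf: float = 0.05
    max_subpop_maf: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_genotype_quality, self.min_depth,
               self.max_overall_maf, self.max_subpop_maf) < 0:
            raise InvalidParameterError("all thresholds must be non-negative")


@dataclass
class AnnotatedVariant:
    """One row of the annotated variant table (the cascade's input unit)."""

    variant_id: str
    gene: str
    hgvs: str
    function_class: str
    genotype: str  # 'het' | 'hom_alt'
    genotype_quality: float
    site_depth: int
    overall_mafs: Dict[str, float] = field(default_factory=dict)   # database -> MAF
    subpop_mafs: Dict[str, float] = field(default_factory=dict)    # population -> MAF
    predictor_mt: Tuple[str, Optional[float]] = (MT_POLY, None)    # (label, P_correct)
    predictor_kgg: Tuple[str, Optional[float]] = (KGG_NONE, None)  # (label, P_disease)
    known_mutation_id: Optional[str] = None
    is_indel: bool = False
    homopolymer_run: int = 0
    multiallelic_pileup: bool = False

    def __post_init__(self) -> None:
        if self.function_class not in FUNCTION_CLASSES:
            raise InvalidParameterError(f"unknown function class {self.function_class!r}")
        if self.genotype not in (GT_HET, GT_HOM_ALT):
            raise InvalidParameterError("genotype must be het or hom_alt")
        for maf in list(self.overall_mafs.values()) + list(self.subpop_mafs.values()):
            if not 0.0 <= maf <= 1.0:
                raise InvalidParameterError("frequencies must lie in [0, 1]")
        if self.genotype_quality < 0:
            raise InvalidParameterError("genotype_quality must be >= 0")


@dataclass
class VerdictEntry:
    filter_name: str
    verdict: str  # pass | fail | not_applicable
    reason: str


@dataclass
class ShortlistReport:
    trails: Dict[str, List[VerdictEntry]]          # variant_id -> trail
    shortlist: List[AnnotatedVariant]              # passed all mandatory filters
    candidates: List[AnnotatedVariant]             # final ranked diagnosis candidates
    suspected_artifacts: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def frequency_filter(v: AnnotatedVariant, t: QCThresholds) -> str:
    """Fail iff any overall database MAF >= threshold; absent data passes."""
    return FAIL if any(m >= t.max_overall_maf for m in v.overall_mafs.values()) else PASS


def subpop_frequency_filter(v: AnnotatedVariant, t: QCThresholds) -> str:
    """Fail iff the maximum sub-population MAF >= threshold (vacuous max passes)."""
    return FAIL if any(m >= t.max_subpop_maf for m in v.subpop_mafs.values()) else PASS


def genotype_qc(v: AnnotatedVariant, t: QCThresholds) -> str:
    """Pass iff GQ >= min_genotype_quality and depth >= min_depth (inclusive)."""
    ok = v.genotype_quality >= t.min_genotype_quality and v.site_depth >= t.min_depth
    return PASS if ok else FAIL


def functional_class_filter(v: AnnotatedVariant) -> str:
    return PASS if v.function_class in DIAGNOSIS_ELIGIBLE_CLASSES else FAIL


def predictor_consensus(v: AnnotatedVariant) -> str:
    """'strong' on a Mendelian-ensemble disease call, 'weak' on classifier-only.

    When only the disease probability is given, P_disease >= 0.5 maps to a
    disease call (the 0.5 boundary is inclusive).
    """
    kgg_label, kgg_p = v.predictor_kgg
    if kgg_label == KGG_DISEASE:
        return "strong"
    # label absent but a probability given: derive the label at the inclusive 0.5 boundary
    if kgg_label not in (KGG_BENIGN, KGG_NONE, KGG_FILTERED) and kgg_p is not None and kgg_p >= 0.5:
        return "strong"
    if v.predictor_mt[0] == MT_DISEASE:
        return "weak"
    return "none"


def inheritance_compatible(v: AnnotatedVariant, pedigree: Pedigree) -> bool:
    if pedigree.inheritance_model == "AR":
        return v.genotype == GT_HOM_ALT
    return v.genotype in (GT_HET, GT_HOM_ALT)


def inheritance_filter(variants: Sequence[AnnotatedVariant],
                       pedigree: Pedigree) -> List[AnnotatedVariant]:
    return [v for v in variants if inheritance_compatible(v, pedigree)]


def known_mutation_lookup(v: AnnotatedVariant,
                          known_table: Dict[Tuple[str, str], str]) -> Optional[str]:
    """Exact (gene, HGVS) lookup in the local known-mutation table."""
    return known_table.get((v.gene, v.hgvs))


def suspected_artifact(v: AnnotatedVariant) -> bool:
    return (v.is_indel and v.homopolymer_run >= ARTIFACT_MIN_HOMOPOLYMER
            and v.multiallelic_pileup)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def run_cascade(variants: Sequence[AnnotatedVariant], pedigree: Pedigree,
                thresholds: Optional[QCThresholds] = None,
                known_table: Optional[Dict[Tuple[str, str], str]] = None) -> ShortlistReport:
    """Run the full filter cascade and rank candidate diagnoses.

    Mandatory filters (frequency, sub-population frequency, genotype QC) are
    an intersection: their order cannot change the surviving set.  The
    functional-class and predictor verdicts are recorded for every variant;
    a final candidate must be shortlisted, diagnosis-eligible, carry a strong
    consensus and fit the pedigree's inheritance model.
    """
    thresholds = thresholds or QCThresholds()
    known_table = known_table or {}
    ids = [v.variant_id for v in variants]
    if len(set(ids)) != len(ids):
        raise InvalidParameterError("variant_id values must be unique")

    trails: Dict[str, List[VerdictEntry]] = {}
    shortlist: List[AnnotatedVariant] = []
    eligible: List[AnnotatedVariant] = []
    artifacts: List[str] = []
    for v in variants:
        trail: List[VerdictEntry] = []
        f1 = frequency_filter(v, thresholds)
        trail.append(VerdictEntry("frequency", f1,
                                  f"max overall MAF {max(v.overall_mafs.values(), default=float('nan'))}"
                                  if v.overall_mafs else "no frequency data"))
        f2 = subpop_frequency_filter(v, thresholds)
        trail.append(VerdictEntry("subpop_frequency", f2,
                                  f"max subpop MAF {max(v.subpop_mafs.values(), default=float('nan'))}"
                                  if v.subpop_mafs else "no subpopulation data"))
        f3 = genotype_qc(v, thresholds)
        trail.append(VerdictEntry("genotype_qc", f3,
                                  f"GQ={v.genotype_quality}, DP={v.site_depth}"))
        f4 = functional_class_filter(v)
        trail.append(VerdictEntry("functional_class",
                                  f4 if f4 == PASS else NA,
                                  v.function_class))
        cons = predictor_consensus(v)
        trail.append(VerdictEntry("predictor_consensus",
                                  PASS if cons == "strong" else (NA if cons == "weak" else FAIL),
                                  f"consensus={cons}"))
        compat = inheritance_compatible(v, pedigree)
        trail.append(VerdictEntry("inheritance", PASS if compat else FAIL,
                                  f"{pedigree.inheritance_model} with genotype {v.genotype}"))
        if suspected_artifact(v):
            artifacts.append(v.variant_id)
            trail.append(VerdictEntry("artifact_screen", FAIL,
                                      f"indel at end of homopolymer run {v.homopolymer_run} "
                                      "with multi-allelic pileup"))
        known = known_mutation_lookup(v, known_table)
        if known:
            trail.append(VerdictEntry("known_mutation", PASS, known))
        trails[v.variant_id] = trail
        if PASS == f1 == f2 == f3:
            shortlist.append(v)
            if f4 == PASS:
                eligible.append(v)

    rank = {"strong": 0, "weak": 1, "none": 2}
    candidates = [
        v for v in eligible
        if predictor_consensus(v) == "strong" and inheritance_compatible(v, pedigree)
    ]
    candidates.sort(key=lambda v: (rank[predictor_consensus(v)],
                                   -(v.predictor_kgg[1] if v.predictor_kgg[1] is not None else 0.0)))
    return ShortlistReport(trails, shortlist, candidates, artifacts)


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------

CONSISTENT = "consistent"
CONSISTENT_IP = "consistent_with_incomplete_penetrance"
INCONSISTENT = "inconsistent"


def segregation_check(pedigree: Pedigree, genotypes: Dict[str, str]) -> str:
    """Grade observed family genotypes against the pedigree's disease model.

    ``genotypes`` maps member id to hom_ref/het/hom_alt for at least two
    members.  Mendelian transmission is verified first; then AR requires all
    affected members homozygous-alt with carrier parents, AD requires every
    affected member to carry the allele.  Under AD an unaffected carrier
    downgrades the verdict to consistent-with-incomplete-penetrance.
    """
    if len(genotypes) < 2:
        raise InvalidParameterError("segregation check needs genotypes for >= 2 members")
    if not transmission_consistent(genotypes, pedigree):
        return INCONSISTENT
    byid = pedigree.by_id
    model = pedigree.inheritance_model
    incomplete = False
    for mid, gt in genotypes.items():
        m = byid.get(mid)
        if m is None:
            continue
        if model == "AR":
            if m.affected == AFFECTED:
                if gt != GT_HOM_ALT:
                    return INCONSISTENT
                for pid in (m.father_id, m.mother_id):
                    if pid in genotypes and genotypes[pid] == GT_HOM_REF:
                        return INCONSISTENT
            elif m.affected == UNAFFECTED and gt == GT_HOM_ALT:
                return INCONSISTENT
        else:  # AD
            carrier = gt in (GT_HET, GT_HOM_ALT)
            if m.affected == AFFECTED and not carrier:
                return INCONSISTENT
            if m.affected == UNAFFECTED and carrier:
                incomplete = True
    return CONSISTENT_IP if incomplete else CONSISTENT


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def _encode_map(d: Dict[str, float]) -> str:
    return ";".join(f"{k}:{v!r}" for k, v in d.items()) if d else "."


def _decode_map(s) -> Dict[str, float]:
    if not isinstance(s, str) or s in (".", ""):
        return {}
    return {k: float(v) for k, v in (item.split(":") for item in s.split(";"))}


_COLUMNS = [
    "variant_id", "gene", "hgvs", "function_class", "genotype",
    "genotype_quality", "site_depth", "overall_mafs", "subpop_mafs",
    "mt_label", "mt_p_correct", "kgg_label", "kgg_p_disease",
    "known_mutation_id", "is_indel", "homopolymer_run", "multiallelic_pileup",
]


def write_annotated_tsv(variants: Sequence[AnnotatedVariant], path) -> None:
    rows = []
    for v in variants:
        rows.append({
            "variant_id": v.variant_id, "gene": v.gene, "hgvs": v.hgvs,
            "function_class": v.function_class, "genotype": v.genotype,
            "genotype_quality": v.genotype_quality, "site_depth": v.site_depth,
            "overall_mafs": _encode_map(v.overall_mafs),
            "subpop_mafs": _encode_map(v.subpop_mafs),
            "mt_label": v.predictor_mt[0],
            "mt_p_correct": "." if v.predictor_mt[1] is None else v.predictor_mt[1],
            "kgg_label": v.predictor_kgg[0],
            "kgg_p_disease": "." if v.predictor_kgg[1] is None else v.predictor_kgg[1],
            "known_mutation_id": v.known_mutation_id or ".",
            "is_indel": int(v.is_indel),
            "homopolymer_run": v.homopolymer_run,
            "multiallelic_pileup": int(v.multiallelic_pileup),
        })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotated_tsv(path) -> List[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for r in df.itertuples():
        out.append(AnnotatedVariant(
            variant_id=r.variant_id, gene=r.gene, hgvs=r.hgvs,
            function_class=r.function_class, genotype=r.genotype,
            genotype_quality=float(r.genotype_quality), site_depth=int(float(r.site_depth)),
            overall_mafs=_decode_map(r.overall_mafs),
            subpop_mafs=_decode_map(r.subpop_mafs),
            predictor_mt=(r.mt_label, None if r.mt_p_correct == "." else float(r.mt_p_correct)),
            predictor_kgg=(r.kgg_label, None if r.kgg_p_disease == "." else float(r.kgg_p_disease)),
            known_mutation_id=None if r.known_mutation_id == "." else r.known_mutation_id,
            is_indel=bool(int(r.is_indel)),
            homopolymer_run=int(r.homopolymer_run),
            multiallelic_pileup=bool(int(r.multiallelic_pileup)),
        ))
    return out


def report_table(report: ShortlistReport) -> pd.DataFrame:
    """Human-readable verdict-trail table, one row per variant x filter."""
    rows = []
    candidate_ids = [v.variant_id for v in report.candidates]
    for vid, trail in report.trails.items():
        for entry in trail:
            rows.append({
                "variant_id": vid,
                "filter": entry.filter_name,
                "verdict": entry.verdict,
                "reason": entry.reason,
                "final_candidate": vid in candidate_ids,
            })
    return pd.DataFrame(rows)
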