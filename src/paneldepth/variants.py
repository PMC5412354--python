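"""Variant records and left-normalization.

Two coordinate conventions coexist in the pipeline and are stated once here:
interval files (BED) are 0-based half-open, variant records (VCF) are 1-based
with the usual anchor-base convention for indels.  Every variant held in
memory is left-normalized: no shared trailing base between the alleles, and a
shared leading base only as the indel anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

VariantKey = Tuple[str, int, str, str]

GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GENOTYPES = (GT_HOM_REF, GT_HET, GT_HOM_ALT)


def variant_class(ref: str, alt: str) -> str:
    """'snp' iff both alleles are single bases, else 'indel'."""
    return "snp" if len(ref) == 1 and len(alt) == 1 else "indel"


@dataclass
class PlantedVariant:
    """A ground-truth variant, optionally with per-member genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for g in self.genotypes.values():
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype state {g!r}")

    @property
    def var_class(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantCall:
    """A called variant with genotype, Phred-scaled confidence and site depth."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # 'het' or 'hom_alt'
    qual: float
    site_depth: int

    def __post_init__(self) -> None:
        if self.genotype not in (GT_HET, GT_HOM_ALT):
            raise ValueError(f"called genotype must be het/hom_alt, got {self.genotype!r}")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")

    @property
    def var_class(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def left_normalize(seq: str, pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Left-normalize an allele pair against its chromosome sequence.

    ``seq`` is the full chromosome string, ``pos`` 1-based.  Implements the
    standard shift-left algorithm: drop shared trailing bases (extending left
    with the previous reference base when an allele would empty), then drop
    shared leading bases while both alleles keep at least one base beyond the
    anchor.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        if (len(ref) == 1 or len(alt) == 1) and pos == 1:
            break  # cannot left-extend past the sequence start; keep as-is
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            pos -= 1
            prev = seq[pos - 1].upper()
            ref, alt = prev + ref, prev + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def sort_variants(variants: Iterable) -> List:
    return sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


def split_by_class(variants: Iterable) -> Dict[str, list]:
    out: Dict[str, list] = {"snp": [], "indel": []}
    for v in variants:
        out[v.var_class].append(v)
    return out
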