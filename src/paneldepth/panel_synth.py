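"""Synthetic gene-panel world: reference, targets, variants, pedigree genotypes, reads.

This module fabricates everything a targeted-capture depth experiment needs,
with the statistical structure of a real hybridization-capture panel but no
real human sequence: a multi-gene exon panel (one chromosome per gene), a
planted truth set of SNPs and small indels, Mendelian genotype assignment
over a pedigree, and error-bearing paired-end reads whose per-interval depth
is gamma-dispersed to reproduce capture non-uniformity.

Read placements are exact by construction (the simulator knows where each
fragment came from), so downstream genotype calling needs no aligner.  Reads
that span a planted indel with at least ``INDEL_FLANK`` bases on each side
are rebuilt from the alternate haplotype and carry an explicit indel event;
shorter overlaps are left reference-built, emulating reads that a mapper
would soft-clip into uninformativeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._util import (
    BASES,
    CapacityError,
    ConsistencyError,
    InvalidParameterError,
    decode_seq,
    encode_seq,
)
from .pedigree import AFFECTED, UNAFFECTED, Pedigree, transmission_consistent
from .variants import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    PlantedVariant,
    VariantKey,
    left_normalize,
    sort_variants,
)

#: Minimum bases a read must have on each side of an indel to count as
#: spanning evidence (both in simulation and in the caller).
INDEL_FLANK = 10

#: Default names for the simulated panel genes.  The first 27 are the genes
#: of a published 27-gene Charcot-Marie-Tooth diagnostic capture design; a
#: larger panel falls back to numbered placeholders.
CMT_PANEL_GENES = [
    "KIF1B", "MFN2", "YARS", "LMNA", "MPZ", "RAB7A", "SH3TC2", "FIG4",
    "GARS", "HSPB1", "NEFL", "GDAP1", "NDRG1", "EGR2", "SBF2", "MTMR2",
    "FGD4", "TRPV4", "HSPB8", "LITAF", "AARS", "PMP22", "DNM2", "PRX",
    "MED25", "GJB1", "PRPS1",
]


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of 0-based half-open intervals, sorted and non-overlapping."""
    out: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class PanelRegion:
    """One gene's exons on its own chromosome, plus padded capture targets."""

    gene_name: str
    chromosome: str
    exons: List[Tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    pad_bp: int
    padded_intervals: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pad_bp < 0:
            raise InvalidParameterError("pad_bp must be >= 0")
        for s, e in self.exons:
            if e - s < 1:
                raise InvalidParameterError("every exon must be at least 1 bp")
        if self.exons != sorted(self.exons):
            raise InvalidParameterError("exons must be sorted")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise InvalidParameterError("exons must not overlap")
        if not self.padded_intervals:
            self.padded_intervals = merge_intervals(
                (max(0, s - self.pad_bp), e + self.pad_bp) for s, e in self.exons
            )

    @property
    def padded_length(self) -> int:
        return sum(e - s for s, e in self.padded_intervals)


def total_padded_length(regions: Sequence[PanelRegion]) -> int:
    return sum(r.padded_length for r in regions)


def build_panel(
    n_genes: int,
    exons_per_gene: int,
    exon_len: int,
    pad_bp: int,
    seed: int,
    exon_gap: int = 300,
    flank: int = 250,
) -> Tuple[List[PanelRegion], Dict[str, str]]:
    """Generate panel regions and a random reference, one chromosome per gene.

    ``exon_gap`` is the intron length between consecutive exons; when it is
    smaller than ``2 * pad_bp`` the padded exons merge into a single target
    interval.  ``flank`` is extra reference sequence outside the outermost
    pads so that read fragments never run off the chromosome.

    Returns ``(regions, reference)`` with the reference as chrom -> sequence.
    """
    if n_genes < 1 or exons_per_gene < 1:
        raise InvalidParameterError("n_genes and exons_per_gene must be >= 1")
    if exon_len < 10:
        raise InvalidParameterError("exon_len must be >= 10")
    if pad_bp < 0 or exon_gap < 0:
        raise InvalidParameterError("pad_bp and exon_gap must be >= 0")
    rng = np.random.default_rng(seed)
    regions: List[PanelRegion] = []
    reference: Dict[str, str] = {}
    for g in range(n_genes):
        gene = CMT_PANEL_GENES[g] if g < len(CMT_PANEL_GENES) else f"GENE{g + 1:03d}"
        chrom = f"panel_chr{g + 1}"
        exons = []
        start = flank + pad_bp
        for _ in range(exons_per_gene):
            exons.append((start, start + exon_len))
            start += exon_len + exon_gap
        chrom_len = exons[-1][1] + pad_bp + flank
        seq_codes = rng.integers(0, 4, size=chrom_len, dtype=np.uint8)
        reference[chrom] = decode_seq(seq_codes)
        regions.append(PanelRegion(gene, chrom, exons, pad_bp))
    return regions, reference


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

def plant_variants(
    regions: Sequence[PanelRegion],
    reference: Dict[str, str],
    n_snps: int,
    n_indels: int,
    indel_len_range: Tuple[int, int] = (1, 6),
    seed: int = 0,
    min_spacing: int = 150,
) -> List[PlantedVariant]:
    """Plant exact counts of SNPs and indels inside the padded targets.

    Variants are spaced at least ``min_spacing`` bases apart (farther than a
    read length, so no read straddles two variants), left-normalized, and
    returned sorted.  Raises :class:`CapacityError` when the requested counts
    do not fit.
    """
    if n_snps < 0 or n_indels < 0:
        raise InvalidParameterError("variant counts must be >= 0")
    lo, hi = indel_len_range
    if not (1 <= lo <= hi):
        raise InvalidParameterError("indel_len_range must satisfy 1 <= min <= max")
    rng = np.random.default_rng(seed)
    margin = hi + INDEL_FLANK + 2

    candidates: List[Tuple[str, int]] = []  # (chrom, pos0)
    for region in regions:
        for s, e in region.padded_intervals:
            for p in range(s + margin, e - margin):
                candidates.append((region.chromosome, p))
    if not candidates:
        raise CapacityError("no candidate positions inside padded targets")
    order = rng.permutation(len(candidates))

    taken: Dict[str, List[int]] = {}
    chosen: List[Tuple[str, int]] = []
    needed = n_snps + n_indels
    for idx in order:
        if len(chosen) == needed:
            break
        chrom, p = candidates[idx]
        near = taken.setdefault(chrom, [])
        if any(abs(p - q) < min_spacing for q in near):
            continue
        near.append(p)
        chosen.append((chrom, p))
    if len(chosen) < needed:
        raise CapacityError(
            f"only {len(chosen)} positions available for {needed} variants "
            f"at min_spacing={min_spacing}"
        )

    is_snp = np.zeros(needed, dtype=bool)
    is_snp[:n_snps] = True
    rng.shuffle(is_snp)

    variants: List[PlantedVariant] = []
    for (chrom, p0), snp in zip(chosen, is_snp):
        seq = reference[chrom]
        if snp:
            ref = seq[p0]
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            pos, ref, alt = p0 + 1, ref, alt
        else:
            length = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5:  # deletion
                ref = seq[p0 : p0 + 1 + length]
                alt = seq[p0]
            else:  # insertion
                ref = seq[p0]
                alt = ref + "".join(BASES[b] for b in rng.integers(0, 4, size=length))
            pos, ref, alt = left_normalize(seq, p0 + 1, ref, alt)
        variants.append(PlantedVariant(chrom, pos, ref, alt))
    variants = sort_variants(variants)
    keys = [v.key for v in variants]
    if len(set((k[0], k[1]) for k in keys)) != len(keys):
        # left-normalization collisions are possible in principle; re-plant
        return plant_variants(regions, reference, n_snps, n_indels,
                              indel_len_range, seed + 104729, min_spacing)
    return variants


# ---------------------------------------------------------------------------
# Pedigree genotype assignment
# ---------------------------------------------------------------------------

def _gene_drop(pedigree: Pedigree, rng: np.random.Generator, founder_maf: float) -> Dict[str, str]:
    """Draw founder genotypes at Hardy-Weinberg and transmit gametes down."""
    gts: Dict[str, int] = {}  # alt-allele count
    for m in pedigree.topological():
        if m.father_id is None and m.mother_id is None:
            gts[m.member_id] = int(rng.binomial(2, founder_maf))
        else:
            def gamete(pid: Optional[str]) -> int:
                if pid is None:
                    return int(rng.binomial(1, founder_maf))
                c = gts[pid]
                return int(rng.integers(0, 2)) if c == 1 else c // 2
            gts[m.member_id] = gamete(m.father_id) + gamete(m.mother_id)
    names = {0: GT_HOM_REF, 1: GT_HET, 2: GT_HOM_ALT}
    return {k: names[v] for k, v in gts.items()}


def _assign_causal(pedigree: Pedigree, rng: np.random.Generator,
                   carrier_parents: bool) -> Dict[str, str]:
    """Genotypes for the causal variant consistent with the disease model."""
    byid = pedigree.by_id
    model = pedigree.inheritance_model
    gts: Dict[str, str] = {}
    carrier_level = GT_HOM_ALT if model == "AR" else GT_HET

    for m in pedigree.members:
        if m.affected == AFFECTED:
            gts[m.member_id] = carrier_level

    # close carrier requirements upward
    changed = True
    while changed:
        changed = False
        for mid, gt in list(gts.items()):
            m = byid[mid]
            if gt == GT_HOM_ALT:
                need = [p for p in (m.father_id, m.mother_id) if p is not None]
                for pid in need:
                    if gts.get(pid, GT_HOM_REF) == GT_HOM_REF:
                        if byid[pid].affected == AFFECTED:
                            gts[pid] = carrier_level
                        elif carrier_parents or model == "AR":
                            gts[pid] = GT_HET
                        changed = True
            elif gt == GT_HET and m.father_id is not None and m.mother_id is not None:
                if all(gts.get(p, GT_HOM_REF) == GT_HOM_REF for p in (m.father_id, m.mother_id)):
                    pid = m.father_id if rng.random() < 0.5 else m.mother_id
                    if byid[pid].affected == UNAFFECTED and model == "AD" and pedigree.penetrance >= 1.0:
                        raise ConsistencyError(
                            f"affected {mid!r} needs a carrier parent but penetrance is 1"
                        )
                    gts[pid] = GT_HET
                    changed = True

    # unaffected member marked hom_alt under full penetrance is impossible
    for mid, gt in gts.items():
        m = byid[mid]
        if m.affected == UNAFFECTED:
            positive = gt == GT_HOM_ALT if model == "AR" else gt in (GT_HET, GT_HOM_ALT)
            if positive and pedigree.penetrance >= 1.0:
                raise ConsistencyError(
                    f"unaffected member {mid!r} would be genotype-positive with penetrance 1"
                )

    # fill the remaining members by rejection-sampled transmission
    for _ in range(1000):
        trial = dict(gts)
        for m in pedigree.topological():
            if m.member_id in trial:
                continue
            def gamete(pid: Optional[str]) -> int:
                if pid is None:
                    return 0
                g = trial.get(pid, GT_HOM_REF)
                if g == GT_HET:
                    return int(rng.integers(0, 2))
                return 1 if g == GT_HOM_ALT else 0
            c = gamete(m.father_id) + gamete(m.mother_id)
            trial[m.member_id] = (GT_HOM_REF, GT_HET, GT_HOM_ALT)[c]
        ok = True
        for m in pedigree.members:
            if m.affected != UNAFFECTED:
                continue
            g = trial[m.member_id]
            positive = g == GT_HOM_ALT if model == "AR" else g in (GT_HET, GT_HOM_ALT)
            if positive and rng.random() < pedigree.penetrance:
                ok = False
                break
        if ok and transmission_consistent(trial, pedigree):
            return trial
    raise ConsistencyError("could not assign Mendelian-consistent causal genotypes")


def assign_pedigree_genotypes(
    variants: Sequence[PlantedVariant],
    pedigree: Pedigree,
    causal_variant_key: Optional[VariantKey],
    carrier_parents: bool = True,
    seed: int = 0,
    founder_maf: float = 0.2,
) -> List[PlantedVariant]:
    """Assign per-member genotypes to every variant by Mendelian gene drop.

    The causal variant follows the pedigree's disease model (AR: affected
    members homozygous-alt, obligate-carrier parents heterozygous; AD:
    affected members carry the allele, with unaffected carriers allowed only
    under incomplete penetrance).  Every other variant is dropped through the
    pedigree from Hardy-Weinberg founders at ``founder_maf``.
    """
    rng = np.random.default_rng(seed)
    keys = [v.key for v in variants]
    if causal_variant_key is not None and causal_variant_key not in keys:
        raise InvalidParameterError(f"causal variant {causal_variant_key} not in variant list")
    out: List[PlantedVariant] = []
    for v in variants:
        if causal_variant_key is not None and v.key == causal_variant_key:
            gts = _assign_causal(pedigree, rng, carrier_parents)
        else:
            gts = _gene_drop(pedigree, rng, founder_maf)
        if not transmission_consistent(gts, pedigree):
            raise ConsistencyError(f"genotype assignment for {v.key} violates transmission")
        out.append(replace(v, genotypes=gts))
    return out


def assign_sample_genotypes(
    variants: Sequence[PlantedVariant],
    member_id: str,
    p_hom: float = 1.0 / 3.0,
    seed: int = 0,
) -> List[PlantedVariant]:
    """Assign het/hom_alt genotypes to a single sample (no pedigree).

    Every variant is carried (this is a truth set for that sample);
    ``p_hom`` controls the homozygous fraction.
    """
    rng = np.random.default_rng(seed)
    out = []
    for v in variants:
        g = GT_HOM_ALT if rng.random() < p_hom else GT_HET
        gts = dict(v.genotypes)
        gts[member_id] = g
        out.append(replace(v, genotypes=gts))
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Column-oriented container for simulated reads of one sample.

    ``seq`` holds base codes (0..3) row per read; ``indel_events`` maps a
    read's row index to the planted indel it carries as ``(pos1, ref, alt)``.
    Mates of a pair share ``pair_id`` and are stored consecutively.
    """

    chroms: List[str]
    read_len: int
    member_id: str
    chrom_idx: np.ndarray  # (n,) int32
    start: np.ndarray      # (n,) int32, 0-based
    seq: np.ndarray        # (n, read_len) uint8
    pair_id: np.ndarray    # (n,) int64
    mate: np.ndarray       # (n,) int8
    indel_events: Dict[int, Tuple[int, str, str]] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.start)

    @property
    def n_pairs(self) -> int:
        return 0 if self.n_reads == 0 else int(self.pair_id.max()) + 1

    def subset_pairs(self, keep: np.ndarray) -> "ReadSet":
        """New ReadSet restricted to pairs where ``keep[pair_id]`` is True."""
        mask = keep[self.pair_id]
        idx = np.flatnonzero(mask)
        remap = {int(old): new for new, old in enumerate(idx)}
        events = {remap[i]: ev for i, ev in self.indel_events.items() if i in remap}
        new_pid = np.unique(self.pair_id[idx], return_inverse=True)[1]
        return ReadSet(
            chroms=self.chroms,
            read_len=self.read_len,
            member_id=self.member_id,
            chrom_idx=self.chrom_idx[idx],
            start=self.start[idx],
            seq=self.seq[idx],
            pair_id=new_pid.astype(np.int64),
            mate=self.mate[idx],
            indel_events=events,
        )

    def read_id(self, i: int) -> str:
        return f"{self.member_id}:p{int(self.pair_id[i]):07d}"


def _rebuild_indel_read(ref_codes: np.ndarray, snp_overlay: Dict[int, int],
                        start: int, read_len: int,
                        p0: int, ref: str, alt: str) -> np.ndarray:
    """Build a read's bases from the alternate haplotype across one indel."""
    lead = p0 + 1 - start  # bases up to and including the anchor
    out = np.empty(read_len, dtype=np.uint8)
    out[:lead] = ref_codes[start : start + lead]
    if len(ref) > len(alt):  # deletion
        dlen = len(ref) - len(alt)
        tail_src = ref_codes[p0 + 1 + dlen : p0 + 1 + dlen + (read_len - lead)]
        out[lead : lead + len(tail_src)] = tail_src
    else:  # insertion
        ins = encode_seq(alt[1:])
        k = min(len(ins), read_len - lead)
        out[lead : lead + k] = ins[:k]
        rem = read_len - lead - k
        if rem > 0:
            out[lead + k :] = ref_codes[p0 + 1 : p0 + 1 + rem]
    for pos0, code in snp_overlay.items():
        off = pos0 - start
        if 0 <= off < lead:  # SNPs beyond the indel are ignored in rebuilt reads
            out[off] = code
    return out


def _expected_on_target_bases_per_pair(interval: Tuple[int, int], mask_cum: np.ndarray,
                                       read_len: int, fragment_mean: int,
                                       fragment_sd: int = 0) -> float:
    """Mean on-target bases contributed by one pair whose fragment center is
    uniform over the interval.  Fragment ends spill past short intervals, so
    this is below ``2 * read_len`` for short intervals (fragment ends spill
    off the target) but credits bases landing in *any* target interval of the
    chromosome, since padded exons sit close enough for reads to spill into a
    neighbour.  ``mask_cum`` is the cumulative sum of the chromosome's target
    indicator.  The fragment-length distribution is integrated by quadrature
    on a +-4 sd grid (lengths floored at two read lengths, as in the sampler).
    """
    from scipy import stats

    s, e = interval
    L = len(mask_cum) - 1
    c = np.arange(s, e)
    if fragment_sd > 0:
        grid = np.linspace(fragment_mean - 4 * fragment_sd,
                           fragment_mean + 4 * fragment_sd, 33)
        w = stats.norm.pdf(grid, fragment_mean, fragment_sd)
        w /= w.sum()
    else:
        grid, w = np.array([fragment_mean], float), np.array([1.0])
    total = 0.0
    for f, wf in zip(grid, w):
        fl = max(int(round(f)), 2 * read_len)
        for a in (-(fl // 2), fl - (fl // 2) - read_len):
            starts = np.clip(c + a, 0, max(L - read_len, 0))
            ovl = mask_cum[starts + read_len] - mask_cum[starts]
            total += wf * float(ovl.mean())
    return max(total, 1e-9)


def simulate_reads(
    reference: Dict[str, str],
    regions: Sequence[PanelRegion],
    mean_target_coverage: float,
    error_rate: float,
    member_id: str = "sample",
    capture_cv: float = 0.7,
    seed: int = 0,
    variants: Optional[Sequence[PlantedVariant]] = None,
    read_len: int = 100,
    fragment_mean: int = 300,
    fragment_sd: int = 30,
    homopolymer_slip_rate: float = 0.0,
) -> ReadSet:
    """Simulate genotype-aware paired-end reads over the padded targets.

    Per padded interval the depth is scaled by a gamma multiplier with
    coefficient of variation ``capture_cv`` (shape ``1/cv**2``), normalized so
    the panel-wide mean coverage stays at ``mean_target_coverage``.  Each
    fragment draws one haplotype; heterozygous variants sit on haplotype 1
    only, so alt alleles appear in half the fragments in expectation.
    Substitution errors are i.i.d. per sequenced base at ``error_rate``.

    ``homopolymer_slip_rate`` optionally emulates polymerase slippage: a read
    spanning the end of a base run of six or more bases has that probability
    of carrying a spurious single-base deletion event at the run's end — the
    error mode behind poly-A tract indel artifacts.  Off by default.
    """
    if mean_target_coverage <= 0:
        raise InvalidParameterError("mean_target_coverage must be > 0")
    if not 0.0 <= error_rate < 0.25:
        raise InvalidParameterError("error_rate must lie in [0, 0.25)")
    if capture_cv < 0:
        raise InvalidParameterError("capture_cv must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = [r.chromosome for r in regions]
    chrom_of = {c: i for i, c in enumerate(chroms)}
    ref_codes = {c: encode_seq(reference[c]) for c in chroms}

    ivals = [(r.chromosome, s, e) for r in regions for s, e in r.padded_intervals]
    lens = np.array([e - s for _, s, e in ivals], dtype=float)
    if capture_cv > 0:
        shape = 1.0 / capture_cv**2
        mult = rng.gamma(shape, 1.0 / shape, size=len(ivals))
    else:
        mult = np.ones(len(ivals))
    mult /= np.average(mult, weights=lens)  # pin the panel-wide mean

    # a variant with no genotype recorded for this member is not simulated
    genotypes: Dict[VariantKey, str] = {}
    if variants:
        for v in variants:
            genotypes[v.key] = v.genotypes.get(member_id, GT_HOM_REF)

    all_chrom, all_start, all_pair, all_mate = [], [], [], []
    pair_hap_parts = []
    pair_counter = 0
    mask_cum: Dict[str, np.ndarray] = {}
    for r in regions:
        L = len(ref_codes[r.chromosome])
        mask = np.zeros(L, dtype=np.int64)
        for s, e in r.padded_intervals:
            mask[s:e] = 1
        mask_cum[r.chromosome] = np.concatenate([[0], np.cumsum(mask)])

    for (chrom, s, e), m, ln in zip(ivals, mult, lens):
        eot = _expected_on_target_bases_per_pair(
            (s, e), mask_cum[chrom], read_len, fragment_mean, fragment_sd
        )
        lam = mean_target_coverage * m * ln / eot
        n_pairs = int(rng.poisson(lam))
        if n_pairs == 0:
            continue
        L = len(ref_codes[chrom])
        flen = np.clip(
            np.rint(rng.normal(fragment_mean, fragment_sd, size=n_pairs)).astype(int),
            2 * read_len, None,
        )
        center = rng.integers(s, e, size=n_pairs)
        fstart = np.clip(center - flen // 2, 0, None)
        fend = np.minimum(fstart + flen, L)
        fstart = np.minimum(fstart, fend - 2 * read_len).clip(0)
        r1 = fstart
        r2 = fend - read_len
        pid = np.arange(pair_counter, pair_counter + n_pairs)
        pair_counter += n_pairs
        ci = chrom_of[chrom]
        all_chrom.append(np.full(2 * n_pairs, ci, dtype=np.int32))
        all_start.append(np.stack([r1, r2], axis=1).ravel().astype(np.int32))
        all_pair.append(np.repeat(pid, 2).astype(np.int64))
        all_mate.append(np.tile(np.array([1, 2], dtype=np.int8), n_pairs))
        pair_hap_parts.append(rng.integers(0, 2, size=n_pairs, dtype=np.int8))

    if pair_counter == 0:
        return ReadSet(chroms, read_len, member_id,
                       np.empty(0, np.int32), np.empty(0, np.int32),
                       np.empty((0, read_len), np.uint8),
                       np.empty(0, np.int64), np.empty(0, np.int8))

    chrom_idx = np.concatenate(all_chrom)
    start = np.concatenate(all_start)
    pair_id = np.concatenate(all_pair)
    mate = np.concatenate(all_mate)
    pair_hap = np.concatenate(pair_hap_parts)

    # reference-built sequences
    n = len(start)
    seq = np.empty((n, read_len), dtype=np.uint8)
    offs = np.arange(read_len)
    for ci, chrom in enumerate(chroms):
        rows = np.flatnonzero(chrom_idx == ci)
        if len(rows):
            seq[rows] = ref_codes[chrom][start[rows, None] + offs]

    # overlay planted variants
    indel_events: Dict[int, Tuple[int, str, str]] = {}
    if variants:
        snp_overlay_by_chrom: Dict[int, Dict[int, int]] = {}
        for v in variants:
            g = genotypes[v.key]
            if g == GT_HOM_REF:
                continue
            ci = chrom_of[v.chrom]
            p0 = v.pos - 1
            rows = np.flatnonzero(
                (chrom_idx == ci) & (start <= p0) & (p0 < start + read_len)
            )
            if g == GT_HET:
                rows = rows[pair_hap[pair_id[rows]] == 1]
            if v.var_class == "snp":
                code = encode_seq(v.alt)[0]
                seq[rows, p0 - start[rows]] = code
                if g == GT_HOM_ALT:
                    snp_overlay_by_chrom.setdefault(ci, {})[p0] = int(code)
            else:
                span = rows[
                    (start[rows] + INDEL_FLANK <= p0)
                    & (start[rows] + read_len >= p0 + len(v.ref) + INDEL_FLANK)
                ]
                overlay = snp_overlay_by_chrom.get(ci, {})
                for i in span:
                    seq[i] = _rebuild_indel_read(
                        ref_codes[v.chrom], overlay, int(start[i]), read_len,
                        p0, v.ref, v.alt,
                    )
                    indel_events[int(i)] = (v.pos, v.ref, v.alt)

    # optional slippage: spurious 1-bp deletion evidence at long homopolymer runs
    if homopolymer_slip_rate > 0:
        for ci, chrom in enumerate(chroms):
            codes = ref_codes[chrom]
            change = np.flatnonzero(np.diff(codes)) + 1
            bounds = np.concatenate([[0], change, [len(codes)]])
            rows_c = np.flatnonzero(chrom_idx == ci)
            starts_c = start[rows_c]
            for rs, re_ in zip(bounds[:-1], bounds[1:]):
                if re_ - rs < 6 or rs < 1:
                    continue
                anchor0 = rs - 1  # left-normalized anchor before the run
                span = rows_c[(starts_c + INDEL_FLANK <= anchor0)
                              & (starts_c + read_len >= anchor0 + 2 + INDEL_FLANK)]
                if len(span) == 0:
                    continue
                hit = span[rng.random(len(span)) < homopolymer_slip_rate]
                ref_al = BASES[codes[anchor0]] + BASES[codes[rs]]
                alt_al = BASES[codes[anchor0]]
                for i in hit:
                    indel_events.setdefault(int(i), (anchor0 + 1, ref_al, alt_al))

    # i.i.d. substitution errors, applied last so they can corrupt alt bases
    if error_rate > 0:
        err = rng.random(seq.shape) < error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        seq[err] = (seq[err] + shift) % 4

    return ReadSet(chroms, read_len, member_id, chrom_idx, start, seq,
                   pair_id, mate, indel_events)


# ---------------------------------------------------------------------------
# Synthetic annotation tables
# ---------------------------------------------------------------------------

def simulate_annotated_variants(
    n_benign: int,
    pedigree: "Pedigree",
    seed: int = 0,
    causal_genotype: Optional[str] = None,
    gene_names: Optional[Sequence[str]] = None,
):
    """Emulate the annotated output of a frequency/predictor annotation stack.

    Returns ``(variants, causal_id)``: one planted causal variant (rare or
    database-absent, disease-model-compatible genotype, high Mendelian
    disease probability) among ``n_benign`` background variants whose
    frequencies, functional classes and predictor outputs follow the mixture
    a diagnostic panel typically sees (most background variants are common
    polymorphisms that the frequency filters remove).

    The predictor fields are *sampled*, not computed: the prediction
    algorithms themselves are upstream tools whose outputs this pipeline
    consumes as annotation columns.
    """
    from .prioritize import (
        KGG_BENIGN,
        KGG_DISEASE,
        KGG_NONE,
        MT_DISEASE,
        MT_POLY,
        AnnotatedVariant,
    )

    rng = np.random.default_rng(seed)
    genes = list(gene_names) if gene_names else CMT_PANEL_GENES
    model = pedigree.inheritance_model
    if causal_genotype is None:
        causal_genotype = GT_HOM_ALT if model == "AR" else GT_HET

    variants = []
    causal_p = float(rng.beta(12, 3))
    causal = AnnotatedVariant(
        variant_id="causal",
        gene=genes[int(rng.integers(len(genes)))],
        hgvs=f"c.{int(rng.integers(100, 3000))}G>A",
        function_class="nonsynonymous_snp",
        genotype=causal_genotype,
        genotype_quality=99.0,
        site_depth=int(rng.poisson(200)),
        overall_mafs={} if rng.random() < 0.7 else {"exac": 1e-4},
        subpop_mafs={},
        predictor_mt=(MT_DISEASE if rng.random() < 0.95 else MT_POLY, 0.999),
        predictor_kgg=(KGG_DISEASE if causal_p >= 0.5 else KGG_BENIGN, causal_p),
    )
    variants.append(causal)

    fn_classes = ["nonsynonymous_snp", "splice_site", "synonymous_snp", "utr_indel", "other"]
    fn_probs = [0.25, 0.05, 0.20, 0.15, 0.35]
    for i in range(n_benign):
        fc = fn_classes[int(rng.choice(len(fn_classes), p=fn_probs))]
        if rng.random() < 0.7:
            maf = float(rng.uniform(0.05, 0.5))  # common polymorphism
        else:
            maf = float(10 ** rng.uniform(-5, np.log10(0.05)))
        overall = {} if rng.random() < 0.1 else {"1kg": maf, "exac": maf * float(rng.uniform(0.7, 1.3))}
        subpop = {}
        if overall and rng.random() < 0.8:
            subpop = {"eas": min(1.0, maf * float(rng.uniform(1.0, 3.0)))}
        if fc == "nonsynonymous_snp":
            p = float(rng.beta(1, 12))
            kgg = (KGG_DISEASE if p >= 0.5 else KGG_BENIGN, p)
        else:
            kgg = (KGG_NONE, None)
        variants.append(AnnotatedVariant(
            variant_id=f"benign{i:03d}",
            gene=genes[int(rng.integers(len(genes)))],
            hgvs=f"c.{int(rng.integers(100, 3000))}{BASES[int(rng.integers(4))]}>"
                 f"{BASES[int(rng.integers(4))]}",
            function_class=fc,
            genotype=GT_HOM_ALT if rng.random() < 0.3 else GT_HET,
            genotype_quality=float(rng.choice([99.0, 99.0, 99.0, 15.0])),
            site_depth=max(1, int(rng.poisson(180))),
            overall_mafs=overall,
            subpop_mafs=subpop,
            predictor_mt=(MT_DISEASE if rng.random() < 0.1 else MT_POLY,
                          float(rng.random())),
            predictor_kgg=kgg,
            is_indel=fc == "utr_indel",
            homopolymer_run=int(rng.integers(6, 10)) if (fc == "utr_indel" and rng.random() < 0.3) else 0,
            multiallelic_pileup=bool(rng.random() < 0.2),
        ))
    return variants, "causal"


def annotate_calls(calls, regions: Sequence[PanelRegion], causal_key: Optional[VariantKey],
                   pedigree: "Pedigree", seed: int = 0):
    """Wrap a call set in synthetic annotations for the prioritization stage.

    The call matching ``causal_key`` receives the causal annotation profile;
    every other call receives a background profile.  Gene names come from the
    panel region containing each call.
    """
    from dataclasses import replace as dc_replace

    rng = np.random.default_rng(seed)
    gene_of = {}
    for r in regions:
        gene_of[r.chromosome] = r.gene_name
    synth, _ = simulate_annotated_variants(len(calls), pedigree, seed=seed)
    profiles = iter(synth[1:])
    causal_profile = synth[0]
    out = []
    for i, c in enumerate(calls):
        base = causal_profile if (causal_key is not None and c.key == causal_key) else next(profiles)
        out.append(dc_replace(
            base,
            variant_id=f"{c.chrom}:{c.pos}:{c.ref}>{c.alt}",
            gene=gene_of.get(c.chrom, base.gene),
            hgvs=f"c.{c.pos}{c.ref}>{c.alt}",
            genotype=c.genotype,
            genotype_quality=min(float(c.qual), 99.0),
            site_depth=int(c.site_depth),
            is_indel=c.var_class == "indel",
        ))
    return out
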