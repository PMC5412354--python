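"""Self-contained diploid genotype caller over simulated read placements.

The model is a deliberately explicit binomial mixture.  At a biallelic site
with per-base error rate *e*, a single read supports the alt allele with
probability e/3 under a hom-ref genotype, (1-e)/2 + e/6 under a het, and
1-e under a hom-alt.  The genotype posterior is the prior times the product
of per-read probabilities, and the emitted confidence is the Phred-scaled
posterior probability that the site is hom-ref::

    QUAL = -10 * log10 P(hom_ref | reads)

capped at ``qual_cap``.  A variant is reported only when its maximum-
posterior genotype is non-reference, QUAL reaches ``qual_threshold``
(default 50, the panel pipeline's calling cutoff), and the site lies inside
a padded target interval.

Indels are genotyped with the same three-genotype model: the alt count is
the number of reads carrying the indel event (reads must span the site with
``INDEL_FLANK`` bases each side to count), the ref count is the number of
spanning reads without it.  Multi-allelic pileups resolve to the
highest-count alt allele, ties broken lexicographically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from ._util import BASES, InvalidParameterError, encode_seq
from .panel_synth import INDEL_FLANK, PanelRegion, ReadSet
from .variants import GT_HET, GT_HOM_ALT, GT_HOM_REF, VariantCall, left_normalize

_GENOTYPES = (GT_HOM_REF, GT_HET, GT_HOM_ALT)


@dataclass
class CallerModel:
    """Error rate, genotype prior and emission thresholds for the caller."""

    error_rate: float = 0.01
    #: hom_ref / het / hom_alt prior; default reflects the ~1e-3 per-base
    #: heterozygosity a diploid caller conventionally assumes
    genotype_prior: Tuple[float, float, float] = (0.998, 0.001, 0.001)
    qual_threshold: float = 50.0
    qual_cap: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.25:
            raise InvalidParameterError("error_rate must lie in (0, 0.25)")
        if abs(sum(self.genotype_prior) - 1.0) > 1e-9 or min(self.genotype_prior) < 0:
            raise InvalidParameterError("genotype_prior must be a probability 3-vector")

    def read_log10_probs(self) -> Tuple[np.ndarray, np.ndarray]:
        """(log10 P(ref-read | g), log10 P(alt-read | g)) for g in the 3 genotypes."""
        e = self.error_rate
        p_alt = np.array([e / 3, (1 - e) / 2 + e / 6, 1 - e])
        p_ref = p_alt[::-1].copy()
        return np.log10(p_ref), np.log10(p_alt)


@dataclass
class PileupColumn:
    """Counts of read support at one site (SNP base counts and indel alleles)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    base_counts: Dict[str, int] = field(default_factory=dict)
    indel_counts: Dict[Tuple[str, str], int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


def genotype_from_counts(n_ref, n_alt, model: CallerModel):
    """Vectorized genotype posterior and Phred confidence from allele counts.

    Accepts scalars or equal-length arrays; returns ``(posterior, qual)``
    where ``posterior`` has shape (..., 3) ordered hom_ref/het/hom_alt.
    """
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    lref, lalt = model.read_log10_probs()
    log10_lik = n_ref[..., None] * lref + n_alt[..., None] * lalt
    log10_post = log10_lik + np.log10(model.genotype_prior)
    m = log10_post.max(axis=-1, keepdims=True)
    log10_norm = m + np.log10(np.sum(10.0 ** (log10_post - m), axis=-1, keepdims=True))
    log10_post = log10_post - log10_norm
    post = 10.0 ** log10_post
    qual = np.minimum(-10.0 * log10_post[..., 0], model.qual_cap)
    return post, qual


def genotype_site(column: PileupColumn, model: CallerModel):
    """Genotype one pileup column; returns ``(posterior 3-vector, qual)``.

    Returns ``None`` (no-call) at zero depth.  SNP evidence reduces to the
    reference base count versus the highest non-reference base count.
    """
    if column.depth == 0 and not column.indel_counts:
        return None
    if column.indel_counts:
        (ref, alt), n_alt = max(column.indel_counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0][1]]))
        n_ref = max(column.depth - sum(column.indel_counts.values()), 0)
    else:
        n_ref = column.base_counts.get(column.ref, 0)
        others = {b: c for b, c in column.base_counts.items() if b != column.ref}
        alt = min((b for b, c in others.items() if c == max(others.values())), default=None) if others else None
        n_alt = others.get(alt, 0) if alt else 0
    post, qual = genotype_from_counts(float(n_ref), float(n_alt), model)
    return post, float(qual)


# ---------------------------------------------------------------------------
# Array pileup over the panel
# ---------------------------------------------------------------------------

class _Pileup:
    """Per-chromosome base-count matrices plus sparse indel evidence."""

    def __init__(self, base_counts, depth, indel_counts, span_starts, read_len):
        self.base_counts = base_counts      # chrom -> (4, L) int32
        self.depth = depth                  # chrom -> (L,) int32
        self.indel_counts = indel_counts    # (chrom, pos1, ref, alt) -> count
        self.span_starts = span_starts      # chrom -> sorted starts of all reads
        self.read_len = read_len

    def spanning_depth(self, chrom: str, pos1: int, ref_len: int) -> int:
        starts = self.span_starts[chrom]
        p0 = pos1 - 1
        lo = p0 + ref_len + INDEL_FLANK - self.read_len  # min start
        hi = p0 - INDEL_FLANK                            # max start
        if hi < lo:
            return 0
        return int(np.searchsorted(starts, hi, side="right") - np.searchsorted(starts, lo, side="left"))


def _array_pileup(reads: ReadSet, reference: Dict[str, str],
                  regions: Sequence[PanelRegion]) -> _Pileup:
    chrom_names = {r.chromosome for r in regions}
    base_counts: Dict[str, np.ndarray] = {}
    depth: Dict[str, np.ndarray] = {}
    span_starts: Dict[str, np.ndarray] = {}
    rl = reads.read_len
    offs = np.arange(rl)

    event_rows = np.array(sorted(reads.indel_events), dtype=int)
    plain = np.ones(reads.n_reads, dtype=bool)
    if len(event_rows):
        plain[event_rows] = False

    for ci, chrom in enumerate(reads.chroms):
        if chrom not in chrom_names:
            continue
        L = len(reference[chrom])
        counts = np.zeros((4, L), dtype=np.int32)
        rows = np.flatnonzero((reads.chrom_idx == ci) & plain)
        if len(rows):
            starts = reads.start[rows]
            if (starts + rl > L).any() or (starts < 0).any():
                raise InvalidParameterError(f"read extends beyond reference end on {chrom}")
            idx = (starts[:, None] + offs).ravel().astype(np.int64)
            codes = reads.seq[rows].ravel().astype(np.int64)
            flat = np.bincount(idx * 4 + codes, minlength=4 * L)
            counts += flat.reshape(L, 4).T.astype(np.int32)
        base_counts[chrom] = counts
        depth[chrom] = counts.sum(axis=0).astype(np.int32)
        span_starts[chrom] = np.sort(reads.start[reads.chrom_idx == ci])

    # indel-bearing reads: walk their reference segments explicitly
    indel_counts: Counter = Counter()
    for i in event_rows:
        ci = int(reads.chrom_idx[i])
        chrom = reads.chroms[ci]
        if chrom not in base_counts:
            continue
        pos1, ref, alt = reads.indel_events[int(i)]
        p0 = pos1 - 1
        start = int(reads.start[i])
        seq = reads.seq[i]
        counts = base_counts[chrom]
        lead = p0 + 1 - start
        np.add.at(counts, (seq[:lead], np.arange(start, start + lead)), 1)
        if len(ref) > len(alt):  # deletion: tail maps downstream of the gap
            tail_ref = np.arange(p0 + 1 + (len(ref) - len(alt)), p0 + 1 + (len(ref) - len(alt)) + rl - lead)
            keep = tail_ref < len(reference[chrom])
            np.add.at(counts, (seq[lead:][keep], tail_ref[keep]), 1)
        else:  # insertion: inserted bases map nowhere
            ilen = len(alt) - len(ref)
            tail = seq[lead + ilen :]
            tail_ref = np.arange(p0 + 1, p0 + 1 + len(tail))
            keep = tail_ref < len(reference[chrom])
            np.add.at(counts, (tail[keep], tail_ref[keep]), 1)
        depth[chrom] = base_counts[chrom].sum(axis=0).astype(np.int32)
        indel_counts[(chrom, pos1, ref, alt)] += 1

    for chrom in base_counts:
        depth[chrom] = base_counts[chrom].sum(axis=0).astype(np.int32)
    return _Pileup(base_counts, depth, indel_counts, span_starts, rl)


def _target_positions(regions: Sequence[PanelRegion]) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    for r in regions:
        pos = np.concatenate([np.arange(s, e) for s, e in r.padded_intervals]) if r.padded_intervals else np.empty(0, int)
        out[r.chromosome] = np.union1d(out.get(r.chromosome, np.empty(0, int)), pos)
    return out


def _in_target(regions_by_chrom: Dict[str, List[Tuple[int, int]]], chrom: str, p0: int) -> bool:
    return any(s <= p0 < e for s, e in regions_by_chrom.get(chrom, []))


def build_pileup(reads: ReadSet, reference: Dict[str, str],
                 regions: Sequence[PanelRegion]) -> Iterator[PileupColumn]:
    """Yield pileup columns for every padded-target position with coverage."""
    pile = _array_pileup(reads, reference, regions)
    targets = _target_positions(regions)
    indels_at: Dict[Tuple[str, int], Dict[Tuple[str, str], int]] = {}
    for (chrom, pos1, ref, alt), n in pile.indel_counts.items():
        indels_at.setdefault((chrom, pos1), {})[(ref, alt)] = n
    for chrom, positions in targets.items():
        if chrom not in pile.base_counts:
            continue
        counts = pile.base_counts[chrom]
        for p0 in positions:
            col_counts = {BASES[b]: int(counts[b, p0]) for b in range(4) if counts[b, p0] > 0}
            ind = indels_at.get((chrom, p0 + 1), {})
            if col_counts or ind:
                yield PileupColumn(chrom, int(p0) + 1, reference[chrom][p0],
                                   col_counts, dict(ind))


def call_variants(reads: ReadSet, reference: Dict[str, str],
                  regions: Sequence[PanelRegion],
                  model: Optional[CallerModel] = None) -> List[VariantCall]:
    """Call SNPs and indels over the padded targets; sorted, QUAL-thresholded."""
    model = model or CallerModel()
    pile = _array_pileup(reads, reference, regions)
    targets = _target_positions(regions)
    target_ivals = {c: [] for c in {r.chromosome for r in regions}}
    for r in regions:
        target_ivals[r.chromosome].extend(r.padded_intervals)
    calls: List[VariantCall] = []

    # SNPs: vectorized over all target positions of each chromosome
    for chrom, positions in targets.items():
        if chrom not in pile.base_counts or len(positions) == 0:
            continue
        counts = pile.base_counts[chrom][:, positions]  # (4, P)
        ref_codes = encode_seq(reference[chrom])[positions]
        n_ref = counts[ref_codes, np.arange(counts.shape[1])]
        masked = counts.copy()
        masked[ref_codes, np.arange(counts.shape[1])] = -1
        alt_codes = masked.argmax(axis=0)  # first (lexicographic) max among non-ref
        n_alt = masked[alt_codes, np.arange(counts.shape[1])]
        cand = np.flatnonzero(n_alt > 0)
        if len(cand) == 0:
            continue
        post, qual = genotype_from_counts(n_ref[cand], n_alt[cand], model)
        gidx = post.argmax(axis=-1)
        emit = (gidx != 0) & (qual >= model.qual_threshold)
        depths = pile.depth[chrom][positions]
        for j in np.flatnonzero(emit):
            p = cand[j]
            calls.append(VariantCall(
                chrom, int(positions[p]) + 1,
                BASES[ref_codes[p]], BASES[alt_codes[p]],
                _GENOTYPES[gidx[j]], float(qual[j]), int(depths[p]),
            ))

    # indels: one candidate site per observed (chrom, pos)
    by_site: Dict[Tuple[str, int], Dict[Tuple[str, str], int]] = {}
    for (chrom, pos1, ref, alt), n in pile.indel_counts.items():
        by_site.setdefault((chrom, pos1), {})[(ref, alt)] = n
    for (chrom, pos1), alleles in by_site.items():
        if not _in_target(target_ivals, chrom, pos1 - 1):
            continue
        (ref, alt), n_alt = max(alleles.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0][1]]))
        n_span = pile.spanning_depth(chrom, pos1, len(ref))
        n_ref = max(n_span - sum(alleles.values()), 0)
        post, qual = genotype_from_counts(float(n_ref), float(n_alt), model)
        gidx = int(post.argmax())
        if gidx != 0 and qual >= model.qual_threshold:
            npos, nref, nalt = left_normalize(reference[chrom], pos1, ref, alt)
            if _in_target(target_ivals, chrom, npos - 1):
                calls.append(VariantCall(chrom, npos, nref, nalt,
                                         _GENOTYPES[gidx], float(qual), int(n_span)))

    calls.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return calls
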