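"""Standard-format readers and writers (FASTA, BED, VCF, FASTQ, read table).

FASTA goes through Biopython, VCF through pysam; BED and the internal read
table are plain TSVs handled with pandas.  The internal read table is the
lossless on-disk form of a :class:`~paneldepth.panel_synth.ReadSet` — unlike
FASTQ it retains true placements and indel events, so the caller can consume
it without an aligner.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import decode_seq, encode_seq
from .panel_synth import PanelRegion, ReadSet
from .variants import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    PlantedVariant,
    VariantCall,
    sort_variants,
)

_GT_CODE = {GT_HOM_REF: (0, 0), GT_HET: (0, 1), GT_HOM_ALT: (1, 1)}
_CODE_GT = {v: k for k, v in _GT_CODE.items()}


# -- FASTA / BED -------------------------------------------------------------

def write_fasta(reference: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(regions: Sequence[PanelRegion], path) -> None:
    """Write the padded target intervals as 4-column BED (0-based half-open)."""
    rows = [
        (r.chromosome, s, e, r.gene_name)
        for r in regions
        for s, e in r.padded_intervals
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path) -> List[Tuple[str, int, int, str]]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str, "start": int, "end": int, "name": str})
    return list(df.itertuples(index=False, name=None))


# -- VCF ---------------------------------------------------------------------

def _vcf_header(reference_lengths: Dict[str, int], samples: Sequence[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for chrom, length in reference_lengths.items():
        h.add_line(f"##contig=<ID={chrom},length={length}>")
    h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    h.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">')
    for s in samples:
        h.add_sample(s)
    return h


def write_truth_vcf(variants: Sequence[PlantedVariant], reference: Dict[str, str],
                    path, members: Optional[Sequence[str]] = None) -> None:
    """Write a sorted truth VCF; per-member genotypes become sample columns."""
    if members is None:
        members = sorted({m for v in variants for m in v.genotypes})
    lengths = {c: len(s) for c, s in reference.items()}
    header = _vcf_header(lengths, members)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sort_variants(variants):
            rec = vf.new_record(contig=v.chrom, start=v.pos - 1,
                                alleles=(v.ref, v.alt), qual=None)
            for m in members:
                rec.samples[m]["GT"] = _GT_CODE[v.genotypes.get(m, GT_HOM_REF)]
            vf.write(rec)


def read_truth_vcf(path) -> List[PlantedVariant]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            gts = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is not None and None not in gt:
                    gts[s] = _CODE_GT[tuple(sorted(gt))]
            out.append(PlantedVariant(rec.contig, rec.pos, rec.ref, rec.alts[0], gts))
    return out


def write_calls_vcf(calls: Sequence[VariantCall], reference: Dict[str, str],
                    path, sample: str = "SAMPLE") -> None:
    lengths = {c: len(s) for c, s in reference.items()}
    header = _vcf_header(lengths, [sample])
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for c in sort_variants(calls):
            rec = vf.new_record(contig=c.chrom, start=c.pos - 1,
                                alleles=(c.ref, c.alt), qual=round(c.qual, 2))
            rec.samples[sample]["GT"] = _GT_CODE[c.genotype]
            rec.samples[sample]["DP"] = int(c.site_depth)
            vf.write(rec)


def read_calls_vcf(path) -> List[VariantCall]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            s = rec.samples[samples[0]]
            gt = _CODE_GT[tuple(sorted(s["GT"]))]
            out.append(VariantCall(rec.contig, rec.pos, rec.ref, rec.alts[0],
                                   gt, float(rec.qual or 0.0), int(s.get("DP") or 0)))
    return out


# -- reads -------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def write_fastq_pair(reads: ReadSet, path_r1, path_r2, qual_char: str = "I") -> None:
    """Write the pair as Phred+33 FASTQ; mate 2 is reverse-complemented."""
    quals = qual_char * reads.read_len
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for i in range(reads.n_reads):
            seq = decode_seq(reads.seq[i])
            rid = reads.read_id(i)
            if reads.mate[i] == 1:
                f1.write(f"@{rid}/1\n{seq}\n+\n{quals}\n")
            else:
                rc = seq.translate(_COMP)[::-1]
                f2.write(f"@{rid}/2\n{rc}\n+\n{quals}\n")


def write_read_table(reads: ReadSet, path) -> None:
    rows = {
        "read_id": [reads.read_id(i) for i in range(reads.n_reads)],
        "mate": reads.mate,
        "chrom": [reads.chroms[c] for c in reads.chrom_idx],
        "start": reads.start,
        "seq": [decode_seq(s) for s in reads.seq],
        "indel": [
            (f"{ev[0]}:{ev[1]}:{ev[2]}" if (ev := reads.indel_events.get(i)) else ".")
            for i in range(reads.n_reads)
        ],
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_read_table(path, member_id: str = "sample") -> ReadSet:
    df = pd.read_csv(path, sep="\t", dtype={"indel": str})
    chroms = list(dict.fromkeys(df["chrom"]))
    chrom_of = {c: i for i, c in enumerate(chroms)}
    read_len = len(df["seq"].iloc[0]) if len(df) else 100
    pair_names = df["read_id"].to_numpy()
    _, pair_id = np.unique(pair_names, return_inverse=True)
    # preserve file order of pairs
    order_first = pd.Series(range(len(df))).groupby(pair_id).min()
    rank = order_first.rank(method="first").astype(int) - 1
    pair_id = rank.to_numpy()[pair_id]
    seq = np.stack([encode_seq(s) for s in df["seq"]]) if len(df) else np.empty((0, read_len), np.uint8)
    events = {}
    for i, token in enumerate(df["indel"]):
        if isinstance(token, str) and token != ".":
            pos, ref, alt = token.split(":")
            events[i] = (int(pos), ref, alt)
    return ReadSet(
        chroms=chroms,
        read_len=read_len,
        member_id=member_id,
        chrom_idx=np.array([chrom_of[c] for c in df["chrom"]], dtype=np.int32),
        start=df["start"].to_numpy(dtype=np.int32),
        seq=seq,
        pair_id=pair_id.astype(np.int64),
        mate=df["mate"].to_numpy(dtype=np.int8),
        indel_events=events,
    )


def regions_from_bed(path) -> List[PanelRegion]:
    """Reconstruct panel regions from a BED of padded targets (pad already applied)."""
    by_gene: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for chrom, start, end, name in read_bed(path):
        by_gene.setdefault((name, chrom), []).append((start, end))
    return [
        PanelRegion(gene, chrom, sorted(ivs), pad_bp=0)
        for (gene, chrom), ivs in by_gene.items()
    ]
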