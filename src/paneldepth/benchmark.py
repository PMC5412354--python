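"""Recall/precision scoring of a call set against an independent truth set.

Matching is exact on (chromosome, position, ref, alt) after both sets are
left-normalized — no distance-window matching.  Genotype concordance is
additionally required only when ``require_genotype`` is set (the validation
mode); recall-style depth experiments match on site and alleles alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import pandas as pd

from ._util import round_half_up
from .variants import VariantCall

CLASSES = ("snp", "indel")


@dataclass
class BenchmarkResult:
    variant_class: str
    true_positives: int
    false_negatives: int
    false_positives: int
    recall: Optional[float]     # percent, 2 decimals; None when truth empty
    precision: Optional[float]  # percent, 2 decimals; None when no calls


def _keyset(variants, var_class: str, with_genotype: bool):
    if with_genotype:
        return {v.key + (_genotype_of(v),) for v in variants if v.var_class == var_class}
    return {v.key for v in variants if v.var_class == var_class}


def _genotype_of(v) -> str:
    if isinstance(v, VariantCall):
        return v.genotype
    gts = set(v.genotypes.values()) - {"hom_ref"}
    return gts.pop() if len(gts) == 1 else "het"


def match_and_score(calls: Sequence[VariantCall], truth: Sequence,
                    require_genotype: bool = False) -> Dict[str, BenchmarkResult]:
    """Score per variant class; returns {'snp': ..., 'indel': ...}."""
    def sorted_ok(vs):
        keys = [v.key for v in vs]
        return keys == sorted(keys)

    if not sorted_ok(calls) or not sorted_ok(truth):
        warnings.warn("inputs were not sorted; sorting before matching", stacklevel=2)
    out: Dict[str, BenchmarkResult] = {}
    for cls in CLASSES:
        t = _keyset(truth, cls, require_genotype)
        c = _keyset(calls, cls, require_genotype)
        tp = len(t & c)
        fn = len(t - c)
        fp = len(c - t)
        recall = round_half_up(100.0 * tp / (tp + fn), 2) if (tp + fn) else None
        precision = round_half_up(100.0 * tp / (tp + fp), 2) if (tp + fp) else None
        out[cls] = BenchmarkResult(cls, tp, fn, fp, recall, precision)
    return out


def results_table(results: Dict[str, BenchmarkResult]) -> pd.DataFrame:
    rows = [{
        "variant_class": r.variant_class,
        "true_positives": r.true_positives,
        "false_negatives": r.false_negatives,
        "false_positives": r.false_positives,
        "recall_pct": r.recall,
        "precision_pct": r.precision,
    } for r in results.values()]
    return pd.DataFrame(rows)
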