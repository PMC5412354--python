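"""Down-sampling rarefaction: recall vs depth, C95 brackets, coverage metrics.

The experiment mirrors the clinical-panel depth titration: call variants on
the full read set once (the pseudo-truth), then repeatedly thin the reads
over a descending fraction grid (default 1.00 -> 0.05 in steps of 0.05, 10
replicates per fraction), re-call, and count how many pseudo-truth variants
of each class are recovered.  The coverage at which the mean recall curve
crosses 95% is reported as a bracket of two adjacent grid coverages
(C_snp95 / C_indel95).

Recall at fraction 1.0 is 100% by construction — the pseudo-truth set is the
full-coverage call set, a bias the reporting deliberately keeps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._util import InvalidParameterError, round_half_up, round_half_up_int
from .panel_synth import PanelRegion, ReadSet
from .pileup_caller import CallerModel, call_variants
from .variants import VariantCall, VariantKey

logger = logging.getLogger(__name__)

CLASSES = ("snp", "indel")


def default_fractions(max_fraction: float = 1.0, min_fraction: float = 0.05,
                      step: float = 0.05) -> List[float]:
    n = int(round((max_fraction - min_fraction) / step)) + 1
    return [round(max_fraction - i * step, 10) for i in range(n)]


@dataclass
class GridConfig:
    fractions: List[float] = field(default_factory=default_fractions)
    replicates_per_fraction: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        fr = self.fractions
        if not fr or any(not 0 < f <= 1 for f in fr):
            raise InvalidParameterError("fractions must lie in (0, 1]")
        if any(b >= a for a, b in zip(fr, fr[1:])):
            raise InvalidParameterError("fractions must be strictly descending")
        if self.replicates_per_fraction < 1:
            raise InvalidParameterError("replicates_per_fraction must be >= 1")


@dataclass
class RarefactionPoint:
    fraction: float
    effective_coverage: float  # fraction x mean target coverage, 1 decimal
    replicate_counts: List[int]
    mean_count: float
    sd_count: float
    mean_recall_pct: float


@dataclass
class C95Bracket:
    variant_class: str
    lower_coverage: Optional[int]
    upper_coverage: Optional[int]
    crossed: bool


@dataclass
class CoverageMetrics:
    mean_target_coverage: float
    pct_ge_2x: float
    pct_ge_10x: float
    pct_ge_50x: float


@dataclass
class RarefactionResult:
    """Grid output: per-class points plus per-replicate call details."""

    points: Dict[str, List[RarefactionPoint]]
    pseudo_truth: Dict[str, List[VariantCall]]
    mean_target_coverage: float
    grid: GridConfig
    # fraction -> list over replicates of (called key set, key -> site_depth)
    replicate_calls: Dict[float, List[Tuple[set, Dict[VariantKey, int]]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------

def subsample_reads(reads: ReadSet, fraction: float, seed: int) -> ReadSet:
    """Thin reads pair-wise: each pair kept independently with prob = fraction."""
    if not 0 < fraction <= 1:
        raise InvalidParameterError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return reads
    rng = np.random.default_rng(seed)
    keep = rng.random(reads.n_pairs) < fraction
    return reads.subset_pairs(keep)


def effective_coverage(fraction: float, mean_target_coverage: float) -> float:
    """fraction x mean coverage, printed to 1 decimal (ties away from zero)."""
    if fraction <= 0 or mean_target_coverage <= 0:
        raise InvalidParameterError("fraction and coverage must be positive")
    return round_half_up(fraction * mean_target_coverage, 1)


def c95_bound(fraction: float, mean_target_coverage: float) -> int:
    """Integer-rounded effective coverage used for C95 bracket endpoints."""
    return round_half_up_int(fraction * mean_target_coverage)


def recall_percent(recovered: float, truth_total: int) -> float:
    """Recall as a percentage to 1 decimal, e.g. 115.0 of 162 -> 71.0."""
    if truth_total <= 0:
        raise InvalidParameterError("truth total must be positive")
    return round_half_up(100.0 * recovered / truth_total, 1)


def compute_recall(calls: Sequence[VariantCall], pseudo_truth: Sequence,
                   var_class: str) -> Tuple[int, float]:
    """(count recovered, recall proportion) for one variant class.

    Matching is on (chromosome, position, ref, alt); genotype is ignored.
    Raises when the pseudo-truth holds no variant of the class (undefined
    recall).
    """
    truth_keys = {v.key for v in pseudo_truth if v.var_class == var_class}
    if not truth_keys:
        raise InvalidParameterError(f"pseudo-truth contains no {var_class} variants")
    call_keys = {c.key for c in calls if c.var_class == var_class}
    recovered = len(truth_keys & call_keys)
    return recovered, recovered / len(truth_keys)


def coverage_metrics(reads: ReadSet, regions: Sequence[PanelRegion]) -> CoverageMetrics:
    """Mean on-target depth and the fraction of target bases at 2x/10x/50x."""
    lengths: Dict[str, int] = {}
    for ci, chrom in enumerate(reads.chroms):
        ends = reads.start[reads.chrom_idx == ci] + reads.read_len
        lengths[chrom] = int(ends.max()) if len(ends) else 0
    target_depths: List[np.ndarray] = []
    for r in regions:
        chrom = r.chromosome
        L = max(lengths.get(chrom, 0), max((e for _, e in r.padded_intervals), default=0))
        if L == 0:
            continue
        diff = np.zeros(L + 1, dtype=np.int64)
        ci = reads.chroms.index(chrom) if chrom in reads.chroms else None
        if ci is not None:
            rows = reads.chrom_idx == ci
            starts = reads.start[rows]
            np.add.at(diff, starts, 1)
            np.add.at(diff, np.minimum(starts + reads.read_len, L), -1)
        depth = np.cumsum(diff[:-1])
        for s, e in r.padded_intervals:
            target_depths.append(depth[s:e])
    if not target_depths:
        raise InvalidParameterError("empty target: no padded intervals")
    d = np.concatenate(target_depths)
    return CoverageMetrics(
        mean_target_coverage=round_half_up(float(d.mean()), 1),
        pct_ge_2x=round_half_up(100.0 * float((d >= 2).mean()), 2),
        pct_ge_10x=round_half_up(100.0 * float((d >= 10).mean()), 2),
        pct_ge_50x=round_half_up(100.0 * float((d >= 50).mean()), 2),
    )


# ---------------------------------------------------------------------------

def run_grid(reads: ReadSet, model: CallerModel, regions: Sequence[PanelRegion],
             reference: Dict[str, str], grid: Optional[GridConfig] = None,
             mean_target_coverage: Optional[float] = None) -> RarefactionResult:
    """Run the full down-sampling grid against the full-coverage pseudo-truth.

    Replicate ``r`` uses seed ``base_seed + r`` at every fraction, which
    couples the thinnings into nested subsets across the grid and makes every
    replicate count exactly reproducible.
    """
    grid = grid or GridConfig()
    if mean_target_coverage is None:
        mean_target_coverage = coverage_metrics(reads, regions).mean_target_coverage
    full_calls = call_variants(reads, reference, regions, model)
    pseudo_truth = {
        cls: [c for c in full_calls if c.var_class == cls] for cls in CLASSES
    }
    if not full_calls:
        raise InvalidParameterError("full-coverage call set is empty")
    truth_keys = {cls: {c.key for c in pseudo_truth[cls]} for cls in CLASSES}

    points: Dict[str, List[RarefactionPoint]] = {cls: [] for cls in CLASSES}
    replicate_calls: Dict[float, List[Tuple[set, Dict[VariantKey, int]]]] = {}
    for fraction in grid.fractions:
        counts = {cls: [] for cls in CLASSES}
        reps: List[Tuple[set, Dict[VariantKey, int]]] = []
        for r in range(grid.replicates_per_fraction):
            sub = subsample_reads(reads, fraction, grid.base_seed + r)
            calls = call_variants(sub, reference, regions, model)
            keys = {c.key for c in calls}
            depths = {c.key: c.site_depth for c in calls}
            reps.append((keys, depths))
            for cls in CLASSES:
                counts[cls].append(len(truth_keys[cls] & keys))
        replicate_calls[fraction] = reps
        for cls in CLASSES:
            arr = np.array(counts[cls], dtype=float)
            n_truth = len(truth_keys[cls])
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            points[cls].append(RarefactionPoint(
                fraction=fraction,
                effective_coverage=effective_coverage(fraction, mean_target_coverage),
                replicate_counts=[int(c) for c in counts[cls]],
                mean_count=round_half_up(float(arr.mean()), 1),
                sd_count=round_half_up(sd, 1),
                mean_recall_pct=recall_percent(float(arr.mean()), n_truth) if n_truth else float("nan"),
            ))
        logger.info("fraction %.2f: mean SNP count %.1f, mean indel count %.1f",
                    fraction,
                    points["snp"][-1].mean_count if truth_keys["snp"] else float("nan"),
                    points["indel"][-1].mean_count if truth_keys["indel"] else float("nan"))
    return RarefactionResult(points, pseudo_truth, mean_target_coverage, grid,
                             replicate_calls)


def estimate_c95(points: Sequence[RarefactionPoint], mean_target_coverage: float,
                 variant_class: str = "snp", threshold_pct: float = 95.0) -> C95Bracket:
    """Bracket the coverage at which mean recall crosses ``threshold_pct``.

    Points must be in descending-fraction order.  The bracket's endpoints are
    the integer-rounded effective coverages of the two adjacent grid points
    around the crossing; with multiple crossings (non-monotone noise) the
    highest-coverage crossing wins and a warning is logged.
    """
    fr = [p.fraction for p in points]
    if fr != sorted(fr, reverse=True):
        raise InvalidParameterError("points must be in descending fraction order")
    above = [p.mean_recall_pct >= threshold_pct for p in points]
    crossings = [
        i for i in range(len(points) - 1) if above[i] and not above[i + 1]
    ]
    if len(crossings) > 1:
        warnings.warn("recall curve crosses the threshold more than once; "
                      "using the highest-coverage crossing", stacklevel=2)
        logger.warning("multiple 95%% crossings for %s; using highest", variant_class)
    if crossings:
        i = crossings[0]
        return C95Bracket(
            variant_class,
            lower_coverage=c95_bound(points[i + 1].fraction, mean_target_coverage),
            upper_coverage=c95_bound(points[i].fraction, mean_target_coverage),
            crossed=True,
        )
    if all(above):  # never drops below threshold on the grid
        return C95Bracket(variant_class, None,
                          c95_bound(points[-1].fraction, mean_target_coverage), False)
    return C95Bracket(variant_class,
                      c95_bound(points[0].fraction, mean_target_coverage), None, False)


def min_fraction_all_replicates(variant, result: RarefactionResult):
    """Smallest grid fraction at which ``variant`` is called in every replicate.

    Returns ``(fraction, effective_coverage, mean site depth across that
    fraction's replicates)``, or ``None`` when no grid fraction recovers the
    variant in all replicates.
    """
    key = variant.key
    if not any(key in {c.key for c in calls} for calls in result.pseudo_truth.values()):
        raise InvalidParameterError(f"variant {key} is not in the pseudo-truth set")
    best = None
    for fraction in sorted(result.replicate_calls):  # ascending
        reps = result.replicate_calls[fraction]
        if all(key in keys for keys, _ in reps):
            depths = [d[key] for _, d in reps]
            best = (
                fraction,
                effective_coverage(fraction, result.mean_target_coverage),
                round_half_up(float(np.mean(depths)), 1),
            )
            break
    return best


# -- tabular output ----------------------------------------------------------

def points_table(result: RarefactionResult):
    """Long-form DataFrame of the rarefaction grid (one row per class x point)."""
    import pandas as pd

    rows = []
    for cls, pts in result.points.items():
        for p in pts:
            rows.append({
                "variant_class": cls,
                "fraction": p.fraction,
                "effective_coverage": p.effective_coverage,
                "mean_count": p.mean_count,
                "sd_count": p.sd_count,
                "mean_recall_pct": p.mean_recall_pct,
                "replicate_counts": ",".join(map(str, p.replicate_counts)),
            })
    return pd.DataFrame(rows)


def plot_rarefaction(result: RarefactionResult, path) -> None:
    """Recall curves with error bars and a dashed 95% line (one panel/class)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, cls in zip(axes, CLASSES):
        pts = result.points[cls]
        n_truth = len(result.pseudo_truth[cls])
        if n_truth == 0:
            continue
        x = [p.effective_coverage for p in pts]
        y = [p.mean_recall_pct for p in pts]
        yerr = [100.0 * p.sd_count / n_truth for p in pts]
        ax.errorbar(x, y, yerr=yerr, fmt="o-", capsize=2)
        ax.axhline(95.0, linestyle="--", color="tab:blue")
        ax.set_xlabel("mean target coverage (x)")
        ax.set_title(f"{cls.upper()} recovery")
    axes[0].set_ylabel("% of pseudo-truth variants called")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
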