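"""End-to-end experiment runner: config, staging, manifest, determinism.

``replicate_experiment`` wires every stage together in the order a panel
depth study runs them: synthesize the panel world, call variants at full
coverage, benchmark against the planted truth, run the down-sampling grid
with C95 brackets and the causal variant's minimal callable fraction, then
annotate and prioritize.  All randomness derives deterministically from the
single top-level seed, so two runs with the same config produce identical
tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any, Dict, Optional

import pandas as pd
import yaml

from . import benchmark as bm
from . import io as pio
from . import panel_synth as ps
from . import prioritize as pz
from . import rarefaction as rf
from ._util import ConfigError
from .pedigree import write_ped
from .pileup_caller import CallerModel, call_variants
from .example_cases import case1_pedigree, case2_pedigree

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: Dict[str, Any] = {
    "seed": 1,
    "panel": {
        "n_genes": 27, "exons_per_gene": 5, "exon_len": 200,
        "pad_bp": 100, "exon_gap": 300,
    },
    "variants": {
        "n_snps": 162, "n_indels": 42, "indel_len_range": [1, 6],
    },
    "pedigree": {"model": "AR", "penetrance": 1.0},
    "coverage": {
        "mean_target_coverage": 213.4, "error_rate": 0.005,
        "capture_cv": 0.7, "read_len": 100,
        "fragment_mean": 300, "fragment_sd": 30,
    },
    "grid": {
        "max_fraction": 1.0, "min_fraction": 0.05, "step": 0.05,
        "replicates": 10,
    },
    "caller": {"error_rate": 0.005, "qual_threshold": 50.0},
    "annotation": {"n_benign_scale": 1.0},
    "plot": False,
}


def _validate_section(section: str, given: Dict[str, Any], allowed: Dict[str, Any]) -> Dict[str, Any]:
    out = dict(allowed)
    for key, value in given.items():
        if key not in allowed:
            raise ConfigError(f"unknown config key: {section}.{key}" if section else
                              f"unknown config key: {key}")
        if isinstance(allowed[key], dict):
            raise ConfigError(f"config key {section}.{key} must be a mapping")
        out[key] = value
    return out


def load_config(overrides: Optional[Dict[str, Any]] = None) -> Dict[str, Any]:
    """Merge user overrides into the defaults, rejecting unknown keys."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise ConfigError(f"unknown config key: {key}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {key} must be a mapping")
            cfg[key] = _validate_section(key, value, cfg[key])
        else:
            cfg[key] = value
    return cfg


def load_config_file(path) -> Dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return load_config(data)


def _pedigree_from_config(cfg: Dict[str, Any]):
    model = cfg["pedigree"]["model"]
    if model == "AR":
        ped = case1_pedigree()
    elif model == "AD":
        ped = case2_pedigree()
    else:
        raise ConfigError("unknown config key: pedigree.model value must be AR or AD")
    ped.penetrance = float(cfg["pedigree"]["penetrance"]) if model == "AD" else 1.0
    return ped


def replicate_experiment(config: Dict[str, Any], outdir) -> Dict[str, Any]:
    """Run the full pipeline per ``config``; write all artifacts to ``outdir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    cfg = load_config(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: Dict[str, Any] = {"config": cfg, "stages": {}, "counts": {}}
    t_all = time.time()

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t_all, 2)}
        return time.time()

    # -- panel world
    t = stage("panel_synth")
    p = cfg["panel"]
    regions, reference = ps.build_panel(
        p["n_genes"], p["exons_per_gene"], p["exon_len"], p["pad_bp"],
        seed=seed, exon_gap=p["exon_gap"],
    )
    pio.write_fasta(reference, out / "reference.fasta")
    pio.write_bed(regions, out / "targets.bed")
    vc = cfg["variants"]
    variants = ps.plant_variants(
        regions, reference, vc["n_snps"], vc["n_indels"],
        tuple(vc["indel_len_range"]), seed=seed + 1,
    )
    pedigree = _pedigree_from_config(cfg)
    proband = "II-2" if pedigree.inheritance_model == "AR" else "II-1"
    snps = [v for v in variants if v.var_class == "snp"]
    causal_key = snps[len(snps) // 2].key if snps else None
    variants = ps.assign_pedigree_genotypes(variants, pedigree, causal_key, seed=seed + 2)
    pio.write_truth_vcf(variants, reference, out / "truth.vcf")
    write_ped(pedigree, out / "family.ped")
    manifest["counts"]["planted_snps"] = vc["n_snps"]
    manifest["counts"]["planted_indels"] = vc["n_indels"]
    manifest["causal_variant"] = list(causal_key) if causal_key else None
    manifest["stages"]["panel_synth"]["seconds"] = round(time.time() - t, 2)

    # -- reads
    t = stage("simulate_reads")
    cov = cfg["coverage"]
    reads = ps.simulate_reads(
        reference, regions, cov["mean_target_coverage"], cov["error_rate"],
        member_id=proband, capture_cv=cov["capture_cv"], seed=seed + 3,
        variants=variants, read_len=cov["read_len"],
        fragment_mean=cov["fragment_mean"], fragment_sd=cov["fragment_sd"],
    )
    pio.write_read_table(reads, out / "reads.tsv")
    metrics = rf.coverage_metrics(reads, regions)
    pd.DataFrame([dataclasses.asdict(metrics)]).to_csv(out / "coverage.tsv", sep="\t", index=False)
    manifest["counts"]["read_pairs"] = int(reads.n_pairs)
    manifest["coverage"] = dataclasses.asdict(metrics)
    manifest["stages"]["simulate_reads"]["seconds"] = round(time.time() - t, 2)

    # -- full-coverage calls + benchmark
    t = stage("call_variants")
    model = CallerModel(error_rate=cfg["caller"]["error_rate"],
                        qual_threshold=cfg["caller"]["qual_threshold"])
    calls = call_variants(reads, reference, regions, model)
    pio.write_calls_vcf(calls, reference, out / "calls.vcf", sample=proband)
    truth_for_member = [v for v in variants if v.genotypes.get(proband, "hom_ref") != "hom_ref"]
    results = bm.match_and_score(calls, truth_for_member)
    bm.results_table(results).to_csv(out / "benchmark.tsv", sep="\t", index=False)
    manifest["counts"]["calls"] = len(calls)
    manifest["counts"]["calls_snp"] = sum(1 for c in calls if c.var_class == "snp")
    manifest["counts"]["calls_indel"] = sum(1 for c in calls if c.var_class == "indel")
    manifest["stages"]["call_variants"]["seconds"] = round(time.time() - t, 2)

    # -- rarefaction grid
    t = stage("rarefaction")
    g = cfg["grid"]
    grid = rf.GridConfig(
        fractions=rf.default_fractions(g["max_fraction"], g["min_fraction"], g["step"]),
        replicates_per_fraction=g["replicates"],
        base_seed=seed + 4,
    )
    result = rf.run_grid(reads, model, regions, reference, grid,
                         mean_target_coverage=metrics.mean_target_coverage)
    rf.points_table(result).to_csv(out / "rarefaction.tsv", sep="\t", index=False)
    c95_rows = []
    for cls in rf.CLASSES:
        if result.pseudo_truth[cls]:
            b = rf.estimate_c95(result.points[cls], metrics.mean_target_coverage, cls)
            c95_rows.append({"variant_class": cls, "lower_coverage": b.lower_coverage,
                             "upper_coverage": b.upper_coverage, "crossed": b.crossed})
    pd.DataFrame(c95_rows).to_csv(out / "c95.tsv", sep="\t", index=False)
    causal_in_truth = causal_key is not None and any(
        causal_key == c.key for cls in rf.CLASSES for c in result.pseudo_truth[cls]
    )
    if causal_in_truth:
        causal_variant = next(v for v in variants if v.key == causal_key)
        mf = rf.min_fraction_all_replicates(causal_variant, result)
        manifest["causal_min_fraction"] = (
            None if mf is None else
            {"fraction": mf[0], "effective_coverage": mf[1], "mean_site_depth": mf[2]}
        )
    if cfg["plot"]:
        rf.plot_rarefaction(result, out / "rarefaction.png")
    manifest["stages"]["rarefaction"]["seconds"] = round(time.time() - t, 2)

    # -- prioritization cascade
    t = stage("prioritize")
    annotated = ps.annotate_calls(calls, regions, causal_key, pedigree, seed=seed + 5)
    pz.write_annotated_tsv(annotated, out / "annotated.tsv")
    report = pz.run_cascade(annotated, pedigree, pz.QCThresholds())
    pz.report_table(report).to_csv(out / "report.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"variant_id": v.variant_id, "gene": v.gene, "genotype": v.genotype}
         for v in report.candidates]
    ).to_csv(out / "shortlist.tsv", sep="\t", index=False)
    manifest["counts"]["shortlisted"] = len(report.shortlist)
    manifest["counts"]["final_candidates"] = len(report.candidates)
    manifest["candidates"] = [v.variant_id for v in report.candidates]
    manifest["stages"]["prioritize"]["seconds"] = round(time.time() - t, 2)

    manifest["total_seconds"] = round(time.time() - t_all, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
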