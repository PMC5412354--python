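"""Shared fixtures: a small synthetic panel world used across test modules."""

from dataclasses import dataclass
from typing import Dict, List

import pytest

from paneldepth import (
    CallerModel,
    assign_sample_genotypes,
    build_panel,
    call_variants,
    plant_variants,
    simulate_reads,
)


@dataclass
class World:
    regions: list
    reference: Dict[str, str]
    variants: list
    reads: object
    model: CallerModel
    member: str


@pytest.fixture(scope="session")
def small_world() -> World:
    """An 8-gene panel (~11 kb padded target) at 150x with planted variants."""
    regions, reference = build_panel(
        n_genes=8, exons_per_gene=3, exon_len=150, pad_bp=100, seed=11, exon_gap=250
    )
    variants = plant_variants(regions, reference, n_snps=30, n_indels=10, seed=12)
    variants = assign_sample_genotypes(variants, "s1", seed=13)
    reads = simulate_reads(
        reference, regions, mean_target_coverage=150.0, error_rate=0.005,
        member_id="s1", capture_cv=0.4, seed=14, variants=variants,
    )
    return World(regions, reference, variants, reads,
                 CallerModel(error_rate=0.005), "s1")


@pytest.fixture(scope="session")
def small_calls(small_world) -> List:
    return call_variants(small_world.reads, small_world.reference,
                         small_world.regions, small_world.model)
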