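"""Down-sampling grid, recall arithmetic, C95 brackets, coverage metrics."""

import numpy as np
import pytest

from paneldepth import (
    GridConfig,
    InvalidParameterError,
    VariantCall,
    compute_recall,
    coverage_metrics,
    effective_coverage,
    estimate_c95,
    min_fraction_all_replicates,
    run_grid,
    subsample_reads,
)
from paneldepth.panel_synth import PanelRegion, ReadSet
from paneldepth.rarefaction import (
    RarefactionPoint,
    RarefactionResult,
    c95_bound,
    default_fractions,
    recall_percent,
)
from paneldepth.variants import PlantedVariant


def _uniform_reads(n, start, read_len=100, chrom="panel_chr1"):
    return ReadSet(
        chroms=[chrom], read_len=read_len, member_id="s",
        chrom_idx=np.zeros(n, np.int32),
        start=np.full(n, start, np.int32),
        seq=np.zeros((n, read_len), np.uint8),
        pair_id=np.arange(n, dtype=np.int64),
        mate=np.ones(n, np.int8),
    )


def _merge(a, b):
    return ReadSet(
        chroms=a.chroms, read_len=a.read_len, member_id=a.member_id,
        chrom_idx=np.concatenate([a.chrom_idx, b.chrom_idx]),
        start=np.concatenate([a.start, b.start]),
        seq=np.concatenate([a.seq, b.seq]),
        pair_id=np.concatenate([a.pair_id, b.pair_id + a.n_pairs]),
        mate=np.concatenate([a.mate, b.mate]),
    )


def _points(fractions, recalls, cov):
    return [
        RarefactionPoint(f, effective_coverage(f, cov), [0], 0.0, 0.0, r)
        for f, r in zip(fractions, recalls)
    ]


class TestArithmetic:
    @pytest.mark.parametrize("count,total,expected", [
        (115.0, 162, 71.0),
        (118.0, 160, 73.8),
        (11.4, 42, 27.1),
        (8.6, 33, 26.1),
        (162.0, 162, 100.0),
    ])
    def test_recall_percent_printed_to_one_decimal(self, count, total, expected):
        assert recall_percent(count, total) == expected

    @pytest.mark.parametrize("fraction,cov,expected", [
        (0.05, 213.4, 10.7),
        (0.10, 213.4, 21.3),
        (0.05, 184.2, 9.2),
        (1.0, 184.2, 184.2),
    ])
    def test_effective_coverage(self, fraction, cov, expected):
        assert effective_coverage(fraction, cov) == expected

    def test_effective_coverage_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            effective_coverage(0.0, 213.4)


class TestComputeRecall:
    def _call(self, pos, ref="A", alt="G"):
        return VariantCall("c1", pos, ref, alt, "het", 60.0, 30)

    def test_identical_sets_give_full_recall(self):
        truth = [self._call(p) for p in (10, 20, 30)]
        count, prop = compute_recall(truth, truth, "snp")
        assert (count, prop) == (3, 1.0)

    def test_matching_ignores_genotype(self):
        truth = [VariantCall("c1", 10, "A", "G", "hom_alt", 99.0, 50)]
        calls = [VariantCall("c1", 10, "A", "G", "het", 55.0, 12)]
        assert compute_recall(calls, truth, "snp") == (1, 1.0)

    def test_empty_truth_class_is_undefined(self):
        truth = [self._call(10)]  # snp only
        with pytest.raises(InvalidParameterError):
            compute_recall([], truth, "indel")


class TestSubsample:
    def test_fraction_one_is_identity(self, small_world):
        sub = subsample_reads(small_world.reads, 1.0, seed=1)
        assert sub.n_reads == small_world.reads.n_reads

    def test_same_seed_same_subset(self, small_world):
        a = subsample_reads(small_world.reads, 0.3, seed=5)
        b = subsample_reads(small_world.reads, 0.3, seed=5)
        assert np.array_equal(a.start, b.start)
        assert np.array_equal(a.seq, b.seq)

    def test_mates_never_split(self, small_world):
        sub = subsample_reads(small_world.reads, 0.4, seed=6)
        _, counts = np.unique(sub.pair_id, return_counts=True)
        assert (counts == 2).all()

    def test_kept_pairs_within_binomial_bound(self, small_world):
        n = small_world.reads.n_pairs
        f = 0.05
        sub = subsample_reads(small_world.reads, f, seed=7)
        sd = (n * f * (1 - f)) ** 0.5
        assert abs(sub.n_pairs - n * f) < 3.5 * sd  # ~99.95% interval

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.01])
    def test_invalid_fraction_rejected(self, small_world, fraction):
        with pytest.raises(InvalidParameterError):
            subsample_reads(small_world.reads, fraction, seed=0)


class TestCoverageMetrics:
    def test_uniform_depth(self):
        regions = [PanelRegion("g", "panel_chr1", [(0, 100)], 0)]
        m = coverage_metrics(_uniform_reads(10, 0), regions)
        assert (m.mean_target_coverage, m.pct_ge_2x, m.pct_ge_10x, m.pct_ge_50x) == \
            (10.0, 100.00, 100.00, 0.00)

    def test_piecewise_depth_hand_computed(self):
        # half the 200 bp target at 60x, half at 4x -> mean 32.0
        regions = [PanelRegion("g", "panel_chr1", [(0, 200)], 0)]
        reads = _merge(_uniform_reads(60, 0), _uniform_reads(4, 100))
        m = coverage_metrics(reads, regions)
        assert (m.mean_target_coverage, m.pct_ge_2x, m.pct_ge_10x, m.pct_ge_50x) == \
            (32.0, 100.00, 50.00, 50.00)

    def test_empty_target_rejected(self):
        with pytest.raises(InvalidParameterError):
            coverage_metrics(_uniform_reads(1, 0), [])


class TestEstimateC95:
    fractions = default_fractions()

    def test_case1_like_crossing_between_020_and_025(self):
        recalls = [100.0] * 15 + [96.0, 94.0, 90.0, 80.0, 70.0]  # crosses at 0.25 -> 0.20
        b = estimate_c95(_points(self.fractions, recalls, 213.4), 213.4, "snp")
        assert (b.lower_coverage, b.upper_coverage, b.crossed) == (43, 53, True)

    def test_case2_like_crossing_between_030_and_035(self):
        recalls = [100.0] * 13 + [95.2, 94.9, 93.0, 90.0, 80.0, 70.0, 60.0]
        b = estimate_c95(_points(self.fractions, recalls, 184.2), 184.2, "snp")
        assert (b.lower_coverage, b.upper_coverage, b.crossed) == (55, 64, True)

    def test_high_coverage_indel_crossing(self):
        recalls = [100.0, 95.0] + [94.0] * 18  # crosses between 0.95 and 0.90
        b = estimate_c95(_points(self.fractions, recalls, 213.4), 213.4, "indel")
        assert (b.lower_coverage, b.upper_coverage) == (192, 203)

    def test_never_dropping_below_threshold(self):
        b = estimate_c95(_points(self.fractions, [99.0] * 20, 213.4), 213.4, "snp")
        assert not b.crossed and b.lower_coverage is None
        assert b.upper_coverage == c95_bound(0.05, 213.4)

    def test_never_reaching_threshold(self):
        b = estimate_c95(_points(self.fractions, [90.0] * 20, 213.4), 213.4, "snp")
        assert not b.crossed and b.upper_coverage is None
        assert b.lower_coverage == c95_bound(1.0, 213.4)

    def test_multiple_crossings_take_highest_and_warn(self):
        recalls = [100.0, 94.0, 96.0, 94.0] + [90.0] * 16
        with pytest.warns(UserWarning):
            b = estimate_c95(_points(self.fractions, recalls, 100.0), 100.0, "snp")
        assert (b.lower_coverage, b.upper_coverage) == (95, 100)

    def test_bracket_endpoints_are_adjacent_grid_points(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            recalls = np.clip(100 - np.cumsum(rng.exponential(2, size=20)), 0, 100)
            b = estimate_c95(_points(self.fractions, recalls, 200.0), 200.0, "snp")
            if b.crossed:
                covs = [c95_bound(f, 200.0) for f in self.fractions]
                i = covs.index(b.upper_coverage)
                assert covs[i + 1] == b.lower_coverage


class TestGridConfig:
    def test_default_grid_is_20_descending_fractions(self):
        g = GridConfig()
        assert len(g.fractions) == 20
        assert g.fractions[0] == 1.0 and g.fractions[-1] == 0.05
        assert all(a > b for a, b in zip(g.fractions, g.fractions[1:]))

    def test_invalid_grids_rejected(self):
        with pytest.raises(InvalidParameterError):
            GridConfig(fractions=[0.5, 0.7])
        with pytest.raises(InvalidParameterError):
            GridConfig(fractions=[1.0, 0.0])
        with pytest.raises(InvalidParameterError):
            GridConfig(replicates_per_fraction=0)


@pytest.fixture(scope="module")
def grid_result(small_world):
    grid = GridConfig(fractions=[1.0, 0.6, 0.3, 0.1], replicates_per_fraction=4,
                      base_seed=100)
    return run_grid(small_world.reads, small_world.model, small_world.regions,
                    small_world.reference, grid)


class TestRunGrid:
    def test_shape_contract(self, grid_result):
        for cls in ("snp", "indel"):
            assert len(grid_result.points[cls]) == 4
            for p in grid_result.points[cls]:
                assert len(p.replicate_counts) == 4
                assert 0 <= p.mean_recall_pct <= 100

    def test_full_fraction_recall_is_exactly_100(self, grid_result):
        for cls in ("snp", "indel"):
            p = grid_result.points[cls][0]
            assert p.fraction == 1.0
            assert p.mean_recall_pct == 100.0
            assert p.sd_count == 0.0

    def test_rerun_reproduces_every_replicate_count(self, small_world, grid_result):
        grid = GridConfig(fractions=[1.0, 0.6, 0.3, 0.1], replicates_per_fraction=4,
                          base_seed=100)
        again = run_grid(small_world.reads, small_world.model, small_world.regions,
                         small_world.reference, grid)
        for cls in ("snp", "indel"):
            assert [p.replicate_counts for p in again.points[cls]] == \
                [p.replicate_counts for p in grid_result.points[cls]]

    def test_min_fraction_for_pseudo_truth_variant(self, grid_result, small_world):
        v = grid_result.pseudo_truth["snp"][0]
        out = min_fraction_all_replicates(v, grid_result)
        if out is not None:
            fraction, eff_cov, depth = out
            assert fraction in (1.0, 0.6, 0.3, 0.1)
            assert depth > 0
            assert eff_cov == effective_coverage(fraction, grid_result.mean_target_coverage)

    def test_min_fraction_unknown_variant_rejected(self, grid_result):
        stranger = PlantedVariant("panel_chr1", 1, "A", "G")
        with pytest.raises(InvalidParameterError):
            min_fraction_all_replicates(stranger, grid_result)


class TestMinFractionDefinition:
    def _fake_result(self, presence):
        """presence: fraction -> list of bool (called in replicate)."""
        key = ("c", 10, "A", "G")
        truth = [VariantCall("c", 10, "A", "G", "het", 99.0, 50)]
        replicate_calls = {
            f: [({key} if hit else set(), {key: 12} if hit else {}) for hit in hits]
            for f, hits in presence.items()
        }
        return RarefactionResult(
            points={}, pseudo_truth={"snp": truth, "indel": []},
            mean_target_coverage=100.0, grid=GridConfig(), replicate_calls=replicate_calls,
        ), truth[0]

    def test_called_everywhere_returns_smallest_fraction(self):
        res, v = self._fake_result({0.05: [True] * 3, 0.10: [True] * 3})
        assert min_fraction_all_replicates(v, res)[0] == 0.05

    def test_missing_in_one_replicate_at_bottom_moves_up(self):
        res, v = self._fake_result({0.05: [True, False, True], 0.10: [True] * 3})
        assert min_fraction_all_replicates(v, res)[0] == 0.10

    def test_never_complete_returns_sentinel(self):
        res, v = self._fake_result({0.05: [False], 0.10: [False]})
        assert min_fraction_all_replicates(v, res) is None
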