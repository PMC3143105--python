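import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon

from pr19scan import classify, synthetic, tiles
from pr19scan.core import (
    ClassifiedRead,
    ConsensusAlignment,
    FlankedRead,
    GenomicInterval,
    ReadClass,
    TileCounts,
)


def _classified_at(pos, strand="+", cls=ReadClass.PR19_A10, chrom="chr1",
                   length=19, count=1, unique=True):
    aln = ConsensusAlignment("r", chrom, pos, pos + length, strand,
                             count=count, unique=unique)
    fl = FlankedRead(aln, "G" * length, "N" * 10, "N" * 10)
    return ClassifiedRead(fl, cls)


class TestMakeTiles:
    def test_partial_final_tile(self):
        out = tiles.make_tiles({"chr1": 6000})
        assert [(t.start, t.end) for t in out] == [
            (0, 2500), (2500, 5000), (5000, 6000)
        ]

    def test_exact_width(self):
        out = tiles.make_tiles({"chr1": 2500})
        assert len(out) == 1

    def test_zero_length_chromosome(self):
        assert tiles.make_tiles({"chr1": 0}) == []

    def test_partition_covers_genome_once(self):
        sizes = {"chr1": 61234, "chr2": 2499, "chr3": 5000}
        out = tiles.make_tiles(sizes)
        assert sum(len(t) for t in out) == sum(sizes.values())


class TestCountTiles:
    def test_half_open_boundary_membership(self):
        tile_list = tiles.make_tiles({"chr1": 5000})
        counts = tiles.count_tiles(
            [_classified_at(2499), _classified_at(2500)], tile_list, width=2500
        )
        by_tile = {(tc.tile.start, tc.strand): tc.pr19_a10 for tc in counts}
        assert by_tile[(0, "+")] == 1
        assert by_tile[(2500, "+")] == 1

    def test_minus_strand_five_prime_membership(self):
        tile_list = tiles.make_tiles({"chr1": 5000})
        # spans the boundary: 5' end (rightmost base 2503) is in tile 2
        counts = tiles.count_tiles(
            [_classified_at(2485, strand="-")], tile_list, width=2500
        )
        by_tile = {(tc.tile.start, tc.strand): tc.pr19_a10 for tc in counts}
        assert by_tile[(2500, "-")] == 1

    def test_multimapper_excluded(self):
        tile_list = tiles.make_tiles({"chr1": 2500})
        counts = tiles.count_tiles(
            [_classified_at(100, unique=False)], tile_list, width=2500
        )
        assert all(tc.pr19_a10 == 0 for tc in counts)

    def test_empty_tiles_retained(self):
        tile_list = tiles.make_tiles({"chr1": 7500})
        counts = tiles.count_tiles([], tile_list, width=2500)
        assert len(counts) == 6  # 3 tiles x 2 strands


def _tc(pr19, other, s, p):
    return TileCounts(GenomicInterval("chr1", 0, 2500), "+",
                      pr19, other, s, p)


class TestSelectEnrichedTiles:
    def test_selection_rules(self):
        assert tiles.select_enriched_tiles([_tc(5, 1, 3, 1)])
        assert not tiles.select_enriched_tiles([_tc(5, 1, 2, 4)])  # p over s
        assert not tiles.select_enriched_tiles([_tc(0, 0, 3, 1)])  # no pr19
        assert not tiles.select_enriched_tiles([_tc(5, 1, 0, 0)])  # no s
        assert not tiles.select_enriched_tiles([_tc(2, 3, 4, 1)])  # other19 over pr19


class TestPairedWilcoxon:
    def test_identical_inputs_degenerate(self):
        with pytest.warns(UserWarning):
            res = tiles.paired_wilcoxon([1, 2, 3], [1, 2, 3])
        assert res.pvalue == 1.0

    def test_all_positive_distinct_n5_exact(self):
        # all five differences positive and distinct: the most extreme of
        # the 2^5 sign assignments on each side, p = 2/32
        res = tiles.paired_wilcoxon([10, 8, 6, 4, 2], [11, 10, 9, 8, 7])
        assert res.pvalue == pytest.approx(0.0625)
        assert res.method == "exact"

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(3, 11))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            d = x - y
            d_nz = d[d != 0]
            if d_nz.size == 0:
                continue
            ranks = rankdata(np.abs(d_nz))
            w_obs = ranks[d_nz > 0].sum()
            sums = np.array([
                sum(r for r, keep in zip(ranks, signs) if keep)
                for signs in itertools.product([0, 1], repeat=d_nz.size)
            ])
            expected = min(
                1.0, 2 * min((sums <= w_obs).mean(), (sums >= w_obs).mean())
            )
            res = tiles.paired_wilcoxon(x, y)
            assert res.pvalue == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_agrees_with_scipy_exact_without_ties(self, alternative):
        rng = np.random.default_rng(8)
        for _ in range(15):
            n = int(rng.integers(5, 16))
            d = rng.choice([-1, 1], n) * rng.permutation(np.arange(1, n + 1))
            res = tiles.paired_wilcoxon(d.astype(float), np.zeros(n),
                                        alternative=alternative)
            ref = wilcoxon(d.astype(float), alternative=alternative,
                           method="exact")
            assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_near_exact_at_boundary(self):
        # shifted pairs at the n=20 boundary, in the moderate-p regime
        # where the continuity-corrected approximation is accurate
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 10:
            d = rng.normal(0.2, 1.0, 20)
            x, y = d, np.zeros(20)
            exact = tiles.paired_wilcoxon(x, y, mode="exact")
            if exact.pvalue < 0.05:
                continue
            approx = tiles.paired_wilcoxon(x, y, mode="approx")
            assert approx.pvalue == pytest.approx(exact.pvalue, rel=0.10)
            checked += 1

    def test_ties_get_midranks(self):
        # tied |differences| must share midranks, changing W+ vs naive ranks
        res = tiles.paired_wilcoxon([3, 3, 0], [0, 0, 3])
        assert res.statistic == pytest.approx(4.0)  # ranks 2, 2 positive


class TestRatioSummary:
    def test_single_tile_ratio(self):
        summary = tiles.ratio_summary([_tc(6, 0, 2, 0)])
        assert summary.median == pytest.approx(3.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            tiles.ratio_summary([])

    def test_planted_ratio_recovery(self):
        refs, sizes, alignments = synthetic.simulate_tile_study(
            200, ratio=2.5, seed=11
        )
        classified, _ = classify.classify_library(alignments, refs)
        tile_list = tiles.make_tiles(sizes)
        counts = tiles.count_tiles(classified, tile_list, width=2500)
        selected = tiles.select_enriched_tiles(counts)
        summary = tiles.ratio_summary(selected)
        assert summary.median == pytest.approx(2.5, rel=0.10)
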