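import math

import numpy as np
import pytest

from pr19scan import classify, signatures, synthetic
from pr19scan.core import ConsensusAlignment, ReadClass, ReferenceSet


def _classified(start, end, strand="+", ref_seq=None, count=1, rid="r"):
    ref_seq = ref_seq or ("ACGT" * 200)
    aln = ConsensusAlignment(rid, "ref", start, end, strand, count=count)
    fl = classify.extract_flanks(aln, ref_seq)
    return classify.classify_read(fl)


def _by_class(classified):
    return {
        cls: [cr for cr in classified if cr.read_class is cls]
        for cls in ReadClass
    }


class TestLengthHistogram:
    def test_strand_split_counts(self):
        reads = [
            _classified(100, 119, "+", rid="a"),
            _classified(200, 219, "+", rid="b"),
            _classified(300, 326, "-", rid="c"),
        ]
        hist = signatures.length_histogram(reads)
        table = {(r.length, r.strand): r.count for r in hist.itertuples()}
        assert table == {(19, "+"): 2, (26, "-"): 1}

    def test_empty(self):
        assert signatures.length_histogram([]).empty

    def test_copy_weighting(self):
        reads = [_classified(100, 119, count=7)]
        hist = signatures.length_histogram(reads)
        assert hist["count"].sum() == 7

    def test_simulated_library_modes_at_planted_lengths(self, small_classified):
        classified, _ = small_classified
        hist = signatures.length_histogram(classified)
        by_length = hist.groupby("length")["count"].sum()
        assert by_length[19] > 0
        assert by_length.loc[24:30].sum() > 0


class TestSequenceLogo:
    def test_information_bounds_and_examples(self):
        assert signatures.column_information({"A": 1.0}) == pytest.approx(2.0)
        assert signatures.column_information(
            {b: 0.25 for b in "ACGT"}
        ) == pytest.approx(0.0)
        assert signatures.column_information(
            {"A": 0.5, "C": 0.5}
        ) == pytest.approx(1.0)

    def test_conserved_and_uniform_columns(self):
        ref = "T" * 50 + "A" * 19 + "GCTAGCTAGA" + "T" * 30
        reads = [
            classify.classify_read(
                classify.extract_flanks(
                    ConsensusAlignment(f"r{i}", "ref", 50, 69, "+"), ref
                )
            )
            for i in range(4)
        ]
        logo = signatures.sequence_logo(reads, downstream_ext=10)
        assert logo.information[0] == pytest.approx(2.0)  # all A
        assert logo.information[19] == pytest.approx(2.0)  # downstream G
        assert logo.frequencies.loc["A", 0] == pytest.approx(1.0)

    def test_information_monotone_in_entropy(self):
        flat = signatures.column_information({b: 0.25 for b in "ACGT"})
        skew = signatures.column_information({"A": 0.7, "C": 0.1, "G": 0.1, "T": 0.1})
        sharp = signatures.column_information({"A": 0.97, "C": 0.01, "G": 0.01, "T": 0.01})
        assert flat < skew < sharp <= 2.0

    def test_n_excluded_from_denominator(self):
        # read ends 5 nt before the reference end: downstream positions
        # beyond the edge are N and must not contribute
        ref = "G" * 19 + "AAAAA"
        reads = [
            classify.classify_read(
                classify.extract_flanks(
                    ConsensusAlignment("r", "ref", 0, 19, "+"), ref
                )
            )
        ]
        logo = signatures.sequence_logo(reads, downstream_ext=10)
        assert logo.n_observations[20] == 1  # real base
        assert logo.n_observations[25] == 0  # padded N
        assert math.isnan(logo.information[25])


class TestOffsetDensity:
    def test_planted_peaks(self, small_classified):
        classified, _ = small_classified
        byc = _by_class(classified)
        same = signatures.offset_density(
            byc[ReadClass.PR19_A10], byc[ReadClass.S_PIRNA], same_strand=True
        )
        anti = signatures.offset_density(
            byc[ReadClass.PR19_A10], byc[ReadClass.P_PIRNA], same_strand=False
        )
        assert same.proportions == {19: pytest.approx(1.0)}
        assert anti.proportions == {28: pytest.approx(1.0)}

    def test_mirrored_configuration_peaks(self, small_classified):
        classified, _ = small_classified
        byc = _by_class(classified)
        same = signatures.offset_density(
            byc[ReadClass.PR19_U1], byc[ReadClass.P_PIRNA], same_strand=True
        )
        anti = signatures.offset_density(
            byc[ReadClass.PR19_U1], byc[ReadClass.S_PIRNA], same_strand=False
        )
        assert same.proportions == {19: pytest.approx(1.0)}
        assert anti.proportions == {28: pytest.approx(1.0)}

    def test_self_comparison_single_peak_at_zero(self):
        reads = [_classified(100, 119, rid="a", count=3)]
        dens = signatures.offset_density(reads, reads)
        assert dens.proportions == {0: pytest.approx(1.0)}

    def test_window_normalisation_sums_to_one(self, small_classified):
        classified, _ = small_classified
        byc = _by_class(classified)
        dens = signatures.offset_density(
            byc[ReadClass.PR19_A10], byc[ReadClass.S_PIRNA]
        )
        assert sum(dens.proportions.values()) == pytest.approx(1.0)

    def test_library_normalisation_bounded_by_one(self, small_classified):
        classified, _ = small_classified
        byc = _by_class(classified)
        dens = signatures.offset_density(
            byc[ReadClass.PR19_U1], byc[ReadClass.S_PIRNA],
            same_strand=False, normalise="library",
        )
        assert 0 < sum(dens.proportions.values()) <= 1.0 + 1e-9


class TestCountConfigurations:
    def test_noise_free_all_flagged(self, small_classified):
        classified, _ = small_classified
        report = signatures.count_configurations(classified)
        assert (report.summary["pct_either"] == 100.0).all()
        assert (report.summary["pct_adjacent"] == 100.0).all()
        assert (report.summary["pct_antisense"] == 100.0).all()

    def test_isolated_19mer_unflagged(self):
        reads = [_classified(100, 119)]
        report = signatures.count_configurations(reads)
        row = report.per_read.iloc[0]
        assert not row["adjacent"] and not row["antisense"]

    def test_percentage_decreases_with_background(self):
        percents = []
        for n_background in (0, 300, 1500):
            config = synthetic.SimulationConfig(
                seed=17, reference_length=30000, n_events_a=20,
                n_events_b=20, n_background=n_background,
            )
            lib = synthetic.simulate_library(config)
            classified, _ = classify.classify_library(
                lib.alignments, lib.references
            )
            report = signatures.count_configurations(classified)
            total = report.summary["n_19mers"].sum()
            either = report.summary["n_either"].sum()
            percents.append(100.0 * either / total)
        assert percents[0] == pytest.approx(100.0)
        assert percents[0] > percents[1] > percents[2]

    def test_reciprocal_statistics_complete_on_config_a_only(self):
        config = synthetic.SimulationConfig(
            seed=23, reference_length=30000, n_events_a=25, n_events_b=0
        )
        lib = synthetic.simulate_library(config)
        classified, _ = classify.classify_library(lib.alignments, lib.references)
        report = signatures.count_configurations(classified)
        recip = report.reciprocal.set_index("class")
        # every config-A s-piRNA is adjacent to its 19mer, every p-piRNA
        # sits 10 nt past a 19mer's 3' end on the opposite strand
        assert recip.loc["s_piRNA", "pct"] == pytest.approx(100.0)
        assert recip.loc["p_piRNA", "pct"] == pytest.approx(100.0)


class TestCoverageDensity:
    def test_five_prime_conventions(self):
        ref = "ACGT" * 50
        plus = _classified(5, 24, "+", ref)
        minus = _classified(5, 24, "-", ref)
        dens = signatures.coverage_density([plus, minus], len(ref))
        plus_key = (plus.read_class.value, "+")
        minus_key = (minus.read_class.value, "-")
        assert dens[plus_key][5] == 1 and dens[plus_key].sum() == 1
        assert dens[minus_key][23] == 1 and dens[minus_key].sum() == 1

    def test_conservation_of_copy_weight(self, small_classified):
        classified, _ = small_classified
        ref_len = 30000
        dens = signatures.coverage_density(classified, ref_len)
        total = sum(arr.sum() for arr in dens.values())
        assert total == sum(cr.alignment.count for cr in classified)


class TestNormalisation:
    def test_rpm_arithmetic(self):
        assert signatures.rpm(500, 2_000_000) == pytest.approx(250.0)
        assert signatures.rpm(0, 100) == 0.0
        assert signatures.rpm(50, 2_000_000) == pytest.approx(
            signatures.rpm(50, 1_000_000) / 2
        )

    def test_rpm_zero_total_rejected(self):
        with pytest.raises(ValueError):
            signatures.rpm(10, 0)

    def test_fold_change_ddct(self):
        assert signatures.fold_change_ddct(20, 18, 20, 18) == pytest.approx(1.0)
        assert signatures.fold_change_ddct(22, 18, 20, 18) == pytest.approx(0.25)
        assert signatures.fold_change_ddct(19, 18, 20, 18) == pytest.approx(2.0)

    def test_ddct_non_finite_rejected(self):
        with pytest.raises(ValueError):
            signatures.fold_change_ddct(float("nan"), 18, 20, 18)
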