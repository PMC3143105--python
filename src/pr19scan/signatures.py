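"""Signature analytics for classified small-RNA reads.

Length histograms, Shannon sequence logos extended past the 3' end,
5'-end offset densities between read classes, ping-pong adjacency
configuration counting, per-position 5'-end coverage, RPM normalisation,
and the 2^-ddCt relative-quantification utility.

Offset conventions: the 5' coordinate of a '-' strand read is its rightmost
covered base; offsets are measured in the anchor's reading direction, so the
two cleavage configurations land at +19 (same-sense piRNA immediately
adjacent to the 19mer's 3' end) and +28 (antisense piRNA whose 5' terminus
sits 10 nt past the 19mer's 3' terminal base) regardless of anchor strand.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ClassifiedRead, ReadClass

PIRNA_SIZE = (24, 30)

NINETEEN_MER_CLASSES = (ReadClass.PR19_A10, ReadClass.PR19_U1, ReadClass.OTHER_19MER)
PIRNA_CLASSES = (ReadClass.P_PIRNA, ReadClass.S_PIRNA, ReadClass.PIRNA_AMBIGUOUS)


def length_histogram(
    classified: Iterable[ClassifiedRead], by_strand: bool = True
) -> pd.DataFrame:
    """Copy-weighted read-length histogram, split by strand by default.

    Antisense counts are reported in their own rows (the convention of
    plotting them below the axis is a display choice).
    """
    tally: Counter = Counter()
    for cr in classified:
        aln = cr.alignment
        key = (aln.length, aln.strand if by_strand else ".")
        tally[key] += aln.count
    rows = [
        {"length": length, "strand": strand, "count": n}
        for (length, strand), n in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["length", "strand", "count"])


@dataclass
class LogoMatrix:
    """Per-position base frequencies and Shannon information content.

    ``positions`` are 0-based from the aligned 5' end; negative positions
    are upstream extension, positions >= read length come from the
    downstream flank. ``information`` is 2 - H bits per column, where
    H = -sum p log2 p over non-N observations; columns with no observations
    hold NaN.
    """

    positions: list[int]
    frequencies: pd.DataFrame  # rows A,C,G,T; columns = positions
    information: pd.Series  # bits in [0, 2], indexed by position
    n_observations: pd.Series

    def to_table(self) -> pd.DataFrame:
        out = self.frequencies.T
        out.index.name = "position"
        out["information_bits"] = self.information
        out["n"] = self.n_observations
        return out.reset_index()


def column_information(freqs: Mapping[str, float]) -> float:
    """Shannon information 2 - H of one logo column (bits)."""
    h = 0.0
    for p in freqs.values():
        if p > 0:
            h -= p * math.log2(p)
    return 2.0 - h


def sequence_logo(
    flanked_reads: Iterable[ClassifiedRead],
    upstream_ext: int = 0,
    downstream_ext: int = 10,
    copy_weighted: bool = True,
) -> LogoMatrix:
    """Build a 5'-anchored sequence logo extended beyond the reads' 3' ends.

    Reads are stacked by their 5' ends; columns past a read's 3' end are
    filled from its downstream reference flank (up to the stored flank
    length), and columns before the 5' end from the upstream flank. N bases
    are excluded from that column's denominator.
    """
    counts: dict[int, Counter] = defaultdict(Counter)
    max_len = 0
    for cr in flanked_reads:
        fl = cr.flanked
        seq, up, down = fl.read_sequence, fl.up_flank, fl.down_flank
        w = cr.alignment.count if copy_weighted else 1
        max_len = max(max_len, len(seq))
        for pos in range(-upstream_ext, len(seq) + downstream_ext):
            if 0 <= pos < len(seq):
                base = seq[pos]
            elif pos < 0 and -pos <= len(up):
                base = up[len(up) + pos]
            elif pos >= len(seq) and pos - len(seq) < len(down):
                base = down[pos - len(seq)]
            else:
                continue
            if base != "N":
                counts[pos][base] += w
    positions = list(range(-upstream_ext, max_len + downstream_ext))
    freq = pd.DataFrame(0.0, index=list("ACGT"), columns=positions)
    info = pd.Series(np.nan, index=positions, dtype=float)
    nobs = pd.Series(0, index=positions, dtype=int)
    for pos in positions:
        col = counts.get(pos)
        if not col:
            continue
        total = sum(col.values())
        nobs[pos] = total
        probs = {b: col.get(b, 0) / total for b in "ACGT"}
        for b, p in probs.items():
            freq.loc[b, pos] = p
        info[pos] = column_information(probs)
    return LogoMatrix(positions, freq, info, nobs)


@dataclass
class OffsetDensity:
    """Signed 5'-to-5' offset spectrum between two read classes."""

    anchor_class: str
    query_class: str
    window: int
    proportions: dict[int, float] = field(default_factory=dict)
    total_tallied: float = 0.0

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"offset": off, "proportion": p}
            for off, p in sorted(self.proportions.items())
        ]
        return pd.DataFrame(rows, columns=["offset", "proportion"])


def _five_prime_index(
    reads: Iterable[ClassifiedRead],
) -> dict[tuple[str, str], list[tuple[int, float]]]:
    """(ref, strand) -> [(5' coordinate, copy weight)]."""
    idx: dict[tuple[str, str], list[tuple[int, float]]] = defaultdict(list)
    for cr in reads:
        aln = cr.alignment
        idx[(aln.ref_id, aln.strand)].append((aln.five_prime(), aln.count))
    return idx


def offset_density(
    anchors: Sequence[ClassifiedRead],
    queries: Sequence[ClassifiedRead],
    window: int = 60,
    same_strand: bool = True,
    normalise: str = "window",
) -> OffsetDensity:
    """Tally query 5' ends at signed offsets from anchor 5' ends.

    The offset is measured in the anchor's reading direction: +19 means 19 nt
    downstream of the anchor's 5' end. With ``same_strand=False`` queries on
    the strand opposite each anchor are tallied instead (the antisense
    configuration). Tallies carry the query's copy weight; anchors sharing
    a 5' position count once per (position, strand). ``normalise='window'``
    divides by the total query mass tallied within the window (the spectrum
    sums to 1); ``'library'`` divides by the total query copy count, so each
    offset reads as a proportion of all query RNAs (a query inside two
    anchors' windows is tallied at both offsets).
    """
    if normalise not in ("window", "library"):
        raise ValueError("normalise must be 'window' or 'library'")
    query_idx = _five_prime_index(queries)
    # anchors sharing a 5' position are tallied once per (position, strand)
    anchor_positions = {
        (cr.alignment.ref_id, cr.alignment.strand, cr.alignment.five_prime())
        for cr in anchors
    }
    tally: Counter = Counter()
    for ref_id, strand, a5 in anchor_positions:
        direction = 1 if strand == "+" else -1
        qstrand = strand if same_strand else ("-" if strand == "+" else "+")
        for q5, weight in query_idx.get((ref_id, qstrand), ()):
            offset = (q5 - a5) * direction
            if -window <= offset <= window:
                tally[offset] += weight
    total_tallied = float(sum(tally.values()))
    if normalise == "window":
        denom = total_tallied
    else:
        denom = float(sum(cr.alignment.count for cr in queries))
    proportions = (
        {off: n / denom for off, n in tally.items()} if denom > 0 else {}
    )
    anchor_cls = anchors[0].read_class.value if anchors else "none"
    query_cls = queries[0].read_class.value if queries else "none"
    dens = OffsetDensity(anchor_cls, query_cls, window, proportions, total_tallied)
    return dens


@dataclass
class ConfigurationReport:
    """Adjacency-configuration statistics for 19mers vs piRNA-sized reads."""

    per_read: pd.DataFrame
    summary: pd.DataFrame
    reciprocal: pd.DataFrame


def percent(part: float, whole: float) -> float:
    """Percentage as a float; NaN for an empty denominator."""
    return 100.0 * part / whole if whole else float("nan")


def format_percent(part: float, whole: float) -> int:
    """Whole-number percentage (rounded to nearest) as reported in tables."""
    return int(round(percent(part, whole)))


def count_configurations(
    classified: Sequence[ClassifiedRead],
    pirna_lengths: tuple[int, int] = PIRNA_SIZE,
) -> ConfigurationReport:
    """Flag each 19mer found in either ping-pong configuration.

    For a 19mer with 5' start ``s`` on strand ``sigma`` (reading direction
    ``d``), tests — disregarding whether the piRNA is primary or secondary:

    * adjacent: a same-strand 24-30 nt read with its 5' end at ``s + 19 d``
      (immediately past the 19mer's 3' end);
    * antisense: an opposite-strand 24-30 nt read with its 5' coordinate at
      ``s + 28 d`` (10 nt past the 19mer's 3' terminal base at ``s + 18 d``).

    Also reports the reciprocal statistics: the fraction of s-piRNAs
    immediately adjacent to a 19mer, and the fraction of p-piRNAs whose 5'
    end sits 10 nt downstream of a 19mer's 3' end on the opposite strand.
    Aggregates are copy-weighted.
    """
    lo, hi = pirna_lengths
    pirna_pos: dict[tuple[str, str], set[int]] = defaultdict(set)
    nineteen_pos: dict[tuple[str, str], set[int]] = defaultdict(set)
    for cr in classified:
        aln = cr.alignment
        if lo <= aln.length <= hi:
            pirna_pos[(aln.ref_id, aln.strand)].add(aln.five_prime())
        elif aln.length == 19:
            nineteen_pos[(aln.ref_id, aln.strand)].add(aln.five_prime())

    rows = []
    agg: Counter = Counter()
    for cr in classified:
        aln = cr.alignment
        if aln.length != 19:
            continue
        d = 1 if aln.strand == "+" else -1
        opp = "-" if aln.strand == "+" else "+"
        s5 = aln.five_prime()
        adjacent = (s5 + 19 * d) in pirna_pos.get((aln.ref_id, aln.strand), ())
        antisense = (s5 + 28 * d) in pirna_pos.get((aln.ref_id, opp), ())
        rows.append(
            {
                "read_id": aln.read_id,
                "class": cr.read_class.value,
                "strand": aln.strand,
                "count": aln.count,
                "adjacent": adjacent,
                "antisense": antisense,
            }
        )
        agg[(aln.strand, "total")] += aln.count
        if adjacent:
            agg[(aln.strand, "adjacent")] += aln.count
        if antisense:
            agg[(aln.strand, "antisense")] += aln.count
        if adjacent or antisense:
            agg[(aln.strand, "either")] += aln.count
    per_read = pd.DataFrame(
        rows, columns=["read_id", "class", "strand", "count",
                       "adjacent", "antisense"]
    )
    summary_rows = []
    for strand in sorted({s for s, _ in agg}):
        total = agg[(strand, "total")]
        row = {"strand": strand, "n_19mers": total}
        for what in ("adjacent", "antisense", "either"):
            n = agg[(strand, what)]
            row[f"n_{what}"] = n
            row[f"pct_{what}"] = percent(n, total)
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    recip_rows = []
    for cls, same_sense in ((ReadClass.S_PIRNA, True), (ReadClass.P_PIRNA, False)):
        total = flagged = 0
        for cr in classified:
            if cr.read_class is not cls:
                continue
            aln = cr.alignment
            d = 1 if aln.strand == "+" else -1
            q5 = aln.five_prime()
            if same_sense:
                # adjacent: 19mer on the same strand ending just 5' of us
                hit = (q5 - 19 * d) in nineteen_pos.get((aln.ref_id, aln.strand), ())
            else:
                # our 5' end 10 nt downstream of an opposite-strand 19mer's 3' end
                opp = "-" if aln.strand == "+" else "+"
                hit = (q5 + 28 * d) in nineteen_pos.get((aln.ref_id, opp), ())
            total += aln.count
            if hit:
                flagged += aln.count
        recip_rows.append(
            {
                "class": cls.value,
                "configuration": "adjacent" if same_sense else "antisense",
                "n_total": total,
                "n_in_configuration": flagged,
                "pct": percent(flagged, total),
            }
        )
    reciprocal = pd.DataFrame(recip_rows)
    return ConfigurationReport(per_read, summary, reciprocal)


def coverage_density(
    classified: Iterable[ClassifiedRead],
    reference_length: int,
    classes: Sequence[ReadClass] | None = None,
    smooth_bandwidth: float = 0.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Copy-weighted 5'-end counts per reference position.

    Returns (class value, strand) -> array of length ``reference_length``.
    Only the 5' ends of reads contribute. Optional Gaussian smoothing with
    the given bandwidth (positions); default off.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    for cr in classified:
        if classes is not None and cr.read_class not in classes:
            continue
        aln = cr.alignment
        key = (cr.read_class.value, aln.strand)
        if key not in out:
            out[key] = np.zeros(reference_length)
        out[key][aln.five_prime()] += aln.count
    if smooth_bandwidth > 0:
        from scipy.ndimage import gaussian_filter1d

        out = {k: gaussian_filter1d(v, smooth_bandwidth) for k, v in out.items()}
    return out


def rpm(count: float, library_mappable_total: float) -> float:
    """Reads-per-million normalisation against the library's mappable total."""
    if library_mappable_total <= 0:
        raise ValueError("library mappable total must be positive")
    return count * 1e6 / library_mappable_total


def fold_change_ddct(
    ct_target_1: float, ct_ref_1: float, ct_target_2: float, ct_ref_2: float
) -> float:
    """Relative abundance by the 2^-ddCt method.

    Condition 1 vs condition 2, each normalised to its reference-gene Ct:
    2 ** -((ct_target_1 - ct_ref_1) - (ct_target_2 - ct_ref_2)).
    """
    for ct in (ct_target_1, ct_ref_1, ct_target_2, ct_ref_2):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_1 - ct_ref_1) - (ct_target_2 - ct_ref_2)
    return 2.0 ** -ddct
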