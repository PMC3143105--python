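"""Genome-wide 19mer annotation.

Multi-mapping reads aligning to fewer than ``max_loci`` loci are assigned
uniformly at random to a single locus (seeded, hence reproducible); reads at
or above the threshold are discarded and reported. Each retained locus is
binned by the identity of the 10th base downstream of its 3' end and
annotated against prioritised interval tracks (repeats first, then piRNA
clusters, then genes); the overlap test uses the read's 5'-end base so reads
straddling a feature boundary are assigned unambiguously.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, ReferenceSet

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

BASE_BINS = ("A", "C", "G", "T", "N")


@dataclass
class AnnotationTrack:
    """A named, prioritised set of category-labelled intervals.

    Priority rank 1 is consulted first. The category of a hit is the
    interval's ``name`` field (e.g. LINE/LTR/SINE sub-categories for the
    repeat track); intervals with empty names fall back to the track name.
    """

    name: str
    priority: int
    intervals: Sequence[GenomicInterval]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list] = defaultdict(list)
        for iv in self.intervals:
            by_chrom[iv.chrom].append((iv.start, iv.end, iv.name or self.name))
        self._trees = {
            chrom: IntervalTree.from_tuples(items)
            for chrom, items in by_chrom.items()
        }

    def category_at(self, chrom: str, position: int) -> str | None:
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[position]
        if not hits:
            return None
        # deterministic tie-break: longest interval, then leftmost
        best = min(hits, key=lambda h: (-(h.end - h.begin), h.begin))
        return best.data


@dataclass
class MappingTotals:
    """Unique/multi-mapper bookkeeping for an annotation run."""

    unique: int = 0
    multi: int = 0
    discarded: int = 0

    @property
    def total(self) -> int:
        """All retained reads (unique + multi-mapping, after the locus cap)."""
        return self.unique + self.multi


def assign_multimappers(
    read_to_loci: Mapping[str, Sequence[GenomicInterval]],
    max_loci: int = 6,
    seed: int = 0,
) -> tuple[dict[str, GenomicInterval], list[str]]:
    """Assign each read one locus; discard reads with >= max_loci loci.

    Reads with a single locus keep it; others draw uniformly at random with
    the given seed (deterministic across runs). Returns (assignments,
    discarded read ids).
    """
    rng = np.random.default_rng(seed)
    assigned: dict[str, GenomicInterval] = {}
    discarded: list[str] = []
    for read_id in sorted(read_to_loci):
        loci = read_to_loci[read_id]
        if not loci:
            raise ValueError(f"read {read_id!r}: empty locus list")
        if len(loci) >= max_loci:
            discarded.append(read_id)
        elif len(loci) == 1:
            assigned[read_id] = loci[0]
        else:
            assigned[read_id] = loci[rng.integers(len(loci))]
    return assigned, discarded


def tenth_downstream_base(locus: GenomicInterval, genome: ReferenceSet) -> str:
    """Base 10 nt downstream of the locus's 3' end, in read orientation.

    For '+' the genome base at ``end + 9``; for '-' the complement of the
    base at ``start - 10``. Positions off the chromosome return 'N'.
    """
    if locus.chrom not in genome:
        raise KeyError(f"unknown chromosome {locus.chrom!r}")
    seq = genome[locus.chrom]
    if len(locus) != 19:
        import logging

        logging.getLogger(__name__).warning(
            "tenth_downstream_base on a %d nt locus", len(locus)
        )
    if locus.strand == "-":
        pos = locus.start - 10
        return _COMPLEMENT[seq[pos]] if 0 <= pos < len(seq) else "N"
    pos = locus.end + 9
    return seq[pos] if 0 <= pos < len(seq) else "N"


def annotate_locus(
    locus: GenomicInterval, tracks: Sequence[AnnotationTrack]
) -> str:
    """Category of the first (highest-priority) track containing the locus's
    5'-end base; 'unannotated' when nothing overlaps."""
    position = locus.five_prime()
    for track in sorted(tracks, key=lambda t: t.priority):
        category = track.category_at(locus.chrom, position)
        if category is not None:
            return category
    return "unannotated"


@dataclass
class AnnotationReport:
    """Per-(category x 10th-downstream-base) counts plus mapping totals."""

    table: pd.DataFrame
    totals: MappingTotals
    per_read: pd.DataFrame


def annotate_genome_19mers(
    read_to_loci: Mapping[str, Sequence[GenomicInterval]],
    genome: ReferenceSet,
    tracks: Sequence[AnnotationTrack],
    seed: int = 0,
    read_counts: Mapping[str, int] | None = None,
    max_loci: int = 6,
) -> AnnotationReport:
    """Assign, bin and annotate a genome-mapped 19mer library.

    ``read_to_loci`` maps read id -> candidate loci (one entry per mapped
    locus). ``read_counts`` supplies copy weights (default 1). The table has
    one row per category with columns A/C/G/T/N (10th-downstream-base bins)
    plus a total; the report also carries unique/multi/discarded totals.
    """
    counts = read_counts or {}
    assigned, discarded_ids = assign_multimappers(read_to_loci, max_loci, seed)
    discarded_set = set(discarded_ids)
    totals = MappingTotals()
    for read_id in read_to_loci:
        w = counts.get(read_id, 1)
        if read_id in discarded_set:
            totals.discarded += w
        elif len(read_to_loci[read_id]) == 1:
            totals.unique += w
        else:
            totals.multi += w
    tally: Counter = Counter()
    rows = []
    for read_id, locus in assigned.items():
        w = counts.get(read_id, 1)
        base = tenth_downstream_base(locus, genome)
        category = annotate_locus(locus, tracks)
        tally[(category, base)] += w
        rows.append(
            {
                "read_id": read_id,
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "strand": locus.strand,
                "category": category,
                "tenth_downstream_base": base,
                "count": w,
            }
        )
    categories = sorted({cat for cat, _ in tally})
    table = pd.DataFrame(0, index=categories, columns=list(BASE_BINS))
    for (category, base), n in tally.items():
        table.loc[category, base] += n
    table["total"] = table.sum(axis=1)
    table.index.name = "category"
    per_read = pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "start", "end", "strand", "category",
                 "tenth_downstream_base", "count"],
    )
    return AnnotationReport(table, totals, per_read)
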