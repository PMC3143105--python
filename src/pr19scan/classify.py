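"""Motif-based classification of aligned reads.

Each aligned read is assigned exactly one class from its length, internal
bases, and the reference bases flanking its 3' end:

* exact 19mers with U immediately downstream -> ``PR19_U1`` (released by
  secondary-piRNA-guided cleavage);
* exact 19mers with no downstream U but A at downstream position 10 ->
  ``PR19_A10`` (the canonical pr19RNA motif N19·V·N8·A);
* remaining 19mers -> ``OTHER_19MER``;
* 24-30 nt reads with 5' U and no A at read position 10 -> ``P_PIRNA``
  (primary piRNA motif U·N8·B);
* 24-30 nt reads with A at position 10 and no 5' U -> ``S_PIRNA``
  (secondary piRNA motif V·N8·A);
* 24-30 nt reads satisfying both or neither motif -> ``PIRNA_AMBIGUOUS``;
* everything else -> ``OTHER``.

Read positions 1 and 10 of the motifs are string indices 0 and 9. Flanks
are taken in read orientation: for a '-' strand alignment the downstream
flank is the reverse complement of the reference upstream of ``start``.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    ClassifiedRead,
    ConsensusAlignment,
    FlankedRead,
    ReadClass,
    ReferenceSet,
    revcomp,
)

PIRNA_LENGTH_RANGE = (24, 30)


def extract_flanks(
    alignment: ConsensusAlignment, reference: str, flank_length: int = 10
) -> FlankedRead:
    """Attach fixed-length reference flanks in read orientation.

    Positions beyond the reference edge are filled with 'N'. For '+'
    alignments ``down_flank`` is ``reference[end:end+F]``; for '-' it is the
    reverse complement of ``reference[start-F:start]``.
    """
    start, end, F = alignment.start, alignment.end, flank_length
    if end > len(reference):
        raise ValueError("alignment extends past the reference")

    def slice_padded(lo: int, hi: int) -> str:
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(reference))
        return "N" * left_pad + reference[max(lo, 0): min(hi, len(reference))] + "N" * right_pad

    if alignment.strand == "+":
        up = slice_padded(start - F, start)
        down = slice_padded(end, end + F)
        read_seq = alignment.sequence or reference[start:end]
    else:
        up = revcomp(slice_padded(end, end + F))
        down = revcomp(slice_padded(start - F, start))
        read_seq = alignment.sequence or revcomp(reference[start:end])
    return FlankedRead(alignment=alignment, read_sequence=read_seq,
                       up_flank=up, down_flank=down)


def classify_read(flanked: FlankedRead) -> ClassifiedRead:
    """Assign the read class; a total function (every read gets one label)."""
    if flanked.flank_length < 10:
        raise ValueError("classification needs flanks of length >= 10")
    seq = flanked.read_sequence
    length = len(seq)
    down = flanked.down_flank
    if length == 19:
        if "N" in (down[0], down[9]):
            return ClassifiedRead(flanked, ReadClass.OTHER_19MER, edge=True)
        if down[0] == "T":
            return ClassifiedRead(flanked, ReadClass.PR19_U1)
        if down[9] == "A":
            return ClassifiedRead(flanked, ReadClass.PR19_A10)
        return ClassifiedRead(flanked, ReadClass.OTHER_19MER)
    if PIRNA_LENGTH_RANGE[0] <= length <= PIRNA_LENGTH_RANGE[1]:
        u1 = seq[0] == "T"
        a10 = seq[9] == "A"
        if u1 and not a10:
            return ClassifiedRead(flanked, ReadClass.P_PIRNA)
        if a10 and not u1:
            return ClassifiedRead(flanked, ReadClass.S_PIRNA)
        return ClassifiedRead(flanked, ReadClass.PIRNA_AMBIGUOUS)
    return ClassifiedRead(flanked, ReadClass.OTHER)


def classify_library(
    alignments: Iterable[ConsensusAlignment],
    references: ReferenceSet | str,
    flank_length: int = 10,
    copy_weighted: bool = True,
) -> tuple[list[ClassifiedRead], pd.DataFrame]:
    """Classify every alignment and summarise per class/strand/length.

    Summary counts are copy-weighted by default (each collapsed read
    contributes its copy count); set ``copy_weighted=False`` to count unique
    sequences instead. Returns (classified reads, summary table with columns
    class, strand, length, count).
    """
    classified: list[ClassifiedRead] = []
    tally: Counter = Counter()
    for aln in alignments:
        ref = references if isinstance(references, str) else references[aln.ref_id]
        cr = classify_read(extract_flanks(aln, ref, flank_length))
        classified.append(cr)
        weight = aln.count if copy_weighted else 1
        tally[(cr.read_class.value, aln.strand, aln.length)] += weight
    rows = [
        {"class": cls, "strand": strand, "length": length, "count": n}
        for (cls, strand, length), n in sorted(tally.items())
    ]
    summary = pd.DataFrame(rows, columns=["class", "strand", "length", "count"])
    return classified, summary


def classified_to_table(classified: Sequence[ClassifiedRead]) -> pd.DataFrame:
    """Per-read table for the classify CLI output."""
    rows = []
    for cr in classified:
        aln = cr.alignment
        rows.append(
            {
                "read_id": aln.read_id,
                "ref_id": aln.ref_id,
                "start": aln.start,
                "end": aln.end,
                "strand": aln.strand,
                "length": aln.length,
                "count": aln.count,
                "unique": aln.unique,
                "class": cr.read_class.value,
                "edge": cr.edge,
                "down_flank": cr.flanked.down_flank,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "ref_id", "start", "end", "strand", "length",
                 "count", "unique", "class", "edge", "down_flank"],
    )
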