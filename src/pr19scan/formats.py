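"""Readers and writers for the external formats the pipeline touches.

All coordinates are normalised to 0-based half-open on ingestion; SAM
(1-based) and fixedStep wiggle (1-based) are converted at the boundary.
The SAM dialect is deliberately minimal: end-to-end short-read placements
with all-match CIGAR strings; records with indels/clips are skipped with a
warning, as are unmapped records.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .core import (
    ConsensusAlignment,
    GenomicInterval,
    ReferenceSet,
    ShortRead,
    normalize_sequence,
    revcomp,
)

logger = logging.getLogger(__name__)

# collapsed-read id convention: trailing _xN carries the copy count
_COUNT_RE = re.compile(r"[_-]x(\d+)$")


class ParseError(ValueError):
    pass


def _count_from_id(read_id: str) -> int:
    m = _COUNT_RE.search(read_id)
    return int(m.group(1)) if m else 1


def _guess_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".fastq", ".fq"):
        return "fastq"
    return "fasta"


def read_sequences(
    path: str | Path,
    format: str | None = None,
    collapse: bool = False,
    parse_counts: bool = True,
) -> list[ShortRead]:
    """Read small-RNA reads from FASTA/FASTQ.

    Sequences are uppercased with U->T; FASTQ qualities are discarded. With
    ``collapse=True`` identical sequences are merged and their copy counts
    summed. Read ids ending in ``_xN`` carry copy count N (common collapsed
    FASTA convention); disable with ``parse_counts=False``.
    """
    fmt = format or _guess_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    reads: list[ShortRead] = []
    for i, record in enumerate(SeqIO.parse(str(path), fmt), start=1):
        try:
            count = _count_from_id(record.id) if parse_counts else 1
            reads.append(ShortRead(record.id, str(record.seq), count))
        except ValueError as exc:
            raise ParseError(f"{path}: record {i} ({record.id!r}): {exc}") from exc
    if not reads:
        logger.warning("%s: no sequences read", path)
    if collapse:
        merged: dict[str, ShortRead] = {}
        for read in reads:
            hit = merged.get(read.sequence)
            if hit is None:
                merged[read.sequence] = read
            else:
                hit.count += read.count
        reads = list(merged.values())
    return reads


def read_reference(path: str | Path) -> ReferenceSet:
    """Read reference sequences (consensus repeats or a genome) from FASTA."""
    refs = ReferenceSet()
    for record in SeqIO.parse(str(path), "fasta"):
        refs.add(record.id, str(record.seq))
    if not refs:
        logger.warning("%s: empty reference FASTA", path)
    return refs


def write_fasta(reads: Iterable[ShortRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f">{read.id}\n{read.sequence}\n")


_ALL_MATCH_CIGAR = re.compile(r"^(\d+)M$")


def read_alignments_sam(
    path: str | Path, references: ReferenceSet
) -> list[ConsensusAlignment]:
    """Import alignments from minimal SAM (header optional).

    Only FLAG bit 0x10, RNAME, POS, SEQ are used; the CIGAR must be a single
    match run (e.g. ``19M``). POS is converted from 1-based to a 0-based
    start. For reverse-strand records the stored read sequence is the reverse
    complement of SEQ so that it reads 5'->3'. Records with indel/clip
    CIGARs or unmapped flags are skipped with a logged warning; records
    naming a reference absent from ``references`` are rejected.
    """
    alignments: list[ConsensusAlignment] = []
    skipped = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(f"{path}:{lineno}: truncated SAM record")
            qname, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
            seq = fields[9]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad FLAG/POS") from exc
            if flag & 0x4 or rname == "*":
                skipped += 1
                logger.warning("%s:%d: unmapped record skipped", path, lineno)
                continue
            if not _ALL_MATCH_CIGAR.match(cigar):
                skipped += 1
                logger.warning(
                    "%s:%d: CIGAR %r not all-match, record skipped",
                    path, lineno, cigar,
                )
                continue
            if rname not in references:
                raise ParseError(
                    f"{path}:{lineno}: reference {rname!r} not in reference set"
                )
            seq = normalize_sequence(seq)
            strand = "-" if flag & 0x10 else "+"
            start = pos - 1
            nm = 0
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            alignments.append(
                ConsensusAlignment(
                    read_id=qname,
                    ref_id=rname,
                    start=start,
                    end=start + len(seq),
                    strand=strand,
                    sequence=revcomp(seq) if strand == "-" else seq,
                    mismatches=nm,
                    count=_count_from_id(qname),
                )
            )
    if skipped:
        logger.info("%s: %d record(s) skipped", path, skipped)
    return alignments


def write_alignments_sam(
    alignments: Sequence[ConsensusAlignment],
    references: ReferenceSet,
    path: str | Path,
) -> None:
    """Write alignments as minimal SAM with @SQ header lines."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references.lengths().items():
            handle.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for aln in alignments:
            flag = 16 if aln.strand == "-" else 0
            seq = revcomp(aln.sequence) if aln.strand == "-" else aln.sequence
            handle.write(
                f"{aln.read_id}\t{flag}\t{aln.ref_id}\t{aln.start + 1}\t255\t"
                f"{aln.length}M\t*\t0\t0\t{seq}\t*\tNM:i:{aln.mismatches}\n"
            )


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3-BED6 intervals; strand defaults to '.'.

    Records with start >= end are rejected with an error naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: need at least 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand, name, score)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_intervals_bed(
    intervals: Iterable[GenomicInterval], path: str | Path
) -> None:
    """Write intervals as BED6 (round-trip identity with the reader)."""
    with open(path, "w") as handle:
        for iv in intervals:
            score = "0" if iv.score is None else (
                str(int(iv.score)) if float(iv.score).is_integer() else str(iv.score)
            )
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: need two columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, length in sizes.items():
            handle.write(f"{name}\t{length}\n")


def write_wiggle(
    per_position_values: Sequence[float],
    chrom: str,
    path: str | Path,
    start: int = 0,
) -> None:
    """Write a density track as fixedStep wiggle (step 1).

    ``start`` is 0-based; the wiggle header is emitted 1-based.
    """
    for value in per_position_values:
        if not math.isfinite(value):
            raise ValueError("wiggle values must be finite")
    with open(path, "w") as handle:
        handle.write(f"fixedStep chrom={chrom} start={start + 1} step=1\n")
        for value in per_position_values:
            handle.write(f"{value:g}\n")


def write_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write a count/statistic table as TSV with a header line."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)
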