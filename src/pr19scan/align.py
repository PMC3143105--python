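"""Self-contained short-read mapper for small references.

End-to-end, substitution-only placements (no indels) on either strand, with
at most 0-2 mismatches — the behaviour of a ``-v``-mode aligner. Candidate
placements are found by exact k-mer seeding with the pigeonhole guarantee
(k = floor(len/(mm+1)): any placement with <= mm mismatches contains at
least one mismatch-free chunk), then verified by direct comparison.
An ambiguity base N never matches anything, including another N, so N-padded
regions cannot create artefactual placements.

Also builds the composite LTR-internal-LTR retrotransposon reference used
for mapping reads across element boundaries.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import ConsensusAlignment, ReferenceSet, ShortRead, revcomp


def build_composite_reference(ltr_sequence: str, internal_sequence: str) -> str:
    """Concatenate LTR + internal + LTR into one composite element."""
    if not ltr_sequence or not internal_sequence:
        raise ValueError("LTR and internal sequences must be non-empty")
    return ltr_sequence + internal_sequence + ltr_sequence


def _mismatches(read: str, ref: str, start: int, budget: int) -> int:
    """Count substitutions of read vs ref[start:start+len(read)].

    N on either side always counts as a mismatch. Returns budget+1 early
    once the budget is exceeded.
    """
    n = 0
    for i, base in enumerate(read):
        r = ref[start + i]
        if base != r or base == "N":
            n += 1
            if n > budget:
                return n
    return n


class ReferenceIndex:
    """Exact k-mer index over one reference sequence."""

    def __init__(self, sequence: str, k: int) -> None:
        self.sequence = sequence
        self.k = k
        self.index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(sequence) - k + 1):
            self.index[sequence[i : i + k]].append(i)


@dataclass
class MappingResult:
    """Alignments for one read, with the multi-hit suppression flag."""

    alignments: list[ConsensusAlignment]
    exceeded_max_hits: bool = False


def _scan_one_strand(
    read_seq: str,
    ref_seq: str,
    index: Mapping[str, list[int]] | None,
    k: int,
    max_mismatches: int,
) -> list[tuple[int, int]]:
    """All (start, mismatches) placements of read_seq on the forward ref."""
    n_chunks = max_mismatches + 1
    candidates: set[int] = set()
    if index is not None and k >= 1:
        for c in range(n_chunks):
            off = c * k
            chunk = read_seq[off : off + k]
            if len(chunk) < k:
                break
            for pos in index.get(chunk, ()):
                start = pos - off
                if 0 <= start <= len(ref_seq) - len(read_seq):
                    candidates.add(start)
    else:  # degenerate k: fall back to a full scan
        candidates = set(range(len(ref_seq) - len(read_seq) + 1))
    hits = []
    for start in sorted(candidates):
        mm = _mismatches(read_seq, ref_seq, start, max_mismatches)
        if mm <= max_mismatches:
            hits.append((start, mm))
    return hits


def map_read(
    read: ShortRead | str,
    reference: str,
    ref_id: str = "ref",
    max_mismatches: int = 0,
    max_hits: int = 50000,
    _index: ReferenceIndex | None = None,
) -> MappingResult:
    """All end-to-end placements of a read on either strand of a reference.

    If the number of placements exceeds ``max_hits`` the read is suppressed:
    the result carries no alignments and ``exceeded_max_hits=True``.
    """
    if isinstance(read, str):
        read = ShortRead("read", read)
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1 or 2")
    if len(read.sequence) > len(reference):
        raise ValueError("read longer than reference")
    k = len(read.sequence) // (max_mismatches + 1)
    if _index is not None and _index.k == k:
        index = _index.index
    elif k >= 1:
        index = ReferenceIndex(reference, k).index
    else:
        index = None
    fwd = _scan_one_strand(read.sequence, reference, index, k, max_mismatches)
    rc = revcomp(read.sequence)
    rev = _scan_one_strand(rc, reference, index, k, max_mismatches)
    alignments = [
        ConsensusAlignment(
            read_id=read.id,
            ref_id=ref_id,
            start=start,
            end=start + len(read.sequence),
            strand="+",
            sequence=read.sequence,
            mismatches=mm,
            count=read.count,
        )
        for start, mm in fwd
    ] + [
        ConsensusAlignment(
            read_id=read.id,
            ref_id=ref_id,
            start=start,
            end=start + len(read.sequence),
            strand="-",
            sequence=read.sequence,
            mismatches=mm,
            count=read.count,
        )
        for start, mm in rev
    ]
    if len(alignments) > max_hits:
        return MappingResult([], exceeded_max_hits=True)
    for aln in alignments:
        aln.unique = len(alignments) == 1
    return MappingResult(alignments)


@dataclass
class LibraryMapping:
    """Alignments plus the unmapped/suppressed report for a read library."""

    alignments: list[ConsensusAlignment]
    unmapped: list[str] = field(default_factory=list)
    suppressed: list[str] = field(default_factory=list)

    @property
    def mapped_read_ids(self) -> set[str]:
        return {aln.read_id for aln in self.alignments}


def map_library(
    reads: Sequence[ShortRead],
    references: ReferenceSet,
    max_mismatches: int = 0,
    max_hits: int = 50000,
) -> LibraryMapping:
    """Map every read against every reference in the set.

    A read's hit count is totalled across references before the max_hits
    suppression is applied; ``unique`` flags reflect the library-wide total.
    """
    indices = {}
    by_len: dict[int, dict[str, ReferenceIndex]] = {}
    result = LibraryMapping(alignments=[])
    for read in reads:
        k = len(read.sequence) // (max_mismatches + 1)
        per_ref = by_len.setdefault(k, {})
        hits: list[ConsensusAlignment] = []
        exceeded = False
        for name, seq in references.items():
            if len(read.sequence) > len(seq):
                continue
            if name not in per_ref:
                per_ref[name] = ReferenceIndex(seq, k) if k >= 1 else None
            res = map_read(
                read, seq, ref_id=name, max_mismatches=max_mismatches,
                max_hits=max_hits, _index=per_ref[name],
            )
            if res.exceeded_max_hits:
                exceeded = True
                break
            hits.extend(res.alignments)
        if exceeded or len(hits) > max_hits:
            result.suppressed.append(read.id)
        elif not hits:
            result.unmapped.append(read.id)
        else:
            for aln in hits:
                aln.unique = len(hits) == 1
            result.alignments.extend(hits)
    return result


def two_pass_map(
    reads: Sequence[ShortRead],
    repeat_database: ReferenceSet,
    consensus: ReferenceSet,
    pass1_max_hits: int = 50000,
    pass2_max_mismatches: int = 2,
    pass2_max_hits: int = 10,
) -> tuple[LibraryMapping, LibraryMapping]:
    """The two-pass protocol: exact mapping to a full repeat database to
    select likely repeat-derived reads, then a <=2-mismatch remap of those
    reads to the consensus sequence.

    Returns (pass1, pass2) mappings; pass 2 only sees reads mapped in pass 1.
    """
    pass1 = map_library(reads, repeat_database, max_mismatches=0,
                        max_hits=pass1_max_hits)
    selected_ids = pass1.mapped_read_ids
    selected = [r for r in reads if r.id in selected_ids]
    pass2 = map_library(selected, consensus,
                        max_mismatches=pass2_max_mismatches,
                        max_hits=pass2_max_hits)
    return pass1, pass2
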