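"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open. The internal alphabet is DNA
(``T``, never ``U``); any ``U`` in input sequences is converted on ingestion.
For a minus-strand alignment the 5' coordinate is the *rightmost* covered
reference base (``end - 1``); this convention is used consistently for offset
spectra, coverage densities and tile membership.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(sequence: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return sequence.upper().replace("U", "T")


class ReadClass(enum.Enum):
    """Read classes assigned from length, internal bases and flanking bases.

    * ``PR19_A10`` — exact 19mer with A 10 nt downstream of its 3' end and no
      U immediately downstream (motif N19·V·N8·A): the canonical pr19RNA.
    * ``PR19_U1`` — exact 19mer with U immediately downstream of its 3' end,
      the product of secondary-piRNA-guided cleavage.
    * ``OTHER_19MER`` — any other exact 19mer.
    * ``P_PIRNA`` — 24-30 nt read with 5' U and no A at position 10 (U·N8·B).
    * ``S_PIRNA`` — 24-30 nt read with A at position 10 and no 5' U (V·N8·A).
    * ``PIRNA_AMBIGUOUS`` — 24-30 nt read satisfying both or neither piRNA
      motif.
    * ``OTHER`` — everything else.
    """

    PR19_A10 = "pr19_A10"
    PR19_U1 = "pr19_U1"
    OTHER_19MER = "other_19mer"
    P_PIRNA = "p_piRNA"
    S_PIRNA = "s_piRNA"
    PIRNA_AMBIGUOUS = "piRNA_ambiguous"
    OTHER = "other"


@dataclass
class ShortRead:
    """A (possibly collapsed) small-RNA sequence with its copy count."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )
        if self.count < 1:
            raise ValueError(f"read {self.id!r}: count must be positive")

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceSet(Mapping[str, str]):
    """Named reference sequences (consensus repeats or a genome).

    Sequences are uppercased DNA over {A,C,G,T,N}; U is converted to T.
    Names must be unique and sequences non-empty.
    """

    def __init__(self, sequences: Mapping[str, str] | None = None) -> None:
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    def add(self, name: str, sequence: str) -> None:
        if name in self._seqs:
            raise ValueError(f"duplicate reference name {name!r}")
        seq = normalize_sequence(sequence)
        if not seq:
            raise ValueError(f"reference {name!r} is empty")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"reference {name!r}: invalid characters {sorted(bad)}")
        self._seqs[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}


@dataclass
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """5'-end coordinate ('-' strand: the rightmost base)."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass
class ConsensusAlignment:
    """End-to-end placement of a read on a reference.

    ``sequence`` is the read 5'->3' (for '-' strand placements it is the
    reverse complement of the reference slice). ``unique`` marks reads that
    align to a single locus; multi-mappers carry ``unique=False``.
    """

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    sequence: str = ""
    mismatches: int = 0
    count: int = 1
    unique: bool = True

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"alignment {self.read_id!r}: need 0 <= start < end, "
                f"got [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"alignment {self.read_id!r}: strand must be +/-")
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"alignment {self.read_id!r}: sequence length "
                f"{len(self.sequence)} != span {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Reference coordinate of the read's 5' end."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass
class FlankedRead:
    """An alignment plus fixed-length reference flanks in read orientation.

    ``down_flank[0]`` is the base immediately 3' of the read;
    ``down_flank[F-1]`` is the F-th downstream base. Positions beyond the
    reference edge are 'N'.
    """

    alignment: ConsensusAlignment
    read_sequence: str
    up_flank: str
    down_flank: str

    def __post_init__(self) -> None:
        if len(self.up_flank) != len(self.down_flank):
            raise ValueError("up_flank and down_flank must have equal length")

    @property
    def flank_length(self) -> int:
        return len(self.down_flank)


@dataclass
class ClassifiedRead:
    """A flanked read with its assigned class."""

    flanked: FlankedRead
    read_class: ReadClass
    edge: bool = False  # flank ran off the reference where the motif looks

    @property
    def alignment(self) -> ConsensusAlignment:
        return self.flanked.alignment


@dataclass
class TileCounts:
    """Per-tile, per-strand copy-weighted counts of uniquely mapping reads."""

    tile: GenomicInterval
    strand: str
    pr19_a10: float = 0.0
    other_19mer: float = 0.0
    s_pirna: float = 0.0
    p_pirna: float = 0.0
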