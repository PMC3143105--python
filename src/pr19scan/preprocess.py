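"""Read-exclusion rules applied before mapping.

Three contamination/artefact filters:

* homopolymer runs longer than 8 nt (strict: a run of 9+ identical bases);
* a tRNA-derived fragment, matched by default in both orientations;
* simple-repeat tetramers (GGA)4/(CCT)4/(GAA)4/(CTT)4 which cause mapping
  artefacts against simple repeats inside LINE elements — applied only in
  LINE mode.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from .core import ShortRead, revcomp

TRNA_FRAGMENT = "CCGGGTTTCGGCACC"

SIMPLE_REPEAT_PATTERNS = ("GGA" * 4, "CCT" * 4, "GAA" * 4, "CTT" * 4)


def has_long_homopolymer(sequence: str, max_run: int = 8) -> bool:
    """True iff some single-base run is strictly longer than ``max_run``."""
    if not sequence:
        raise ValueError("empty sequence")
    return re.search(r"(.)\1{%d,}" % max_run, sequence) is not None


def matches_trna_fragment(sequence: str, both_orientations: bool = True) -> bool:
    """True iff the tRNA-derived fragment occurs in the read.

    By default the reverse complement of the pattern is also matched (the
    conservative contamination filter); restrict to forward-only with
    ``both_orientations=False``.
    """
    if TRNA_FRAGMENT in sequence:
        return True
    return both_orientations and revcomp(TRNA_FRAGMENT) in sequence


def matches_simple_repeat(
    sequence: str, patterns: Sequence[str] = SIMPLE_REPEAT_PATTERNS
) -> bool:
    """True iff any simple-repeat pattern occurs as a substring."""
    return any(p in sequence for p in patterns)


def filter_reads(
    reads: Iterable[ShortRead],
    mode: str = "general",
    max_run: int = 8,
    trna_both_orientations: bool = True,
) -> tuple[list[ShortRead], dict[str, int]]:
    """Apply the exclusion rules; return kept reads and per-rule removal counts.

    ``mode`` is ``general`` or ``line``; the simple-repeat rule is active only
    in LINE mode. A removed read is attributed to the first rule that fires
    (homopolymer, then tRNA fragment, then simple repeat), so
    kept + sum(removed) equals the input record count.
    """
    if mode not in ("general", "line"):
        raise ValueError(f"unknown filter mode {mode!r}")
    kept: list[ShortRead] = []
    removed = {"homopolymer": 0, "trna_fragment": 0, "simple_repeat": 0}
    for read in reads:
        if has_long_homopolymer(read.sequence, max_run):
            removed["homopolymer"] += 1
        elif matches_trna_fragment(read.sequence, trna_both_orientations):
            removed["trna_fragment"] += 1
        elif mode == "line" and matches_simple_repeat(read.sequence):
            removed["simple_repeat"] += 1
        else:
            kept.append(read)
    return kept, removed
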