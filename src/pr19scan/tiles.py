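"""Genome tiling, enriched-tile selection and abundance comparison.

The genome is split into non-overlapping 2.5 kb tiles; uniquely mapping
reads are counted per (tile, strand) by the tile containing their 5'-end
base. Tiles where pr19RNAs outnumber other 19mers and s-piRNAs outnumber
p-piRNAs (and both are present) are selected, and the per-tile pr19RNA vs
s-piRNA abundances are compared with a two-sided paired Wilcoxon
signed-rank test.

The signed-rank test is implemented here because its exact behaviour is
part of the contract: midranks for tied |differences|, zero differences
dropped (classic Wilcoxon; Pratt available), exact null enumeration by
dynamic programming for n <= 25 and a tie-corrected normal approximation
with continuity correction above.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core import ClassifiedRead, GenomicInterval, ReadClass, TileCounts

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25

# tile-count buckets: 19mers lacking the A-at-+10 motif (including the
# downstream-U class) count as "other" 19mers
_CLASS_BUCKET = {
    ReadClass.PR19_A10: "pr19_a10",
    ReadClass.PR19_U1: "other_19mer",
    ReadClass.OTHER_19MER: "other_19mer",
    ReadClass.S_PIRNA: "s_pirna",
    ReadClass.P_PIRNA: "p_pirna",
}


def make_tiles(
    chrom_sizes: Mapping[str, int], width: int = 2500
) -> list[GenomicInterval]:
    """Consecutive non-overlapping tiles covering each chromosome.

    The final partial tile is included, so the tiles partition the genome.
    """
    if width <= 0:
        raise ValueError("tile width must be positive")
    tiles = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, width):
            tiles.append(
                GenomicInterval(chrom, start, min(start + width, size), ".")
            )
    return tiles


def count_tiles(
    classified: Iterable[ClassifiedRead],
    tiles: Sequence[GenomicInterval],
    width: int | None = None,
) -> list[TileCounts]:
    """Per-(tile, strand) copy-weighted counts of uniquely mapping reads.

    A read contributes to the tile containing its 5'-end base. Multi-mapping
    reads (``unique=False``) are excluded. Tiles with zero counts are
    retained (with both strands present only if touched).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for tile in tiles:
        by_chrom.setdefault(tile.chrom, []).append(tile)
    for chrom_tiles in by_chrom.values():
        chrom_tiles.sort(key=lambda t: t.start)
    uniform_width = width
    if uniform_width is None:
        widths = {len(t) for t in tiles}
        # partial final tiles are narrower; use the modal full width
        uniform_width = max(widths) if widths else 0

    counts: dict[tuple[str, int, str], TileCounts] = {}

    def tile_for(chrom: str, pos: int) -> GenomicInterval | None:
        chrom_tiles = by_chrom.get(chrom)
        if not chrom_tiles:
            return None
        idx = pos // uniform_width if uniform_width else 0
        if idx < len(chrom_tiles):
            tile = chrom_tiles[idx]
            if tile.start <= pos < tile.end:
                return tile
        for tile in chrom_tiles:  # non-uniform tiling fallback
            if tile.start <= pos < tile.end:
                return tile
        return None

    for tile in tiles:
        for strand in "+-":
            counts[(tile.chrom, tile.start, strand)] = TileCounts(tile, strand)
    for cr in classified:
        aln = cr.alignment
        if not aln.unique:
            continue
        bucket = _CLASS_BUCKET.get(cr.read_class)
        if bucket is None:
            continue
        tile = tile_for(aln.ref_id, aln.five_prime())
        if tile is None:
            continue
        tc = counts[(tile.chrom, tile.start, aln.strand)]
        setattr(tc, bucket, getattr(tc, bucket) + aln.count)
    return list(counts.values())


def tile_counts_table(tile_counts: Iterable[TileCounts]) -> pd.DataFrame:
    rows = [
        {
            "chrom": tc.tile.chrom,
            "start": tc.tile.start,
            "end": tc.tile.end,
            "strand": tc.strand,
            "pr19_a10": tc.pr19_a10,
            "other_19mer": tc.other_19mer,
            "s_pirna": tc.s_pirna,
            "p_pirna": tc.p_pirna,
        }
        for tc in tile_counts
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "pr19_a10",
                       "other_19mer", "s_pirna", "p_pirna"]
    )


def select_enriched_tiles(
    tile_counts: Iterable[TileCounts],
) -> list[TileCounts]:
    """Tiles where pr19RNAs outnumber other 19mers and s-piRNAs outnumber
    p-piRNAs, with both pr19RNAs and s-piRNAs present on that strand."""
    return [
        tc
        for tc in tile_counts
        if tc.pr19_a10 > tc.other_19mer
        and tc.s_pirna > tc.p_pirna
        and tc.pr19_a10 > 0
        and tc.s_pirna > 0
    ]


def _exact_signed_rank_cdf(doubled_ranks: Sequence[int]) -> np.ndarray:
    """Null distribution of the doubled positive-rank sum by DP convolution.

    Ranks are midranks doubled to integers; each is included in the positive
    sum independently with probability 1/2. Returns P(W2 = w) for
    w = 0..sum(doubled_ranks).
    """
    total = int(sum(doubled_ranks))
    probs = np.zeros(total + 1)
    probs[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[: total + 1 - r]
        probs = 0.5 * (probs + shifted)
    return probs


@dataclass
class WilcoxonResult:
    statistic: float  # positive-rank sum W+
    pvalue: float
    n_used: int
    method: str


def paired_wilcoxon(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
    mode: str = "auto",
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on x - y.

    Zero differences are dropped (``zero_method='wilcox'``; ``'pratt'``
    keeps them in the ranking). Tied |differences| receive midranks. The
    null distribution is enumerated exactly for n <= 25 (``mode='auto'``)
    or always (``mode='exact'``); otherwise a normal approximation with tie
    correction and continuity correction is used. If every difference is
    zero the test is degenerate and p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be equal-length, non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = x - y
    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            warnings.warn("all differences zero; test is degenerate")
            return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    elif zero_method != "pratt":
        raise ValueError(f"unknown zero_method {zero_method!r}")
    ranks = rankdata(np.abs(d))
    if zero_method == "pratt":
        nonzero = d != 0
        if not nonzero.any():
            warnings.warn("all differences zero; test is degenerate")
            return WilcoxonResult(0.0, 1.0, 0, "degenerate")
        w_plus = float(ranks[nonzero & (d > 0)].sum())
        used = ranks[nonzero]
        signs_n = int(nonzero.sum())
    else:
        w_plus = float(ranks[d > 0].sum())
        used = ranks
        signs_n = d.size

    exact = mode == "exact" or (mode == "auto" and signs_n <= EXACT_N_MAX)
    if exact:
        doubled = np.rint(2 * used).astype(int)
        pmf = _exact_signed_rank_cdf(doubled)
        w2 = int(round(2 * w_plus))
        p_le = float(pmf[: w2 + 1].sum())
        p_ge = float(pmf[w2:].sum())
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_le, p_ge))
        return WilcoxonResult(w_plus, p, signs_n, "exact")

    mean = used.sum() / 2.0
    var = float(np.square(used).sum()) / 4.0
    if var == 0:
        return WilcoxonResult(w_plus, 1.0, signs_n, "degenerate")
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        p = float(norm.sf(z))
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        p = float(norm.cdf(z))
    else:
        z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / sd
        p = float(min(1.0, 2 * norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, signs_n, "normal")


@dataclass
class RatioSummary:
    ratios: np.ndarray
    median: float
    q1: float
    q3: float
    scatter: pd.DataFrame  # x = s-piRNA count, y = pr19 count per tile


def ratio_summary(selected: Sequence[TileCounts]) -> RatioSummary:
    """Per-tile pr19RNA / s-piRNA abundance ratios with quartiles.

    The scatter table (x = s-piRNA, y = pr19RNA per tile) reproduces the
    genome-wide abundance comparison plot's underlying values.
    """
    if not selected:
        raise ValueError("no tiles selected")
    ratios = np.array([tc.pr19_a10 / tc.s_pirna for tc in selected])
    scatter = pd.DataFrame(
        {
            "chrom": [tc.tile.chrom for tc in selected],
            "start": [tc.tile.start for tc in selected],
            "strand": [tc.strand for tc in selected],
            "s_pirna": [tc.s_pirna for tc in selected],
            "pr19_a10": [tc.pr19_a10 for tc in selected],
            "ratio": ratios,
        }
    )
    q1, med, q3 = np.percentile(ratios, [25, 50, 75])
    return RatioSummary(ratios, float(med), float(q1), float(q3), scatter)
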