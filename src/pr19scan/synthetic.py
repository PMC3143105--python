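"""Synthetic references, annotation tracks and small-RNA libraries with
exact ping-pong / pr19RNA cleavage geometry.

Two cleavage configurations are planted, mirroring the biology:

* configuration A (primary-piRNA guided): an antisense p-piRNA with 5'
  terminal U at sense coordinate ``c`` directs cleavage across from its
  position 10, releasing a sense s-piRNA starting at ``c - 9`` (A at read
  position 10), and a second cleavage 19 nt further upstream releases an
  exact 19mer covering ``[c - 28, c - 9)`` with A 10 nt downstream of its
  3' end (class PR19_A10);
* configuration B (secondary-piRNA guided): the mirrored arrangement — a
  sense p-piRNA starting at ``d`` (5' U), an exact 19mer covering
  ``[d - 19, d)`` with U immediately downstream (class PR19_U1), and an
  antisense s-piRNA whose 5' coordinate is ``d + 9``;

plus unstructured degradation background (uniform positions, strands and
lengths). Every emitted read carries a ground-truth record, and all outputs
are byte-reproducible for a fixed seed.

Site constraints (the bases the motifs require) are enforced by resampling
candidate positions rather than editing the reference, so the reference's
composition statistics stay clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ConsensusAlignment,
    GenomicInterval,
    ReferenceSet,
    ShortRead,
    revcomp,
)

UNIFORM = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}

# unimodal piRNA length weights over 24-30, peaking at 26 (Mili-like IPs)
# or 30 (Miwi-like IPs)
PIRNA_LENGTH_WEIGHTS = {
    "mili": {24: 1, 25: 3, 26: 6, 27: 3, 28: 2, 29: 1, 30: 1},
    "miwi": {24: 1, 25: 1, 26: 1, 27: 2, 28: 3, 29: 5, 30: 6},
}


@dataclass
class SimulationConfig:
    """Parameters of a simulated consensus-mapped small-RNA library.

    ``pr19_to_s_ratio`` scales pr19RNA copy counts relative to their
    partner s-piRNA (the study conditions have pr19RNAs more than twice as
    abundant as s-piRNAs, hence the 2.5 default); ``p_level`` scales
    p-piRNA copies the same way. Copy counts are log-normal (heavy right
    tail typical of small-RNA libraries).
    """

    seed: int
    reference_length: int = 50000
    composition: dict = field(default_factory=lambda: dict(UNIFORM))
    n_events_a: int = 50
    n_events_b: int = 50
    n_background: int = 0
    copy_lognormal_mu: float = 1.0
    copy_lognormal_sigma: float = 0.8
    pirna_length_mode: str = "mili"
    pr19_to_s_ratio: float = 2.5
    p_level: float = 1.0
    background_length_range: tuple[int, int] = (18, 32)
    antisense_fraction: float = 0.0
    min_event_spacing: int = 150  # keeps events outside each other's offset windows
    ref_name: str = "synthetic_consensus"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass
class SimulatedLibrary:
    """Reads plus ground truth for one simulated library."""

    references: ReferenceSet
    reads: list[ShortRead]
    alignments: list[ConsensusAlignment]
    truth: pd.DataFrame  # read_id, true_class, event_id, configuration
    config: SimulationConfig | None = None


def random_reference(
    length: int,
    composition: dict | None = None,
    seed: int = 0,
    name: str = "synthetic_consensus",
) -> ReferenceSet:
    """An i.i.d. random DNA reference at the given base composition."""
    if length <= 100:
        raise ValueError("reference length must exceed 100")
    comp = composition or UNIFORM
    rng = np.random.default_rng(seed)
    bases = sorted(comp)
    seq = "".join(
        rng.choice(bases, size=length, p=[comp[b] for b in bases])
    )
    return ReferenceSet({name: seq})


def _draw_copies(rng: np.random.Generator, mu: float, sigma: float,
                 scale: float = 1.0) -> int:
    return max(1, int(round(scale * rng.lognormal(mu, sigma))))


def _draw_pirna_length(rng: np.random.Generator, mode: str) -> int:
    weights = PIRNA_LENGTH_WEIGHTS[mode]
    lengths = sorted(weights)
    p = np.array([weights[l] for l in lengths], dtype=float)
    return int(rng.choice(lengths, p=p / p.sum()))


def _mk_alignment(read_id: str, ref_id: str, start: int, end: int,
                  strand: str, reference: str, count: int) -> ConsensusAlignment:
    seq = reference[start:end]
    if strand == "-":
        seq = revcomp(seq)
    return ConsensusAlignment(
        read_id=read_id, ref_id=ref_id, start=start, end=end,
        strand=strand, sequence=seq, mismatches=0, count=count,
    )


def _flip(aln: ConsensusAlignment, ref_len: int) -> ConsensusAlignment:
    """Mirror an alignment onto the opposite strand of the reference
    (coordinates reflected, strand swapped, sequence preserved as the read's
    5'->3' sequence on the mirrored strand)."""
    new_start = ref_len - aln.end
    return replace(
        aln,
        start=new_start,
        end=ref_len - aln.start,
        strand="-" if aln.strand == "+" else "+",
    )


def find_config_a_site(reference: str, rng: np.random.Generator,
                       max_tries: int = 10000) -> int:
    """Sample a cleavage coordinate c with sense base A at c and non-T at
    c - 9, leaving room for all three reads."""
    n = len(reference)
    for _ in range(max_tries):
        c = int(rng.integers(40, n - 40))
        if reference[c] == "A" and reference[c - 9] != "T":
            return c
    raise RuntimeError("no valid configuration-A site found")


def find_config_b_site(reference: str, rng: np.random.Generator,
                       max_tries: int = 10000) -> int:
    """Sample a coordinate d with sense base T at d and non-A at d + 9."""
    n = len(reference)
    for _ in range(max_tries):
        d = int(rng.integers(40, n - 45))
        if reference[d] == "T" and reference[d + 9] != "A":
            return d
    raise RuntimeError("no valid configuration-B site found")


def plant_config_A_event(
    reference: str,
    site: int,
    rng: np.random.Generator,
    event_id: str = "A0",
    ref_name: str = "synthetic_consensus",
    pirna_length_mode: str = "mili",
    copy_mu: float = 1.0,
    copy_sigma: float = 0.8,
    pr19_to_s_ratio: float = 2.5,
    p_level: float = 1.0,
    copies: tuple[int, int, int] | None = None,
) -> list[tuple[ConsensusAlignment, str]]:
    """Emit the three reads of a p-piRNA-guided cleavage event at sense
    coordinate ``site`` (= c): antisense p-piRNA with 5' coordinate c, sense
    s-piRNA starting at c - 9, and the sense 19mer covering [c-28, c-9).

    ``copies`` overrides the sampled (pr19, s, p) copy counts. Returns
    (alignment, true class) pairs.
    """
    c = site
    if reference[c] != "A" or reference[c - 9] == "T":
        raise ValueError("site violates configuration-A base constraints")
    if c < 28:
        raise ValueError("site too close to the reference start")
    lp = _draw_pirna_length(rng, pirna_length_mode)
    ls = _draw_pirna_length(rng, pirna_length_mode)
    if copies is None:
        s_copies = _draw_copies(rng, copy_mu, copy_sigma)
        pr_copies = max(1, int(round(pr19_to_s_ratio * s_copies)))
        p_copies = max(1, int(round(p_level * _draw_copies(rng, copy_mu, copy_sigma))))
    else:
        pr_copies, s_copies, p_copies = copies
    out = [
        (
            _mk_alignment(f"{event_id}_pr19", ref_name, c - 28, c - 9, "+",
                          reference, pr_copies),
            "pr19_A10",
        ),
        (
            _mk_alignment(f"{event_id}_s", ref_name, c - 9, c - 9 + ls, "+",
                          reference, s_copies),
            "s_piRNA",
        ),
        (
            _mk_alignment(f"{event_id}_p", ref_name, c - lp + 1, c + 1, "-",
                          reference, p_copies),
            "p_piRNA",
        ),
    ]
    return out


def plant_config_B_event(
    reference: str,
    site: int,
    rng: np.random.Generator,
    event_id: str = "B0",
    ref_name: str = "synthetic_consensus",
    pirna_length_mode: str = "mili",
    copy_mu: float = 1.0,
    copy_sigma: float = 0.8,
    pr19_to_s_ratio: float = 2.5,
    p_level: float = 1.0,
    copies: tuple[int, int, int] | None = None,
) -> list[tuple[ConsensusAlignment, str]]:
    """Emit the three reads of an s-piRNA-guided cleavage event at sense
    coordinate ``site`` (= d): sense p-piRNA starting at d (5' U), the sense
    19mer covering [d-19, d) with U immediately downstream (PR19_U1), and an
    antisense s-piRNA with 5' coordinate d + 9."""
    d = site
    if reference[d] != "T" or reference[d + 9] == "A":
        raise ValueError("site violates configuration-B base constraints")
    if d < 19:
        raise ValueError("site too close to the reference start")
    lp = _draw_pirna_length(rng, pirna_length_mode)
    ls = _draw_pirna_length(rng, pirna_length_mode)
    if copies is None:
        s_copies = _draw_copies(rng, copy_mu, copy_sigma)
        pr_copies = max(1, int(round(pr19_to_s_ratio * s_copies)))
        p_copies = max(1, int(round(p_level * _draw_copies(rng, copy_mu, copy_sigma))))
    else:
        pr_copies, s_copies, p_copies = copies
    out = [
        (
            _mk_alignment(f"{event_id}_pr19", ref_name, d - 19, d, "+",
                          reference, pr_copies),
            "pr19_U1",
        ),
        (
            _mk_alignment(f"{event_id}_p", ref_name, d, d + lp, "+",
                          reference, p_copies),
            "p_piRNA",
        ),
        (
            _mk_alignment(f"{event_id}_s", ref_name, d + 10 - ls, d + 10, "-",
                          reference, s_copies),
            "s_piRNA",
        ),
    ]
    return out


def add_background(
    reference: str,
    n: int,
    length_range: tuple[int, int] = (18, 32),
    seed: int | np.random.Generator = 0,
    ref_name: str = "synthetic_consensus",
    id_prefix: str = "bg",
    fixed_length: int | None = None,
) -> list[tuple[ConsensusAlignment, str]]:
    """Unstructured degradation background: uniform random positions,
    strands and lengths. ``fixed_length`` forces every read to one length
    (e.g. 19 for null-rate studies)."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = []
    lo, hi = length_range
    n_ref = len(reference)
    lengths = (
        np.full(n, fixed_length)
        if fixed_length is not None
        else rng.integers(lo, hi + 1, size=n)
    )
    starts = rng.integers(0, n_ref - int(lengths.max()) + 1, size=n) if n else []
    strands = rng.choice(["+", "-"], size=n)
    for i in range(n):
        length = int(lengths[i])
        start = int(starts[i])
        out.append(
            (
                _mk_alignment(f"{id_prefix}{i}", ref_name, start,
                              start + length, str(strands[i]), reference, 1),
                "background",
            )
        )
    return out


def simulate_library(config: SimulationConfig) -> SimulatedLibrary:
    """Compose a full labelled library: planted events plus background.

    With ``antisense_fraction > 0`` that fraction of events is mirrored onto
    the opposite strand of the reference (coordinates reflected), emulating
    elements transcribed from both strands. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    refs = random_reference(
        config.reference_length, config.composition,
        seed=int(rng.integers(2**31)), name=config.ref_name,
    )
    reference = refs[config.ref_name]
    records: list[tuple[ConsensusAlignment, str, str, str]] = []
    used_sites: list[int] = []

    rc_reference = revcomp(reference)

    def plant(kind: str, i: int) -> None:
        # antisense events live on the reference's reverse strand: plant
        # them in reverse-complement context, then reflect coordinates back
        flip = rng.random() < config.antisense_fraction
        context = rc_reference if flip else reference
        planter = plant_config_A_event if kind == "A" else plant_config_B_event
        finder = find_config_a_site if kind == "A" else find_config_b_site
        site = None
        for _ in range(20000):
            cand = finder(context, rng)
            mirrored = len(reference) - cand
            if all(abs(p - s) >= config.min_event_spacing
                   for p in (cand, mirrored) for s in used_sites):
                used_sites.extend((cand, mirrored))
                site = cand
                break
        if site is None:
            raise RuntimeError(
                "could not place events with the requested spacing; "
                "increase reference_length or lower min_event_spacing"
            )
        event = planter(
            context, site, rng, event_id=f"{kind}{i}",
            ref_name=config.ref_name,
            pirna_length_mode=config.pirna_length_mode,
            copy_mu=config.copy_lognormal_mu,
            copy_sigma=config.copy_lognormal_sigma,
            pr19_to_s_ratio=config.pr19_to_s_ratio,
            p_level=config.p_level,
        )
        for aln, true_class in event:
            if flip:
                aln = _flip(aln, len(reference))  # sequence already from rc context
            records.append((aln, true_class, f"{kind}{i}", kind))

    for i in range(config.n_events_a):
        plant("A", i)
    for i in range(config.n_events_b):
        plant("B", i)
    for aln, true_class in add_background(
        reference, config.n_background, config.background_length_range,
        seed=rng, ref_name=config.ref_name,
    ):
        records.append((aln, true_class, aln.read_id, "background"))

    reads = [
        ShortRead(aln.read_id, aln.sequence, aln.count)
        for aln, _, _, _ in records
    ]
    truth = pd.DataFrame(
        [
            {
                "read_id": aln.read_id,
                "true_class": cls,
                "event_id": event,
                "configuration": cfg,
            }
            for aln, cls, event, cfg in records
        ],
        columns=["read_id", "true_class", "event_id", "configuration"],
    )
    return SimulatedLibrary(
        references=refs,
        reads=reads,
        alignments=[aln for aln, _, _, _ in records],
        truth=truth,
        config=config,
    )


@dataclass
class SimulatedGenome:
    """A toy multi-chromosome genome with labelled feature tracks."""

    genome: ReferenceSet
    repeats: list[GenomicInterval]
    clusters: list[GenomicInterval]
    genes: list[GenomicInterval]
    chrom_sizes: dict[str, int]
    alignments: list[ConsensusAlignment]
    truth: pd.DataFrame


def simulate_genome(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 30000,
    events_per_feature: int = 3,
    n_background: int = 0,
) -> SimulatedGenome:
    """A toy genome with one LTR repeat, one piRNA cluster and one gene per
    chromosome, and configuration-A events planted inside each feature (so
    the expected annotation category of every planted 19mer is known).

    The repeat is placed inside the cluster on each chromosome, exercising
    annotation priority (repeat beats cluster).
    """
    rng = np.random.default_rng(seed)
    genome = ReferenceSet()
    repeats, clusters, genes = [], [], []
    alignments: list[ConsensusAlignment] = []
    truth_rows = []
    sizes: dict[str, int] = {}
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        sub = random_reference(chrom_length, seed=int(rng.integers(2**31)),
                               name=chrom)
        genome.add(chrom, sub[chrom])
        sizes[chrom] = chrom_length
        seq = genome[chrom]
        third = chrom_length // 3
        cluster = GenomicInterval(chrom, 100, third, "+", "Clusters")
        repeat = GenomicInterval(chrom, 200, min(2200, third - 100), "+", "LTR")
        gene = GenomicInterval(chrom, 2 * third, chrom_length - 100, "+", "RefSeq")
        clusters.append(cluster)
        repeats.append(repeat)
        genes.append(gene)
        for feature, label in ((repeat, "LTR"), (cluster, "Clusters"),
                               (gene, "RefSeq")):
            planted = 0
            tries = 0
            while planted < events_per_feature and tries < 20000:
                tries += 1
                c = int(rng.integers(feature.start + 40, feature.end - 40))
                if seq[c] != "A" or seq[c - 9] == "T":
                    continue
                if label == "Clusters" and repeat.start <= c - 28 < repeat.end:
                    continue  # keep cluster events clear of the nested repeat
                event_id = f"{chrom}_{label}_{planted}"
                for aln, cls in plant_config_A_event(
                    seq, c, rng, event_id=event_id, ref_name=chrom
                ):
                    alignments.append(aln)
                    truth_rows.append(
                        {
                            "read_id": aln.read_id,
                            "true_class": cls,
                            "event_id": event_id,
                            "configuration": "A",
                            "expected_category": label,
                        }
                    )
                planted += 1
            if planted < events_per_feature:
                raise RuntimeError(f"could not place events in {label} on {chrom}")
        for aln, cls in add_background(seq, n_background, seed=rng,
                                       ref_name=chrom, id_prefix=f"{chrom}_bg"):
            alignments.append(aln)
            truth_rows.append(
                {
                    "read_id": aln.read_id,
                    "true_class": cls,
                    "event_id": aln.read_id,
                    "configuration": "background",
                    "expected_category": "",
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "true_class", "event_id", "configuration",
                 "expected_category"],
    )
    return SimulatedGenome(genome, repeats, clusters, genes, sizes,
                           alignments, truth)


def simulate_tile_study(
    n_tiles: int,
    ratio: float,
    seed: int,
    width: int = 2500,
    chrom: str = "chrT",
) -> tuple[ReferenceSet, dict[str, int], list[ConsensusAlignment]]:
    """One configuration-A event per tile with pr19 copies = ratio x s
    copies, for ratio-recovery studies on the tiling statistics."""
    length = n_tiles * width
    rng = np.random.default_rng(seed)
    refs = random_reference(length, seed=int(rng.integers(2**31)), name=chrom)
    seq = refs[chrom]
    alignments = []
    for t in range(n_tiles):
        lo = t * width + 40
        hi = (t + 1) * width - 40
        site = None
        for _ in range(5000):
            c = int(rng.integers(lo, hi))
            if seq[c] == "A" and seq[c - 9] != "T":
                site = c
                break
        if site is None:
            continue
        s_copies = 1 + int(rng.poisson(3))
        pr_copies = max(1, int(round(ratio * s_copies)))
        for aln, _cls in plant_config_A_event(
            seq, site, rng, event_id=f"T{t}", ref_name=chrom,
            copies=(pr_copies, s_copies, 1),
        ):
            alignments.append(aln)
    return refs, {chrom: length}, alignments


def write_library(lib: SimulatedLibrary, out_dir: str | Path) -> dict[str, Path]:
    """Write reads (FASTA), truth alignments (minimal SAM) and the truth
    table (TSV) for a simulated library.

    Copy counts survive the round trip through the collapsed-read id
    convention: ids gain an ``_xN`` suffix for counts > 1, consistently in
    the FASTA, the SAM and the truth table.
    """
    from . import formats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": out / "reads.fasta",
        "reference": out / "reference.fasta",
        "alignments": out / "truth.sam",
        "truth": out / "truth.tsv",
    }

    def suffixed(read_id: str, count: int) -> str:
        return f"{read_id}_x{count}" if count > 1 else read_id

    id_map = {r.id: suffixed(r.id, r.count) for r in lib.reads}
    with open(paths["reference"], "w") as handle:
        for name, seq in lib.references.items():
            handle.write(f">{name}\n{seq}\n")
    formats.write_fasta(
        [ShortRead(id_map[r.id], r.sequence, r.count) for r in lib.reads],
        paths["reads"],
    )
    formats.write_alignments_sam(
        [replace(a, read_id=id_map.get(a.read_id, a.read_id))
         for a in lib.alignments],
        lib.references,
        paths["alignments"],
    )
    truth = lib.truth.copy()
    truth["read_id"] = truth["read_id"].map(lambda i: id_map.get(i, i))
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
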