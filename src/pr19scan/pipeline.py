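"""End-to-end workflows: filter -> map -> classify -> signatures on a
consensus reference, and map -> assign -> annotate -> tile on a genome.

Every run writes a manifest (parameters, derived per-stage seeds, input
checksums, per-stage record counts) sufficient to reproduce it
byte-identically. A single global seed fans out to per-stage seeds through
a fixed SeedSequence derivation, so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import align, annotate, classify, formats, preprocess, signatures, tiles
from .core import ReadClass, ReferenceSet, ShortRead

logger = logging.getLogger(__name__)

MIN_LIBRARY_MAPPABLE = 100  # libraries at or below this are excluded

_STAGES = ("simulate", "filter", "map", "classify", "annotate", "tiles")


def derive_stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from one global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """Settings for the consensus and genome workflows."""

    reads: str = ""
    reference: str = ""
    repeat_database: str = ""  # optional pass-1 database for two-pass mapping
    tracks: list[str] = field(default_factory=list)  # "path:priority"
    chrom_sizes: str = ""
    out_dir: str = "pr19scan_out"
    mode: str = "consensus"  # or "genome"
    filter_mode: str = "general"
    max_mismatches: int = 2
    max_hits: int = 10
    pass1_max_hits: int = 50000
    flank_length: int = 10
    offset_window: int = 60
    max_loci: int = 6
    tile_width: int = 2500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_inputs(self, required: Sequence[str]) -> None:
        for fieldname in required:
            value = getattr(self, fieldname)
            if not value:
                raise ValueError(f"config field {fieldname!r} is required")
            if fieldname != "out_dir" and not Path(value).exists():
                raise FileNotFoundError(
                    f"config field {fieldname!r}: no such file {value!r}"
                )


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    parameters: dict
    stage_seeds: dict
    input_checksums: dict
    record_counts: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "parameters": self.parameters,
                    "stage_seeds": self.stage_seeds,
                    "input_checksums": self.input_checksums,
                    "record_counts": self.record_counts,
                },
                handle,
                indent=2,
                sort_keys=True,
            )


def _weighted_total(reads: Sequence[ShortRead]) -> int:
    return sum(r.count for r in reads)


def run_consensus_workflow(config: PipelineConfig) -> dict:
    """Filter, map (optionally two-pass), classify and emit all signature
    tables for a consensus-repeat analysis. Returns a report dict and
    writes tables under ``config.out_dir``."""
    config.validate_inputs(["reads", "reference"])
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    checksums = {"reads": _sha256(config.reads),
                 "reference": _sha256(config.reference)}
    manifest = RunManifest(vars(config).copy(), seeds, checksums)

    reads = formats.read_sequences(config.reads)
    manifest.record_counts["input_reads"] = len(reads)
    manifest.record_counts["input_copies"] = _weighted_total(reads)

    kept, removed = preprocess.filter_reads(reads, mode=config.filter_mode)
    manifest.record_counts["filtered_out"] = dict(removed)
    manifest.record_counts["kept_reads"] = len(kept)
    if len(kept) + sum(removed.values()) != len(reads):
        raise RuntimeError("filter stage lost reads (conservation violated)")
    formats.write_table(
        pd.DataFrame([{"rule": k, "removed": v} for k, v in removed.items()]),
        out / "filter_stats.tsv",
    )

    consensus = formats.read_reference(config.reference)
    if config.repeat_database:
        repeat_db = formats.read_reference(config.repeat_database)
        _pass1, mapping = align.two_pass_map(
            kept, repeat_db, consensus,
            pass1_max_hits=config.pass1_max_hits,
            pass2_max_mismatches=config.max_mismatches,
            pass2_max_hits=config.max_hits,
        )
    else:
        mapping = align.map_library(
            kept, consensus, max_mismatches=config.max_mismatches,
            max_hits=config.max_hits,
        )
    manifest.record_counts["aligned"] = len(mapping.alignments)
    manifest.record_counts["unmapped"] = len(mapping.unmapped)
    manifest.record_counts["suppressed"] = len(mapping.suppressed)
    formats.write_alignments_sam(mapping.alignments, consensus, out / "aln.sam")

    classified, summary = classify.classify_library(
        mapping.alignments, consensus, flank_length=config.flank_length
    )
    formats.write_table(summary, out / "class_counts.tsv")
    formats.write_table(classify.classified_to_table(classified),
                        out / "classified.tsv")
    manifest.record_counts["classified"] = len(classified)

    hist = signatures.length_histogram(classified)
    formats.write_table(hist, out / "length_hist.tsv")

    by_class = {
        cls: [cr for cr in classified if cr.read_class is cls]
        for cls in ReadClass
    }
    for cls in (ReadClass.PR19_A10, ReadClass.PR19_U1, ReadClass.P_PIRNA,
                ReadClass.S_PIRNA):
        group = by_class[cls]
        if not group:
            continue
        logo = signatures.sequence_logo(group, downstream_ext=config.flank_length)
        formats.write_table(logo.to_table(), out / f"logo_{cls.value}.tsv")

    offsets = {}
    for name, anchors, queries, same in (
        ("pr19_A10_vs_s_same", by_class[ReadClass.PR19_A10],
         by_class[ReadClass.S_PIRNA], True),
        ("pr19_A10_vs_p_anti", by_class[ReadClass.PR19_A10],
         by_class[ReadClass.P_PIRNA], False),
        ("pr19_U1_vs_p_same", by_class[ReadClass.PR19_U1],
         by_class[ReadClass.P_PIRNA], True),
        ("pr19_U1_vs_s_anti", by_class[ReadClass.PR19_U1],
         by_class[ReadClass.S_PIRNA], False),
    ):
        dens = signatures.offset_density(
            anchors, queries, window=config.offset_window, same_strand=same
        )
        offsets[name] = dens
        formats.write_table(dens.to_table(), out / f"offsets_{name}.tsv")

    configs = signatures.count_configurations(classified)
    formats.write_table(configs.summary, out / "configs.tsv")
    formats.write_table(configs.reciprocal, out / "configs_reciprocal.tsv")

    for ref_name, seq in consensus.items():
        density = signatures.coverage_density(classified, len(seq))
        for (cls, strand), values in density.items():
            tag = "plus" if strand == "+" else "minus"
            formats.write_wiggle(values, ref_name,
                                 out / f"coverage_{cls}_{tag}.wig")

    manifest.write(out / "manifest.json")
    return {
        "classified": classified,
        "summary": summary,
        "length_hist": hist,
        "offsets": offsets,
        "configurations": configs,
        "manifest": manifest,
    }


def run_genome_workflow(config: PipelineConfig) -> dict:
    """Genome-wide workflow: import genome mappings, assign multi-mappers,
    bin by the 10th downstream base, annotate against prioritised tracks,
    tile the genome and run the pr19 vs s-piRNA comparison."""
    config.validate_inputs(["reads", "reference", "chrom_sizes"])
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    checksums = {"alignments": _sha256(config.reads),
                 "genome": _sha256(config.reference),
                 "chrom_sizes": _sha256(config.chrom_sizes)}
    manifest = RunManifest(vars(config).copy(), seeds, checksums)

    genome = formats.read_reference(config.reference)
    alignments = formats.read_alignments_sam(config.reads, genome)
    manifest.record_counts["alignments"] = len(alignments)
    chrom_sizes = formats.read_chrom_sizes(config.chrom_sizes)

    tracks = []
    for spec_str in config.tracks:
        path, _, rank = spec_str.rpartition(":")
        intervals = formats.read_intervals_bed(path)
        tracks.append(
            annotate.AnnotationTrack(Path(path).stem, int(rank), intervals)
        )

    # group per read for multi-mapper handling; only 19mers are annotated
    by_read: dict[str, list] = {}
    counts: dict[str, int] = {}
    for aln in alignments:
        if aln.length != 19:
            continue
        from .core import GenomicInterval

        by_read.setdefault(aln.read_id, []).append(
            GenomicInterval(aln.ref_id, aln.start, aln.end, aln.strand,
                            aln.read_id)
        )
        counts[aln.read_id] = aln.count
    report = annotate.annotate_genome_19mers(
        by_read, genome, tracks, seed=seeds["annotate"],
        read_counts=counts, max_loci=config.max_loci,
    )
    report.table.reset_index().to_csv(out / "annotation_counts.tsv",
                                      sep="\t", index=False)
    manifest.record_counts["annotate_totals"] = {
        "unique": report.totals.unique,
        "multi": report.totals.multi,
        "discarded": report.totals.discarded,
        "total": report.totals.total,
    }

    # mark uniqueness from the per-read locus counts, then classify & tile
    n_loci = {rid: len(loci) for rid, loci in by_read.items()}
    for aln in alignments:
        if aln.length == 19:
            aln.unique = n_loci.get(aln.read_id, 1) == 1
    classified, _summary = classify.classify_library(
        alignments, genome, flank_length=config.flank_length
    )
    tile_list = tiles.make_tiles(chrom_sizes, config.tile_width)
    tile_counts = tiles.count_tiles(classified, tile_list,
                                    width=config.tile_width)
    formats.write_table(tiles.tile_counts_table(tile_counts),
                        out / "tiles.tsv")
    selected = tiles.select_enriched_tiles(tile_counts)
    result: dict = {
        "annotation": report,
        "tile_counts": tile_counts,
        "selected_tiles": selected,
        "manifest": manifest,
    }
    if selected:
        summary = tiles.ratio_summary(selected)
        test = tiles.paired_wilcoxon(
            [tc.pr19_a10 for tc in selected],
            [tc.s_pirna for tc in selected],
        )
        formats.write_table(summary.scatter, out / "tile_scatter.tsv")
        formats.write_table(
            pd.DataFrame(
                [
                    {
                        "n_tiles": len(selected),
                        "median_ratio": summary.median,
                        "q1": summary.q1,
                        "q3": summary.q3,
                        "wilcoxon_statistic": test.statistic,
                        "wilcoxon_p": test.pvalue,
                        "wilcoxon_method": test.method,
                    }
                ]
            ),
            out / "tile_summary.tsv",
        )
        result["ratio_summary"] = summary
        result["wilcoxon"] = test
    manifest.record_counts["tiles_selected"] = len(selected)
    manifest.write(out / "manifest.json")
    return result


def compare_libraries(
    library_tables: Mapping[str, pd.DataFrame],
    min_mappable: int = MIN_LIBRARY_MAPPABLE,
) -> pd.DataFrame:
    """RPM-normalised per-length, per-class comparison across libraries.

    Each input table needs columns class/strand/length/count (the classify
    summary). Libraries whose mappable total is <= ``min_mappable`` are
    excluded with a warning. The output carries one row per
    (library, class, strand, length) with raw and RPM counts, plus a
    ``peak_19nt`` flag per library: whether the total 19-nt RPM exceeds both
    neighbouring lengths (18 and 20).
    """
    if len(library_tables) < 2:
        raise ValueError("need at least two libraries to compare")
    rows = []
    peaks = {}
    excluded = []
    for name, table in library_tables.items():
        total = table["count"].sum()
        if total <= min_mappable:
            logger.warning(
                "library %s excluded: %d mappable reads (need > %d)",
                name, total, min_mappable,
            )
            excluded.append(name)
            continue
        by_len = table.groupby("length")["count"].sum()
        rpm_by_len = {
            length: signatures.rpm(n, total) for length, n in by_len.items()
        }
        peaks[name] = (
            rpm_by_len.get(19, 0.0) > rpm_by_len.get(18, 0.0)
            and rpm_by_len.get(19, 0.0) > rpm_by_len.get(20, 0.0)
        )
        for _, row in table.iterrows():
            rows.append(
                {
                    "library": name,
                    "class": row["class"],
                    "strand": row["strand"],
                    "length": row["length"],
                    "count": row["count"],
                    "rpm": signatures.rpm(row["count"], total),
                    "peak_19nt": peaks[name],
                }
            )
    if not rows:
        raise ValueError("all libraries excluded by the mappable-read rule")
    return pd.DataFrame(
        rows, columns=["library", "class", "strand", "length", "count",
                       "rpm", "peak_19nt"]
    )
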