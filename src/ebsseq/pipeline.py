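"""End-to-end orchestration of the enrichment-deamination pipeline.

Stage order: read SAM -> call conversion states -> conversion filter ->
spike partition (spike QC) -> dedup (genomic fragments) -> presence filter
(ebs mode only) -> quantification. The three modes mirror the three assay
families: ``ebs`` runs everything; ``ace`` (whole-genome deamination, no
enrichment) skips the presence filter; ``seal`` (enrichment only, no
deamination) skips conversion calling entirely and quantifies fragment
counts alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import filters as flt
from . import quantify as qt
from . import readcall as rc
from . import refmod as rm
from . import spikein as sp

logger = logging.getLogger(__name__)

MODES = ("ebs", "ace", "seal")


@dataclass
class PipelineConfig:
    mode: str = "ebs"
    reference: Optional[str] = None
    sam: Optional[str] = None
    regions_bed: Optional[str] = None  # e.g. gene bodies for region signal
    spike_fasta: Optional[str] = None
    spike_tsv: Optional[str] = None
    output_dir: str = "ebsseq_out"
    max_noncpg_unconverted: int = flt.DEFAULT_MAX_NONCPG_UNCONVERTED
    min_quality: int = rc.DEFAULT_MIN_QUALITY
    dedup: bool = True
    merge_strands: bool = True
    bin_size: int = 10_000
    flank: int = 3_000
    body_bins: int = 100
    flank_bins: int = 30
    min_signals: int = 3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "seal" and (self.spike_fasta or self.spike_tsv):
            raise ValueError("seal mode has no deamination; spike QC unavailable")


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    config: PipelineConfig
    stage_counts: Dict[str, int] = field(default_factory=dict)
    retained_fragments: List[rc.AlignedFragment] = field(default_factory=list)
    retained_callsets: List[rc.FragmentCallSet] = field(default_factory=list)
    filter_report: Optional[flt.FilterReport] = None
    spike_report: Optional[sp.SpikeInReport] = None
    spike_report_filtered: Optional[sp.SpikeInReport] = None
    site_counts: Optional[qt.SiteCounts] = None
    site_counts_stranded: Optional[qt.SiteCounts] = None
    region_signals: List[qt.RegionSignal] = field(default_factory=list)


def run_pipeline_objects(
    config: PipelineConfig,
    genome: rm.ReferenceGenome,
    fragments: Sequence[rc.AlignedFragment],
    regions: Optional[Sequence[rm.GenomicInterval]] = None,
    design: Optional[sp.SpikeInDesign] = None,
) -> PipelineResult:
    """Run all stages on in-memory inputs; see module docstring for ordering."""
    result = PipelineResult(config=config)
    counts = result.stage_counts
    counts["input"] = len(fragments)
    index = rm.build_cpg_index(genome)

    if config.mode == "seal":
        frags = list(fragments)
        if config.dedup:
            frags = rc.deduplicate(frags, genome)
        counts["after_dedup"] = len(frags)
        result.retained_fragments = frags
        if regions:
            # no calling: site counts empty, RPKM only
            result.region_signals = qt.region_signal_table(
                frags, qt.SiteCounts(), regions, index, library_total=len(frags)
            )
        _log_counts(counts)
        return result

    # call conversion states
    callsets = [
        rc.call_fragment(f, genome, min_quality=config.min_quality) for f in fragments
    ]
    keep = [
        flt.conversion_filter(cs, config.max_noncpg_unconverted) for cs in callsets
    ]
    counts["failed_conversion"] = keep.count(False)
    conv_frags = [f for f, k in zip(fragments, keep) if k]
    conv_calls = [c for c, k in zip(callsets, keep) if k]
    counts["after_conversion_filter"] = len(conv_frags)

    # spike partition before dedup: spike oligos share coordinates, and QC
    # must see every spike molecule
    if design is not None:
        partition = sp.match_spikein(conv_frags, design)
        spike_frags = partition["hmc_spike"] + partition["control_spike"]
        spike_ids = {id(f) for f in spike_frags}
        enr = sp.enrichment_fraction(partition) if spike_frags else None
        by_id = {id(f): c for f, c in zip(conv_frags, conv_calls)}
        spike_calls = [by_id[id(f)] for f in spike_frags]
        result.spike_report = sp.conversion_report(spike_calls, design, enrichment=enr)
        # variant with the conversion filter NOT applied: recompute from all
        # input fragments restricted to spikes
        all_partition = sp.match_spikein(list(fragments), design)
        all_spike = all_partition["hmc_spike"] + all_partition["control_spike"]
        all_by_id = {id(f): c for f, c in zip(fragments, callsets)}
        result.spike_report_filtered = result.spike_report
        result.spike_report = sp.conversion_report(
            [all_by_id[id(f)] for f in all_spike],
            design,
            enrichment=sp.enrichment_fraction(all_partition) if all_spike else None,
        )
        conv_pairs = [
            (f, c) for f, c in zip(conv_frags, conv_calls) if id(f) not in spike_ids
        ]
        conv_frags = [f for f, _ in conv_pairs]
        conv_calls = [c for _, c in conv_pairs]
        counts["spike_fragments"] = len(spike_frags)
        counts["genomic_after_spike_split"] = len(conv_frags)

    if config.dedup:
        deduped = rc.deduplicate(conv_frags, genome)
        kept_ids = {id(f) for f in deduped}
        conv_pairs = [(f, c) for f, c in zip(conv_frags, conv_calls) if id(f) in kept_ids]
        conv_frags = [f for f, _ in conv_pairs]
        conv_calls = [c for _, c in conv_pairs]
    counts["after_dedup"] = len(conv_frags)

    # presence filter partitions the library in ebs mode; the report is
    # informative in every deaminating mode
    result.filter_report = flt.filter_report(
        conv_calls, conv_frags, config.max_noncpg_unconverted
    )
    if config.mode == "ebs":
        pairs = [
            (f, c) for f, c in zip(conv_frags, conv_calls) if flt.hmc_presence_filter(c)
        ]
        conv_frags = [f for f, _ in pairs]
        conv_calls = [c for _, c in pairs]
    counts["retained"] = len(conv_frags)
    result.retained_fragments = conv_frags
    result.retained_callsets = conv_calls

    result.site_counts = qt.accumulate_site_counts(conv_calls, index, merge_strands=True)
    result.site_counts_stranded = qt.accumulate_site_counts(
        conv_calls, index, merge_strands=False
    )
    if regions:
        result.region_signals = qt.region_signal_table(
            conv_frags, result.site_counts, regions, index, library_total=len(conv_frags)
        )
    _log_counts(counts)
    return result


def _log_counts(counts: Dict[str, int]) -> None:
    for stage, n in counts.items():
        logger.info("stage %-28s %d", stage, n)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load inputs, run stages, write the bundle."""
    if not config.reference or not config.sam:
        raise ValueError("reference FASTA and SAM input are required")
    genome = rm.load_reference(config.reference)
    fragments = rc.read_fragments_sam(config.sam)
    regions = rm.read_bed(config.regions_bed) if config.regions_bed else None
    design = None
    if config.spike_fasta and config.spike_tsv:
        design = sp.SpikeInDesign.from_files(config.spike_fasta, config.spike_tsv)
        # spike contigs must be resolvable for calling
        for name, seq in design.sequences.items():
            if name not in genome:
                genome.contigs[name] = seq

    result = run_pipeline_objects(config, genome, fragments, regions, design)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2) + "\n"
    )
    (outdir / "stage_counts.json").write_text(
        json.dumps(result.stage_counts, indent=2) + "\n"
    )
    if result.retained_fragments:
        rc.write_fragments_sam(result.retained_fragments, genome, outdir / "retained.sam")
    if result.filter_report is not None:
        result.filter_report.to_json(outdir / "filter_report.json")
        (outdir / "filter_report.txt").write_text(result.filter_report.to_text())
    if result.spike_report is not None:
        result.spike_report.to_json(outdir / "spike_report.json")
        result.spike_report.to_tsv(outdir / "spike_positions.tsv")
    if result.spike_report_filtered is not None:
        result.spike_report_filtered.to_json(outdir / "spike_report_conversion_filtered.json")
    if result.site_counts is not None and result.site_counts.counts:
        qt.write_bedgraph(result.site_counts, outdir / "hmc.bedGraph", "hmc_count")
        qt.write_bedgraph(result.site_counts, outdir / "coverage.bedGraph", "coverage")
    if result.site_counts_stranded is not None:
        index = rm.build_cpg_index(genome)
        qt.write_cytosine_report(
            result.site_counts_stranded, index, outdir / "cytosine_report.tsv"
        )
    if result.region_signals:
        qt.region_signal_frame(result.region_signals).to_csv(
            outdir / "region_signals.tsv", sep="\t", index=False
        )
    logger.info("pipeline outputs in %s", outdir)
    return result
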