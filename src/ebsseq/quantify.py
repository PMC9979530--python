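"""Per-CpG 5hmC quantification, normalization, site sets and profiles.

The quantification substrate is SiteCounts: for every CpG cytosine the
number of unconverted calls (5hmC signals) and the informative coverage
(converted + unconverted). Region-level signal comes in two flavours:
RPKM on fragment counts, which inherits CpG-density bias in an enrichment
library, and the CpG-normalized signal — 5hmC signals per million detected,
divided by the region's CpG-site count — which removes that bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .readcall import CONVERTED, UNCONVERTED, AlignedFragment, FragmentCallSet
from .refmod import CpGIndex, GenomicInterval, ReferenceGenome, count_cpg_in

SiteKey = Tuple[str, int, str]  # contig, dyad/base position, strand ('.', '+', '-')


@dataclass
class SiteCounts:
    """Per-site 5hmC signal and informative-coverage tallies.

    With ``merged`` strand handling, reverse-strand calls (at the dyad's
    forward G) fold onto the forward C coordinate with strand '.'.
    """

    counts: Dict[SiteKey, List[int]] = field(default_factory=dict)  # [hmc, coverage]
    merged: bool = True

    def add(self, contig: str, pos: int, strand: str, unconverted: bool) -> None:
        key = (contig, pos, strand)
        entry = self.counts.setdefault(key, [0, 0])
        entry[1] += 1
        if unconverted:
            entry[0] += 1

    def hmc(self, contig: str, pos: int, strand: str = ".") -> int:
        return self.counts.get((contig, pos, strand), [0, 0])[0]

    def coverage(self, contig: str, pos: int, strand: str = ".") -> int:
        return self.counts.get((contig, pos, strand), [0, 0])[1]

    @property
    def total_hmc(self) -> int:
        return sum(v[0] for v in self.counts.values())

    @property
    def total_coverage(self) -> int:
        return sum(v[1] for v in self.counts.values())

    def contig_arrays(self, contig: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sorted (positions, hmc, coverage) arrays for one contig (merged only)."""
        items = sorted(
            (pos, v[0], v[1])
            for (c, pos, s), v in self.counts.items()
            if c == contig
        )
        if not items:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        pos, hmc, cov = map(np.asarray, zip(*items))
        return pos.astype(np.int64), hmc.astype(np.int64), cov.astype(np.int64)


def accumulate_site_counts(
    callsets: Sequence[FragmentCallSet],
    index: CpGIndex,
    merge_strands: bool = True,
) -> SiteCounts:
    """Tally informative CpG calls of retained fragments per site.

    Reverse-strand (OB) calls sit at the dyad's forward G; with strand
    merging they fold onto the forward C coordinate (pos - 1). A CpG call at
    a position absent from the index indicates a context bug and is an error.
    """
    counts = SiteCounts(merged=merge_strands)
    for cs in callsets:
        is_cpg = cs.context_codes == 0
        informative = (cs.states == CONVERTED) | (cs.states == UNCONVERTED)
        sel = is_cpg & informative
        if not sel.any():
            continue
        strand = cs.strand
        for pos, state in zip(cs.positions[sel], cs.states[sel]):
            dyad = int(pos) - 1 if strand == "-" else int(pos)
            if (cs.contig, dyad) not in index:
                raise ValueError(
                    f"CpG call at {cs.contig}:{pos}{strand} has no dyad in the index"
                )
            if merge_strands:
                counts.add(cs.contig, dyad, ".", state == UNCONVERTED)
            else:
                counts.add(cs.contig, int(pos), strand, state == UNCONVERTED)
    return counts


# --- output formats --------------------------------------------------------

BEDGRAPH_HEADER = "track type=bedGraph\n"


def write_bedgraph(
    counts: SiteCounts,
    path: Union[str, Path],
    channel: str = "hmc_count",
) -> None:
    """0-based half-open, sorted bedGraph of one channel per site."""
    if channel not in ("hmc_count", "coverage", "fraction"):
        raise ValueError(f"unknown channel {channel!r}")
    with open(path, "w") as fh:
        fh.write(BEDGRAPH_HEADER)
        for (contig, pos, strand), (hmc, cov) in sorted(counts.counts.items()):
            if channel == "hmc_count":
                val: Union[int, float] = hmc
            elif channel == "coverage":
                val = cov
            else:
                val = hmc / cov if cov else 0.0
            fh.write(f"{contig}\t{pos}\t{pos + 1}\t{val}\n")


def read_bedgraph(path: Union[str, Path]) -> Dict[Tuple[str, int], float]:
    out: Dict[Tuple[str, int], float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            contig, start, _end, val = line.rstrip("\n").split("\t")
            out[(contig, int(start))] = float(val)
    return out


def write_cytosine_report(
    counts: SiteCounts,
    index: CpGIndex,
    path: Union[str, Path],
) -> None:
    """Exhaustive per-strand CpG report, 1-based positions.

    Columns: contig, position (1-based), strand, unconverted count,
    converted count, context. Requires per-strand (unmerged) counts; every
    dyad in the index yields two rows, 0/0 where uncovered.
    """
    if counts.merged:
        raise ValueError("cytosine report needs per-strand counts (merge_strands=False)")
    with open(path, "w") as fh:
        for contig in sorted(index.positions):
            for dyad in index.positions[contig]:
                dyad = int(dyad)
                for strand, pos in (("+", dyad), ("-", dyad + 1)):
                    hmc = counts.hmc(contig, pos, strand)
                    cov = counts.coverage(contig, pos, strand)
                    fh.write(
                        f"{contig}\t{pos + 1}\t{strand}\t{hmc}\t{cov - hmc}\tCpG\n"
                    )


# --- region-level signal ---------------------------------------------------


def fragment_midpoints(fragments: Sequence[AlignedFragment]) -> Dict[str, np.ndarray]:
    mids: Dict[str, List[int]] = {}
    for frag in fragments:
        mids.setdefault(frag.contig, []).append((frag.start + frag.end) // 2)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}


def region_fragment_counts(
    fragments: Sequence[AlignedFragment],
    regions: Sequence[GenomicInterval],
) -> np.ndarray:
    """Fragments per region under the midpoint rule (one bin per fragment)."""
    mids = fragment_midpoints(fragments)
    out = np.zeros(len(regions), dtype=np.int64)
    for i, region in enumerate(regions):
        arr = mids.get(region.contig)
        if arr is None:
            continue
        lo, hi = np.searchsorted(arr, [region.start, region.end])
        out[i] = hi - lo
    return out


def rpkm(
    counts: np.ndarray, lengths_bp: np.ndarray, library_total: int
) -> np.ndarray:
    """Reads per kilobase of region per million library fragments."""
    counts = np.asarray(counts, dtype=float)
    lengths_bp = np.asarray(lengths_bp, dtype=float)
    if library_total < 1:
        raise ValueError("library total must be >= 1")
    if np.any(lengths_bp <= 0):
        raise ValueError("zero-length region")
    return counts / (lengths_bp / 1e3) / (library_total / 1e6)


def cpg_normalized_signal(
    counts: SiteCounts,
    region: GenomicInterval,
    index: CpGIndex,
    total_hmc: Optional[int] = None,
) -> float:
    """5hmC signals per million detected, divided by the region's CpG count.

    Undefined (NaN) for regions without CpG sites; a library with zero
    detected 5hmC is an error.
    """
    total = counts.total_hmc if total_hmc is None else total_hmc
    if total < 1:
        raise ValueError("library has no detected 5hmC signals")
    n_cpg = count_cpg_in(index, region)
    if n_cpg == 0:
        return float("nan")
    pos, hmc, _cov = counts.contig_arrays(region.contig)
    lo, hi = np.searchsorted(pos, [region.start, region.end])
    hmc_in_region = int(hmc[lo:hi].sum())
    return (hmc_in_region / total * 1e6) / n_cpg


@dataclass
class RegionSignal:
    region: GenomicInterval
    fragment_count: int
    rpkm: float
    cpg_norm: float  # NaN when region has no CpG sites


def region_signal_table(
    fragments: Sequence[AlignedFragment],
    counts: SiteCounts,
    regions: Sequence[GenomicInterval],
    index: CpGIndex,
    library_total: Optional[int] = None,
) -> List[RegionSignal]:
    total = library_total if library_total is not None else len(fragments)
    frag_counts = region_fragment_counts(fragments, regions)
    lengths = np.asarray([r.length for r in regions], dtype=float)
    rpkms = rpkm(frag_counts, lengths, max(total, 1))
    total_hmc = counts.total_hmc
    out = []
    for region, n, r in zip(regions, frag_counts, rpkms):
        cn = (
            cpg_normalized_signal(counts, region, index, total_hmc)
            if total_hmc >= 1
            else float("nan")
        )
        out.append(RegionSignal(region, int(n), float(r), cn))
    return out


def region_signal_frame(signals: Sequence[RegionSignal]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [s.region.contig for s in signals],
            "start": [s.region.start for s in signals],
            "end": [s.region.end for s in signals],
            "name": [s.region.name for s in signals],
            "fragment_count": [s.fragment_count for s in signals],
            "rpkm": [s.rpkm for s in signals],
            "cpg_norm": [s.cpg_norm for s in signals],
        }
    )


# --- site sets -------------------------------------------------------------


def high_confidence_sites(counts: SiteCounts, min_signals: int = 3) -> Set[Tuple[str, int]]:
    """Dyads with at least ``min_signals`` 5hmC signals (strand-merged)."""
    if min_signals < 1:
        raise ValueError("min_signals must be >= 1")
    if not counts.merged:
        raise ValueError("site sets need strand-merged counts")
    return {
        (contig, pos)
        for (contig, pos, _s), (hmc, _cov) in counts.counts.items()
        if hmc >= min_signals
    }


def overlap_fractions(
    a: Set[Tuple[str, int]], b: Set[Tuple[str, int]]
) -> Tuple[float, float]:
    """(share of A found in B, share of B found in A)."""
    if not a or not b:
        raise ValueError("site sets must be non-empty")
    inter = len(a & b)
    return inter / len(a), inter / len(b)


# --- replicate correlation -------------------------------------------------


def tile_genome(
    genome: ReferenceGenome,
    bin_size: int = 10_000,
    step: Optional[int] = None,
    contigs: Optional[Sequence[str]] = None,
) -> List[GenomicInterval]:
    """Fixed windows across contigs; ``step`` < bin_size gives sliding windows."""
    step = step or bin_size
    bins: List[GenomicInterval] = []
    for contig in contigs or genome.contigs:
        n = genome.length(contig)
        start = 0
        while start < n:
            bins.append(GenomicInterval(contig, start, min(start + bin_size, n)))
            start += step
    return bins


def binned_correlation(
    replicate_fragments: Sequence[Sequence[AlignedFragment]],
    genome: ReferenceGenome,
    bin_size: int = 10_000,
    step: Optional[int] = None,
    contigs: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, List[GenomicInterval]]:
    """Pairwise Pearson of per-bin RPKM between replicates.

    Raw RPKM, no log transform. Zero-variance replicates yield NaN entries.
    Returns (matrix, bins); the matrix is symmetric with unit diagonal.
    """
    if len(replicate_fragments) < 2:
        raise ValueError("need at least two replicates")
    bins = tile_genome(genome, bin_size, step, contigs)
    lengths = np.asarray([b.length for b in bins], dtype=float)
    vectors = []
    for frags in replicate_fragments:
        c = region_fragment_counts(frags, bins)
        vectors.append(rpkm(c, lengths, max(len(frags), 1)))
    k = len(vectors)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            x, y = vectors[i], vectors[j]
            if np.std(x) == 0 or np.std(y) == 0:
                r = float("nan")
            elif np.array_equal(x, y):
                r = 1.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            mat[i, j] = mat[j, i] = r
    labels = [f"rep{i + 1}" for i in range(k)]
    return pd.DataFrame(mat, index=labels, columns=labels), bins


# --- metagene profiles -----------------------------------------------------


def _per_base_coverage(
    fragments: Sequence[AlignedFragment], genome: ReferenceGenome
) -> Dict[str, np.ndarray]:
    """Per-base fragment coverage (each fragment covers its full span)."""
    cov = {c: np.zeros(genome.length(c) + 1, dtype=np.int64) for c in genome.contigs}
    for frag in fragments:
        arr = cov.get(frag.contig)
        if arr is None:
            continue
        arr[frag.start] += 1
        arr[frag.end] -= 1
    return {c: np.cumsum(a[:-1]) for c, a in cov.items()}


def _bin_edges(start: float, end: float, n_bins: int) -> np.ndarray:
    return np.linspace(start, end, n_bins + 1)


def metagene_matrix(
    regions: Sequence[GenomicInterval],
    mode: str,
    genome: ReferenceGenome,
    index: Optional[CpGIndex] = None,
    counts: Optional[SiteCounts] = None,
    fragments: Optional[Sequence[AlignedFragment]] = None,
    flank: int = 3_000,
    body_bins: int = 100,
    flank_bins: int = 30,
) -> Tuple[np.ndarray, np.ndarray]:
    """Scale-regions profile matrix around regions, rows reading 5'->3'.

    mode 'coverage': mean per-base fragment coverage per bin.
    mode 'hmc_per_cpg': summed 5hmC signals at CpG dyads in the bin divided
    by the bin's CpG-site count (NaN where the bin holds no CpG or falls
    outside the contig).
    Returns (matrix of shape n_regions x (2*flank_bins + body_bins),
    column-wise nan-mean profile).
    """
    if flank_bins > flank:
        raise ValueError("more flank bins than flank bases")
    if mode == "coverage":
        if fragments is None:
            raise ValueError("coverage mode needs fragments")
        coverage = _per_base_coverage(fragments, genome)
        cum = {c: np.concatenate(([0], np.cumsum(a))) for c, a in coverage.items()}
    elif mode == "hmc_per_cpg":
        if counts is None or index is None:
            raise ValueError("hmc_per_cpg mode needs counts and a CpG index")
        site_arrays = {
            c: counts.contig_arrays(c) for c in {r.contig for r in regions}
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n_cols = 2 * flank_bins + body_bins
    mat = np.full((len(regions), n_cols), np.nan)
    for ri, region in enumerate(regions):
        contig_len = genome.length(region.contig)
        edges = np.concatenate(
            [
                _bin_edges(region.start - flank, region.start, flank_bins)[:-1],
                _bin_edges(region.start, region.end, body_bins)[:-1],
                _bin_edges(region.end, region.end + flank, flank_bins),
            ]
        )
        starts = np.floor(edges[:-1]).astype(np.int64)
        ends = np.ceil(edges[1:]).astype(np.int64)
        ends = np.maximum(ends, starts + 1)
        row = np.full(n_cols, np.nan)
        for bi in range(n_cols):
            a = max(int(starts[bi]), 0)
            b = min(int(ends[bi]), contig_len)
            if b <= a:
                continue
            if mode == "coverage":
                c = cum[region.contig]
                row[bi] = (c[b] - c[a]) / (b - a)
            else:
                pos, hmc, _cov = site_arrays[region.contig]
                if index is None:
                    continue
                dyads = index.contig_positions(region.contig)
                lo, hi = np.searchsorted(dyads, [a, b])
                n_cpg = hi - lo
                if n_cpg == 0:
                    continue
                slo, shi = np.searchsorted(pos, [a, b])
                row[bi] = float(hmc[slo:shi].sum()) / n_cpg
        if region.strand == "-":
            row = row[::-1]
        mat[ri] = row
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        profile = np.nanmean(mat, axis=0)
    return mat, profile


# --- expression correlation ------------------------------------------------


def expression_correlation(
    gene_signal: Dict[str, float],
    expression: Dict[str, float],
) -> float:
    """Pearson R between gene-body signal and expression over shared genes.

    Genes with a zero value on either side are excluded (unmeasured in one
    assay); fewer than three remaining genes is an error.
    """
    from scipy import stats

    keys = sorted(set(gene_signal) & set(expression))
    pairs = [
        (gene_signal[k], expression[k])
        for k in keys
        if gene_signal[k] != 0 and expression[k] != 0
    ]
    if len(pairs) < 3:
        raise ValueError("fewer than three genes with signal on both sides")
    x, y = zip(*pairs)
    return float(stats.pearsonr(x, y)[0])
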