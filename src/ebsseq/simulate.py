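"""Seeded simulator of enrichment + APOBEC-deamination 5hmC sequencing.

The generator emulates the wet chemistry end to end on a synthetic genome:
CpG-dyad modification states are placed per region class (gene body, CpG
island, intergenic), fragments of ~200 bp are drawn uniformly, a
glucosylation/biotin pull-down retains fragments whose original strand
carries at least one 5hmC with a capture probability (and signal-free
fragments with a small carry-over probability), APOBEC deaminates C and 5mC
— but not glucosyl-protected 5hmC — on the fragment's original strand, and
150 bp paired-end reads are taken from the fragment ends, leaving the middle
of long fragments uncovered. Everything downstream of alignment is emitted:
reference FASTA, gene/island/truth BED, pre-aligned SAM with the ZS
conversion-strand tag, FASTQ, and a two-duplex spike-in design.

All randomness flows from named, seeded sub-streams so stages vary
independently; the same seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .readcall import (
    STRAND_TAG, AlignedFragment, ConversionStrand, Mate, sam_header,
)
from .refmod import (
    CpGIndex, GenomicInterval, ReferenceGenome, build_cpg_index,
    reverse_complement, write_bed, write_reference,
)
from .spikein import SpikeInDesign

MOD_CLASSES = ("C", "5mC", "5hmC", "5fC")

_STREAMS = ("genome", "placement", "fragmentation", "pulldown", "conversion",
            "error", "duplication", "spike")


@dataclass
class RegionRates:
    """Per-CpG-cytosine modification probabilities within one region class."""

    p_5hmC: float
    p_5mC: float
    p_5fC: float = 0.0

    def validate(self) -> None:
        for p in (self.p_5hmC, self.p_5mC, self.p_5fC):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.p_5hmC + self.p_5mC + self.p_5fC > 1.0:
            raise ValueError("modification probabilities sum above 1 for a site")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic chemistry.

    Defaults follow the published protocol scale: 200 bp mean fragments read
    on a 150PE layout, per-class deamination probabilities of 0.994 (C),
    0.989 (5mC) and 0.008 (5hmC), and a pull-down that captures
    5hmC-bearing fragments at 0.95 against a 0.01 carry-over for
    signal-free ones.
    """

    seed: int = 0
    # genome layout
    genome_length: int = 200_000
    n_contigs: int = 1
    gc_fraction: float = 0.45
    n_genes: int = 20
    gene_length: int = 5_000
    n_islands: int = 10
    island_length: int = 1_000
    island_cpg_rate: float = 0.12  # per-bp probability of planting a CpG in islands
    # modification landscape (per CpG cytosine, per strand)
    rates_genebody: RegionRates = field(default_factory=lambda: RegionRates(0.10, 0.60))
    rates_island: RegionRates = field(default_factory=lambda: RegionRates(0.05, 0.10))
    rates_intergenic: RegionRates = field(default_factory=lambda: RegionRates(0.01, 0.60))
    symmetric_dyads: bool = False
    # library
    fragment_mean: float = 200.0
    fragment_sd: float = 50.0
    fragment_min: int = 50
    read_length: int = 150
    library_size: int = 20_000
    capture_prob: float = 0.95
    carryover_prob: float = 0.01
    # chemistry
    p_convert: Dict[str, float] = field(
        default_factory=lambda: {"C": 0.994, "5mC": 0.989, "5hmC": 0.008, "5fC": 0.0}
    )
    error_rate: float = 0.001
    duplicate_rate: float = 0.02
    base_quality: int = 37
    # spike-ins
    spike_length: int = 200
    spike_copies: int = 2_000

    def validate(self) -> None:
        for rr in (self.rates_genebody, self.rates_island, self.rates_intergenic):
            rr.validate()
        for cls, p in self.p_convert.items():
            if cls not in MOD_CLASSES or not 0.0 <= p <= 1.0:
                raise ValueError(f"bad conversion probability {cls}={p}")
        for p in (self.capture_prob, self.carryover_prob, self.error_rate,
                  self.duplicate_rate, self.gc_fraction, self.island_cpg_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.fragment_min <= 0 or self.read_length <= 0 or self.genome_length <= 0:
            raise ValueError("lengths must be positive")

    def rngs(self) -> Dict[str, np.random.Generator]:
        base = np.random.SeedSequence(self.seed)
        children = base.spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


@dataclass
class ModificationTruth:
    """Ground-truth class of every cytosine; unlisted cytosines are plain C."""

    modified: Dict[Tuple[str, int, str], str] = field(default_factory=dict)

    def class_of(self, contig: str, pos: int, strand: str) -> str:
        return self.modified.get((contig, pos, strand), "C")

    def hmc_positions(self, contig: str, strand: str) -> np.ndarray:
        pos = sorted(
            p for (c, p, s), cls in self.modified.items()
            if c == contig and s == strand and cls == "5hmC"
        )
        return np.asarray(pos, dtype=np.int64)

    def write_bed(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for (contig, pos, strand), cls in sorted(self.modified.items()):
                fh.write(f"{contig}\t{pos}\t{pos + 1}\t{cls}\t0\t{strand}\n")


@dataclass
class SimFragment:
    """A molecule before/after pull-down, with truth annotation."""

    contig: str
    start: int
    end: int
    original_strand: str  # '+' (OT) or '-' (OB)
    n_hmc_strand: int  # truth 5hmC count on the original strand
    is_spike: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def conversion_strand(self) -> str:
        return ConversionStrand.OT if self.original_strand == "+" else ConversionStrand.OB


# --- genome ---------------------------------------------------------------


def build_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[ReferenceGenome, List[GenomicInterval], List[GenomicInterval]]:
    """Synthetic contigs with CpG-dense islands, plus gene and island BED layouts."""
    config.validate()
    rng = rng if rng is not None else config.rngs()["genome"]
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")

    contigs: Dict[str, str] = {}
    genes: List[GenomicInterval] = []
    islands: List[GenomicInterval] = []
    per_contig = config.genome_length // config.n_contigs
    n_genes_per = config.n_genes // config.n_contigs
    n_islands_per = config.n_islands // config.n_contigs
    for ci in range(config.n_contigs):
        name = f"chr{ci + 1}"
        seq = bases[rng.choice(4, size=per_contig, p=probs)]
        gene_ivs = _place_nonoverlapping(rng, per_contig, n_genes_per, config.gene_length)
        island_ivs = _place_nonoverlapping(
            rng, per_contig, n_islands_per, config.island_length
        )
        if (n_genes_per and not gene_ivs) or (n_islands_per and not island_ivs):
            raise ValueError("gene/island layout does not fit the contig")
        # plant CpGs inside islands at the island rate
        for s, e in island_ivs:
            starts = s + np.flatnonzero(
                rng.random(max(e - s - 1, 0)) < config.island_cpg_rate
            )
            # avoid overlapping plants
            keep = []
            last = -2
            for p in starts:
                if p > last + 1:
                    keep.append(p)
                    last = p
            for p in keep:
                seq[p] = b"C"
                seq[p + 1] = b"G"
        contigs[name] = seq.tobytes().decode("ascii")
        for gi, (s, e) in enumerate(gene_ivs):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GenomicInterval(name, s, e, strand, f"gene_{ci}_{gi}"))
        for ii, (s, e) in enumerate(island_ivs):
            islands.append(GenomicInterval(name, s, e, ".", f"island_{ci}_{ii}"))
    return ReferenceGenome(contigs), genes, islands


def _place_nonoverlapping(
    rng: np.random.Generator, contig_len: int, n: int, length: int
) -> List[Tuple[int, int]]:
    if n == 0:
        return []
    if n * length > contig_len:
        raise ValueError("layout exceeds contig length")
    placed: List[Tuple[int, int]] = []
    for _ in range(n * 50):
        if len(placed) == n:
            break
        s = int(rng.integers(0, contig_len - length))
        e = s + length
        if all(e <= ps or s >= pe for ps, pe in placed):
            placed.append((s, e))
    placed.sort()
    return placed


# --- modification placement ------------------------------------------------


def place_modifications(
    genome: ReferenceGenome,
    genes: Sequence[GenomicInterval],
    islands: Sequence[GenomicInterval],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    index: Optional[CpGIndex] = None,
) -> ModificationTruth:
    """Assign each CpG cytosine a class by its region's probabilities.

    Islands take precedence over gene bodies; both strands of a dyad draw
    independently unless ``symmetric_dyads`` forces the reverse cytosine to
    copy the forward one. Modifications stay in CpG context.
    """
    rng = rng if rng is not None else config.rngs()["placement"]
    index = index or build_cpg_index(genome)
    truth = ModificationTruth()
    for contig in genome.contigs:
        dyads = index.contig_positions(contig)
        if dyads.size == 0:
            continue
        in_island = _membership(dyads, islands, contig)
        in_gene = _membership(dyads, genes, contig)
        for i, dyad in enumerate(dyads):
            if in_island[i]:
                rates = config.rates_island
            elif in_gene[i]:
                rates = config.rates_genebody
            else:
                rates = config.rates_intergenic
            cls_fwd = _draw_class(rng, rates)
            cls_rev = cls_fwd if config.symmetric_dyads else _draw_class(rng, rates)
            if cls_fwd != "C":
                truth.modified[(contig, int(dyad), "+")] = cls_fwd
            if cls_rev != "C":
                truth.modified[(contig, int(dyad) + 1, "-")] = cls_rev
    return truth


def _membership(
    positions: np.ndarray, regions: Sequence[GenomicInterval], contig: str
) -> np.ndarray:
    mask = np.zeros(positions.shape, dtype=bool)
    for r in regions:
        if r.contig != contig:
            continue
        mask |= (positions >= r.start) & (positions < r.end)
    return mask


def _draw_class(rng: np.random.Generator, rates: RegionRates) -> str:
    u = rng.random()
    if u < rates.p_5hmC:
        return "5hmC"
    if u < rates.p_5hmC + rates.p_5mC:
        return "5mC"
    if u < rates.p_5hmC + rates.p_5mC + rates.p_5fC:
        return "5fC"
    return "C"


# --- fragmentation and pull-down -------------------------------------------


def fragmentize_and_pulldown(
    genome: ReferenceGenome,
    truth: ModificationTruth,
    config: SimulationConfig,
    rng_frag: Optional[np.random.Generator] = None,
    rng_pull: Optional[np.random.Generator] = None,
    mode: str = "ebs",
) -> Tuple[List[SimFragment], List[SimFragment]]:
    """Draw ``library_size`` candidate molecules; return (candidates, retained).

    A fragment's original strand is uniform; pull-down retains it with
    ``capture_prob`` when that strand carries >= 1 truth 5hmC, else with
    ``carryover_prob``. ACE mode bypasses the pull-down entirely.
    """
    if mode not in ("ebs", "seal", "ace"):
        raise ValueError(f"unknown mode {mode!r}")
    rngs = config.rngs()
    rng_frag = rng_frag if rng_frag is not None else rngs["fragmentation"]
    rng_pull = rng_pull if rng_pull is not None else rngs["pulldown"]
    contig_names = list(genome.contigs)
    lengths = np.asarray([genome.length(c) for c in contig_names], dtype=float)
    weights = lengths / lengths.sum()
    hmc_cache = {
        (c, s): truth.hmc_positions(c, s) for c in contig_names for s in "+-"
    }
    candidates: List[SimFragment] = []
    retained: List[SimFragment] = []
    for _ in range(config.library_size):
        ci = int(rng_frag.choice(len(contig_names), p=weights))
        contig = contig_names[ci]
        clen = int(lengths[ci])
        flen = int(round(rng_frag.normal(config.fragment_mean, config.fragment_sd)))
        flen = max(config.fragment_min, min(flen, clen))
        start = int(rng_frag.integers(0, clen - flen + 1))
        end = start + flen
        strand = "+" if rng_frag.random() < 0.5 else "-"
        hpos = hmc_cache[(contig, strand)]
        lo, hi = np.searchsorted(hpos, [start, end])
        frag = SimFragment(contig, start, end, strand, int(hi - lo))
        candidates.append(frag)
        if mode == "ace":
            retained.append(frag)
        else:
            p = config.capture_prob if frag.n_hmc_strand >= 1 else config.carryover_prob
            if rng_pull.random() < p:
                retained.append(frag)
    if not retained:
        raise ValueError(
            "pull-down retained zero fragments; raise library_size, capture_prob "
            "or modification rates"
        )
    return candidates, retained


def expected_no_hmc_fraction(
    candidates: Sequence[SimFragment],
    truth: ModificationTruth,
    genome: ReferenceGenome,
    config: SimulationConfig,
) -> float:
    """Closed-form expectation of FilterReport.fraction_no_hmc.

    Derived from config + truth only (independent of the calling path):
    for each candidate molecule, P(retained) is capture or carry-over by its
    strand-level truth, and P(no signal) is the product of per-covered-CpG
    conversion probabilities over the read-covered cytosines of its strand.
    Sequencing error and the conversion filter are neglected, so this is
    exact for error-free chemistry.
    """
    index = build_cpg_index(genome)
    e_no = 0.0
    e_with = 0.0
    for frag in candidates:
        p_keep = (
            config.capture_prob if frag.n_hmc_strand >= 1 else config.carryover_prob
        )
        covered = _covered_intervals(frag, config.read_length)
        p_no_signal = 1.0
        dyads = index.contig_positions(frag.contig)
        for a, b in covered:
            if frag.original_strand == "+":
                lo, hi = np.searchsorted(dyads, [a, b])
                cyt = dyads[lo:hi]
                strand = "+"
            else:
                lo, hi = np.searchsorted(dyads + 1, [a, b])
                cyt = dyads[lo:hi] + 1
                strand = "-"
            for pos in cyt:
                cls = truth.class_of(frag.contig, int(pos), strand)
                p_no_signal *= config.p_convert.get(cls, 1.0)
        e_no += p_keep * p_no_signal
        e_with += p_keep * (1.0 - p_no_signal)
    if e_no + e_with == 0:
        raise ValueError("no fragments expected to survive pull-down")
    return e_no / (e_no + e_with)


def _mate_extents(frag: SimFragment, read_length: int) -> List[Tuple[int, int]]:
    """The two mate intervals: first and last ``read_length`` bp of the fragment."""
    return [
        (frag.start, min(frag.start + read_length, frag.end)),
        (max(frag.end - read_length, frag.start), frag.end),
    ]


def _covered_intervals(frag: SimFragment, read_length: int) -> List[Tuple[int, int]]:
    """Union of read-covered sub-intervals under the paired-end layout."""
    if frag.length <= 2 * read_length:
        return [(frag.start, frag.end)]
    return _mate_extents(frag, read_length)


# --- deamination and reads -------------------------------------------------

_ERROR_CHOICES = {b: [x for x in b"ACGT" if x != b] for b in b"ACGT"}


def deaminate_and_read(
    fragments: Sequence[SimFragment],
    genome: ReferenceGenome,
    truth: ModificationTruth,
    config: SimulationConfig,
    rng_conv: Optional[np.random.Generator] = None,
    rng_err: Optional[np.random.Generator] = None,
    rng_dup: Optional[np.random.Generator] = None,
    id_prefix: str = "frag",
) -> List[AlignedFragment]:
    """Deaminate each molecule's original strand and cut 150 bp paired reads.

    Conversion shows as C->T (OT) or G->A (OB) in the forward projection.
    Sequencing errors are applied per read copy after conversion; duplicates
    are injected at the configured rate as extra identical molecules
    (re-reading the same converted strand, with independent errors).
    """
    rngs = config.rngs()
    rng_conv = rng_conv if rng_conv is not None else rngs["conversion"]
    rng_err = rng_err if rng_err is not None else rngs["error"]
    rng_dup = rng_dup if rng_dup is not None else rngs["duplication"]
    out: List[AlignedFragment] = []
    for fi, frag in enumerate(fragments):
        fwd = genome[frag.contig][frag.start : frag.end]
        converted = _convert_strand(fwd, frag, truth, config, rng_conv)
        n_copies = 1 + (1 if rng_dup.random() < config.duplicate_rate else 0)
        for copy in range(n_copies):
            name = f"{id_prefix}_{fi}" if copy == 0 else f"{id_prefix}_{fi}_dup{copy}"
            mates = []
            for a, b in _mate_extents(frag, config.read_length):
                seq = list(converted[a - frag.start : b - frag.start])
                if config.error_rate > 0:
                    hits = np.flatnonzero(rng_err.random(len(seq)) < config.error_rate)
                    for h in hits:
                        cur = ord(seq[h])
                        if cur in _ERROR_CHOICES:
                            seq[h] = chr(rng_err.choice(_ERROR_CHOICES[cur]))
                quals = np.full(len(seq), config.base_quality, dtype=np.int16)
                mates.append(Mate(a, "".join(seq), quals))
            out.append(
                AlignedFragment(
                    fragment_id=name,
                    contig=frag.contig,
                    mate1=mates[0],
                    mate2=mates[1],
                    strand_tag=frag.conversion_strand,
                )
            )
    return out


def _convert_strand(
    fwd: str,
    frag: SimFragment,
    truth: ModificationTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    """Forward projection of the deaminated original strand."""
    seq = np.frombuffer(fwd.encode("ascii"), dtype="S1").copy()
    if frag.original_strand == "+":
        target, converted_to, strand = b"C", b"T", "+"
    else:
        target, converted_to, strand = b"G", b"A", "-"
    idx = np.flatnonzero(seq == target)
    if idx.size:
        u = rng.random(idx.size)
        for j, off in enumerate(idx):
            cls = truth.class_of(frag.contig, frag.start + int(off), strand)
            if u[j] < config.p_convert.get(cls, 1.0):
                seq[off] = converted_to
    return seq.tobytes().decode("ascii")


# --- spike-ins -------------------------------------------------------------


def make_spike_design(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SpikeInDesign:
    """Synthetic stand-in for the spike-in oligo pair (no published sequences).

    Two duplexes of equal length, identical except for four A<->T swaps that
    survive both conversion-collapses. The 5hmC duplex carries 5hmC at
    alternating CpG cytosines and 5mC at the rest; every other cytosine, and
    the whole control duplex, is unmodified. Dyad classes are symmetric so
    either strand of the modified duplex is captured.
    """
    rng = rng if rng is not None else config.rngs()["spike"]
    n = config.spike_length
    while True:
        seq = rng.choice(list("ACGT"), size=n, p=[0.3, 0.22, 0.22, 0.26])
        # guarantee a handful of CpGs
        for p in range(10, n - 2, 25):
            seq[p], seq[p + 1] = "C", "G"
        hmc_seq = "".join(seq)
        a_sites = [i for i, b in enumerate(hmc_seq) if b == "A" and 2 < i < n - 3]
        if len(a_sites) >= 4:
            break
    swap = sorted(rng.choice(a_sites, size=4, replace=False))
    ctl = list(hmc_seq)
    for p in swap:
        ctl[p] = "T"
    ctl_seq = "".join(ctl)

    classes: Dict[Tuple[str, int, str], str] = {}
    alternate = 0
    for name, s in (("spike_hmc", hmc_seq), ("spike_ctl", ctl_seq)):
        for i, b in enumerate(s):
            if b == "C":
                key_fwd = (name, i, "+")
                if name == "spike_hmc" and i + 1 < n and s[i + 1] == "G":
                    cls = "5hmC" if alternate % 2 == 0 else "5mC"
                    alternate += 1
                    classes[key_fwd] = cls
                    classes[(name, i + 1, "-")] = cls  # symmetric dyad
                else:
                    classes.setdefault(key_fwd, "C")
            elif b == "G":
                classes.setdefault((name, i, "-"), "C")
    return SpikeInDesign("spike_hmc", "spike_ctl", {"spike_hmc": hmc_seq, "spike_ctl": ctl_seq}, classes)


def spike_truth(design: SpikeInDesign) -> ModificationTruth:
    truth = ModificationTruth()
    for (name, pos, strand), cls in design.classes.items():
        if cls != "C":
            truth.modified[(name, pos, strand)] = cls
    return truth


def simulate_spike_fragments(
    design: SpikeInDesign, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[SimFragment], List[SimFragment]]:
    """Full-length spike molecules through the pull-down; (candidates, retained)."""
    rng = rng if rng is not None else config.rngs()["spike"]
    truth = spike_truth(design)
    candidates: List[SimFragment] = []
    retained: List[SimFragment] = []
    for name in design.names:
        n = len(design.sequences[name])
        hpos = {s: truth.hmc_positions(name, s) for s in "+-"}
        for _ in range(config.spike_copies):
            strand = "+" if rng.random() < 0.5 else "-"
            frag = SimFragment(name, 0, n, strand, int(hpos[strand].size), is_spike=True)
            candidates.append(frag)
            p = config.capture_prob if frag.n_hmc_strand >= 1 else config.carryover_prob
            if rng.random() < p:
                retained.append(frag)
    return candidates, retained


# --- end-to-end ------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: ReferenceGenome  # genomic + spike contigs
    genes: List[GenomicInterval]
    islands: List[GenomicInterval]
    truth: ModificationTruth  # genomic + spike truth
    design: SpikeInDesign
    candidates: List[SimFragment]
    retained: List[SimFragment]
    spike_candidates: List[SimFragment]
    spike_retained: List[SimFragment]
    fragments: List[AlignedFragment]  # reads of retained genomic + spike molecules


def simulate_dataset(config: SimulationConfig, mode: str = "ebs",
                     with_spikes: bool = True) -> SimulatedDataset:
    """Compose the full chemistry in memory under one seed."""
    config.validate()
    rngs = config.rngs()
    genome, genes, islands = build_genome(config, rngs["genome"])
    truth = place_modifications(genome, genes, islands, config, rngs["placement"])
    candidates, retained = fragmentize_and_pulldown(
        genome, truth, config, rngs["fragmentation"], rngs["pulldown"], mode=mode
    )
    design = make_spike_design(config, rngs["spike"])
    combined = ReferenceGenome({**genome.contigs, **design.sequences})
    full_truth = ModificationTruth(dict(truth.modified))
    spike_cand: List[SimFragment] = []
    spike_ret: List[SimFragment] = []
    if with_spikes and config.spike_copies > 0 and mode != "seal":
        full_truth.modified.update(spike_truth(design).modified)
        spike_cand, spike_ret = simulate_spike_fragments(design, config, rngs["spike"])
    reads = deaminate_and_read(
        list(retained) + list(spike_ret), combined, full_truth, config,
        rngs["conversion"], rngs["error"], rngs["duplication"],
    )
    return SimulatedDataset(
        config=config, genome=combined, genes=genes, islands=islands,
        truth=full_truth, design=design, candidates=candidates,
        retained=retained, spike_candidates=spike_cand, spike_retained=spike_ret,
        fragments=reads,
    )


def emit_dataset(
    config: SimulationConfig,
    outdir: Union[str, Path],
    mode: str = "ebs",
    with_spikes: bool = True,
    overwrite: bool = False,
) -> Dict[str, Path]:
    """Write the dataset bundle; same seed twice gives identical checksums."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (use overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config, mode=mode, with_spikes=with_spikes)
    paths = {
        "reference": outdir / "reference.fa",
        "genes": outdir / "genes.bed",
        "islands": outdir / "islands.bed",
        "truth": outdir / "truth.bed",
        "sam": outdir / "reads.sam",
        "fastq1": outdir / "reads_R1.fastq.gz",
        "fastq2": outdir / "reads_R2.fastq.gz",
        "spike_fasta": outdir / "spike_design.fa",
        "spike_tsv": outdir / "spike_truth.tsv",
        "config": outdir / "config.json",
    }
    write_reference(ds.genome, paths["reference"])
    write_bed(ds.genes, paths["genes"])
    write_bed(ds.islands, paths["islands"])
    ds.truth.write_bed(paths["truth"])
    _write_sam(ds.fragments, ds.genome, paths["sam"])
    _write_fastq(ds.fragments, paths["fastq1"], paths["fastq2"])
    ds.design.to_files(paths["spike_fasta"], paths["spike_tsv"])
    config.to_json(paths["config"])
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tmd5\n")
        for key in sorted(paths):
            data = paths[key].read_bytes()
            if paths[key].suffix == ".gz":
                data = gzip.decompress(data)
            fh.write(f"{paths[key].name}\t{hashlib.md5(data).hexdigest()}\n")
    paths["manifest"] = manifest
    return paths


def _write_sam(
    fragments: Sequence[AlignedFragment], genome: ReferenceGenome, path: Path
) -> None:
    from .readcall import write_fragments_sam

    write_fragments_sam(fragments, genome, path)


def _write_fastq(
    fragments: Sequence[AlignedFragment], path1: Path, path2: Path
) -> None:
    with gzip.open(path1, "wt") as f1, gzip.open(path2, "wt") as f2:
        for frag in fragments:
            m1, m2 = frag.mate1, frag.mate2
            q1 = "".join(chr(q + 33) for q in (m1.quals if m1.quals is not None else []))
            f1.write(f"@{frag.fragment_id}/1\n{m1.seq}\n+\n{q1}\n")
            if m2 is not None:
                q2 = "".join(chr(q + 33) for q in (m2.quals if m2.quals is not None else []))
                f2.write(
                    f"@{frag.fragment_id}/2\n{reverse_complement(m2.seq)}\n+\n{q2[::-1]}\n"
                )
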