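"""Per-fragment cytosine conversion-state calling from aligned read pairs.

The deamination chemistry acts on one strand of the denatured fragment: a
fragment from the original top strand (OT) shows deamination as C->T against
the forward reference, one from the original bottom strand (OB) as G->A.
Calling therefore walks every reference C (OT) or G (OB) covered by either
mate and classifies the read base as converted, unconverted (the 5hmC
signal) or ambiguous. Positions covered by both mates yield a single call;
mate disagreement and sub-threshold base qualities are ambiguous, and
ambiguous calls never count toward any filter or tally.

SAM interchange uses the two-letter tag ``ZS`` (value ``OT`` or ``OB``) to
carry the conversion strand; alignment is modelled as ungapped, and records
whose CIGAR contains anything but a single match run are skipped with a
logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Tuple, Union

import numpy as np
import pysam

from .refmod import CONTEXT_BY_CODE, CytosineContext, ReferenceGenome

logger = logging.getLogger(__name__)

STRAND_TAG = "ZS"

# call-state codes used in the packed arrays
CONVERTED, UNCONVERTED, AMBIGUOUS = 1, 2, 3
STATE_NAMES = {CONVERTED: "converted", UNCONVERTED: "unconverted", AMBIGUOUS: "ambiguous"}

DEFAULT_MIN_QUALITY = 20


class AmbiguousStrandError(ValueError):
    """Conversion-strand evidence is tied or absent."""


class ConversionStrand:
    OT = "OT"
    OB = "OB"


class CytosineCall(NamedTuple):
    contig: str
    pos: int
    strand: str
    context: CytosineContext
    state: str


@dataclass
class Mate:
    """One ungapped aligned mate, sequence stored forward-projected."""

    start: int
    seq: str
    quals: Optional[np.ndarray] = None  # phred, aligned with seq

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class AlignedFragment:
    fragment_id: str
    contig: str
    mate1: Mate
    mate2: Optional[Mate] = None
    strand_tag: Optional[str] = None

    @property
    def mates(self) -> List[Mate]:
        return [m for m in (self.mate1, self.mate2) if m is not None]

    @property
    def start(self) -> int:
        return min(m.start for m in self.mates)

    @property
    def end(self) -> int:
        return max(m.end for m in self.mates)

    @property
    def insert_size(self) -> int:
        return self.end - self.start

    def mean_quality(self) -> float:
        vals = [m.quals for m in self.mates if m.quals is not None]
        if not vals:
            return 0.0
        return float(np.mean(np.concatenate(vals)))


@dataclass
class FragmentCallSet:
    """Calls of one fragment, packed as parallel arrays.

    ``positions`` are forward coordinates of the dyad base (forward C for OT,
    forward G for OB); ``context_codes`` follow refmod (0 CpG / 1 CHG /
    2 CHH); ``states`` use the codes above. All calls share the fragment's
    conversion strand, so the per-call strand is '+' for OT and '-' for OB.
    """

    fragment_id: str
    contig: str
    conversion_strand: str
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    context_codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    states: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))

    @property
    def strand(self) -> str:
        return "+" if self.conversion_strand == ConversionStrand.OT else "-"

    @property
    def n_calls(self) -> int:
        return int(self.positions.size)

    @property
    def n_unconverted_nonCpG(self) -> int:
        return int(np.count_nonzero((self.states == UNCONVERTED) & (self.context_codes != 0)))

    @property
    def n_unconverted_CpG(self) -> int:
        return int(np.count_nonzero((self.states == UNCONVERTED) & (self.context_codes == 0)))

    @property
    def calls(self) -> List[CytosineCall]:
        return [
            CytosineCall(
                self.contig,
                int(p),
                self.strand,
                CONTEXT_BY_CODE[int(c)],
                STATE_NAMES[int(s)],
            )
            for p, c, s in zip(self.positions, self.context_codes, self.states)
        ]


def infer_conversion_strand(
    fragment: AlignedFragment, genome: ReferenceGenome, honor_tag: bool = True
) -> str:
    """Majority vote over C->T (OT) versus G->A (OB) evidence across mates.

    An input ``ZS`` tag, when present and honored, wins; a contradiction with
    the read-level majority is logged. Tied or absent evidence without a tag
    raises AmbiguousStrandError.
    """
    ref = genome.seq_bytes(fragment.contig)
    n_ot = n_ob = 0
    for mate in fragment.mates:
        read = np.frombuffer(mate.seq.encode("ascii"), dtype="S1")
        refslice = ref[mate.start : mate.end]
        n_ot += int(np.count_nonzero((refslice == b"C") & (read == b"T")))
        n_ob += int(np.count_nonzero((refslice == b"G") & (read == b"A")))
    majority: Optional[str] = None
    if n_ot > n_ob:
        majority = ConversionStrand.OT
    elif n_ob > n_ot:
        majority = ConversionStrand.OB
    if honor_tag and fragment.strand_tag in (ConversionStrand.OT, ConversionStrand.OB):
        if majority is not None and majority != fragment.strand_tag:
            logger.warning(
                "fragment %s: %s tag %s contradicts read evidence (%d C>T vs %d G>A); tag wins",
                fragment.fragment_id, STRAND_TAG, fragment.strand_tag, n_ot, n_ob,
            )
        return fragment.strand_tag
    if majority is None:
        raise AmbiguousStrandError(
            f"fragment {fragment.fragment_id}: tied/absent conversion evidence "
            f"({n_ot} C>T vs {n_ob} G>A)"
        )
    return majority


def _mate_states(
    mate: Mate, positions: np.ndarray, conv_from: bytes, conv_to: bytes, min_quality: int
) -> np.ndarray:
    """States (0 = not covered) observed by one mate at reference positions."""
    states = np.zeros(positions.shape, dtype=np.int8)
    covered = (positions >= mate.start) & (positions < mate.end)
    if not covered.any():
        return states
    idx = positions[covered] - mate.start
    read = np.frombuffer(mate.seq.encode("ascii"), dtype="S1")[idx]
    s = np.full(idx.shape, AMBIGUOUS, dtype=np.int8)
    s[read == conv_to] = CONVERTED
    s[read == conv_from] = UNCONVERTED
    if mate.quals is not None and min_quality > 0:
        s[mate.quals[idx] < min_quality] = AMBIGUOUS
    states[covered] = s
    return states


def call_fragment(
    fragment: AlignedFragment,
    genome: ReferenceGenome,
    conversion_strand: Optional[str] = None,
    min_quality: int = DEFAULT_MIN_QUALITY,
) -> FragmentCallSet:
    """Call conversion states for every informative cytosine of a fragment.

    Context comes from the reference, never from the read; positions without
    a defined context (N in the deciding window, truncated window) are
    dropped. A position covered by both mates yields one call, ambiguous on
    disagreement.
    """
    if fragment.contig not in genome:
        raise KeyError(f"unknown contig {fragment.contig!r}")
    strand = conversion_strand or infer_conversion_strand(fragment, genome)
    if strand == ConversionStrand.OT:
        all_pos = genome.c_positions(fragment.contig)
        conv_from, conv_to = b"C", b"T"
        ctx_all = genome.context_codes(fragment.contig, "+")
    else:
        all_pos = genome.g_positions(fragment.contig)
        conv_from, conv_to = b"G", b"A"
        ctx_all = genome.context_codes(fragment.contig, "-")
    lo, hi = np.searchsorted(all_pos, [fragment.start, fragment.end])
    positions = all_pos[lo:hi]
    contexts = ctx_all[lo:hi]

    combined = np.zeros(positions.shape, dtype=np.int8)
    for mate in fragment.mates:
        s = _mate_states(mate, positions, conv_from, conv_to, min_quality)
        new = combined == 0
        combined[new] = s[new]
        disagree = (combined != 0) & (s != 0) & (combined != s)
        combined[disagree] = AMBIGUOUS

    keep = (combined != 0) & (contexts >= 0)
    return FragmentCallSet(
        fragment_id=fragment.fragment_id,
        contig=fragment.contig,
        conversion_strand=strand,
        positions=positions[keep].astype(np.int64),
        context_codes=contexts[keep],
        states=combined[keep],
    )


def deduplicate(
    fragments: List[AlignedFragment], genome: Optional[ReferenceGenome] = None
) -> List[AlignedFragment]:
    """Coordinate deduplication on (contig, start, end, conversion strand).

    The survivor is the fragment with the highest mean base quality; ties
    keep the earliest in input order. Directional-library semantics: two
    fragments with identical coordinates but opposite conversion strands are
    distinct molecules.
    """
    best: Dict[Tuple[str, int, int, str], Tuple[float, int]] = {}
    strands: List[str] = []
    for i, frag in enumerate(fragments):
        strand = frag.strand_tag
        if strand not in (ConversionStrand.OT, ConversionStrand.OB):
            if genome is None:
                raise ValueError(
                    f"fragment {frag.fragment_id} lacks a strand tag and no genome "
                    "was given for inference"
                )
            strand = infer_conversion_strand(frag, genome)
        strands.append(strand)
        key = (frag.contig, frag.start, frag.end, strand)
        q = frag.mean_quality()
        if key not in best or q > best[key][0]:
            best[key] = (q, i)
    winners = sorted(i for _, i in best.values())
    return [fragments[i] for i in winners]


# --- SAM interchange -------------------------------------------------------


def _is_ungapped(rec: pysam.AlignedSegment) -> bool:
    return rec.cigartuples is not None and len(rec.cigartuples) == 1 and rec.cigartuples[0][0] == 0


def read_fragments_sam(path: Union[str, Path]) -> List[AlignedFragment]:
    """Read paired ungapped alignments into fragments, pairing by name.

    Records that are unmapped, secondary/supplementary, or not a single
    match run are skipped (counted in the log). Mates must share a contig.
    """
    pending: Dict[str, pysam.AlignedSegment] = {}
    fragments: List[AlignedFragment] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            if not _is_ungapped(rec):
                n_skipped += 1
                continue
            name = rec.query_name
            if name in pending:
                other = pending.pop(name)
                first, second = (other, rec) if other.is_read1 else (rec, other)
                if first.reference_name != second.reference_name:
                    n_skipped += 2
                    continue
                tag = first.get_tag(STRAND_TAG) if first.has_tag(STRAND_TAG) else None
                fragments.append(
                    AlignedFragment(
                        fragment_id=name,
                        contig=first.reference_name,
                        mate1=_mate_from_record(first),
                        mate2=_mate_from_record(second),
                        strand_tag=tag,
                    )
                )
            else:
                pending[name] = rec
    # unpaired leftovers become single-mate fragments
    for name, rec in pending.items():
        tag = rec.get_tag(STRAND_TAG) if rec.has_tag(STRAND_TAG) else None
        fragments.append(
            AlignedFragment(name, rec.reference_name, _mate_from_record(rec), None, tag)
        )
    if n_skipped:
        logger.info("skipped %d SAM records (unmapped/secondary/gapped)", n_skipped)
    return fragments


def _mate_from_record(rec: pysam.AlignedSegment) -> Mate:
    quals = None
    if rec.query_qualities is not None:
        quals = np.asarray(rec.query_qualities, dtype=np.int16)
    return Mate(start=rec.reference_start, seq=rec.query_sequence.upper(), quals=quals)


def sam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(seq)} for name, seq in genome.contigs.items()
            ],
        }
    )


def write_fragments_sam(
    fragments: Iterable[AlignedFragment],
    genome: ReferenceGenome,
    path: Union[str, Path],
) -> None:
    """Write fragments back as a coordinate-sorted plain-text SAM."""
    header = sam_header(genome)
    order = {name: i for i, name in enumerate(genome.contigs)}
    frags = sorted(fragments, key=lambda f: (order[f.contig], f.start, f.end))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for frag in frags:
            mates = frag.mates
            for i, mate in enumerate(mates):
                rec = pysam.AlignedSegment(header)
                rec.query_name = frag.fragment_id
                rec.reference_id = header.get_tid(frag.contig)
                rec.reference_start = mate.start
                rec.query_sequence = mate.seq
                rec.cigartuples = [(0, len(mate.seq))]
                rec.mapping_quality = 42
                if mate.quals is not None:
                    rec.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in mate.quals)
                    )
                if len(mates) == 2:
                    other = mates[1 - i]
                    rec.flag = (0x1 | 0x2) | (0x40 if i == 0 else 0x80)
                    if i == 1:
                        rec.flag |= 0x10
                    else:
                        rec.flag |= 0x20
                    rec.next_reference_id = rec.reference_id
                    rec.next_reference_start = other.start
                    span = frag.end - frag.start
                    rec.template_length = span if i == 0 else -span
                else:
                    rec.flag = 0
                if frag.strand_tag:
                    rec.set_tag(STRAND_TAG, frag.strand_tag)
                out.write(rec)


def write_calls_tsv(callsets: Iterable[FragmentCallSet], path: Union[str, Path]) -> None:
    """Export calls as TSV: fragment id, contig, pos, strand, context, state."""
    with open(path, "w") as fh:
        fh.write("fragment_id\tcontig\tpos\tstrand\tcontext\tstate\n")
        for cs in callsets:
            for call in cs.calls:
                fh.write(
                    f"{cs.fragment_id}\t{call.contig}\t{call.pos}\t{call.strand}"
                    f"\t{call.context.value}\t{call.state}\n"
                )
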