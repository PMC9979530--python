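"""Reference genome handling, cytosine context classification and CpG indexing.

Coordinates are 0-based half-open everywhere in this package; 1-based
positions appear only in the cytosine-report output format. A "CpG site" is
the forward-strand C coordinate of the symmetric CG/CG dyad.

Cytosine context (CpG / CHG / CHH) is always classified on the reading
strand, 5'->3': for a forward-strand cytosine the two downstream forward
bases decide; for a reverse-strand cytosine (a forward-strand G) the
complements of the two upstream forward bases decide. Positions whose
deciding window contains an N or runs off the contig get no context and are
excluded from all downstream counting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CytosineContext(enum.Enum):
    """Trinucleotide context of a cytosine on its reading strand."""

    CPG = "CpG"
    CHG = "CHG"
    CHH = "CHH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class ReferenceGenome:
    """In-memory reference: uppercase contig sequences over {A,C,G,T,N}."""

    def __init__(self, contigs: Dict[str, str], map_invalid_to_n: bool = False):
        if not contigs:
            raise ValueError("reference has no contigs")
        clean: Dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                if map_invalid_to_n:
                    seq = "".join(b if b in VALID_BASES else "N" for b in seq)
                else:
                    raise ValueError(
                        f"contig {name!r} contains invalid bases {sorted(bad)}"
                    )
            clean[name] = seq
        self.contigs = clean
        # lazy per-contig caches used by the vectorised calling path
        self._bytes: Dict[str, np.ndarray] = {}
        self._c_positions: Dict[str, np.ndarray] = {}
        self._g_positions: Dict[str, np.ndarray] = {}
        self._ctx_plus: Dict[str, np.ndarray] = {}
        self._ctx_minus: Dict[str, np.ndarray] = {}

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __getitem__(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None

    def length(self, contig: str) -> int:
        return len(self[contig])

    def base(self, contig: str, pos: int) -> str:
        seq = self[contig]
        if not 0 <= pos < len(seq):
            raise IndexError(f"position {pos} outside {contig} (len {len(seq)})")
        return seq[pos]

    # --- numpy caches -----------------------------------------------------

    def seq_bytes(self, contig: str) -> np.ndarray:
        """Contig as an array of single-byte codes (b'A' etc.)."""
        if contig not in self._bytes:
            self._bytes[contig] = np.frombuffer(
                self[contig].encode("ascii"), dtype="S1"
            )
        return self._bytes[contig]

    def c_positions(self, contig: str) -> np.ndarray:
        """Sorted forward-strand C coordinates."""
        if contig not in self._c_positions:
            self._c_positions[contig] = np.flatnonzero(
                self.seq_bytes(contig) == b"C"
            )
        return self._c_positions[contig]

    def g_positions(self, contig: str) -> np.ndarray:
        """Sorted forward-strand G coordinates (reverse-strand cytosines)."""
        if contig not in self._g_positions:
            self._g_positions[contig] = np.flatnonzero(
                self.seq_bytes(contig) == b"G"
            )
        return self._g_positions[contig]

    def context_codes(self, contig: str, strand: str) -> np.ndarray:
        """Per-cytosine context codes aligned with c_positions / g_positions.

        Codes: 0 = CpG, 1 = CHG, 2 = CHH, -1 = no context (N or truncated).
        """
        cache = self._ctx_plus if strand == "+" else self._ctx_minus
        if contig not in cache:
            b = self.seq_bytes(contig)
            n = len(b)
            if strand == "+":
                pos = self.c_positions(contig)
                b1 = np.full(pos.shape, b"N", dtype="S1")
                b2 = np.full(pos.shape, b"N", dtype="S1")
                ok1 = pos + 1 < n
                ok2 = pos + 2 < n
                b1[ok1] = b[pos[ok1] + 1]
                b2[ok2] = b[pos[ok2] + 2]
                off1 = ~ok1
                off2 = ~ok2
            else:
                pos = self.g_positions(contig)
                # reverse-strand reading: next bases are complements of
                # forward pos-1, pos-2; complement(C)=G decides CpG/CHG
                b1 = np.full(pos.shape, b"N", dtype="S1")
                b2 = np.full(pos.shape, b"N", dtype="S1")
                ok1 = pos - 1 >= 0
                ok2 = pos - 2 >= 0
                b1[ok1] = b[pos[ok1] - 1]
                b2[ok2] = b[pos[ok2] - 2]
                off1 = ~ok1
                off2 = ~ok2
            codes = np.full(pos.shape, -1, dtype=np.int8)
            if strand == "+":
                is_g1 = b1 == b"G"
                is_g2 = b2 == b"G"
            else:
                is_g1 = b1 == b"C"  # complement(C) == G on reading strand
                is_g2 = b2 == b"C"
            n1 = (b1 == b"N") | off1
            n2 = (b2 == b"N") | off2
            codes[is_g1] = 0  # CpG decided by the first base alone
            need2 = ~is_g1 & ~n1
            codes[need2 & is_g2] = 1
            codes[need2 & ~is_g2 & ~n2] = 2
            # CpG stands even if the +2 base is N; CHG/CHH need both
            codes[n1] = -1
            cache[contig] = codes
        return cache[contig]


CONTEXT_BY_CODE = {0: CytosineContext.CPG, 1: CytosineContext.CHG, 2: CytosineContext.CHH}


def load_reference(path: Union[str, Path], map_invalid_to_n: bool = False) -> ReferenceGenome:
    """Load a (multi-)FASTA into memory; duplicate contig names are an error."""
    contigs: Dict[str, str] = {}
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq)
    if n_records == 0:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(contigs, map_invalid_to_n=map_invalid_to_n)


def write_reference(genome: ReferenceGenome, path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def classify_context(
    genome: ReferenceGenome, contig: str, pos: int, strand: str
) -> Optional[CytosineContext]:
    """Context of the cytosine at (contig, pos, strand), or None.

    ``pos`` is the forward coordinate: a forward C for strand '+', a forward
    G for strand '-'. Raises if the base there is not a cytosine on the
    requested strand. Returns None when a deciding base is N or off-contig.
    """
    base = genome.base(contig, pos)
    if strand == "+":
        if base != "C":
            raise ValueError(f"{contig}:{pos}+ is {base}, not C")
        positions = genome.c_positions(contig)
    elif strand == "-":
        if base != "G":
            raise ValueError(f"{contig}:{pos}- is {base}, not a reverse-strand C")
        positions = genome.g_positions(contig)
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    idx = int(np.searchsorted(positions, pos))
    code = int(genome.context_codes(contig, strand)[idx])
    return CONTEXT_BY_CODE.get(code)


@dataclass
class CpGIndex:
    """Per-contig sorted arrays of CpG dyad positions (forward C coordinate)."""

    positions: Dict[str, np.ndarray] = field(default_factory=dict)

    def __contains__(self, key) -> bool:
        contig, pos = key
        arr = self.positions.get(contig)
        if arr is None or arr.size == 0:
            return False
        i = int(np.searchsorted(arr, pos))
        return i < arr.size and arr[i] == pos

    def size(self, contig: Optional[str] = None) -> int:
        if contig is not None:
            return int(self.positions.get(contig, np.empty(0)).size)
        return int(sum(a.size for a in self.positions.values()))

    def contig_positions(self, contig: str) -> np.ndarray:
        return self.positions.get(contig, np.empty(0, dtype=np.int64))


def build_cpg_index(genome: ReferenceGenome) -> CpGIndex:
    """Index every position p with base(p)=C and base(p+1)=G."""
    index = CpGIndex()
    for contig in genome.contigs:
        b = genome.seq_bytes(contig)
        dyads = np.flatnonzero((b[:-1] == b"C") & (b[1:] == b"G"))
        index.positions[contig] = dyads.astype(np.int64)
    return index


def count_cpg_in(index: CpGIndex, region: GenomicInterval) -> int:
    """Number of dyad positions p with region.start <= p < region.end."""
    if region.contig not in index.positions:
        raise KeyError(f"unknown contig {region.contig!r}")
    arr = index.positions[region.contig]
    lo, hi = np.searchsorted(arr, [region.start, region.end])
    return int(hi - lo)


# --- BED I/O ---------------------------------------------------------------


def read_bed(path: Union[str, Path]) -> List[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open; strand column optional)."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(contig, start, end, strand, name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )
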