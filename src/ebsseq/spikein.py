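"""Spike-in control QC: enrichment fraction and deamination efficiency.

Two near-identical synthetic duplexes are spiked into a library, one
carrying 5hmC at its CpGs and one without the modification. Because only
5hmC-bearing molecules should survive the pull-down, the share of spike
reads from the modified duplex measures enrichment; and because the truth
class of every spike cytosine is known, conversion rates per class
(C / 5mC / 5hmC), per position, and for unmodified cytosines next to a 5hmC
measure the deamination chemistry itself.

Spike assignment is conversion-collapsed: T is treated as C when comparing
an OT fragment (and A as G for OB), so deamination can never break the
match. The two designs must therefore stay distinguishable after collapse.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .readcall import (
    AMBIGUOUS, CONVERTED, UNCONVERTED, AlignedFragment, ConversionStrand,
    FragmentCallSet,
)
from .refmod import ReferenceGenome

CLASSES = ("C", "5mC", "5hmC")


@dataclass
class SpikeInDesign:
    """Two spike duplexes with per-cytosine truth classes.

    ``classes`` maps (spike name, forward pos, strand) -> one of C/5mC/5hmC
    for every cytosine on both strands of both duplexes (strand '-' entries
    sit at forward G coordinates).
    """

    hmc_name: str
    control_name: str
    sequences: Dict[str, str]
    classes: Dict[Tuple[str, int, str], str]

    def __post_init__(self) -> None:
        for name in (self.hmc_name, self.control_name):
            if name not in self.sequences:
                raise ValueError(f"missing sequence for spike {name!r}")
        for collapse in ("CT", "GA"):
            a = _collapse(self.sequences[self.hmc_name], collapse)
            b = _collapse(self.sequences[self.control_name], collapse)
            if a == b:
                raise ValueError(
                    "spike designs are indistinguishable after "
                    f"{collapse[0]}/{collapse[1]} conversion-collapse"
                )
        for (name, pos, strand), cls in self.classes.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown truth class {cls!r}")
            base = self.sequences[name][pos]
            want = "C" if strand == "+" else "G"
            if base != want:
                raise ValueError(
                    f"truth class at {name}:{pos}{strand} sits on {base}, not a cytosine"
                )

    @property
    def names(self) -> Tuple[str, str]:
        return (self.hmc_name, self.control_name)

    def class_of(self, name: str, pos: int, strand: str) -> Optional[str]:
        return self.classes.get((name, pos, strand))

    def to_files(self, fasta: Union[str, Path], tsv: Union[str, Path]) -> None:
        with open(fasta, "w") as fh:
            for name in self.names:
                fh.write(f">{name}\n{self.sequences[name]}\n")
        rows = [
            {"spike": n, "pos": p, "strand": s, "class": c}
            for (n, p, s), c in sorted(self.classes.items())
        ]
        pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)

    @classmethod
    def from_files(cls, fasta: Union[str, Path], tsv: Union[str, Path]) -> "SpikeInDesign":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        if len(seqs) != 2:
            raise ValueError("spike design FASTA must hold exactly two sequences")
        df = pd.read_csv(tsv, sep="\t")
        classes = {
            (r.spike, int(r.pos), r.strand): r["class"] for _, r in df.iterrows()
        }
        names = list(seqs)
        has_hmc = {n: any(k[0] == n and v == "5hmC" for k, v in classes.items()) for n in names}
        hmc_name = next(n for n in names if has_hmc[n])
        control_name = next(n for n in names if n != hmc_name)
        return cls(hmc_name, control_name, seqs, classes)


_CT = str.maketrans("T", "C")
_GA = str.maketrans("A", "G")


def _collapse(seq: str, mode: str) -> str:
    return seq.translate(_CT if mode == "CT" else _GA)


def _mismatches(read: str, ref: str, offset: int, mode: str) -> int:
    """Collapsed mismatch count of a read against a spike at an offset."""
    if offset < 0 or offset + len(read) > len(ref):
        return len(read)  # effectively non-matching
    window = ref[offset : offset + len(read)]
    r = np.frombuffer(_collapse(read, mode).encode("ascii"), dtype="S1")
    w = np.frombuffer(_collapse(window, mode).encode("ascii"), dtype="S1")
    return int(np.count_nonzero(r != w))


def match_spikein(
    fragments: Sequence[AlignedFragment],
    design: SpikeInDesign,
    max_mismatch: int = 2,
) -> Dict[str, List[AlignedFragment]]:
    """Partition fragments into {'hmc_spike', 'control_spike', 'other'}.

    A fragment aligned to a spike contig is compared against *both* spike
    sequences at its aligned offset under the conversion-collapse of its
    strand; it is assigned to the closer one when within the mismatch
    budget, otherwise to 'other'. Fragments on genomic contigs are 'other'.
    """
    out: Dict[str, List[AlignedFragment]] = {"hmc_spike": [], "control_spike": [], "other": []}
    for frag in fragments:
        if frag.contig not in design.names:
            out["other"].append(frag)
            continue
        mode = "GA" if frag.strand_tag == ConversionStrand.OB else "CT"
        dists = {}
        for name in design.names:
            ref = design.sequences[name]
            dists[name] = sum(
                _mismatches(m.seq, ref, m.start, mode) for m in frag.mates
            )
        hmc_d = dists[design.hmc_name]
        ctl_d = dists[design.control_name]
        budget = max_mismatch * len(frag.mates)
        if hmc_d < ctl_d and hmc_d <= budget:
            out["hmc_spike"].append(frag)
        elif ctl_d < hmc_d and ctl_d <= budget:
            out["control_spike"].append(frag)
        elif hmc_d == ctl_d and hmc_d <= budget:
            # equidistant: fall back to the aligned contig
            key = "hmc_spike" if frag.contig == design.hmc_name else "control_spike"
            out[key].append(frag)
        else:
            out["other"].append(frag)
    return out


def enrichment_fraction(partition: Dict[str, List[AlignedFragment]]) -> float:
    """Share of spike molecules coming from the 5hmC-bearing duplex."""
    n_hmc = len(partition.get("hmc_spike", ()))
    n_ctl = len(partition.get("control_spike", ()))
    if n_hmc + n_ctl == 0:
        raise ValueError("no spike-in reads found")
    return n_hmc / (n_hmc + n_ctl)


@dataclass
class RateEntry:
    converted: int
    total: int

    @property
    def rate_pct(self) -> Optional[float]:
        if self.total == 0:
            return None
        return 100.0 * self.converted / self.total


@dataclass
class SpikeInReport:
    """Deamination-efficiency QC surface; rates in percent with denominators."""

    enrichment_fraction: Optional[float]
    class_rates: Dict[str, RateEntry]
    position_rates: pd.DataFrame  # spike, pos, strand, class, converted, total, rate_pct
    neighbor_rate: RateEntry

    def to_json(self, path: Union[str, Path]) -> None:
        d = {
            "enrichment_fraction": self.enrichment_fraction,
            "class_rates_pct": {
                k: {"rate_pct": v.rate_pct, "converted": v.converted, "total": v.total}
                for k, v in self.class_rates.items()
            },
            "neighbor_rate_pct": {
                "rate_pct": self.neighbor_rate.rate_pct,
                "converted": self.neighbor_rate.converted,
                "total": self.neighbor_rate.total,
            },
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.position_rates.to_csv(path, sep="\t", index=False)


def conversion_report(
    callsets: Sequence[FragmentCallSet],
    design: SpikeInDesign,
    enrichment: Optional[float] = None,
) -> SpikeInReport:
    """Per-class / per-position / 5hmC-neighbor conversion rates on spikes.

    Each rate is converted/(converted+unconverted) over informative calls;
    ambiguous calls are excluded. Classes with no informative calls report
    an undefined (None) rate with a zero denominator. The neighbor rate
    covers unmodified cytosines with a truth 5hmC at an immediately adjacent
    base position (either strand).
    """
    conv: Dict[Tuple[str, int, str], int] = {}
    tot: Dict[Tuple[str, int, str], int] = {}
    for cs in callsets:
        if cs.contig not in design.names:
            continue
        strand = cs.strand
        for pos, state in zip(cs.positions, cs.states):
            if state == AMBIGUOUS:
                continue
            key = (cs.contig, int(pos), strand)
            if design.class_of(*key) is None:
                continue
            tot[key] = tot.get(key, 0) + 1
            if state == CONVERTED:
                conv[key] = conv.get(key, 0) + 1

    hmc_positions = {
        (name, pos)
        for (name, pos, strand), cls in design.classes.items()
        if cls == "5hmC"
    }

    class_rates = {c: RateEntry(0, 0) for c in CLASSES}
    neighbor = RateEntry(0, 0)
    rows = []
    for key in sorted(tot):
        name, pos, strand = key
        cls = design.class_of(name, pos, strand)
        t, c = tot[key], conv.get(key, 0)
        class_rates[cls].converted += c
        class_rates[cls].total += t
        if cls == "C" and (
            (name, pos - 1) in hmc_positions or (name, pos + 1) in hmc_positions
        ):
            neighbor.converted += c
            neighbor.total += t
        rows.append(
            {
                "spike": name, "pos": pos, "strand": strand, "class": cls,
                "converted": c, "total": t,
                "rate_pct": 100.0 * c / t,
            }
        )
    position_rates = pd.DataFrame(
        rows, columns=["spike", "pos", "strand", "class", "converted", "total", "rate_pct"]
    )
    return SpikeInReport(
        enrichment_fraction=enrichment,
        class_rates=class_rates,
        position_rates=position_rates,
        neighbor_rate=neighbor,
    )
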