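"""Independent brute-force re-derivations used as oracles in tests.

Everything here works on plain Python strings and dicts, deliberately
avoiding the package's vectorised calling path so that agreement between
the two is meaningful.
"""

from typing import Dict, Optional, Tuple

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_context(seq: str, pos: int, strand: str) -> Optional[str]:
    """Context by direct string inspection; None when undecidable."""
    n = len(seq)
    if strand == "+":
        assert seq[pos] == "C"
        b1 = seq[pos + 1] if pos + 1 < n else "N"
        b2 = seq[pos + 2] if pos + 2 < n else "N"
    else:
        assert seq[pos] == "G"
        b1 = COMPLEMENT[seq[pos - 1]] if pos - 1 >= 0 else "N"
        b2 = COMPLEMENT[seq[pos - 2]] if pos - 2 >= 0 else "N"
    if b1 == "G":
        return "CpG"
    if b1 == "N":
        return None
    if b2 == "G":
        return "CHG"
    if b2 == "N":
        return None
    return "CHH"


def brute_calls(
    contig_seq: str,
    mates,
    conversion_strand: str,
    min_quality: int = 20,
) -> Dict[int, Tuple[str, str]]:
    """Per-position (context, state) from raw read sequences.

    ``mates`` is a list of (start, seq, quals) triples. Returns
    {pos: (context, state)} over positions with a defined context.
    """
    if conversion_strand == "OT":
        ref_base, unconv, conv, strand = "C", "C", "T", "+"
    else:
        ref_base, unconv, conv, strand = "G", "G", "A", "-"
    observations: Dict[int, list] = {}
    for start, seq, quals in mates:
        for i, base in enumerate(seq):
            pos = start + i
            if contig_seq[pos] != ref_base:
                continue
            if quals is not None and quals[i] < min_quality:
                state = "ambiguous"
            elif base == conv:
                state = "converted"
            elif base == unconv:
                state = "unconverted"
            else:
                state = "ambiguous"
            observations.setdefault(pos, []).append(state)
    out: Dict[int, Tuple[str, str]] = {}
    for pos, states in observations.items():
        ctx = brute_context(contig_seq, pos, strand)
        if ctx is None:
            continue
        state = states[0] if all(s == states[0] for s in states) else "ambiguous"
        out[pos] = (ctx, state)
    return out


def brute_filter_decisions(
    contig_seq: str, mates, conversion_strand: str, threshold: int = 3
) -> Tuple[bool, bool]:
    """(passes conversion filter, passes presence filter) from raw sequences."""
    calls = brute_calls(contig_seq, mates, conversion_strand)
    n_noncpg = sum(
        1 for ctx, st in calls.values() if st == "unconverted" and ctx != "CpG"
    )
    n_cpg = sum(
        1 for ctx, st in calls.values() if st == "unconverted" and ctx == "CpG"
    )
    return n_noncpg <= threshold, n_cpg >= 1
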