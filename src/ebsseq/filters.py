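"""The two enrichment-deamination read filters and their bookkeeping.

Filter 1 (conversion filter) discards fragments with more than a threshold
number (default 3) of unconverted cytosines in non-CpG context — evidence of
incomplete enzymatic deamination of the molecule. Filter 2 (presence filter)
discards fragments carrying no unconverted CpG cytosine at all: in an
enrichment library every genuine pull-down fragment should contain at least
one 5hmC signal, so signal-free pairs are carry-over noise. Both filters act
on whole fragments (pairs), and ambiguous calls never count for or against
either rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Sequence, Tuple, Union

from .readcall import AlignedFragment, FragmentCallSet

DEFAULT_MAX_NONCPG_UNCONVERTED = 3


def conversion_filter(
    callset: FragmentCallSet,
    max_noncpg_unconverted: int = DEFAULT_MAX_NONCPG_UNCONVERTED,
) -> bool:
    """Keep unless strictly more than the threshold of non-CpG unconverted calls."""
    if max_noncpg_unconverted < 0:
        raise ValueError("threshold must be non-negative")
    return callset.n_unconverted_nonCpG <= max_noncpg_unconverted


def hmc_presence_filter(callset: FragmentCallSet) -> bool:
    """Keep iff the fragment carries at least one unconverted CpG call."""
    return callset.n_unconverted_CpG >= 1


@dataclass
class FilterReport:
    n_input: int
    n_failed_conversion: int
    n_no_hmc: int
    n_retained: int
    fraction_no_hmc: float
    mean_insert_with_hmc: float  # NaN when no retained fragments
    mean_insert_without_hmc: float  # NaN when no signal-free fragments

    def to_json(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, float) and math.isnan(v):
                d[k] = None
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    def to_text(self) -> str:
        return (
            f"fragments in: {self.n_input}\n"
            f"  failed conversion filter: {self.n_failed_conversion}\n"
            f"  no 5hmC signal:           {self.n_no_hmc}\n"
            f"  retained:                 {self.n_retained}\n"
            f"fraction without 5hmC: {self.fraction_no_hmc:.4f}\n"
            f"mean insert (with 5hmC):    {self.mean_insert_with_hmc:.1f} bp\n"
            f"mean insert (without 5hmC): {self.mean_insert_without_hmc:.1f} bp\n"
        )


def filter_report(
    callsets: Sequence[FragmentCallSet],
    fragments: Sequence[AlignedFragment],
    max_noncpg_unconverted: int = DEFAULT_MAX_NONCPG_UNCONVERTED,
) -> FilterReport:
    """Partition fragments by the two filters and summarise.

    ``fraction_no_hmc`` is taken among conversion-passing fragments, i.e.
    n_no_hmc / (n_no_hmc + n_retained), matching how the signal-free share
    of an enrichment library is quoted.
    """
    if len(callsets) != len(fragments):
        raise ValueError("need exactly one callset per fragment")
    insert_with: List[int] = []
    insert_without: List[int] = []
    n_failed = n_no_hmc = n_retained = 0
    for cs, frag in zip(callsets, fragments):
        if not conversion_filter(cs, max_noncpg_unconverted):
            n_failed += 1
        elif not hmc_presence_filter(cs):
            n_no_hmc += 1
            insert_without.append(frag.insert_size)
        else:
            n_retained += 1
            insert_with.append(frag.insert_size)
    denom = n_no_hmc + n_retained
    return FilterReport(
        n_input=len(fragments),
        n_failed_conversion=n_failed,
        n_no_hmc=n_no_hmc,
        n_retained=n_retained,
        fraction_no_hmc=(n_no_hmc / denom) if denom else 0.0,
        mean_insert_with_hmc=(sum(insert_with) / len(insert_with)) if insert_with else float("nan"),
        mean_insert_without_hmc=(sum(insert_without) / len(insert_without)) if insert_without else float("nan"),
    )


def apply_filters(
    callsets: Sequence[FragmentCallSet],
    fragments: Sequence[AlignedFragment],
    max_noncpg_unconverted: int = DEFAULT_MAX_NONCPG_UNCONVERTED,
    presence: bool = True,
) -> Tuple[List[FragmentCallSet], List[AlignedFragment]]:
    """Return (callsets, fragments) that survive conversion (+ presence) filtering."""
    kept_cs: List[FragmentCallSet] = []
    kept_fr: List[AlignedFragment] = []
    for cs, frag in zip(callsets, fragments):
        if not conversion_filter(cs, max_noncpg_unconverted):
            continue
        if presence and not hmc_presence_filter(cs):
            continue
        kept_cs.append(cs)
        kept_fr.append(frag)
    return kept_cs, kept_fr
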