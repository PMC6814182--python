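"""Paralog screening from assembled-contig tables.

A locus is flagged as potentially paralogous for a sample when its contig
table shows multiple long contigs — length strictly greater than 85% of the
reference locus — with similar mean coverage (max/min ratio at most 10x
among the qualifying contigs).  These are the HybPiper-default criteria for
a paralog warning.  Because loci flagged in any member of a sample group are
removed from the whole group, the group-level result is the union of
per-sample flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig mapped to a reference locus."""

    sample: str
    locus: str
    contig_id: str
    length: int
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("contig length must be > 0")
        if self.mean_coverage <= 0:
            raise ValueError("contig mean coverage must be > 0")


@dataclass
class ParalogFlag:
    """Flag plus evidence for one (sample, locus) cell."""

    sample: str
    locus: str
    flagged: bool
    evidence: tuple[str, ...] = ()


def flag_paralogs(contigs: Sequence[ContigRecord], reference_length: int,
                  length_fraction: float = 0.85,
                  coverage_ratio: float = 10.0) -> ParalogFlag:
    """Apply the long-contig / similar-coverage criterion to one cell.

    Let Q be the contigs with length > ``length_fraction * reference_length``
    (strict).  The cell is flagged iff |Q| >= 2 and the max/min mean-coverage
    ratio within Q is <= ``coverage_ratio``.  An empty contig list is simply
    not flagged.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be > 0")
    if not 0.0 < length_fraction <= 1.0:
        raise ValueError("length_fraction must be in (0, 1]")
    if coverage_ratio < 1.0:
        raise ValueError("coverage_ratio must be >= 1")
    if not contigs:
        return ParalogFlag("", "", False, ())
    samples = {c.sample for c in contigs}
    loci = {c.locus for c in contigs}
    if len(samples) > 1 or len(loci) > 1:
        raise ValueError("contigs must all belong to one (sample, locus) cell")
    qualifying = [c for c in contigs
                  if c.length > length_fraction * reference_length]
    flagged = False
    evidence: tuple[str, ...] = ()
    if len(qualifying) >= 2:
        covs = [c.mean_coverage for c in qualifying]
        if max(covs) / min(covs) <= coverage_ratio:
            flagged = True
            evidence = tuple(c.contig_id for c in qualifying)
    return ParalogFlag(samples.pop(), loci.pop(), flagged, evidence)


def screen_contig_table(contigs: pd.DataFrame, reference_length: int,
                        length_fraction: float = 0.85,
                        coverage_ratio: float = 10.0) -> pd.DataFrame:
    """Flag every (sample, locus) cell of a contig table.

    Expects columns sample, locus, contig_id, length, mean_coverage; returns
    one row per cell with columns sample, locus, flagged, evidence (the
    qualifying contig ids, comma-joined).
    """
    rows = []
    for (sample, locus), grp in contigs.groupby(["sample", "locus"], sort=True):
        records = [ContigRecord(str(sample), str(locus), str(r.contig_id),
                                int(r.length), float(r.mean_coverage))
                   for r in grp.itertuples()]
        flag = flag_paralogs(records, reference_length, length_fraction,
                             coverage_ratio)
        rows.append((sample, locus, flag.flagged, ",".join(flag.evidence)))
    return pd.DataFrame(rows, columns=["sample", "locus", "flagged", "evidence"])


def group_paralog_union(per_sample_flags: Mapping[str, Iterable[str]],
                        group_samples: Iterable[str]) -> set[str]:
    """Union of flagged loci over a sample group.

    ``per_sample_flags`` maps sample id to the loci flagged for that sample;
    every flagged sample must belong to the group.  Returns the loci flagged
    in at least one group member — these are removed from all samples of the
    group downstream.
    """
    members = set(group_samples)
    if not members:
        raise ValueError("empty sample group")
    stray = set(per_sample_flags) - members
    if stray:
        raise ValueError(f"flagged samples outside the group: {sorted(stray)}")
    union: set[str] = set()
    for loci in per_sample_flags.values():
        union.update(loci)
    return union


def flags_frame_to_mapping(flags: pd.DataFrame) -> dict[str, set[str]]:
    """Convert a screen_contig_table result into sample -> flagged loci."""
    out: dict[str, set[str]] = {}
    for r in flags.itertuples():
        if r.flagged:
            out.setdefault(str(r.sample), set()).add(str(r.locus))
    return out
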