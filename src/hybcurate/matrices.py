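"""Group-matrix construction: the locus-filtering cascade.

For each sample group (a monophyletic set of samples at some taxonomic
level) the curated matrix keeps only loci that survive, in order:

1. per-locus removal of samples with more than 70% missing data,
2. a sample-presence criterion (by default 100%: a locus must contain every
   group sample),
3. removal of every locus in the group's paralog union.

Every input locus receives exactly one provenance reason, so the removal
categories partition the input set — the per-stage accounting a study
reports alongside its final locus counts.  The module also provides the
supercontig-style trimming steps (spurious-sequence removal by residue
overlap, and data-driven removal of gappy columns) and concatenation into a
supermatrix with a partition table.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .alignments import MISSING_CHARS, LocusAlignment
from .config import Thresholds

#: Locus removal reasons, in cascade order.
REASONS = ("not_captured", "sample_missing_data", "presence_filter",
           "paralog", "retained")


@dataclass
class ProvenanceLog:
    """Per-locus removal reason and per-sample loss accounting."""

    locus_reasons: dict[str, str] = field(default_factory=dict)
    sample_losses: dict[str, Counter] = field(default_factory=dict)

    def record(self, locus: str, reason: str,
               samples: Iterable[str] = ()) -> None:
        if reason not in REASONS:
            raise ValueError(f"unknown reason {reason!r}")
        self.locus_reasons[locus] = reason
        for s in samples:
            self.sample_losses.setdefault(s, Counter())[reason] += 1

    def counts(self) -> Counter:
        return Counter(self.locus_reasons.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.locus_reasons.items()), columns=["locus", "reason"])


@dataclass
class GroupMatrix:
    """Filtered set of locus alignments for one sample group."""

    group: str
    samples: list[str]
    alignments: list[LocusAlignment]
    provenance: ProvenanceLog

    @property
    def loci(self) -> list[str]:
        return [a.locus for a in self.alignments]

    @property
    def n_retained(self) -> int:
        return len(self.alignments)


# --------------------------------------------------------------------------
# cascade stages
# --------------------------------------------------------------------------

def filter_sample_missing(alignment: LocusAlignment,
                          cutoff: float = 0.70) -> LocusAlignment:
    """Drop samples whose missing fraction (N, '-', '?') is strictly above
    ``cutoff``; other samples are untouched."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    drop = [s for s in alignment.samples
            if alignment.missing_fraction(s) > cutoff]
    return alignment.drop_samples(drop) if drop else alignment.copy()


def enforce_sample_presence(alignments: Iterable[LocusAlignment],
                            group_samples: Iterable[str],
                            presence_fraction: float = 1.0,
                            ) -> list[LocusAlignment]:
    """Keep only alignments containing at least
    ``ceil(presence_fraction * |group|)`` of the group's samples."""
    group = set(group_samples)
    if not group:
        raise ValueError("empty sample group")
    if not 0.0 < presence_fraction <= 1.0:
        raise ValueError("presence_fraction must be in (0, 1]")
    needed = math.ceil(presence_fraction * len(group))
    return [a for a in alignments
            if len(group.intersection(a.samples)) >= needed]


def build_group_matrix(alignments: Mapping[str, LocusAlignment],
                       group: str, group_samples: Iterable[str],
                       paralog_union: Iterable[str],
                       thresholds: Thresholds = Thresholds()) -> GroupMatrix:
    """Run the full cascade for one group and account for every locus.

    Stage order is fixed: the per-locus missing-data filter runs first (it
    can push a locus below the presence criterion), then the presence
    filter, then paralog-union removal.  The provenance reasons partition
    the input locus set.
    """
    group_set = set(group_samples)
    if not group_set:
        raise ValueError("empty sample group")
    paralogs = set(paralog_union)
    needed = math.ceil(thresholds.sample_presence_fraction * len(group_set))
    log = ProvenanceLog()
    retained: list[LocusAlignment] = []
    for locus, aln in alignments.items():
        sub = aln.drop_samples([s for s in aln.samples if s not in group_set])
        if sub.n_samples == 0:
            log.record(locus, "not_captured", group_set)
            continue
        absent = group_set - set(sub.samples)
        filtered = filter_sample_missing(sub, thresholds.sample_missing_cutoff)
        lost_missing = set(sub.samples) - set(filtered.samples)
        if filtered.n_samples == 0:
            log.record(locus, "sample_missing_data", group_set)
            continue
        if filtered.n_samples < needed:
            # lost to the presence criterion for every group member
            log.record(locus, "presence_filter", group_set)
            continue
        if locus in paralogs:
            log.record(locus, "paralog", group_set)
            continue
        log.record(locus, "retained")
        for s in lost_missing:
            log.sample_losses.setdefault(s, Counter())["sample_missing_data"] += 1
        for s in absent:
            log.sample_losses.setdefault(s, Counter())["not_captured"] += 1
        retained.append(filtered)
    kept_samples = sorted({s for a in retained for s in a.samples})
    return GroupMatrix(group, kept_samples, retained, log)


# --------------------------------------------------------------------------
# supercontig-style trimming
# --------------------------------------------------------------------------

def _is_residue(ch: str) -> bool:
    return ch not in MISSING_CHARS


def remove_spurious_sequences(alignment: LocusAlignment,
                              resoverlap: float = 0.65,
                              seqoverlap: float = 70.0) -> LocusAlignment:
    """Drop sequences that overlap poorly with the rest of the alignment.

    For each sequence, a column is "good" if at least ``resoverlap`` of the
    *other* sequences share its character class (residue vs. gap/N) there;
    the sequence is removed iff its percentage of good columns is below
    ``seqoverlap``.  All sequences are evaluated against the original
    alignment, then removed together.  Alignments with fewer than two
    sequences are returned unchanged.
    """
    if not 0.0 <= resoverlap <= 1.0:
        raise ValueError("resoverlap must be in [0, 1]")
    if not 0.0 <= seqoverlap <= 100.0:
        raise ValueError("seqoverlap must be in [0, 100]")
    n = alignment.n_samples
    if n < 2 or alignment.length == 0:
        return alignment.copy()
    is_res = np.array([[_is_residue(c) for c in seq]
                       for seq in alignment.sequences.values()])
    res_counts = is_res.sum(axis=0)  # residues per column
    keep = []
    for i, sample in enumerate(alignment.samples):
        same = np.where(is_res[i], res_counts - 1, (n - res_counts) - 1)
        good = (same / (n - 1)) >= resoverlap
        if 100.0 * good.mean() >= seqoverlap:
            keep.append(sample)
    drop = [s for s in alignment.samples if s not in keep]
    return alignment.drop_samples(drop)


def trim_gappy_columns(alignment: LocusAlignment) -> LocusAlignment:
    """Remove gap-rich columns using a data-driven cutoff.

    The per-column gap fractions are sorted ascending; the cutoff is the gap
    fraction at the point of maximum slope of that curve (3-point window),
    and columns with gap fraction strictly above the cutoff are removed.  A
    flat curve (all columns equally gappy) removes nothing.  This is a
    deterministic re-statement of the "gappyout"-style heuristic, chosen for
    reproducibility rather than tool equivalence.
    """
    L = alignment.length
    if L < 3 or alignment.n_samples == 0:
        return alignment.copy()
    gap_frac = np.array([
        sum(not _is_residue(c) for c in col) / alignment.n_samples
        for col in alignment.columns()])
    curve = np.sort(gap_frac)
    slopes = (curve[2:] - curve[:-2]) / 2.0
    if slopes.size == 0 or slopes.max() <= 0:
        return alignment.copy()
    cutoff = curve[int(slopes.argmax())]  # lower end of the steepest window
    keep = [i for i, g in enumerate(gap_frac) if g <= cutoff]
    return alignment.keep_columns(keep)


# --------------------------------------------------------------------------
# concatenation
# --------------------------------------------------------------------------

def concatenate_matrix(matrix: GroupMatrix,
                       ) -> tuple[LocusAlignment, pd.DataFrame]:
    """Concatenate retained loci into a supermatrix plus a partition table.

    The partition table gives 1-based inclusive column ranges per locus.
    Samples absent from a locus (possible at presence fractions below 1)
    are padded with '-' over that locus's columns.
    """
    if not matrix.alignments:
        raise ValueError("empty group matrix")
    samples = matrix.samples or sorted(
        {s for a in matrix.alignments for s in a.samples})
    parts = []
    chunks: dict[str, list[str]] = {s: [] for s in samples}
    start = 1
    for aln in matrix.alignments:
        end = start + aln.length - 1
        parts.append((aln.locus, start, end))
        for s in samples:
            chunks[s].append(aln.sequences.get(s, "-" * aln.length))
        start = end + 1
    supermatrix = LocusAlignment(
        f"{matrix.group}_concatenated",
        {s: "".join(chunks[s]) for s in samples})
    table = pd.DataFrame(parts, columns=["locus", "start", "end"])
    return supermatrix, table


def write_partition_table(table: pd.DataFrame, path) -> None:
    """RAxML-style partition file: ``DNA, locus = start-end`` per line."""
    with open(path, "w") as fh:
        for r in table.itertuples():
            fh.write(f"DNA, {r.locus} = {r.start}-{r.end}\n")
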