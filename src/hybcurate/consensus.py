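"""Majority-rule consensus calling from mapped-read pileups.

A pileup is the per-position count of A/C/G/T reads mapped to one locus for
one sample.  The consensus rule is the one used for reference-guided
assembly of target-enrichment data: a position is called base ``b`` iff its
coverage reaches ``min_coverage`` (default 4x) and ``b`` accounts for at
least ``majority_fraction`` (default 70%) of the reads; otherwise the
position is N.  When several pseudoreferences were used for mapping, the
best consensus per locus is the one with least missing data.  The recovery
fraction (the off-target plastome statistic) is simply the proportion of
non-N characters in a consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

_BASES = "ACGT"


@dataclass
class Pileup:
    """Ordered per-position base counts for one (sample, locus).

    ``counts`` is an (L, 4) non-negative integer array in A, C, G, T order;
    positions are contiguous from 1.
    """

    locus: str
    counts: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ConsensusSeq:
    """A called consensus over {A,C,G,T,N} for one locus."""

    locus: str
    reference: str
    sequence: str
    missing_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.missing_count = self.sequence.count("N")


def call_consensus(pileup: Pileup, majority_fraction: float = 0.70,
                   min_coverage: int = 4, reference: str = "") -> ConsensusSeq:
    """Apply the majority rule position by position.

    A position gets base ``b`` iff coverage >= ``min_coverage`` and
    count(b)/coverage >= ``majority_fraction`` (both inclusive, so an exact
    70% call at exactly 4x passes); otherwise N.  If two bases tie at or
    above the threshold (impossible for fractions > 0.5) the call is N.
    """
    if not 0.5 < majority_fraction <= 1.0:
        raise ValueError("majority_fraction must be in (0.5, 1]")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if pileup.length == 0:
        raise ValueError("empty pileup")
    counts = pileup.counts
    coverage = counts.sum(axis=1)
    out = np.full(pileup.length, "N", dtype="<U1")
    covered = coverage >= min_coverage
    if covered.any():
        best = counts[covered].argmax(axis=1)
        best_count = counts[covered].max(axis=1)
        frac_ok = best_count >= majority_fraction * coverage[covered]
        # a tie among top bases can only pass at fractions <= 0.5; guarded
        # anyway so permissive configs still produce a defined N call
        ties = (counts[covered] == best_count[:, None]).sum(axis=1) > 1
        calls = np.where(frac_ok & ~ties,
                         np.array(list(_BASES))[best], "N")
        out[covered] = calls
    return ConsensusSeq(pileup.locus, reference, "".join(out))


def select_best_reference(candidates: Sequence[ConsensusSeq],
                          priority_order: Sequence[str] = ()) -> ConsensusSeq:
    """Pick the consensus with the least missing data for one locus.

    Ties are broken by ``priority_order`` (first listed reference wins);
    references absent from the order rank after those listed, in input order.
    """
    if not candidates:
        raise ValueError("no candidate consensus sequences")
    loci = {c.locus for c in candidates}
    if len(loci) > 1:
        raise ValueError(f"candidates span multiple loci: {sorted(loci)}")
    prio = {ref: i for i, ref in enumerate(priority_order)}

    def key(item):
        i, c = item
        return (c.missing_count, prio.get(c.reference, len(prio)), i)

    return min(enumerate(candidates), key=key)[1]


def recovery_fraction(consensus: ConsensusSeq) -> float:
    """Proportion of non-N characters in the consensus (plastome recovery)."""
    n = len(consensus.sequence)
    if n == 0:
        raise ValueError("empty consensus sequence")
    return (n - consensus.missing_count) / n


# --------------------------------------------------------------------------
# TSV plumbing
# --------------------------------------------------------------------------

def pileups_from_frame(frame: pd.DataFrame) -> dict[tuple[str, str], Pileup]:
    """Load pileups from the long TSV layout (sample, locus, position,
    count_A..count_T); positions must be contiguous from 1."""
    out: dict[tuple[str, str], Pileup] = {}
    cols = ["count_A", "count_C", "count_G", "count_T"]
    for (sample, locus), grp in frame.groupby(["sample", "locus"], sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(
                f"pileup positions for ({sample}, {locus}) not contiguous from 1")
        out[(str(sample), str(locus))] = Pileup(
            str(locus), grp[cols].to_numpy(), sample=str(sample))
    return out


def read_pileups(path: str | Path) -> dict[tuple[str, str], Pileup]:
    return pileups_from_frame(pd.read_csv(path, sep="\t"))
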