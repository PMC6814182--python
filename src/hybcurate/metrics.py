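"""Alignment informativeness metrics and locus-set comparisons.

Site classification follows the standard parsimony convention: counting
only unambiguous A/C/G/T states (gaps, N and ambiguity codes are ignored),
a column is parsimony informative (PI) iff at least two distinct states
each occur in at least two sequences; variable-but-uninformative iff it has
two or more states without meeting that bar; constant with exactly one
state; and empty with none.

The module also aggregates per-group locus counts at each taxonomic level
(the worked-example table of 21 Asteraceae sample groups ships as a
packaged fixture) and compares non-paralogous locus sets between groups
(which loci are group-specific vs. shared — the Venn-diagram statistic).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .alignments import NUCLEOTIDES, LocusAlignment

SITE_CLASSES = ("constant", "variable_not_pi", "pi", "uninformative_empty")

#: Taxonomic levels recognised in level reports.
LEVELS = ("tribe", "genus", "species_complex", "species")


@dataclass(frozen=True)
class AlignmentSummary:
    """Per-alignment site-class counts and derived percentages."""

    locus: str
    length: int
    n_samples: int
    variable_sites: int
    pi_sites: int
    missing_percent: float

    @property
    def pi_percent(self) -> float:
        return 100.0 * self.pi_sites / self.length if self.length else 0.0

    @property
    def variable_percent(self) -> float:
        return 100.0 * self.variable_sites / self.length if self.length else 0.0


def classify_site(column) -> str:
    """Classify one alignment column (any iterable of characters)."""
    counts = Counter(c for c in (ch.upper() for ch in column)
                     if c in NUCLEOTIDES)
    if not counts:
        return "uninformative_empty"
    if len(counts) == 1:
        return "constant"
    if sum(1 for n in counts.values() if n >= 2) >= 2:
        return "pi"
    return "variable_not_pi"


def classify_sites(alignment: LocusAlignment) -> list[str]:
    """Per-column site classes, in column order."""
    if alignment.length == 0:
        raise ValueError("alignment has no columns")
    return [classify_site(col) for col in alignment.columns()]


def summarize_alignment(alignment: LocusAlignment) -> AlignmentSummary:
    """Site-class counts plus missing-data percentage for one alignment.

    ``missing_percent`` is the mean per-sequence missing fraction x 100.
    """
    classes = Counter(classify_sites(alignment))
    variable = classes["pi"] + classes["variable_not_pi"]
    missing = float(np.mean([alignment.missing_fraction(s)
                             for s in alignment.samples])) * 100.0
    return AlignmentSummary(
        locus=alignment.locus, length=alignment.length,
        n_samples=alignment.n_samples, variable_sites=variable,
        pi_sites=classes["pi"], missing_percent=missing)


def summarize_matrix(alignments) -> pd.DataFrame:
    """One summary row per alignment."""
    rows = []
    for aln in alignments:
        s = summarize_alignment(aln)
        rows.append((s.locus, s.length, s.n_samples, s.variable_sites,
                     s.pi_sites, round(s.pi_percent, 3),
                     round(s.missing_percent, 3)))
    return pd.DataFrame(rows, columns=[
        "locus", "length", "n_samples", "variable_sites", "pi_sites",
        "pi_percent", "missing_percent"])


# --------------------------------------------------------------------------
# level-report aggregation (the printed-table worked example)
# --------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """The packaged 21-sample-group fixture table (per-group paralogous and
    non-paralogous locus counts at tribe/genus/species levels), transcribed
    transcribed verbatim from the published table."""
    with resources.files("hybcurate.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def aggregate_level_report(report: pd.DataFrame, level: str | None,
                           column: str, statistic: str = "mean",
                           rounding: bool = True) -> float | int:
    """Aggregate one column of a level report.

    ``level`` restricts rows to one taxonomic level (None = all rows);
    ``statistic`` is mean, min or max; means are rounded half-up to the
    nearest integer when ``rounding`` is set.
    """
    if "taxonomic_level" not in report.columns or column not in report.columns:
        raise KeyError(f"unknown column {column!r}")
    rows = report
    if level is not None:
        if level not in LEVELS:
            raise KeyError(f"unknown taxonomic level {level!r}")
        rows = report[report["taxonomic_level"] == level]
    if rows.empty:
        raise ValueError(f"no rows at level {level!r}")
    values = rows[column].astype(float)
    if statistic == "mean":
        out = float(values.mean())
        return _round_half_up(out) if rounding else out
    if statistic == "min":
        return float(values.min())
    if statistic == "max":
        return float(values.max())
    raise ValueError(f"unknown statistic {statistic!r}")


# --------------------------------------------------------------------------
# locus-set comparison between groups
# --------------------------------------------------------------------------

@dataclass
class LocusSetComparison:
    """Group-specific vs. shared locus accounting within one level."""

    sets: dict[str, frozenset]
    unique: dict[str, frozenset]
    unique_fraction: dict[str, float]
    pairwise_shared: dict[tuple[str, str], int]
    shared_all: frozenset

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, len(self.sets[g]), len(self.unique[g]),
                 round(self.unique_fraction[g], 4))
                for g in self.sets]
        return pd.DataFrame(rows, columns=[
            "group", "n_loci", "n_unique", "unique_fraction"])


def compare_locus_sets(sets: Mapping[str, set]) -> LocusSetComparison:
    """Per-group unique loci (in no other group), pairwise intersections,
    and the loci shared by every group."""
    if len(sets) < 2:
        raise ValueError("need at least two groups to compare")
    frozen = {g: frozenset(s) for g, s in sets.items()}
    for g, s in frozen.items():
        if not s:
            raise ValueError(f"group {g!r} has an empty locus set")
    unique, frac = {}, {}
    for g, s in frozen.items():
        others = frozenset().union(*(frozen[h] for h in frozen if h != g))
        unique[g] = s - others
        frac[g] = len(unique[g]) / len(s)
    pairwise = {(a, b): len(frozen[a] & frozen[b])
                for a, b in combinations(frozen, 2)}
    shared_all = frozenset.intersection(*frozen.values())
    return LocusSetComparison(frozen, unique, frac, pairwise, shared_all)
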