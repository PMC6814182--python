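"""The per-locus alignment container and FASTA round-tripping.

A :class:`LocusAlignment` is an ordered mapping of sample id to an
equal-length sequence for one locus.  Sequences here are nucleotide strings
over A/C/G/T plus the missing-data characters N, '-' and '?'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Characters treated as missing data throughout the pipeline.
MISSING_CHARS = frozenset("Nn-?")

#: Unambiguous nucleotide states.
NUCLEOTIDES = frozenset("ACGT")


@dataclass
class LocusAlignment:
    """Equal-length sequences keyed by sample id for a single locus."""

    locus: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"locus {self.locus}: unequal sequence lengths {sorted(lengths)}")
        if len(self.sequences) != len(set(self.sequences)):
            raise ValueError(f"locus {self.locus}: duplicate sample ids")

    @property
    def length(self) -> int:
        """Number of alignment columns (0 if empty)."""
        for s in self.sequences.values():
            return len(s)
        return 0

    @property
    def samples(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_samples(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, sample: str) -> bool:
        return sample in self.sequences

    def __getitem__(self, sample: str) -> str:
        return self.sequences[sample]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def column(self, i: int) -> list[str]:
        """Characters of column ``i`` (0-based), in sample order."""
        return [s[i] for s in self.sequences.values()]

    def columns(self) -> Iterator[list[str]]:
        for i in range(self.length):
            yield self.column(i)

    def missing_fraction(self, sample: str) -> float:
        seq = self.sequences[sample]
        if not seq:
            return 0.0
        return sum(c in MISSING_CHARS for c in seq) / len(seq)

    def drop_samples(self, samples: Iterable[str]) -> "LocusAlignment":
        drop = set(samples)
        return LocusAlignment(
            self.locus,
            {s: q for s, q in self.sequences.items() if s not in drop})

    def keep_columns(self, indices: Iterable[int]) -> "LocusAlignment":
        idx = sorted(indices)
        return LocusAlignment(
            self.locus,
            {s: "".join(q[i] for i in idx) for s, q in self.sequences.items()})

    def copy(self) -> "LocusAlignment":
        return LocusAlignment(self.locus, dict(self.sequences))


def write_fasta(alignment: LocusAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=sample, description="")
               for sample, seq in alignment.sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, locus: str | None = None) -> LocusAlignment:
    locus = locus if locus is not None else Path(path).stem
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
    return LocusAlignment(locus, seqs)
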