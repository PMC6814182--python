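"""Configuration records: every numeric cutoff used by the pipeline, plus the
simulation parameters of the synthetic-data generator.

``Thresholds`` collects the curation cutoffs in one place so that a whole run
is reproducible from a single record; the defaults are the values used
throughout the pipeline (70% majority-rule consensus at >=4x coverage,
HybPiper-default paralog flagging, >70% missing-data sample removal, 100%
sample presence, trimAl-style overlap parameters, TreeShrink-style tolerance
0.10, and the 80%/95% bootstrap-support conventions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class Thresholds:
    """All numeric cutoffs of the curation cascade.

    Attributes
    ----------
    majority_fraction : float
        Minimum within-column base frequency for a consensus call
        (inclusive; an exact 70% call yields the base).
    min_coverage : int
        Minimum pileup coverage for a consensus call; below it, N.
    paralog_length_fraction : float
        A contig qualifies as "long" if length > fraction * reference length
        (strict, matching the ">85%" rule).
    paralog_coverage_ratio : float
        Max/min mean-coverage ratio among qualifying contigs must be <= this
        for a paralog flag ("within 10x of each other").
    sample_missing_cutoff : float
        Samples with missing fraction strictly above this are dropped from a
        locus alignment.
    sample_presence_fraction : float
        Loci present in fewer than ceil(fraction * group size) samples are
        dropped (1.0 = the exon default; lower values suit supercontigs).
    resoverlap : float
        Minimum fraction of other sequences sharing a sequence's character
        class (residue vs. gap) for a column to count as "good".
    seqoverlap : float
        Percent of good columns a sequence needs to be retained.
    shrink_tolerance : float
        False-positive tolerance of the long-branch detector.
    shrink_min_signature : float
        Minimum relative diameter reduction for a long-branch flag.
    conflict_bs_threshold : float
        Gene-tree nodes below this percent support are collapsed before
        conflict counting (80 by default; 50 is also in common use).
    well_supported_bs : float
        Convention for calling a node "well-supported" in reports.
    """

    majority_fraction: float = 0.70
    min_coverage: int = 4
    paralog_length_fraction: float = 0.85
    paralog_coverage_ratio: float = 10.0
    sample_missing_cutoff: float = 0.70
    sample_presence_fraction: float = 1.00
    resoverlap: float = 0.65
    seqoverlap: float = 70.0
    shrink_tolerance: float = 0.10
    shrink_min_signature: float = 0.2
    conflict_bs_threshold: float = 80.0
    well_supported_bs: float = 95.0

    def __post_init__(self) -> None:
        for name in ("majority_fraction", "paralog_length_fraction",
                     "sample_missing_cutoff", "sample_presence_fraction",
                     "resoverlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 < self.majority_fraction <= 1.0:
            raise ValueError("majority_fraction must be in (0.5, 1]")
        for name in ("seqoverlap", "conflict_bs_threshold", "well_supported_bs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.paralog_coverage_ratio < 1:
            raise ValueError("paralog_coverage_ratio must be >= 1")
        if not 0.0 < self.shrink_tolerance < 1.0:
            raise ValueError("shrink_tolerance must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


#: Ultrametric depths (expected substitutions/site from the tips) at which
#: each taxonomic level diverges.  Arbitrary but fixed defaults; exposed so a
#: simulation can emulate shallower or deeper radiations.
DEFAULT_LEVEL_DEPTHS: dict[str, float] = {
    "tribe": 1.0,
    "genus": 0.4,
    "species": 0.15,
    "sample": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic Hyb-Seq dataset generator.

    The nested taxonomy is balanced: ``n_tribes`` tribes, each with
    ``genera_per_tribe`` genera, and so on; the species tree is ultrametric
    with level-specific divergence depths. Sequence evolution is Jukes-Cantor
    with no indels, so simulated sequences are natively aligned.
    """

    n_tribes: int = 2
    genera_per_tribe: int = 2
    species_per_genus: int = 2
    samples_per_species: int = 2
    n_loci: int = 20
    locus_length: int = 300
    subst_scale: float = 0.05
    discordance_rate: float = 0.2
    long_branch_rate: float = 0.1
    long_branch_factor: float = 10.0
    paralog_loci: tuple = ()  # (locus id, clade id, extra divergence)
    dropout_prob: float = 0.05
    partial_prob: float = 0.05
    partial_fraction: float = 0.3
    mean_coverage: float = 30.0
    error_rate: float = 0.01
    seed: int = 0
    level_depths: tuple = tuple(sorted(DEFAULT_LEVEL_DEPTHS.items()))

    def __post_init__(self) -> None:
        for name in ("n_tribes", "genera_per_tribe", "species_per_genus",
                     "samples_per_species", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        for name in ("discordance_rate", "long_branch_rate", "dropout_prob",
                     "partial_prob", "partial_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.long_branch_factor <= 1.0:
            raise ValueError("long_branch_factor must be > 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        # normalise paralog_loci to a tuple of 3-tuples so the config hashes
        object.__setattr__(
            self, "paralog_loci",
            tuple((str(l), str(c), float(d)) for l, c, d in self.paralog_loci))

    @property
    def n_samples(self) -> int:
        return (self.n_tribes * self.genera_per_tribe
                * self.species_per_genus * self.samples_per_species)

    @property
    def depths(self) -> dict[str, float]:
        return dict(self.level_depths)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["level_depths"] = dict(self.level_depths)
        d["paralog_loci"] = [list(p) for p in self.paralog_loci]
        return d
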