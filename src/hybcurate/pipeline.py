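"""End-to-end orchestration of the curation pipeline.

A single :class:`PipelineConfig` — either a simulation block or a set of
input paths, plus thresholds, an output directory and a seed — drives the
stages in order: simulate, consensus, paralog screen, matrix build, metrics,
shrink, conflict.  Each stage writes self-describing TSV/FASTA/Newick
outputs; a run manifest records the config hash, seed and package version so
a run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from .alignments import LocusAlignment, read_fasta, write_fasta
from .config import SimConfig, Thresholds
from .consensus import Pileup, call_consensus, read_pileups, recovery_fraction
from .matrices import (GroupMatrix, build_group_matrix, concatenate_matrix,
                       write_partition_table)
from .metrics import (aggregate_level_report, compare_locus_sets,
                      load_table1, summarize_matrix)
from .paralogs import (flags_frame_to_mapping, group_paralog_union,
                       screen_contig_table)
from .simulate import SyntheticDataset, dataset_pileup, export_dataset, \
    generate_dataset
from .trees import conflict_analysis, detect_long_branches, shrink_dataset

log = logging.getLogger("hybcurate")

ALL_STAGES = ("simulate", "consensus", "paralogs", "matrix", "metrics",
              "shrink", "conflict")


@dataclass
class PipelineConfig:
    """One record describing a whole run."""

    simulation: SimConfig | None = None
    inputs: dict | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "config must have exactly one of a simulation block or inputs")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = d.get("simulation")
        seed = int(d.get("seed", 0))
        if sim is not None:
            sim = SimConfig(**{**sim, "seed": int(sim.get("seed", seed))})
        thresholds = Thresholds(**d.get("thresholds", {}))
        stages = tuple(d.get("stages", ALL_STAGES))
        return cls(simulation=sim, inputs=d.get("inputs"),
                   thresholds=thresholds, stages=stages, seed=seed)

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "inputs": self.inputs,
            "thresholds": self.thresholds.to_dict(),
            "stages": list(self.stages),
            "seed": self.seed,
        }


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _groups_from_table(table: pd.DataFrame) -> dict[str, tuple[str, list[str]]]:
    """All sample groups at every level: name -> (level, member samples)."""
    groups: dict[str, tuple[str, list[str]]] = {}
    for level in ("tribe", "genus", "species"):
        for name, grp in table.groupby(level, sort=True):
            groups[str(name)] = (level, list(grp["sample"]))
    return groups


# --------------------------------------------------------------------------
# input loading (file-driven runs)
# --------------------------------------------------------------------------

def _load_inputs(inputs: dict):
    required = ("sample_table",)
    for key in required:
        if key not in inputs:
            raise ValueError(f"inputs missing required path {key!r}")
    paths = {k: Path(v) for k, v in inputs.items()}
    for k, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"input {k!r}: {p} does not exist")
    table = pd.read_csv(paths["sample_table"], sep="\t")
    alignments: dict[str, LocusAlignment] = {}
    if "alignments" in paths:
        for fp in sorted(paths["alignments"].glob("*.fasta")):
            aln = read_fasta(fp)
            alignments[aln.locus] = aln
    contigs = (pd.read_csv(paths["contigs"], sep="\t")
               if "contigs" in paths else None)
    pileups = read_pileups(paths["pileups"]) if "pileups" in paths else None
    species_tree = None
    if "species_tree" in paths:
        species_tree = dendropy.Tree.get(path=str(paths["species_tree"]),
                                         schema="newick")
        species_tree.is_rooted = True
    gene_trees = None
    if "gene_trees" in paths:
        from .trees import read_gene_trees
        gene_trees = read_gene_trees(paths["gene_trees"])
    return table, alignments, contigs, pileups, species_tree, gene_trees


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_consensus(dataset: SyntheticDataset | None, pileups, outdir: Path,
                     thresholds: Thresholds) -> pd.DataFrame:
    rows = []
    if dataset is not None:
        cells = [(sample, locus)
                 for locus, aln in dataset.alignments.items()
                 for sample in aln.samples]
        get = lambda s, l: Pileup(l, dataset_pileup(dataset, s, l), sample=s)
    elif pileups:
        cells = sorted(pileups)
        get = lambda s, l: pileups[(s, l)]
    else:
        raise ValueError("consensus stage needs simulated data or a pileup TSV")
    records = []
    for sample, locus in cells:
        cons = call_consensus(get(sample, locus),
                              thresholds.majority_fraction,
                              thresholds.min_coverage)
        rows.append((sample, locus, cons.missing_count,
                     round(recovery_fraction(cons), 4)))
        records.append((f"{sample}|{locus}", cons.sequence))
    frame = pd.DataFrame(rows, columns=["sample", "locus", "missing_count",
                                        "recovery_fraction"])
    frame.to_csv(outdir / "consensus_summary.tsv", sep="\t", index=False)
    with open(outdir / "consensus.fasta", "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{seq}\n")
    log.info("consensus: %d cells called", len(records))
    return frame


def _stage_paralogs(contigs: pd.DataFrame, groups, reference_length: int,
                    thresholds: Thresholds, outdir: Path,
                    ) -> dict[str, set[str]]:
    flags = screen_contig_table(contigs, reference_length,
                                thresholds.paralog_length_fraction,
                                thresholds.paralog_coverage_ratio)
    flags.to_csv(outdir / "paralog_flags.tsv", sep="\t", index=False)
    per_sample = flags_frame_to_mapping(flags)
    unions: dict[str, set[str]] = {}
    rows = []
    for name, (level, members) in groups.items():
        member_flags = {s: per_sample.get(s, set()) for s in members}
        unions[name] = group_paralog_union(member_flags, members)
        for locus in sorted(unions[name]):
            rows.append((name, level, locus))
        log.info("paralogs: group %s (%s): %d flagged loci",
                 name, level, len(unions[name]))
    pd.DataFrame(rows, columns=["group", "level", "locus"]).to_csv(
        outdir / "paralog_unions.tsv", sep="\t", index=False)
    return unions


def _stage_matrix(alignments, groups, unions, thresholds: Thresholds,
                  outdir: Path) -> dict[str, GroupMatrix]:
    matrices: dict[str, GroupMatrix] = {}
    prov_rows = []
    for name, (level, members) in groups.items():
        gm = build_group_matrix(alignments, name, members,
                                unions.get(name, set()), thresholds)
        matrices[name] = gm
        for locus, reason in sorted(gm.provenance.locus_reasons.items()):
            prov_rows.append((name, level, locus, reason))
        counts = gm.provenance.counts()
        log.info("matrix: group %s (%s): %s", name, level, dict(counts))
        if gm.alignments:
            supermatrix, parts = concatenate_matrix(gm)
            write_fasta(supermatrix, outdir / f"{name}_supermatrix.fasta")
            write_partition_table(parts, outdir / f"{name}_partitions.txt")
    pd.DataFrame(prov_rows, columns=["group", "level", "locus", "reason"]
                 ).to_csv(outdir / "provenance.tsv", sep="\t", index=False)
    return matrices


def _stage_metrics(matrices: dict[str, GroupMatrix], groups, unions,
                   outdir: Path) -> pd.DataFrame:
    level_rows = []
    per_locus = []
    for name, gm in matrices.items():
        level, members = groups[name]
        summary = summarize_matrix(gm.alignments)
        if not summary.empty:
            summary.insert(0, "group", name)
            per_locus.append(summary)
        level_rows.append((
            name, level, len(members), len(unions.get(name, set())),
            gm.n_retained,
            round(float(summary["pi_percent"].mean()), 3)
            if not summary.empty else 0.0))
    report = pd.DataFrame(level_rows, columns=[
        "sample_group", "taxonomic_level", "n_samples", "n_paralogous_loci",
        "n_non_paralogous_loci", "mean_pi_percent"])
    report.to_csv(outdir / "level_report.tsv", sep="\t", index=False)
    if per_locus:
        pd.concat(per_locus).to_csv(outdir / "alignment_summaries.tsv",
                                    sep="\t", index=False)
    # group-specific vs. shared non-paralogous loci, per taxonomic level
    cmp_frames = []
    for level in sorted({lvl for lvl, _ in groups.values()}):
        sets = {name: set(matrices[name].loci) for name, (lvl, _) in
                groups.items() if lvl == level and matrices[name].loci}
        if len(sets) >= 2:
            frame = compare_locus_sets(sets).to_frame()
            frame.insert(0, "taxonomic_level", level)
            cmp_frames.append(frame)
    if cmp_frames:
        pd.concat(cmp_frames).to_csv(outdir / "locus_set_comparison.tsv",
                                     sep="\t", index=False)
    return report


def _pick_outgroup(table: pd.DataFrame) -> str:
    """First sample of the first tribe: the conventionally distant leaf."""
    return str(table.sort_values(["tribe", "sample"]).iloc[0]["sample"])


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    stages = config.stages

    dataset = None
    pileups = None
    gene_trees = None
    species_tree = None
    if config.simulation is not None:
        dataset = generate_dataset(config.simulation)
        table = dataset.sample_table
        alignments = dataset.alignments
        contigs = dataset.contigs
        gene_trees = dataset.gene_trees
        species_tree = dataset.species_tree
        if "simulate" in stages:
            export_dataset(dataset, outdir / "simulate")
            log.info("simulate: %d samples x %d loci",
                     len(table), len(alignments))
    else:
        (table, alignments, contigs, pileups,
         species_tree, gene_trees) = _load_inputs(config.inputs)

    groups = _groups_from_table(table)

    if "consensus" in stages:
        sub = outdir / "consensus"
        sub.mkdir(exist_ok=True)
        _stage_consensus(dataset, pileups, sub, thresholds)

    unions: dict[str, set[str]] = {}
    if "paralogs" in stages:
        if contigs is None or contigs.empty:
            raise ValueError("paralog stage needs a contig table")
        sub = outdir / "paralogs"
        sub.mkdir(exist_ok=True)
        ref_len = (config.simulation.locus_length if config.simulation
                   else int(config.inputs.get("reference_length", 0)) or
                   int(contigs["length"].max()))
        unions = _stage_paralogs(contigs, groups, ref_len, thresholds, sub)

    matrices: dict[str, GroupMatrix] = {}
    if "matrix" in stages:
        sub = outdir / "matrix"
        sub.mkdir(exist_ok=True)
        matrices = _stage_matrix(alignments, groups, unions, thresholds, sub)

    if "metrics" in stages and matrices:
        sub = outdir / "metrics"
        sub.mkdir(exist_ok=True)
        _stage_metrics(matrices, groups, unions, sub)

    if "shrink" in stages:
        if not gene_trees:
            raise ValueError("shrink stage needs gene trees")
        sub = outdir / "shrink"
        sub.mkdir(exist_ok=True)
        report = detect_long_branches(gene_trees, thresholds.shrink_tolerance,
                                      thresholds.shrink_min_signature)
        shrunk, fraction = shrink_dataset(alignments, report)
        rows = [(locus, ",".join(sorted(samples)))
                for locus, samples in sorted(report.removed.items())]
        pd.DataFrame(rows, columns=["locus", "removed_samples"]).to_csv(
            sub / "shrink_report.tsv", sep="\t", index=False)
        with open(sub / "shrunken_fraction.txt", "w") as fh:
            fh.write(f"{fraction:.4f}\n")
        log.info("shrink: %.1f%% of alignments shrunken", 100 * fraction)

    if "conflict" in stages:
        if not gene_trees or species_tree is None:
            raise ValueError("conflict stage needs gene trees and a species tree")
        sub = outdir / "conflict"
        sub.mkdir(exist_ok=True)
        outgroup = (config.inputs or {}).get("outgroup") or _pick_outgroup(table)
        sp = species_tree.clone(depth=1)
        og = next((lf for lf in sp.leaf_node_iter()
                   if lf.taxon.label == outgroup), None)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} absent from species tree")
        sp.to_outgroup_position(og, update_bipartitions=False)
        sp.is_rooted = True
        report = conflict_analysis(sp, gene_trees,
                                   thresholds.conflict_bs_threshold, outgroup)
        report.to_frame().to_csv(sub / "conflict_report.tsv", sep="\t",
                                 index=False)
        log.info("conflict: %d usable gene trees, %d excluded",
                 report.n_usable, report.n_excluded_missing_outgroup)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": list(stages),
        "n_samples": int(len(table)),
        "n_loci": int(len(alignments)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def table1_report(outpath: str | Path | None = None) -> pd.DataFrame:
    """Aggregate the packaged 21-group fixture table at each level."""
    t = load_table1()
    rows = [
        ("all", "n_paralogous_loci", "mean",
         aggregate_level_report(t, None, "n_paralogous_loci", "mean")),
        ("genus", "n_non_paralogous_loci", "mean",
         aggregate_level_report(t, "genus", "n_non_paralogous_loci", "mean")),
        ("tribe", "n_non_paralogous_loci", "mean",
         aggregate_level_report(t, "tribe", "n_non_paralogous_loci", "mean")),
        ("genus", "n_non_paralogous_loci", "min",
         aggregate_level_report(t, "genus", "n_non_paralogous_loci", "min")),
        ("genus", "n_non_paralogous_loci", "max",
         aggregate_level_report(t, "genus", "n_non_paralogous_loci", "max")),
    ]
    report = pd.DataFrame(rows, columns=["level", "column", "statistic", "value"])
    if outpath is not None:
        report.to_csv(outpath, sep="\t", index=False)
    return report
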