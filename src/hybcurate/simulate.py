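"""Synthetic Hyb-Seq dataset generator with planted ground truth.

Emulates the structure of a nested target-enrichment study — tribes contain
genera contain species contain samples — so that every downstream curation
stage (consensus calling, paralog screening, matrix filtering, shrinking,
conflict analysis) can be tested against known answers without any sequencing
data.

The model, deliberately minimal and fully controllable:

* an ultrametric, binary species tree with level-specific divergence depths
  (expected substitutions/site from the tips);
* per-locus gene trees cloned from the species tree; a configurable fraction
  receive one random nearest-neighbor interchange (topological discordance)
  and/or one terminal branch inflated by a constant factor (a long-branch
  outlier);
* Jukes-Cantor sequence evolution along each gene tree, with no indels, so
  simulated sequences are natively aligned;
* planted paralogous gene copies: affected (sample, locus) cells receive a
  second contig, long and similarly covered by construction, whose sequence
  is the sample's sequence diverged by a stated extra amount;
* per-position sequencing-error pileups (Poisson coverage, uniform miscalls);
* per-(sample, locus) missingness: whole-cell dropout or a contiguous masked
  run of N characters.

All randomness flows from the single integer seed in :class:`SimConfig`;
sub-streams are derived deterministically per stage and per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignments import LocusAlignment, write_fasta
from .config import SimConfig

_BASES = np.array(list("ACGT"))
_LEVELS = ("tribe", "genus", "species", "sample")


# --------------------------------------------------------------------------
# ground truth ledger
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Ledger of everything the generator planted."""

    species_tree: dendropy.Tree | None = None
    gene_trees: dict[str, dendropy.Tree] = field(default_factory=dict)
    planted_paralogs: set[tuple[str, str]] = field(default_factory=set)
    discordant_loci: set[str] = field(default_factory=set)
    inflated_leaves: set[tuple[str, str, float]] = field(default_factory=set)
    masked_cells: set[tuple[str, str, str]] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus in sorted(self.discordant_loci):
            rows.append(("discordant", "", locus, ""))
        for sample, locus in sorted(self.planted_paralogs):
            rows.append(("paralog", sample, locus, ""))
        for locus, sample, factor in sorted(self.inflated_leaves):
            rows.append(("long_branch", sample, locus, repr(factor)))
        for sample, locus, kind in sorted(self.masked_cells):
            rows.append((kind, sample, locus, ""))
        return pd.DataFrame(rows, columns=["kind", "sample", "locus", "detail"])


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    config: SimConfig
    sample_table: pd.DataFrame
    species_tree: dendropy.Tree
    gene_trees: dict[str, dendropy.Tree]
    alignments: dict[str, LocusAlignment]
    true_sequences: dict[str, dict[str, str]]
    contigs: pd.DataFrame
    paralog_copies: dict[tuple[str, str], str]
    truth: GroundTruth

    @property
    def loci(self) -> list[str]:
        return list(self.alignments)

    @property
    def samples(self) -> list[str]:
        return list(self.sample_table["sample"])

    def group_samples(self, group: str) -> list[str]:
        """Samples belonging to a named tribe / genus / species group."""
        t = self.sample_table
        mask = (t["tribe"] == group) | (t["genus"] == group) | (t["species"] == group)
        if not mask.any():
            raise KeyError(f"unknown group: {group!r}")
        return list(t.loc[mask, "sample"])


# --------------------------------------------------------------------------
# taxonomy and species tree
# --------------------------------------------------------------------------

def _resolve_radiation(children: list, heights: list[float], split_height: float,
                       lower_height: float) -> tuple:
    """Resolve a k-furcation into a ladder of binary splits.

    Splits are evenly spaced from ``split_height`` down toward
    ``lower_height`` so the tree stays ultrametric and strictly binary.
    Returns (node, height) tuples suitable for nesting.
    """
    k = len(children)
    if k == 1:
        return children[0], heights[0]
    step = (split_height - lower_height) / k
    node_h = split_height - (k - 2) * step  # height of the deepest split
    node = dendropy.Node()
    node.add_child(children[-2])
    node.add_child(children[-1])
    children[-2].edge.length = node_h - heights[-2]
    children[-1].edge.length = node_h - heights[-1]
    for i in range(k - 3, -1, -1):
        parent = dendropy.Node()
        parent_h = node_h + step * (k - 2 - i)
        parent.add_child(children[i])
        parent.add_child(node)
        children[i].edge.length = parent_h - heights[i]
        node.edge.length = parent_h - node_h
        node, node_h = parent, parent_h
    return node, node_h


def generate_taxonomy(config: SimConfig) -> tuple[pd.DataFrame, dendropy.Tree]:
    """Build the sample-to-group table and the ultrametric species tree.

    Returns a table with one row per sample (columns: sample, species,
    genus, tribe) and a rooted binary tree whose leaves are the samples.
    Radiations at each level occur at that level's configured depth;
    multifurcations are resolved into ladders within the level's time span.
    """
    depths = config.depths
    counts = {
        "tribe": config.n_tribes,
        "genus": config.genera_per_tribe,
        "species": config.species_per_genus,
        "sample": config.samples_per_species,
    }
    rows: list[dict[str, str]] = []
    tns = dendropy.TaxonNamespace()

    def build(level_idx: int, prefix: str, labels: dict[str, str]) -> tuple:
        """Subtree for one taxon at _LEVELS[level_idx - 1]; returns (node, height)."""
        if level_idx == len(_LEVELS):
            sample = prefix
            rows.append({"sample": sample, **labels})
            leaf = dendropy.Node()
            leaf.taxon = tns.new_taxon(label=sample)
            return leaf, 0.0
        level = _LEVELS[level_idx]
        k = counts[level]
        tag = level[0] if level != "sample" else "i"
        children, heights = [], []
        for j in range(1, k + 1):
            child_prefix = f"{prefix}{tag}{j}" if prefix else f"{tag}{j}"
            child_labels = dict(labels)
            if level != "sample":
                child_labels[level] = child_prefix
            node, h = build(level_idx + 1, child_prefix, child_labels)
            children.append(node)
            heights.append(h)
        lower = depths[_LEVELS[level_idx + 1]] if level_idx + 1 < len(_LEVELS) else 0.0
        return _resolve_radiation(children, heights, depths[level], lower)

    root, _root_h = build(0, "", {})
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    table = pd.DataFrame(rows, columns=["sample", "species", "genus", "tribe"])
    return table, tree


# --------------------------------------------------------------------------
# gene trees
# --------------------------------------------------------------------------

def _eligible_nni_nodes(tree: dendropy.Tree) -> list[dendropy.Node]:
    # exclude children of the root: the root edge is trivial once unrooted,
    # so an interchange across it would only re-root the tree
    out = []
    for node in tree.preorder_node_iter():
        if (node.parent_node is not None
                and node.parent_node is not tree.seed_node
                and not node.is_leaf()
                and len(node.child_nodes()) == 2):
            out.append(node)
    return out


def _apply_random_nni(tree: dendropy.Tree, rng: np.random.Generator) -> bool:
    """One random nearest-neighbor interchange; returns False if no edge is
    eligible (fewer than 4 leaves)."""
    nodes = _eligible_nni_nodes(tree)
    if not nodes:
        return False
    v = nodes[rng.integers(len(nodes))]
    u = v.parent_node
    siblings = [c for c in u.child_nodes() if c is not v]
    s = siblings[rng.integers(len(siblings))]
    c = v.child_nodes()[rng.integers(2)]
    # swap subtree c (child of v) with subtree s (sibling of v)
    u.remove_child(s)
    v.remove_child(c)
    v.add_child(s)
    u.add_child(c)
    return True


def simulate_gene_trees(species_tree: dendropy.Tree, config: SimConfig,
                        truth: GroundTruth | None = None,
                        ) -> tuple[dict[str, dendropy.Tree], GroundTruth]:
    """Clone one gene tree per locus, planting discordance and long branches.

    Each discordant locus differs from the species tree by exactly one random
    NNI; each long-branch locus has one leaf's terminal branch multiplied by
    ``long_branch_factor``.  The ground truth records both sets.
    """
    for node in species_tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) not in (0, 2):
            raise ValueError("species tree must be binary")
    truth = truth if truth is not None else GroundTruth()
    truth.species_tree = species_tree
    rng = np.random.default_rng([config.seed, 1])
    gene_trees: dict[str, dendropy.Tree] = {}
    for i in range(config.n_loci):
        locus = f"L{i + 1:04d}"
        gt = species_tree.clone(depth=1)
        gt.is_rooted = True
        if rng.random() < config.discordance_rate:
            if _apply_random_nni(gt, rng):
                truth.discordant_loci.add(locus)
        if rng.random() < config.long_branch_rate:
            leaves = gt.leaf_nodes()
            leaf = leaves[rng.integers(len(leaves))]
            leaf.edge.length *= config.long_branch_factor
            truth.inflated_leaves.add(
                (locus, leaf.taxon.label, config.long_branch_factor))
        gene_trees[locus] = gt
    truth.gene_trees = gene_trees
    return gene_trees, truth


# --------------------------------------------------------------------------
# sequence evolution (Jukes-Cantor)
# --------------------------------------------------------------------------

def jc_expected_p(d: float) -> float:
    """Expected proportion of differing sites at JC distance ``d``."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an integer-coded sequence along one branch of JC length ``d``."""
    p = jc_expected_p(d)
    out = seq.copy()
    hit = rng.random(seq.size) < p
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def simulate_alignment(gene_tree: dendropy.Tree, locus_length: int,
                       subst_scale: float, seed,
                       locus: str | None = None) -> LocusAlignment:
    """Evolve one natively-aligned locus along ``gene_tree`` under JC.

    Each site mutates on a branch of length ``b`` with probability
    ``3/4 * (1 - exp(-4/3 * b * subst_scale))``, landing uniformly on one of
    the other three bases — exactly the Jukes-Cantor transition kernel.
    """
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    for edge in gene_tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("branch lengths must be non-negative")
    rng = np.random.default_rng(seed)
    root = gene_tree.seed_node
    states: dict[int, np.ndarray] = {
        id(root): rng.integers(0, 4, size=locus_length)}
    seqs: dict[str, str] = {}
    for node in gene_tree.preorder_node_iter():
        if node is root:
            parent_state = states[id(root)]
        else:
            d = (node.edge.length or 0.0) * subst_scale
            parent_state = _mutate(states[id(node.parent_node)], d, rng)
            states[id(node)] = parent_state
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(_BASES[parent_state])
    name = locus if locus is not None else "locus"
    return LocusAlignment(name, seqs)


# --------------------------------------------------------------------------
# contigs and paralogs
# --------------------------------------------------------------------------

def plant_paralogs(dataset: SyntheticDataset,
                   paralog_loci=None,
                   seed=None) -> tuple[pd.DataFrame, GroundTruth]:
    """Build per-(sample, locus) contig tables, planting paralogous copies.

    Every present cell gets one contig of near-reference length with coverage
    near the configured mean.  Cells listed in ``paralog_loci`` — each entry
    ``(locus, clade, extra_divergence)`` applies to all samples of the named
    clade — additionally get a second long contig with coverage within the
    flaggable ratio of the first, and a second gene copy diverged from the
    sample's true sequence by ``extra_divergence`` substitutions/site.
    """
    config = dataset.config
    paralog_loci = (config.paralog_loci if paralog_loci is None
                    else tuple((str(l), str(c), float(d)) for l, c, d in paralog_loci))
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 3])
    ref_len = config.locus_length

    planted: dict[tuple[str, str], float] = {}
    for locus, clade, extra_div in paralog_loci:
        if locus not in dataset.true_sequences:
            raise KeyError(f"unknown locus in paralog_loci: {locus!r}")
        for sample in dataset.group_samples(clade):  # raises on unknown clade
            planted[(sample, locus)] = extra_div

    rows = []
    for locus, per_sample in dataset.true_sequences.items():
        for sample, true_seq in per_sample.items():
            cov1 = config.mean_coverage * rng.uniform(0.8, 1.2)
            len1 = int(round(ref_len * rng.uniform(0.90, 1.0)))
            rows.append((sample, locus, f"{sample}|{locus}|c1", len1, cov1))
            if (sample, locus) in planted:
                extra_div = planted[(sample, locus)]
                len2 = int(np.ceil(ref_len * rng.uniform(0.86, 1.0)))
                cov2 = cov1 / rng.uniform(1.0, 5.0)
                rows.append((sample, locus, f"{sample}|{locus}|c2", len2, cov2))
                coded = np.frombuffer(true_seq.encode(), dtype=np.uint8)
                lut = np.full(256, -1, dtype=np.int64)
                for i, b in enumerate("ACGT"):
                    lut[ord(b)] = i
                copy = _mutate(lut[coded], extra_div, rng)
                dataset.paralog_copies[(sample, locus)] = "".join(_BASES[copy])
                dataset.truth.planted_paralogs.add((sample, locus))
    contigs = pd.DataFrame(
        rows, columns=["sample", "locus", "contig_id", "length", "mean_coverage"])
    dataset.contigs = contigs
    return contigs, dataset.truth


# --------------------------------------------------------------------------
# pileups
# --------------------------------------------------------------------------

def simulate_pileup(true_sequence: str, mean_coverage: float, error_rate: float,
                    seed) -> np.ndarray:
    """Per-position A/C/G/T base counts for one sequence.

    Coverage is Poisson(``mean_coverage``) per position; each read base equals
    the truth with probability ``1 - error_rate`` and otherwise is uniform
    over the remaining three bases.  Positions whose true character is not an
    unambiguous base (e.g., a masked N) get zero coverage.  Returns an (L, 4)
    integer array of counts in A, C, G, T order.
    """
    if mean_coverage < 0:
        raise ValueError("mean_coverage must be >= 0")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    L = len(true_sequence)
    counts = np.zeros((L, 4), dtype=np.int64)
    lut = {b: i for i, b in enumerate("ACGT")}
    coverage = rng.poisson(mean_coverage, size=L)
    for pos, ch in enumerate(true_sequence):
        idx = lut.get(ch.upper())
        if idx is None:
            continue
        cov = int(coverage[pos])
        if cov == 0:
            continue
        correct = rng.binomial(cov, 1.0 - error_rate)
        counts[pos, idx] += correct
        n_err = cov - correct
        if n_err:
            others = [i for i in range(4) if i != idx]
            errs = rng.multinomial(n_err, [1 / 3] * 3)
            for o, e in zip(others, errs):
                counts[pos, o] += int(e)
    return counts


# --------------------------------------------------------------------------
# missingness
# --------------------------------------------------------------------------

def apply_missingness(dataset: SyntheticDataset,
                      dropout_prob: float | None = None,
                      partial_prob: float | None = None,
                      partial_fraction: float | None = None,
                      seed=None) -> tuple[SyntheticDataset, GroundTruth]:
    """Drop or partially mask (sample, locus) cells in place.

    A dropped cell disappears from its locus alignment entirely; a partial
    cell has a contiguous run of ``ceil(partial_fraction * length)`` positions
    replaced by N, starting at a uniform random offset (mimicking partial
    capture of a target).  The ground truth records every masked cell.
    """
    cfg = dataset.config
    dropout_prob = cfg.dropout_prob if dropout_prob is None else dropout_prob
    partial_prob = cfg.partial_prob if partial_prob is None else partial_prob
    partial_fraction = (cfg.partial_fraction if partial_fraction is None
                        else partial_fraction)
    if not 0.0 <= partial_fraction <= 1.0:
        raise ValueError("partial_fraction must be in [0, 1]")
    for p in (dropout_prob, partial_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 4])
    for locus, aln in dataset.alignments.items():
        dropped = []
        for sample in list(aln.sequences):
            u = rng.random()
            if u < dropout_prob:
                dropped.append(sample)
                dataset.truth.masked_cells.add((sample, locus, "dropped"))
            elif rng.random() < partial_prob:
                L = aln.length
                run = int(np.ceil(partial_fraction * L))
                if run > 0:
                    start = int(rng.integers(0, L - run + 1))
                    seq = aln.sequences[sample]
                    aln.sequences[sample] = (
                        seq[:start] + "N" * run + seq[start + run:])
                    dataset.truth.masked_cells.add((sample, locus, "partial"))
        for sample in dropped:
            del aln.sequences[sample]
    return dataset, dataset.truth


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run the full generator: taxonomy, gene trees, alignments, paralog
    contigs, and missingness.  Identical configs give identical datasets."""
    table, species_tree = generate_taxonomy(config)
    truth = GroundTruth(species_tree=species_tree)
    dataset = SyntheticDataset(
        config=config, sample_table=table, species_tree=species_tree,
        gene_trees={}, alignments={}, true_sequences={}, contigs=pd.DataFrame(),
        paralog_copies={}, truth=truth)
    gene_trees, _ = simulate_gene_trees(species_tree, config, truth)
    dataset.gene_trees = gene_trees
    for i, (locus, gt) in enumerate(gene_trees.items()):
        aln = simulate_alignment(gt, config.locus_length, config.subst_scale,
                                 seed=[config.seed, 2, i], locus=locus)
        dataset.true_sequences[locus] = dict(aln.sequences)
        dataset.alignments[locus] = aln
    plant_paralogs(dataset)
    apply_missingness(dataset)
    return dataset


def dataset_pileup(dataset: SyntheticDataset, sample: str, locus: str,
                   ) -> np.ndarray:
    """Simulate the pileup for one present (sample, locus) cell.

    Uses the post-missingness sequence, so masked positions have zero
    coverage; the sub-seed is derived from the cell so pileups are
    reproducible independently of generation order.
    """
    aln = dataset.alignments[locus]
    if sample not in aln:
        raise KeyError(f"cell ({sample}, {locus}) was dropped")
    idx = dataset.sample_table.index[dataset.sample_table["sample"] == sample][0]
    locus_idx = list(dataset.alignments).index(locus)
    return simulate_pileup(aln[sample], dataset.config.mean_coverage,
                           dataset.config.error_rate,
                           seed=[dataset.config.seed, 5, int(idx), locus_idx])


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def export_dataset(dataset: SyntheticDataset, outdir: str | Path,
                   write_pileups: bool = False) -> None:
    """Write the dataset as plain-text files (FASTA / Newick / TSV)."""
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    dataset.sample_table.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    dataset.contigs.to_csv(outdir / "contigs.tsv", sep="\t", index=False)
    dataset.truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t",
                                    index=False)
    dataset.species_tree.write(path=str(outdir / "species_tree.nwk"),
                               schema="newick")
    with open(outdir / "gene_trees.nwk", "w") as fh:
        for locus, gt in dataset.gene_trees.items():
            fh.write(gt.as_string(schema="newick").strip() + "\n")
    for locus, aln in dataset.alignments.items():
        if aln.n_samples:
            write_fasta(aln, outdir / "alignments" / f"{locus}.fasta")
    if write_pileups:
        rows = []
        for locus, aln in dataset.alignments.items():
            for sample in aln.samples:
                counts = dataset_pileup(dataset, sample, locus)
                for pos in range(counts.shape[0]):
                    rows.append((sample, locus, pos + 1, *counts[pos]))
        pd.DataFrame(rows, columns=["sample", "locus", "position",
                                    "count_A", "count_C", "count_G", "count_T"]
                     ).to_csv(outdir / "pileups.tsv", sep="\t", index=False)
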