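"""Gene-tree plumbing and gene-tree/species-tree comparison.

Provides the internal tree toolkit of the pipeline: neighbor-joining on
Jukes-Cantor distances (the stand-in estimator — externally supplied Newick
gene trees are accepted everywhere trees are consumed), bootstrap support,
majority-rule consensus, detection and removal of unexpectedly long
terminal branches ("shrinking"), and per-node categorization of gene-tree
concordance and conflict against a species tree.

Conflict categorization follows the bipartition-counting approach used for
large phylogenomic datasets: gene-tree nodes below a bootstrap threshold
are collapsed first; then, for each species-tree clade, every usable gene
tree is counted as concordant (it contains the clade, restricted to its own
leaves), conflicting (it contains an incompatible clade — the most frequent
such clade across gene trees is the "top alternative"), or uninformative.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .alignments import LocusAlignment


# --------------------------------------------------------------------------
# distances and neighbor joining
# --------------------------------------------------------------------------

def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Proportion of differing sites with pairwise deletion.

    Only positions where both sequences carry an unambiguous base are
    compared.  Returns (p, number of comparable sites).
    """
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    if a.size != b.size:
        raise ValueError("sequences differ in length")
    valid = np.zeros(256, dtype=bool)
    valid[[ord(c) for c in "ACGT"]] = True
    ok = valid[a] & valid[b]
    comparable = int(ok.sum())
    diff = int((a[ok] != b[ok]).sum())
    return (diff / comparable if comparable else float("nan")), comparable


def jc_distance(p: float, max_distance: float = 5.0) -> float:
    """Jukes-Cantor distance ``-3/4 ln(1 - 4/3 p)``; saturated pairs
    (p >= 0.75) are capped at ``max_distance`` with a warning."""
    if p >= 0.75:
        warnings.warn(
            f"p-distance {p:.3f} at or beyond JC saturation; "
            f"capping distance at {max_distance}", stacklevel=2)
        return max_distance
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def jc_distance_matrix(alignment: LocusAlignment,
                       max_distance: float = 5.0,
                       ) -> tuple[list[str], np.ndarray]:
    labels = alignment.samples
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, comparable = p_distance(alignment[labels[i]],
                                       alignment[labels[j]])
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]} and {labels[j]}")
            d[i, j] = d[j, i] = jc_distance(p, max_distance)
    return labels, d


def nj_from_matrix(labels: Sequence[str], matrix: np.ndarray,
                   ) -> dendropy.Tree:
    """Neighbor-joining tree from a labelled distance matrix.

    Fully deterministic: Q-matrix ties are broken by the lexicographically
    first index pair, so identical inputs always give identical trees (a
    guarantee the bootstrap and the pipeline's byte-identical reruns rely
    on).  Exact on additive matrices.
    """
    n = len(labels)
    if n < 2 or matrix.shape != (n, n):
        raise ValueError("need an (n, n) matrix with n >= 2")
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    nodes: dict[int, dendropy.Node] = {}
    for i, label in enumerate(labels):
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=label)
        nodes[i] = node
    d = {(i, j): float(matrix[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n

    def dist(a, b):
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist(a, b) for b in active if b != a)
                  for a in active}
        best, best_q = None, None
        for x in range(r):
            for y in range(x + 1, r):
                a, b = active[x], active[y]
                q = (r - 2) * dist(a, b) - totals[a] - totals[b]
                if best_q is None or q < best_q:
                    best_q, best = q, (a, b)
        a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[next_id] = parent
        for c in active:
            if c not in (a, b):
                d[(next_id, c)] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1

    root = tree.seed_node
    if len(active) == 3:
        a, b, c = active
        nodes[a].edge.length = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
        nodes[b].edge.length = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
        nodes[c].edge.length = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
        for x in active:
            root.add_child(nodes[x])
    elif len(active) == 2:
        a, b = active
        nodes[a].edge.length = nodes[b].edge.length = 0.5 * dist(a, b)
        root.add_child(nodes[a])
        root.add_child(nodes[b])
    else:
        root.add_child(nodes[active[0]])
    return tree


def nj_tree(alignment: LocusAlignment, max_distance: float = 5.0,
            ) -> dendropy.Tree:
    """Neighbor-joining gene tree from JC distances with pairwise deletion."""
    if alignment.n_samples < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    labels, d = jc_distance_matrix(alignment, max_distance)
    tree = nj_from_matrix(labels, d)
    tree.locus = alignment.locus
    return tree


# --------------------------------------------------------------------------
# bipartitions (leaf-set form, shared across consensus / bootstrap / conflict)
# --------------------------------------------------------------------------

def _leafset(node: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def unrooted_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial splits of a tree, each normalised to the side *not*
    containing the lexicographically smallest leaf label."""
    universe = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(universe)
    out = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = _leafset(node)
        if ref in side:
            side = universe - side
        if 2 <= len(side) <= len(universe) - 2:
            out.add(side)
    return out


def rooted_clades(tree: dendropy.Tree, min_size: int = 2) -> set[frozenset]:
    """Leaf sets of internal nodes (root excluded)."""
    universe = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        clade = _leafset(node)
        if min_size <= len(clade) < len(universe):
            out.add(clade)
    return out


def _build_tree_from_clades(universe: frozenset,
                            clades: dict[frozenset, float],
                            ) -> dendropy.Tree:
    """Assemble a rooted tree from a nested (compatible) clade set; clade
    values become node supports (percent)."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    ordered = sorted(clades, key=len, reverse=True)
    nodes: dict[frozenset, dendropy.Node] = {}
    root = tree.seed_node

    def parent_of(item: frozenset) -> dendropy.Node:
        best = None
        for c in ordered:
            if item < c and (best is None or len(c) < len(best)):
                best = c
        return nodes[best] if best is not None else root

    for clade in ordered:
        node = dendropy.Node()
        node.label = f"{clades[clade]:g}"
        node.support = clades[clade]
        nodes[clade] = node
    for clade in ordered:
        parent_of(clade).add_child(nodes[clade])
    for leaf_label in sorted(universe):
        leaf = dendropy.Node()
        leaf.taxon = tns.new_taxon(label=leaf_label)
        parent_of(frozenset([leaf_label])).add_child(leaf)
    return tree


def majority_consensus_tree(gene_trees: Sequence[dendropy.Tree],
                            ) -> dendropy.Tree:
    """Majority-rule consensus: splits present in more than half of the
    trees, with per-node support equal to their occurrence percentage."""
    trees = list(gene_trees)
    if not trees:
        raise ValueError("no input trees")
    universes = {frozenset(lf.taxon.label for lf in t.leaf_node_iter())
                 for t in trees}
    if len(universes) > 1:
        raise ValueError("input trees must share one leaf universe")
    universe = universes.pop()
    counts: Counter = Counter()
    for t in trees:
        counts.update(unrooted_splits(t))
    n = len(trees)
    majority = {split: 100.0 * c / n
                for split, c in counts.items() if c / n > 0.5}
    # splits in >50% of trees are pairwise compatible, so they nest once the
    # normalisation leaf is treated as the root
    ref = min(universe)
    clades = {split: support for split, support in majority.items()}
    return _build_tree_from_clades(universe, clades)


def bootstrap_support(alignment: LocusAlignment, n_reps: int, seed,
                      max_distance: float = 5.0) -> dendropy.Tree:
    """NJ tree with split supports from column-resampled replicates.

    Support = percentage of replicate NJ trees containing each split of the
    original tree, attached as ``node.support`` and ``node.label``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(alignment, max_distance)
    rng = np.random.default_rng(seed)
    L = alignment.length
    counts: Counter = Counter()
    samples = alignment.samples
    seq_rows = [alignment[s] for s in samples]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = LocusAlignment(alignment.locus, {
            s: "".join(row[c] for c in cols)
            for s, row in zip(samples, seq_rows)})
        try:
            counts.update(unrooted_splits(nj_tree(rep, max_distance)))
        except ValueError:
            continue  # replicate with an incomparable pair contributes nothing
    universe = frozenset(samples)
    ref = min(universe)
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = _leafset(node)
        if ref in side:
            side = universe - side
        if 2 <= len(side) <= len(universe) - 2:
            node.support = 100.0 * counts[side] / n_reps
            node.label = f"{node.support:g}"
    return tree


# --------------------------------------------------------------------------
# long-branch detection and shrinking
# --------------------------------------------------------------------------

@dataclass
class ShrinkReport:
    """Leaves flagged as long-branch outliers, per gene tree."""

    removed: dict[str, set[str]] = field(default_factory=dict)
    signatures: pd.DataFrame | None = None

    @property
    def n_flagged(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def shrunken_fraction(self, n_total: int) -> float:
        return (sum(1 for v in self.removed.values() if v) / n_total
                if n_total else 0.0)


def _leaf_signatures(tree: dendropy.Tree) -> dict[str, float]:
    """Relative diameter reduction from dropping each leaf.

    delta(leaf) = (diameter(T) - diameter(T without leaf)) / diameter(T);
    zero for leaves off every maximal path.
    """
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace
            if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]])
    diameter = d.max()
    out = {}
    for i, label in enumerate(labels):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = d[np.ix_(mask, mask)]
        reduced = sub.max() if sub.size else 0.0
        out[label] = ((diameter - reduced) / diameter) if diameter > 0 else 0.0
    return out


def detect_long_branches(gene_trees: Mapping[str, dendropy.Tree],
                         tolerance: float = 0.10,
                         min_signature: float = 0.2) -> ShrinkReport:
    """Flag leaf occurrences whose removal shrinks the tree diameter
    unexpectedly much.

    For every leaf occurrence across all gene trees the diameter-impact
    signature delta is computed; occurrences are flagged when delta exceeds
    both the empirical (1 - tolerance) quantile of all signatures (pooled
    across trees and species) and ``min_signature``.  Trees with fewer than
    4 leaves are skipped with a warning.
    """
    if not 0.0 < tolerance < 1.0:
        raise ValueError("tolerance must be in (0, 1)")
    rows = []
    for locus, tree in gene_trees.items():
        if len(tree.leaf_nodes()) < 4:
            warnings.warn(f"gene tree {locus} has <4 leaves; skipped",
                          stacklevel=2)
            continue
        for label, delta in _leaf_signatures(tree).items():
            rows.append((locus, label, delta))
    report = ShrinkReport()
    if not rows:
        return report
    sig = pd.DataFrame(rows, columns=["locus", "sample", "signature"])
    threshold = float(np.quantile(sig["signature"], 1.0 - tolerance))
    flagged = sig[(sig["signature"] > threshold)
                  & (sig["signature"] > min_signature)]
    for r in flagged.itertuples():
        report.removed.setdefault(r.locus, set()).add(r.sample)
    report.signatures = sig
    return report


def shrink_dataset(alignments: Mapping[str, LocusAlignment],
                   report: ShrinkReport, min_samples: int = 3,
                   ) -> tuple[dict[str, LocusAlignment], float]:
    """Remove flagged samples from the corresponding alignments.

    Returns the shrunken alignments and the fraction of alignments touched.
    Flagged samples absent from their alignment are warned about and
    skipped; alignments left with fewer than ``min_samples`` sequences are
    dropped entirely (with a warning).
    """
    out: dict[str, LocusAlignment] = {}
    n_total = len(alignments)
    n_shrunk = 0
    for locus, aln in alignments.items():
        to_remove = report.removed.get(locus, set())
        present = to_remove & set(aln.samples)
        for missing in sorted(to_remove - present):
            warnings.warn(
                f"sample {missing} not in alignment {locus}; skipped",
                stacklevel=2)
        if present:
            n_shrunk += 1
            shrunk = aln.drop_samples(present)
            if shrunk.n_samples < min_samples:
                warnings.warn(
                    f"alignment {locus} left with <{min_samples} samples "
                    "after shrinking; dropped", stacklevel=2)
                continue
            out[locus] = shrunk
        else:
            out[locus] = aln.copy()
    return out, (n_shrunk / n_total if n_total else 0.0)


# --------------------------------------------------------------------------
# conflict analysis
# --------------------------------------------------------------------------

@dataclass
class NodeConflict:
    """Category counts for one species-tree clade."""

    clade: frozenset
    concordant: int = 0
    top_alternative: int = 0
    other_conflict: int = 0
    uninformative: int = 0
    top_alternative_clade: frozenset | None = None

    @property
    def total(self) -> int:
        return (self.concordant + self.top_alternative
                + self.other_conflict + self.uninformative)


@dataclass
class ConflictReport:
    """Per-node conflict categories plus usable-tree accounting."""

    nodes: dict[frozenset, NodeConflict]
    n_usable: int
    n_excluded_missing_outgroup: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for clade, nc in self.nodes.items():
            rows.append(("|".join(sorted(clade)), nc.concordant,
                         nc.top_alternative, nc.other_conflict,
                         nc.uninformative,
                         "|".join(sorted(nc.top_alternative_clade))
                         if nc.top_alternative_clade else ""))
        return pd.DataFrame(rows, columns=[
            "clade", "concordant", "top_alternative", "other_conflict",
            "uninformative", "top_alternative_clade"])


def _node_support(node: dendropy.Node) -> float | None:
    if getattr(node, "support", None) is not None:
        return float(node.support)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def collapse_low_support(tree: dendropy.Tree,
                         bs_threshold: float) -> dendropy.Tree:
    """Collapse internal edges whose node support is below ``bs_threshold``.

    Nodes without any support annotation are kept (hand-built or fully
    resolved trees are counted at face value).
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_internal_node_iter(exclude_seed_node=True):
        support = _node_support(node)
        if support is not None and support < bs_threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


def _clade_sort_key(clade: frozenset) -> tuple:
    return tuple(sorted(clade))


def conflict_analysis(species_tree: dendropy.Tree,
                      gene_trees: Mapping[str, dendropy.Tree],
                      bs_threshold: float = 80.0,
                      outgroup: str | None = None) -> ConflictReport:
    """Categorize every gene tree at every internal species-tree node.

    When ``outgroup`` is given, gene trees lacking it are excluded (and
    counted) and the rest are rerooted on it, mirroring the requirement
    that all trees share one outgroup; otherwise gene-tree rootings are
    taken as supplied.  Gene-tree nodes with support below ``bs_threshold``
    are collapsed before counting.  At each species-tree clade C a gene
    tree is concordant if it contains C restricted to its own leaf set,
    conflicting if it contains an incompatible clade (the most frequent
    such clade over gene trees is the top alternative; ties break
    lexicographically), and uninformative otherwise.
    """
    if not species_tree.is_rooted:
        raise ValueError("species tree must be rooted")
    usable: dict[str, dendropy.Tree] = {}
    n_excluded = 0
    for locus, gt in gene_trees.items():
        labels = {lf.taxon.label for lf in gt.leaf_node_iter()}
        if outgroup is not None:
            if outgroup not in labels:
                n_excluded += 1
                continue
            gt = gt.clone(depth=1)
            og = next(lf for lf in gt.leaf_node_iter()
                      if lf.taxon.label == outgroup)
            gt.to_outgroup_position(og, update_bipartitions=False)
            gt.is_rooted = True
        usable[locus] = collapse_low_support(gt, bs_threshold)

    gene_clades = {locus: rooted_clades(gt) for locus, gt in usable.items()}
    gene_leaves = {locus: frozenset(lf.taxon.label
                                    for lf in gt.leaf_node_iter())
                   for locus, gt in usable.items()}

    nodes: dict[frozenset, NodeConflict] = {}
    for clade in sorted(rooted_clades(species_tree), key=_clade_sort_key):
        nc = NodeConflict(clade)
        alternatives: Counter = Counter()
        per_tree_alt: dict[str, frozenset] = {}
        for locus in usable:
            restricted = clade & gene_leaves[locus]
            if len(restricted) < 2 or restricted == gene_leaves[locus]:
                nc.uninformative += 1
                continue
            clades_here = gene_clades[locus]
            if restricted in clades_here:
                nc.concordant += 1
                continue
            conflicting = [x for x in clades_here
                           if x & restricted and not x <= restricted
                           and not restricted <= x]
            if conflicting:
                alt = min(conflicting,
                          key=lambda x: (-len(x & restricted), len(x),
                                         _clade_sort_key(x)))
                alternatives[alt] += 1
                per_tree_alt[locus] = alt
            else:
                nc.uninformative += 1
        if alternatives:
            top = min(alternatives,
                      key=lambda x: (-alternatives[x], _clade_sort_key(x)))
            nc.top_alternative_clade = top
            nc.top_alternative = alternatives[top]
            nc.other_conflict = sum(alternatives.values()) - alternatives[top]
        nodes[clade] = nc
    return ConflictReport(nodes, n_usable=len(usable),
                          n_excluded_missing_outgroup=n_excluded)


# --------------------------------------------------------------------------
# Newick IO
# --------------------------------------------------------------------------

def read_gene_trees(path, rooted: bool = True) -> dict[str, dendropy.Tree]:
    """Read a multi-tree Newick file; trees are keyed L0001, L0002, ... or by
    their internal labels if present."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    out = {}
    for i, t in enumerate(trees):
        if rooted:
            t.is_rooted = True
        key = getattr(t, "label", None) or f"L{i + 1:04d}"
        out[key] = t
    return out
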