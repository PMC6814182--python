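# Methods and design notes

This note documents the models, rules and numerical choices behind
`hybcurate`, and what the synthetic-data tests do and do not demonstrate
about real Hyb-Seq data.

## The curation rules and their parameters

All cutoffs live in one `Thresholds` record (defaults in parentheses):

| parameter | default | meaning |
|---|---|---|
| `majority_fraction` | 0.70 | minimum within-column base frequency for a consensus call; **inclusive**, so an exact 70% call yields the base |
| `min_coverage` | 4 | reads required for any call; the two textual readings of the coverage rule (">4×" vs. "<4× → N") are reconciled as: coverage ≥ 4 passes, < 4 gives N |
| `paralog_length_fraction` | 0.85 | contig qualifies as long if length **strictly** > 0.85 × reference |
| `paralog_coverage_ratio` | 10 | "similar coverage" read as max/min mean coverage ≤ 10 among the qualifying contigs (an all-pairs criterion; the alternative best-contig-vs-rest pairing is not used) |
| `sample_missing_cutoff` | 0.70 | samples with missing fraction **strictly** above are dropped from a locus; missing characters are `N`, `-`, `?` |
| `sample_presence_fraction` | 1.00 | a locus needs ⌈fraction × group size⌉ group samples; 1.0 is the exon-matrix default, 0.70–0.80 suits trimmed supercontigs |
| `resoverlap` / `seqoverlap` | 0.65 / 70 | spurious-sequence removal (below) |
| `shrink_tolerance` | 0.10 | false-positive tolerance of long-branch detection |
| `shrink_min_signature` | 0.2 | minimum relative diameter reduction for a flag |
| `conflict_bs_threshold` | 80 | gene-tree nodes below this support are collapsed before conflict counting (50 is the other conventional choice) |
| `well_supported_bs` | 95 | reporting convention only |

The filter cascade runs in a fixed order — per-locus missing-data filter,
then sample presence, then paralog-union removal — because the first stage
can push a locus below the presence criterion.  The order matters and is
pinned by a test.  Provenance reasons (`not_captured`,
`sample_missing_data`, `presence_filter`, `paralog`, `retained`) partition
the input locus set by construction; a locus that is both under-present
and paralogous is recorded under the earlier stage.

When consensus calling is run with permissive configurations
(majority fraction ≤ 0.5 is rejected outright, but ties could arise in
principle), tied top bases yield `N`; at the default 0.70 a tie above
threshold is impossible.

### Trimming approximations

Two supercontig-style trimming steps are deliberate re-statements, chosen
for determinism rather than equivalence with any external tool:

* **Spurious-sequence removal** evaluates, for each sequence, the fraction
  of *other* sequences sharing its character class (residue vs. gap/`N`)
  per column; a column is good when that fraction is ≥ `resoverlap`, and
  the sequence is dropped when its good-column percentage is below
  `seqoverlap`.  This uses character *class*, not residue identity — an
  approximation of the original overlap semantics.
* **Gappy-column removal** sorts per-column gap fractions ascending and
  takes as cutoff the value at the steepest point of that curve (3-point
  window, first maximum, lower end of the window); columns strictly above
  the cutoff are removed, and a flat curve removes nothing.  This is a
  simplified, fully deterministic analogue of the usual data-driven
  gap-trimming heuristic.

## Tree methods

**Distances and NJ.** Pairwise distances are Jukes–Cantor,
`d = −¾ ln(1 − 4p/3)`, with pairwise deletion of sites that are not
unambiguous bases in both sequences; saturated pairs (p ≥ 0.75) are capped
at a configurable maximum (default 5.0 substitutions/site) with a warning,
and a pair with zero comparable sites is an error.  Neighbor joining is
implemented in-house with explicit first-index tie-breaking in the
Q-matrix so that identical inputs always give identical trees — a
guarantee the bootstrap (column resampling with a fixed seed) and the
pipeline's byte-identical rerun contract both rely on.  NJ is exact on
additive matrices (tested).  These are plumbing: externally estimated gene
trees in Newick are accepted everywhere trees are consumed.

**Long-branch detection.** For every leaf occurrence in every gene tree
the signature δ = (diameter(T) − diameter(T ∖ leaf)) / diameter(T) is
computed; occurrences are flagged when δ exceeds both the empirical
(1 − tolerance) quantile of the signatures **pooled across all trees and
species** and `shrink_min_signature`.  The pooled quantile (rather than a
per-species quantile) is a deliberate choice: a per-species quantile at
tolerance τ can never flag more than ~τ of one species' occurrences, so it
fails precisely in the regime of interest — one rogue sample with inflated
branches in a substantial fraction of gene trees.  The detector shares the
interface (tolerance 0.10) of the tree-shrinking tools used in practice
but is validated by planted-outlier recovery on synthetic trees, not by
tool equivalence.  Note a geometric consequence of the signature: a ×10
inflation of a terminal branch *b* in a tree of diameter *D* gives
δ ≈ 9b/(D + 9b), so very short terminal branches (deeply nested extra
samples per species) can fall below the 0.2 floor; with one sample per
species — the usual sampling design at genus level and above — terminal
branches sit at the species-divergence depth and ×10 inflation yields
δ ≈ 0.40, far above the floor.

**Conflict analysis.** Rooted-clade comparison after collapsing gene-tree
nodes below the support threshold (nodes without any support annotation
are kept).  For species-tree clade C and a gene tree with leaf set L:
C′ = C ∩ L; the tree is uninformative when |C′| < 2 or C′ = L; concordant
when some gene-tree clade equals C′; conflicting when some clade overlaps
C′ without nesting.  A conflicting tree's recorded alternative is the
incompatible clade with the largest overlap with C′ (ties: smaller clade,
then lexicographic by leaf labels); the per-node "top alternative" is the
most frequent recorded clade, ties again lexicographic.  When an outgroup
is specified, gene trees lacking it are excluded (and counted) and the
remainder rerooted on it; the four categories sum to the usable-tree count
at every node by construction, and that conservation is asserted in tests.

## The synthetic-data generator

The generator emulates the *structure* of a nested target-enrichment
study, not its biology:

* **Taxonomy/species tree.** Balanced nesting (tribes ⊃ genera ⊃ species ⊃
  samples) with an ultrametric binary tree; radiations occur at
  level-specific depths (defaults, in expected substitutions/site from the
  tips: tribe 1.0, genus 0.4, species 0.15, sample 0.05 — arbitrary but
  fixed, exposed in `SimConfig.level_depths`).  Radiations with more than
  two children are resolved into evenly spaced ladders within the level's
  time span, keeping the tree binary and ultrametric.
* **Gene trees.** Clones of the species tree; with probability
  `discordance_rate` a locus receives one random nearest-neighbor
  interchange (the simplest controllable discordance — full coalescent
  simulation is intentionally out of scope), and with probability
  `long_branch_rate` one leaf's terminal branch is multiplied by
  `long_branch_factor`.  NNI edges incident to the root are excluded,
  since an interchange across the degree-2 root edge only re-roots the
  tree.
* **Sequences.** Jukes–Cantor evolution, per branch and per site:
  substitution with probability ¾(1 − e^{−4d/3}) at scaled branch length
  d, landing uniformly on one of the other three bases — the exact JC
  kernel, so the empirical p-distance matches the closed form (tested at
  L = 10⁴ within ±0.01).  No indels: sequences are natively aligned.
  `subst_scale` (default 1.0) rescales all branch lengths, e.g. for
  low-divergence round-trip experiments.
* **Paralogs.** Planted per (locus, clade, extra divergence): affected
  cells get a second contig whose length (> 0.86 × reference) and coverage
  ratio (≤ 5) satisfy the flagging criterion by construction, plus a gene
  copy diverged from the sample's sequence by the stated amount; all other
  cells get exactly one contig.  Flagging on noiseless planted data is
  therefore perfect by design — the test establishes that the rule is
  implemented correctly, not that the rule is powerful on real assemblies.
* **Pileups.** Poisson(coverage) depth per position; each read matches the
  truth with probability 1 − error_rate, else uniform over the other three
  bases.  Masked (`N`) positions get zero coverage, so consensus calling
  round-trips the post-missingness sequence.
* **Missingness.** Per (sample, locus): whole-cell dropout with
  `dropout_prob`, else a contiguous run of ⌈`partial_fraction` · L⌉ `N`s
  at a uniform random offset with `partial_prob` (mimicking partial
  capture of a target).

All randomness derives from the single `seed` through
`numpy.random.default_rng([seed, stage, index])` sub-streams, so identical
configs give byte-identical datasets regardless of generation order.

**What the synthetic tests do not show.**  The generator has no indels or
alignment error, no GC/length capture bias, no allelic variation (a
flagged "paralog" in real data may be a divergent allele), no
multispecies-coalescent gene-tree distribution, and no read-level
artifacts.  Green tests demonstrate that the curation rules are
implemented exactly and behave correctly where truth is known; they do not
quantify the rules' error rates on real assemblies.

## Problem sizes

The default test and acceptance runs use deliberately small instances
chosen to exercise every code path: 8–16-sample taxonomies, 100-locus
gene-tree sets for rate calibration (binomial 99% bounds), 100 replicates
of L = 5000 alignments for NJ topology recovery, 200 clean trees for the
long-branch null calibration, and 50 random groups for cascade
conservation.  These sizes make the whole suite run in seconds while
keeping the binomial bounds meaningful.

## Known limitations and recorded discrepancies

* The packaged 21-group locus-count table is transcribed verbatim from the
  published table.  Two internal inconsistencies of the publication are
  preserved, not resolved: its running text gives a tribe-level count of
  213 where the table prints 212 for the same group, and its stated
  tribe-level maximum (465) is exceeded by one two-sample tribe (547).
  Aggregates here are computed from the table as printed.
* Mean aggregates round half-up to the nearest integer, which reproduces
  all three printed means (434, 510, 325) exactly.
* Supercontig-style trimming and long-branch detection are documented
  approximations (see above), interface-compatible with the field's tools
  but not drop-in replacements.
* The consensus model covers A/C/G/T counts only; ambiguity codes and
  indels in pileups are out of scope.
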