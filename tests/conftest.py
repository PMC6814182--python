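import warnings

import dendropy
import numpy as np
import pytest

from hybcurate import SimConfig, generate_dataset
from hybcurate.alignments import LocusAlignment


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 16-sample, 20-locus dataset with a little of everything."""
    cfg = SimConfig(
        n_tribes=2, genera_per_tribe=2, species_per_genus=2,
        samples_per_species=2, n_loci=20, locus_length=200,
        subst_scale=0.3, discordance_rate=0.2, long_branch_rate=0.1,
        dropout_prob=0.05, partial_prob=0.05, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_alignment(locus="L1", **seqs) -> LocusAlignment:
    return LocusAlignment(locus, dict(seqs))


def rooted_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree
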