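"""Shared fixtures, including the two session-scoped synthetic studies.

The heavyweight fixtures run the full pipeline once per session:

* ``support_study`` — 14 taxa on a short-internode reference tree, used by
  the support-vs-size and rate-category analyses.
* ``rate_study`` — 22 taxa, 40 genes all above the 800 nt cutoff, used by
  the rate-recovery analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import cpphylo as cp
from cpphylo.pipeline import run_study
from cpphylo.seeding import child_seed
from cpphylo.simulate import short_internode_tree

warnings.filterwarnings("ignore", message="branch-length optimization hit the round limit")

STUDY_SEED = 2


@pytest.fixture(scope="session")
def support_study():
    """Full desk-scale data-requirement experiment (sizes 1k-10k, 3x30)."""
    tree = short_internode_tree(14, child_seed(STUDY_SEED, 99))
    config = cp.SimConfig(
        n_taxa=14,
        n_genes=60,
        gene_length_min=600,
        gene_length_shape=2.0,
        gene_length_scale=250.0,
        seed=STUDY_SEED,
        tree=tree,
    )
    return run_study(
        config,
        sizes=(1000, 2500, 5000, 10000),
        n_replicates=3,
        n_boot=30,
        category_sizes=(2500,),
    )


@pytest.fixture(scope="session")
def rate_study():
    """22-taxon rate-recovery dataset: 40 genes, every gene >= 800 nt."""
    config = cp.SimConfig(
        n_taxa=22,
        n_genes=40,
        gene_length_min=800,
        gene_length_shape=1.0,
        gene_length_scale=100.0,
        seed=STUDY_SEED + 1,
    )
    return run_study(config, run_curves=False)


@pytest.fixture
def tiny_alignment():
    return cp.Alignment(
        ["a", "b", "c", "d"],
        np.array(
            [
                list("ACGT-RNTAC"),
                list("ACGTTTGTAA"),
                list("ACTTATGTAC"),
                list("ANGTATGAAC"),
            ]
        ),
    )


@pytest.fixture
def quartet_tree():
    return cp.parse_newick("((a:0.1,b:0.23):0.07,c:0.15,d:0.31);")


@pytest.fixture
def gtr_model():
    return cp.SubstModel(
        np.array([1.2, 3.0, 0.8, 1.1, 3.5, 1.0]),
        np.array([0.3, 0.2, 0.2, 0.3]),
        alpha=0.7,
        n_categories=4,
    )
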