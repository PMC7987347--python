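"""Shared fixtures: tiny hand-built tables and small generated datasets."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from wilddom.datasets import CountTable
from wilddom.simulate import LongitudinalBlock, SyntheticSpec, generate, generate_longitudinal

logging.getLogger("wilddom").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 0, 3, 2], [1, 1, 1, 1], [0, 2, 0, 8]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    taxonomy = pd.Series(
        [
            "k__Bacteria;p__A;c__;o__;f__FamX;g__Escherichia;s__coli",
            "k__Bacteria;p__A;c__;o__;f__FamX;g__Streptococcus;s__pneumoniae",
            "k__Bacteria;p__B;c__;o__;f__FamY;g__Streptococcus;s__",
            "k__Bacteria;p__B;c__;o__;f__FamY;g__Harmless;s__thing",
        ],
        index=["t1", "t2", "t3", "t4"],
    )
    return CountTable(counts, taxonomy)


@pytest.fixture
def star_tree():
    # star topology with unit tip branches, written rooted (zero-length
    # internal edges) because UniFrac requires a rooted tree
    return TreeNode.read(["((t1:1,t2:1):0,(t3:1,t4:1):0);"])


def random_bifurcating_tree(taxa: list[str], rng: np.random.Generator) -> TreeNode:
    """Independent random-tree builder for oracle tests."""
    nodes = [f"{t}:{rng.exponential(0.5):.6f}" for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(0.5):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode.read([nodes[0].rsplit(":", 1)[0] + ";"])


# Small-but-structured generated datasets, reused across test modules.
SMALL_SURVEY_SPEC = SyntheticSpec(
    n_dyads=4,
    samples_per_species=6,
    n_taxa=60,
    n_pathogen_taxa=8,
    depth_mean=20_000.0,
    depth_sd=8_000.0,
    include_primates=True,
    n_per_population=5,
    seed=11,
)


@pytest.fixture(scope="session")
def small_survey():
    return generate(SMALL_SURVEY_SPEC)


@pytest.fixture(scope="session")
def small_diet_experiment():
    spec = SyntheticSpec(
        n_taxa=60,
        n_pathogen_taxa=8,
        depth_mean=20_000.0,
        depth_sd=8_000.0,
        seed=13,
        longitudinal=LongitudinalBlock(kind="diet", n_per_group=8, timepoints=(0, 14, 28)),
    )
    return generate_longitudinal(spec)


@pytest.fixture(scope="session")
def small_colonization_experiment():
    spec = SyntheticSpec(
        n_taxa=60,
        n_pathogen_taxa=8,
        depth_mean=20_000.0,
        depth_sd=8_000.0,
        seed=17,
        longitudinal=LongitudinalBlock(kind="colonization", n_per_group=8, timepoints=(0, 2, 8)),
    )
    return generate_longitudinal(spec)
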