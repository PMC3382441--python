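"""Shared fixtures: hand-worked small trees and seeded random instances."""

from __future__ import annotations

import random

import pytest

from dlrecon import CostWeights, SpeciesTree, UnrootedGeneTree
from dlrecon.search import random_rooted_topology
from dlrecon.simulate import _species_labels


@pytest.fixture
def s_quartet() -> SpeciesTree:
    """Balanced four-species tree ((a,b),(c,d))."""
    return SpeciesTree.from_newick("((a,b),(c,d));")


@pytest.fixture
def s_caterpillar() -> SpeciesTree:
    """Three-species tree (a,(b,c)) with internal nodes bc and abc."""
    return SpeciesTree.from_newick("(a,(b,c));")


@pytest.fixture
def g_congruent(s_quartet) -> UnrootedGeneTree:
    """Quartet gene tree ab|cd, congruent with the quartet species tree."""
    return UnrootedGeneTree.from_newick("((a,b),(c,d));")


@pytest.fixture
def g_displaced(s_quartet) -> UnrootedGeneTree:
    """Quartet gene tree bc|ad: one NNI away from congruence."""
    return UnrootedGeneTree.from_newick("((b,c),(a,d));")


def random_species_nested(rng: random.Random, n_taxa: int):
    return random_rooted_topology(_species_labels(n_taxa), rng)


def random_species(rng: random.Random, n_taxa: int) -> SpeciesTree:
    return SpeciesTree.from_nested(random_species_nested(rng, n_taxa))


def random_gene(rng: random.Random, species_labels, n_leaves: int) -> UnrootedGeneTree:
    """Random unrooted gene tree whose leaves draw labels (with repetition)
    from the species set."""
    labs = [rng.choice(species_labels) for _ in range(n_leaves)]
    return UnrootedGeneTree.from_nested(random_rooted_topology(labs, rng))


def random_instance(rng: random.Random, max_taxa: int = 12,
                    min_leaves: int = 4, max_leaves: int = 20):
    """A random (gene tree, species tree) pair for oracle comparisons."""
    s = random_species(rng, rng.randint(2, max_taxa))
    g = random_gene(rng, s.labels, rng.randint(min_leaves, max_leaves))
    return g, s


WEIGHT_CHOICES = [CostWeights(1, 1), CostWeights(1, 2), CostWeights(3, 1),
                  CostWeights(0.5, 0.5)]
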