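"""Synthetic data: duplication-loss gene trees with weak-edge NNI errors.

The generator emulates the statistical setting the correction method
assumes: gene families evolve inside a known species tree by a constant-rate
birth-death process (duplications copy a gene lineage, losses kill it), so
the *true* gene trees reconcile with the species tree at a small cost; the
*observed* trees differ from the truth by a few NNI rearrangements
concentrated on short ("weak") branches, mimicking poorly supported splits
in ML gene trees.

Branch lengths are decorative but structured: a log-normal body with a
separate short-length regime assigned to a random fraction of internal
edges, so that a weakness threshold omega cleanly separates the two regimes
and error injection has well-defined targets.  Everything is driven by a
``random.Random`` instance (or an integer seed) and is bit-reproducible.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Union

from .nni import apply_nni_raw, make_frame
from .search import random_rooted_topology
from .trees import RootedGeneTree, SpeciesTree, TreeError, UnrootedGeneTree

__all__ = ["SimulationConfig", "random_species_tree", "evolve_gene_tree",
           "inject_errors", "simulate_dataset", "DatasetRecord"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Rates are per lineage per unit time; every species-tree branch spans
    ``branch_length`` time units.  ``median_length``/``length_sigma``
    parameterize the log-normal branch-length body of the emitted gene
    trees; ``short_fraction`` of the internal edges instead draw from the
    uniform short regime [short_min, short_max).  ``error_threshold`` is the
    length below which an internal edge is an error-injection target (set
    between ``short_max`` and the log-normal bulk so the regimes separate).
    """

    n_taxa: int = 8
    dup_rate: float = 0.1
    loss_rate: float = 0.1
    branch_length: float = 1.0
    median_length: float = 0.4
    length_sigma: float = 0.5
    short_fraction: float = 0.25
    short_min: float = 0.001
    short_max: float = 0.02
    n_errors: int = 0
    error_threshold: float = 0.05
    min_leaves: int = 2
    max_retries: int = 1000

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_errors < 0:
            raise ValueError("n_errors must be non-negative")


def _rng(seed_or_rng: Union[int, random.Random]) -> random.Random:
    if isinstance(seed_or_rng, random.Random):
        return seed_or_rng
    return random.Random(seed_or_rng)


def _species_labels(n: int) -> list[str]:
    if n <= 26:
        return [chr(ord("a") + i) for i in range(n)]
    return [f"s{i:03d}" for i in range(n)]


def random_species_tree(n_taxa: int,
                        seed: Union[int, random.Random] = 0) -> SpeciesTree:
    """Uniform random rooted binary species tree with distinct labels."""
    if n_taxa < 2:
        raise TreeError("need at least 2 taxa")
    rng = _rng(seed)
    return SpeciesTree.from_nested(
        random_rooted_topology(_species_labels(n_taxa), rng))


def _evolve_from(s: SpeciesTree, v: int, t_remaining: float,
                 rng: random.Random, cfg: SimulationConfig):
    """One gene lineage evolving along the species branch ending at v with
    ``t_remaining`` time left; returns a nested label tuple or None (lost).
    Lineages surviving to a speciation copy into both child branches; a
    single surviving copy passes through silently (that is a loss on the
    other side, recovered later by reconciliation)."""
    total = cfg.dup_rate + cfg.loss_rate
    while True:
        wait = rng.expovariate(total) if total > 0 else math.inf
        if wait < t_remaining:
            t_remaining -= wait
            if rng.random() < cfg.dup_rate / total:
                a = _evolve_from(s, v, t_remaining, rng, cfg)
                b = _evolve_from(s, v, t_remaining, rng, cfg)
                if a is not None and b is not None:
                    return (a, b)
                return a if a is not None else b
            return None  # loss
        break
    if s.is_leaf(v):
        return s.leaf_label[v]
    c1, c2 = s.children[v]
    a = _evolve_from(s, c1, cfg.branch_length, rng, cfg)
    b = _evolve_from(s, c2, cfg.branch_length, rng, cfg)
    if a is not None and b is not None:
        return (a, b)
    return a if a is not None else b


def _assign_lengths(g: UnrootedGeneTree, rng: random.Random,
                    cfg: SimulationConfig) -> None:
    mu = math.log(cfg.median_length)
    for e in g.edges:
        internal = not g.is_leaf(e.u) and not g.is_leaf(e.v)
        if internal and rng.random() < cfg.short_fraction:
            e.length = rng.uniform(cfg.short_min, cfg.short_max)
        else:
            e.length = rng.lognormvariate(mu, cfg.length_sigma)


def evolve_gene_tree(s: SpeciesTree, cfg: SimulationConfig = SimulationConfig(),
                     seed: Union[int, random.Random] = 0
                     ) -> tuple[RootedGeneTree, UnrootedGeneTree]:
    """A birth-death gene family in s: returns (true rooted tree, its
    unrooted form with branch lengths).  Families losing all lineages (or
    ending below ``min_leaves``) are resampled up to ``max_retries``."""
    rng = _rng(seed)
    for _ in range(cfg.max_retries):
        c1, c2 = s.children[s.root]
        a = _evolve_from(s, c1, cfg.branch_length, rng, cfg)
        b = _evolve_from(s, c2, cfg.branch_length, rng, cfg)
        nested = (a, b) if (a is not None and b is not None) else (a or b)
        if nested is None or isinstance(nested, str):
            continue
        if len(_flat(nested)) < max(cfg.min_leaves, 2):
            continue
        rooted = RootedGeneTree.from_nested(nested)
        unrooted = UnrootedGeneTree.from_nested(nested)
        _assign_lengths(unrooted, rng, cfg)
        return rooted, unrooted
    raise TreeError("all gene lineages were repeatedly lost; "
                    "raise the duplication rate or lower the loss rate")


def _flat(nested) -> list[str]:
    if isinstance(nested, str):
        return [nested]
    return _flat(nested[0]) + _flat(nested[1])


def inject_errors(g: UnrootedGeneTree, cfg: SimulationConfig = SimulationConfig(),
                  seed: Union[int, random.Random] = 0
                  ) -> tuple[UnrootedGeneTree, list[tuple[int, int]]]:
    """Corrupt a copy of g with ``cfg.n_errors`` random NNIs centered on
    internal edges shorter than ``cfg.error_threshold``; returns the copy
    and the applied (edge id, variant) moves (so tests can verify the truth
    is reachable by reversing them)."""
    rng = _rng(seed)
    corrupted = g.copy()
    moves: list[tuple[int, int]] = []
    if cfg.n_errors == 0:
        return corrupted, moves
    eligible = [e for e in corrupted.internal_edges()
                if e.length is not None and e.length < cfg.error_threshold]
    if not eligible:
        raise TreeError("no internal edge below the error threshold")
    for _ in range(cfg.n_errors):
        e = eligible[rng.randrange(len(eligible))]
        variant = rng.randrange(2)
        apply_nni_raw(corrupted, make_frame(corrupted, e, variant))
        moves.append((e.id, variant))
    return corrupted, moves


@dataclass
class DatasetRecord:
    true_rooted: RootedGeneTree
    true_unrooted: UnrootedGeneTree
    observed: UnrootedGeneTree
    moves: list[tuple[int, int]]


def simulate_dataset(s: SpeciesTree, n_trees: int,
                     cfg: SimulationConfig = SimulationConfig(),
                     seed: Union[int, random.Random] = 0,
                     require_weak_edge: bool = False) -> list[DatasetRecord]:
    """A seeded collection of gene families; when errors are requested (or
    ``require_weak_edge``), families are resampled until they have at least
    4 leaves and one short internal edge to corrupt."""
    rng = _rng(seed)
    need_edge = require_weak_edge or cfg.n_errors > 0
    out = []
    for _ in range(n_trees):
        for _attempt in range(cfg.max_retries):
            rooted, unrooted = evolve_gene_tree(s, cfg, rng)
            if not need_edge:
                break
            if any(e.length is not None and e.length < cfg.error_threshold
                   for e in unrooted.internal_edges()):
                break
        else:
            raise TreeError("could not generate a family with a weak internal edge")
        observed, moves = inject_errors(unrooted, cfg, rng)
        out.append(DatasetRecord(rooted, unrooted, observed, moves))
    return out
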