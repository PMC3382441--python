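"""Error correction: weak edges, the k-NNI neighborhood minimum, kNNIC
aggregation and the mu curation filter."""

import math
import random

import pytest

from dlrecon import (CorrectionConfig, CostWeights, UnrootedGeneTree,
                     brute_force_optimal, corrected_cost,
                     corrected_cost_value, filter_by_mu, knnic_total,
                     optimal_edges, weak_edges)
from dlrecon.nni import apply_nni_raw, make_frame
from conftest import random_gene, random_instance, random_species


def _quartet_with_lengths() -> UnrootedGeneTree:
    return UnrootedGeneTree.from_newick(
        "((a:1,b:2):0.05,(c:1,d:1):0.06);")  # center merges to 0.11


class TestWeakEdges:
    def test_strictness_at_zero(self):
        assert weak_edges(_quartet_with_lengths(), 0.0) == []

    def test_center_only(self):
        g = _quartet_with_lengths()
        assert [e.id for e in weak_edges(g, 0.2)] == \
            [e.id for e in g.internal_edges()]

    def test_infinite_threshold_catches_all(self):
        g = _quartet_with_lengths()
        assert len(weak_edges(g, math.inf)) == len(g.edges)

    def test_unmeasured_edges_never_weak(self):
        g = UnrootedGeneTree.from_newick("((a,b),(c,d));")
        assert weak_edges(g, math.inf) == []


class TestCorrectedCost:
    def test_congruent_needs_no_correction(self, s_quartet, g_congruent):
        r = corrected_cost(g_congruent, s_quartet, CorrectionConfig(k=0))
        assert r.cost == 0.0 and not r.errors_found

    def test_displaced_quartet_corrected_at_k1(self, s_quartet, g_displaced):
        r0 = corrected_cost(g_displaced, s_quartet, CorrectionConfig(k=0))
        assert r0.cost == 5.0 and not r0.errors_found
        r1 = corrected_cost(g_displaced, s_quartet, CorrectionConfig(k=1))
        assert r1.cost == 0.0 and r1.errors_found
        assert len(r1.moves) == 1
        assert r1.corrected_key == UnrootedGeneTree.from_newick(
            "((a,b),(c,d));").topology_key()
        assert r1.cost_before == 5.0

    def test_k2_no_further_improvement(self, s_quartet, g_displaced):
        r2 = corrected_cost(g_displaced, s_quartet, CorrectionConfig(k=2))
        assert r2.cost == 0.0
        assert len(r2.moves) == 1  # shorter sequence preferred on ties

    def test_one_nni_neighborhood_costs(self, s_quartet, g_displaced):
        """The 1-NNI neighborhood of bc|ad is {ab|cd, ac|bd}: costs 0 and 5."""
        costs = set()
        for variant in (0, 1):
            g = g_displaced.copy()
            (e,) = g.internal_edges()
            apply_nni_raw(g, make_frame(g, e, variant))
            costs.add(brute_force_optimal(g, s_quartet).sigma)
        assert costs == {0.0, 5.0}

    def test_k0_reduces_to_plain_unrooted_reconciliation(self, s_quartet,
                                                         g_displaced):
        st = optimal_edges(g_displaced, s_quartet)
        r = corrected_cost(g_displaced, s_quartet, CorrectionConfig(k=0))
        assert r.cost == st.sigma
        assert r.min_size == len(st.minset)
        assert r.optimal_bipartition == g_displaced.bipartition(
            st.canonical_min_edge())

    def test_omega_zero_means_no_corrections(self, s_quartet):
        g = _quartet_with_lengths()
        # relabel to the displaced quartet so a correction would help
        g2 = UnrootedGeneTree.from_newick("((b:1,c:2):0.11,(a:1,d:1):0.0);")
        r = corrected_cost(g2, s_quartet, CorrectionConfig(k=2, omega=0.0))
        assert r.cost == 5.0 and not r.errors_found and r.moves == []

    def test_omega_restricts_centers(self, s_quartet):
        # center long, so the weak-edge variant cannot fix the topology
        g = UnrootedGeneTree.from_newick("((b:0.01,c:2):5.0,(a:1,d:1):5.0);")
        r = corrected_cost(g, s_quartet, CorrectionConfig(k=1, omega=0.1))
        assert r.cost == 5.0
        r = corrected_cost(g, s_quartet, CorrectionConfig(k=1, omega=10.5))
        assert r.cost == 0.0  # merged center length 5+5=10 is now weak

    def test_unmeasured_tree_with_omega_does_nothing(self, s_quartet,
                                                     g_displaced):
        r = corrected_cost(g_displaced, s_quartet,
                           CorrectionConfig(k=1, omega=0.5))
        assert r.cost == 5.0 and r.moves == []

    @pytest.mark.parametrize("seed", range(12))
    def test_monotone_in_k_and_neighborhood_oracle(self, seed):
        """sigma_{k+1} <= sigma_k, and for k <= 2 the DFS minimum equals
        brute-force minimization over the explicitly materialized
        neighborhood (breadth-first over tree copies)."""
        rng = random.Random(3000 + seed)
        g, s = random_instance(rng, max_taxa=8, min_leaves=4, max_leaves=12)
        w = CostWeights(1, 1)
        sigmas = [corrected_cost_value(g, s, CorrectionConfig(k=k, weights=w))
                  for k in range(3)]
        assert sigmas[1] <= sigmas[0] and sigmas[2] <= sigmas[1]

        level = {g.topology_key(): g}
        seen = dict(level)
        best = brute_force_optimal(g, s, w).sigma
        for _depth in range(2):
            nxt = {}
            for t in level.values():
                for e in t.internal_edges():
                    for variant in (0, 1):
                        t2 = t.copy()
                        e2 = t2.edges[e.id]
                        apply_nni_raw(t2, make_frame(t2, e2, variant))
                        key = t2.topology_key()
                        if key not in seen:
                            seen[key] = t2
                            nxt[key] = t2
                            best = min(best,
                                       brute_force_optimal(t2, s, w).sigma)
            level = nxt
        assert sigmas[2] == best

    @pytest.mark.parametrize("seed", range(6))
    def test_error_injection_recovery_bound(self, seed):
        """A tree corrupted by e <= k eligible NNIs corrects to at most the
        uncorrupted tree's uncorrected cost."""
        rng = random.Random(4000 + seed)
        s = random_species(rng, 8)
        g = random_gene(rng, s.labels, 10)
        for e in g.edges:
            e.length = 1.0
        base = corrected_cost_value(g, s, CorrectionConfig(k=0))
        corrupted = g.copy()
        for _ in range(2):
            edges = corrupted.internal_edges()
            e = edges[rng.randrange(len(edges))]
            apply_nni_raw(corrupted, make_frame(corrupted, e, rng.randrange(2)))
        assert corrected_cost_value(corrupted, s,
                                    CorrectionConfig(k=2)) <= base


class TestAggregation:
    def test_knnic_worked_collection(self, s_quartet, g_congruent, g_displaced):
        res = knnic_total([g_congruent, g_displaced], s_quartet,
                          CorrectionConfig(k=1))
        assert res.total == 0.0
        assert [r.errors_found for r in res.per_tree] == [False, True]

    def test_knnic_empty_and_single(self, s_quartet, g_displaced):
        assert knnic_total([], s_quartet, CorrectionConfig()).total == 0.0
        assert knnic_total([g_displaced], s_quartet,
                           CorrectionConfig(k=0)).total == 5.0

    def test_unmappable_tree_reports_identity(self, s_quartet):
        g = UnrootedGeneTree.from_newick("((a,b),(z,d));")
        with pytest.raises(Exception, match="#0"):
            knnic_total([g], s_quartet, CorrectionConfig())


class TestMuFilter:
    def test_no_weak_edges_always_accepted(self, g_congruent):
        acc, rej = filter_by_mu([g_congruent], omega=1.0, mu=1)
        assert len(acc) == 1 and not rej

    def test_rejection_over_threshold(self):
        g = UnrootedGeneTree.from_newick(
            "((a:0.01,b:0.01):1,(c:0.01,d:1):1);")  # 3 weak edges at 0.1
        acc, rej = filter_by_mu([g], omega=0.1, mu=2)
        assert not acc and len(rej) == 1
        acc, rej = filter_by_mu([g], omega=0.1, mu=3)
        assert len(acc) == 1

    def test_mu_sweep_monotone(self):
        rng = random.Random(5)
        s = random_species(rng, 6)
        trees = []
        for _ in range(50):
            g = random_gene(rng, s.labels, 8)
            for e in g.edges:
                e.length = rng.lognormvariate(-1.5, 1.0)
            trees.append(g)
        sizes = [len(filter_by_mu(trees, omega=0.2, mu=mu)[0])
                 for mu in range(1, 10)]
        assert sizes == sorted(sizes)
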