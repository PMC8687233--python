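import itertools
import math

import networkx as nx
import numpy as np
import pytest

from conftest import random_dag, small_dataset
from wspia.engine import (
    combine_pg,
    fdr_adjust,
    p_nde_hypergeometric,
    p_pert_bootstrap,
    pathway_seed,
    perturbation_factors,
    results_frame,
    run_analysis,
)
from wspia.pathways import PathwayGraph
from wspia.weights import WeightMatrix


def forward_propagation(graph, weights, delta_e):
    """Independent oracle: accumulate perturbation factors in topological order."""
    pf = {}
    nds = graph.nds
    for g in nx.topological_sort(graph.to_networkx()):
        total = delta_e.get(g, 0.0)
        for src, tgt, beta in graph.edges:
            if tgt == g:
                total += beta * weights.weights[(src, tgt)] * pf[src] / nds[src]
        pf[g] = total
    return pf


def enumeration_p_nde(m, t, h, r):
    """Independent oracle: exhaustive enumeration of all C(m, h) DEG draws."""
    hits = total = 0
    for draw in itertools.combinations(range(m), h):
        total += 1
        if sum(1 for x in draw if x < t) >= r:
            hits += 1
    return hits / total


class TestPerturbationFactors:
    def test_isolated_gene_accumulates_nothing(self):
        g = PathwayGraph("iso", "iso", ["A"], [])
        res = perturbation_factors(g, WeightMatrix.unit(g), {"A": 2.0})
        assert res.pf["A"] == 2.0
        assert res.acc["A"] == 0.0
        assert res.t_a == 0.0

    @pytest.mark.parametrize(
        "beta,w,expected_pf,expected_ta",
        [(+1, 1.0, (1.0, 1.0), 1.0), (+1, 0.5, (1.0, 0.5), 0.5), (-1, 1.0, (1.0, -1.0), -1.0)],
    )
    def test_two_gene_chain_hand_computed(self, beta, w, expected_pf, expected_ta):
        g = PathwayGraph("pair", "pair", ["g1", "g2"], [("g1", "g2", beta)])
        wm = WeightMatrix("pearson", {("g1", "g2"): w})
        res = perturbation_factors(g, wm, {"g1": 1.0, "g2": 0.0})
        assert res.pf["g1"] == pytest.approx(expected_pf[0], abs=1e-12)
        assert res.pf["g2"] == pytest.approx(expected_pf[1], abs=1e-12)
        assert res.t_a == pytest.approx(expected_ta, abs=1e-12)

    def test_direct_solve_matches_topological_oracle_on_random_dags(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            graph = random_dag(rng, rng.integers(3, 13))
            weights = WeightMatrix(
                "pearson",
                {(s, t): float(rng.uniform(-1, 1)) for s, t, _ in graph.edges},
            )
            delta_e = {g: float(rng.normal()) for g in graph.genes}
            res = perturbation_factors(graph, weights, delta_e)
            assert res.solver_status == "solved"
            oracle = forward_propagation(graph, weights, delta_e)
            for g in graph.genes:
                assert res.pf[g] == pytest.approx(oracle[g], abs=1e-10)
            assert res.t_a == pytest.approx(sum(res.acc.values()), abs=1e-10)

    def test_fixed_point_residual_within_tolerance(self):
        rng = np.random.default_rng(4)
        graph = random_dag(rng, 8)
        wm = WeightMatrix.unit(graph)
        delta_e = {g: float(rng.normal()) for g in graph.genes}
        res = perturbation_factors(graph, wm, delta_e)
        from wspia.engine import _propagation_matrix

        m = _propagation_matrix(graph, wm)
        pf = np.array([res.pf[g] for g in graph.genes])
        de = np.array([delta_e[g] for g in graph.genes])
        assert np.abs(pf - (de + m @ pf)).max() < 1e-8

    def test_singular_cycle_reported(self):
        # A -> B -> A with unit weights: (I - M) has a zero eigenvalue
        g = PathwayGraph("cyc", "cyc", ["A", "B"], [("A", "B", 1), ("B", "A", 1)])
        res = perturbation_factors(g, WeightMatrix.unit(g), {"A": 1.0})
        assert res.solver_status == "singular"


class TestBootstrap:
    def test_edgeless_graph_gives_p_one(self):
        g = PathwayGraph("flat", "flat", ["A", "B", "C"], [])
        p, t_obs = p_pert_bootstrap(
            g, WeightMatrix.unit(g), 1, [1.0], 500, 0, delta_e={"A": 1.0}
        )
        assert t_obs == 0.0
        assert p == 1.0

    def test_chain_single_deg_matches_exact_enumeration(self, chain_graph):
        # exact null: one unit fold-change on each of the 4 chain genes in turn
        wm = WeightMatrix.unit(chain_graph)
        exact_null = []
        for g in chain_graph.genes:
            res = perturbation_factors(chain_graph, wm, {g: 1.0})
            exact_null.append(res.t_a)
        assert sorted(exact_null) == [0.0, 1.0, 2.0, 3.0]
        t_obs = 3.0  # DE gene at the head
        med = float(np.median(exact_null))
        p_exact = np.mean([abs(t - med) >= abs(t_obs - med) for t in exact_null])
        p_boot, t_got = p_pert_bootstrap(
            chain_graph, wm, 1, [1.0], 2000, 0, delta_e={"g1": 1.0}
        )
        assert t_got == pytest.approx(3.0, abs=1e-10)
        assert abs(p_boot - p_exact) < 0.02

    def test_null_has_two_values_when_pool_constant(self, two_gene_chain):
        wm = WeightMatrix.unit(two_gene_chain)
        p, _ = p_pert_bootstrap(
            two_gene_chain, wm, 1, [1.0], 1000, 5, delta_e={"g1": 1.0}
        )
        assert 0 < p <= 1

    def test_linearity_identity_against_full_solve(self):
        # the vectorised null relies on t_A being linear in the fold-changes
        rng = np.random.default_rng(23)
        graph = random_dag(rng, 9)
        wm = WeightMatrix(
            "pearson", {(s, t): float(rng.uniform(-1, 1)) for s, t, _ in graph.edges}
        )
        from wspia.engine import _propagation_matrix

        a_t = (np.eye(graph.n_genes) - _propagation_matrix(graph, wm)).T
        v = np.linalg.solve(a_t, np.ones(graph.n_genes)) - 1.0
        for _ in range(20):
            delta_e = {g: float(rng.normal()) for g in graph.genes}
            res = perturbation_factors(graph, wm, delta_e)
            de_vec = np.array([delta_e[g] for g in graph.genes])
            assert v @ de_vec == pytest.approx(res.t_a, abs=1e-10)

    def test_requires_enough_pathway_genes(self, two_gene_chain):
        with pytest.raises(ValueError, match="exceed"):
            p_pert_bootstrap(
                two_gene_chain, WeightMatrix.unit(two_gene_chain), 3,
                [1.0, 2.0, 3.0], 100, 0, t_a_observed=0.0,
            )


class TestHypergeometric:
    def test_r_zero_is_one(self):
        assert p_nde_hypergeometric(10, 5, 4, 0) == 1.0

    def test_hand_computed_case(self):
        assert p_nde_hypergeometric(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    def test_matches_enumeration_oracle_small_grid(self):
        for m in (5, 8):
            for t in range(1, m + 1):
                for h in range(1, m + 1):
                    for r in range(0, min(t, h) + 1):
                        assert p_nde_hypergeometric(m, t, h, r) == pytest.approx(
                            enumeration_p_nde(m, t, h, r), abs=1e-12
                        )

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            p_nde_hypergeometric(10, 5, 4, 5)
        with pytest.raises(ValueError):
            p_nde_hypergeometric(10, 11, 4, 2)


class TestCombineAndFdr:
    def test_perfect_inputs_combine_to_one(self):
        assert combine_pg(1.0, 1.0) == 1.0

    def test_hand_computed_combination(self):
        assert combine_pg(0.1, 0.1) == pytest.approx(0.01 * (1 + math.log(100)), abs=1e-12)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            combine_pg(0.0, 0.5)

    def test_uniform_inputs_give_uniform_output(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        u, v = rng.uniform(size=2000), rng.uniform(size=2000)
        out = [combine_pg(a, b) for a, b in zip(u, v)]
        assert stats.kstest(out, "uniform").pvalue > 0.01

    def test_bh_hand_computation(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bh_single_and_ties(self):
        assert fdr_adjust([0.2]).tolist() == [0.2]
        assert np.allclose(fdr_adjust([0.04, 0.04, 0.04]), [0.04, 0.04, 0.04])

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        adj = fdr_adjust(p)
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestRunAnalysis:
    def _fixture(self, seed=0):
        from wspia.synthetic import FixtureSpec, make_expression, make_pathways

        spec = FixtureSpec(
            n_genes=40, n_pathways=2, genes_per_pathway=8, edge_density=0.3,
            n_control=6, n_test=6, effect_size=2.0, noise_sd=0.5,
            edge_correlation=0.5, de_fraction=0.05, seed=seed,
        )
        pathways = make_pathways(spec)
        data, _ = make_expression(spec, pathways, perturbed_pathway_index=0)
        return data, pathways

    def test_weighted_modes_with_unit_override_reduce_to_spia(self):
        data, pathways = self._fixture(seed=31)
        base = run_analysis(data, pathways, method="spia", iterations=300, seed=9)
        for method in ("pspia", "mspia"):
            forced = run_analysis(
                data, pathways, method=method, iterations=300, seed=9,
                force_unit_weights=True,
            )
            for a, b in zip(base, forced):
                assert (a.p_nde, a.t_a, a.p_pert, a.p_g) == (b.p_nde, b.t_a, b.p_pert, b.p_g)

    def test_perturbed_pathway_ranks_first(self):
        data, pathways = self._fixture(seed=13)
        results = run_analysis(data, pathways, method="spia", iterations=500, seed=1)
        df = results_frame(results)
        assert df.iloc[0]["pathway_id"] == "SYN000"

    def test_zero_degs_skips_all_pathways(self):
        data = small_dataset(seed=6, n_genes=10, n_per_group=4)
        graph = PathwayGraph("p", "p", ["g1", "g2"], [("g1", "g2", 1)])
        results = run_analysis(data, [graph], method="spia", alpha=1e-12, iterations=50, seed=0)
        assert all(r.status == "skipped_no_de" for r in results)
        assert all(math.isnan(r.p_g) for r in results)

    def test_per_pathway_seed_stable_under_pathway_set_changes(self):
        data, pathways = self._fixture(seed=7)
        full = run_analysis(data, pathways, method="spia", iterations=200, seed=4)
        only_first = run_analysis(data, pathways[:1], method="spia", iterations=200, seed=4)
        assert full[0].p_pert == only_first[0].p_pert

    def test_probability_invariants(self):
        data, pathways = self._fixture(seed=19)
        for r in run_analysis(data, pathways, method="mspia", iterations=200, seed=2):
            if r.status != "ok":
                continue
            assert 0 < r.p_nde <= 1 and 0 < r.p_pert <= 1
            assert r.c == pytest.approx(r.p_nde * r.p_pert, abs=1e-12)
            assert r.p_g == pytest.approx(combine_pg(r.p_nde, r.p_pert), abs=1e-12)

    def test_pathway_seed_distinct_and_stable(self):
        a = np.random.default_rng(pathway_seed(1, "P1")).random()
        b = np.random.default_rng(pathway_seed(1, "P2")).random()
        a2 = np.random.default_rng(pathway_seed(1, "P1")).random()
        assert a == a2 and a != b
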