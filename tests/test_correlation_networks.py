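"""Spearman/BH primitives against independent oracles; network criteria."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats
from statsmodels.stats.multitest import multipletests

from syncom_core import (
    AnalysisConfig,
    SampleMeta,
    VolatileTable,
    bh_fdr,
    build_cooccurrence,
    flavor_associated_taxa,
    hub_taxa,
    normalize_relative,
    spearman,
)
from syncom_core.correlation_networks import CorrelationNetwork, CorrelationResult

from conftest import make_table


def oracle_spearman_exact(x, y):
    """Exhaustive-permutation Spearman oracle (independent code path)."""
    rx = scipy_stats.rankdata(x)
    ry = scipy_stats.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        count += abs(r) >= abs(rho) - 1e-12
        total += 1
    return rho, count / total


def oracle_bh(pvalues):
    """Literal step-up definition, quadratic loop."""
    p = np.asarray(pvalues, float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        q[i] = min(
            min(m * pj / (np.sum(p <= pj)) for pj in p if pj >= p[i]), 1.0
        )
    return q


class TestSpearman:
    def test_identity_and_reversal(self, rng):
        x = rng.normal(size=10)
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)
        xs = np.sort(x)
        assert spearman(xs, xs[::-1])[0] == pytest.approx(-1.0)

    def test_exact_permutation_with_ties(self):
        # length 6 with one tie pair: p must equal the proportion over
        # all 720 permutations with |rho| >= observed
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p = spearman(x, y)
        o_rho, o_p = oracle_spearman_exact(x, y)
        assert rho == pytest.approx(o_rho)
        assert p == pytest.approx(o_p)

    def test_matches_permutation_oracle_small_n(self, rng):
        for _ in range(20):
            n = rng.integers(4, 8)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p = spearman(x, y)
            o_rho, o_p = oracle_spearman_exact(x, y)
            assert rho == pytest.approx(o_rho, abs=1e-12)
            assert p == pytest.approx(o_p, abs=1e-12)

    def test_matches_scipy_large_n(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=25), rng.normal(size=25)
            rho, p = spearman(x, y)
            s = scipy_stats.spearmanr(x, y)
            assert rho == pytest.approx(s.statistic, abs=1e-12)
            assert p == pytest.approx(s.pvalue, abs=1e-9)

    def test_constant_vector_flagged_not_raised(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [3, 2, 1])


class TestBH:
    def test_all_zero(self):
        assert np.array_equal(bh_fdr([0, 0, 0]), [0, 0, 0])

    def test_hand_evaluated_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_statsmodels_and_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(2, 40))
            q = bh_fdr(p)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(q, q_sm, atol=1e-12)
            assert np.allclose(q, oracle_bh(p), atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariance_and_q_ge_p(self, pvals, rnd):
        p = np.array(pvals)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q_perm = bh_fdr(p[perm])
        assert np.allclose(q_perm, q[perm], atol=1e-12)


class TestCooccurrence:
    def test_perfectly_correlated_pair_is_edge(self, rng):
        base = rng.uniform(1, 10, size=12)
        vals = np.vstack([base, 2 * base] + [rng.uniform(1, 10, size=12) for _ in range(4)])
        net = build_cooccurrence(normalize_relative(make_table(vals)))
        assert net.has_edge("taxon_0", "taxon_1")

    def test_requires_normalized(self, rng):
        with pytest.raises(ValueError, match="normalized"):
            build_cooccurrence(make_table(rng.uniform(1, 5, (4, 6))))

    def test_edge_sets_shrink_with_rising_r_threshold(self, default_dataset):
        abundance = default_dataset[0]
        edges = {}
        for r in (0.5, 0.6, 0.8):
            cfg = AnalysisConfig(edge_r_threshold=r)
            net = build_cooccurrence(abundance, cfg)
            edges[r] = {frozenset((e.item_a, e.item_b)) for e in net.edges}
        assert edges[0.8] <= edges[0.6] <= edges[0.5]

    def test_no_self_loops_and_symmetry(self, default_dataset):
        net = build_cooccurrence(default_dataset[0])
        for e in net.edges:
            assert e.item_a != e.item_b
        g = net.to_networkx()
        assert not any(g.has_edge(n, n) for n in g)

    def test_planted_clique_edges_present(self):
        from syncom_core import GeneratorConfig, generate_dataset

        found = 0
        for seed in range(5):
            abundance, _, _, truth = generate_dataset(GeneratorConfig(seed=seed))
            net = build_cooccurrence(abundance)
            clique = sorted(truth.clique_memberships[0])[:3]
            pairs = list(itertools.combinations(clique, 2))
            found += all(net.has_edge(a, b) for a, b in pairs)
        assert found >= 3  # majority of seeds

    def test_display_kind_stricter(self, default_dataset):
        abundance = default_dataset[0]
        analysis = build_cooccurrence(abundance, kind="analysis")
        display = build_cooccurrence(abundance, kind="display")
        d_edges = {frozenset((e.item_a, e.item_b)) for e in display.edges}
        for e in display.edges:
            assert abs(e.rho) > 0.8 and e.p < 0.01
        assert len(d_edges) <= len(analysis.edges)


class TestHubs:
    def _net(self, degrees):
        nodes = [f"n{i}" for i in range(len(degrees))]
        edges = []
        for i, d in enumerate(degrees):
            for j in range(d):
                edges.append(
                    CorrelationResult(nodes[i], f"n{i}_stub{j}", 0.9, 1e-6, 1e-5)
                )
        all_nodes = nodes + [e.item_b for e in edges]
        return CorrelationNetwork(kind="analysis", nodes=all_nodes, edges=edges)

    def test_strict_threshold_boundary(self):
        net = self._net([10, 9])
        hubs = hub_taxa(net)
        assert "n0" in hubs and "n1" not in hubs

    def test_matches_brute_force_recount(self, rng):
        import networkx as nx

        g = nx.gnp_random_graph(30, 0.3, seed=7)
        nodes = [f"t{i}" for i in range(30)]
        edges = [
            CorrelationResult(nodes[a], nodes[b], 0.9, 1e-6, 1e-5) for a, b in g.edges
        ]
        net = CorrelationNetwork(kind="analysis", nodes=nodes, edges=edges)
        hubs = hub_taxa(net)
        brute = {nodes[i] for i in range(30) if g.degree[i] > 9}
        assert hubs == brute

    def test_wrong_kind_rejected(self):
        net = CorrelationNetwork(kind="display", nodes=["a"])
        with pytest.raises(ValueError):
            hub_taxa(net)


class TestFlavorAssociation:
    def _tables(self, n_links, rng, n_samples=14):
        taxon = rng.uniform(1, 5, size=n_samples)
        others = rng.uniform(1, 5, size=(5, n_samples))
        abundance = normalize_relative(make_table(np.vstack([taxon, others])))
        ra = abundance.values[0]
        compounds, values = [], []
        for i in range(10):
            if i < n_links:
                values.append(100 * (1 + 2 * ra / ra.mean()) + rng.normal(0, 2, n_samples))
            else:
                values.append(rng.uniform(50, 150, size=n_samples))
            compounds.append((f"c{i}", "ester"))
        samples = list(abundance.samples)
        volatiles = VolatileTable(
            compounds=compounds, samples=samples, values=np.clip(values, 0, None)
        )
        return abundance, volatiles

    def test_six_links_qualifies_four_does_not(self, rng):
        a6, v6 = self._tables(6, rng)
        _, qual6 = flavor_associated_taxa(a6, v6)
        assert "taxon_0" in qual6
        a4, v4 = self._tables(4, rng)
        _, qual4 = flavor_associated_taxa(a4, v4)
        assert "taxon_0" not in qual4

    def test_sample_mismatch_errors(self, rng):
        abundance, volatiles = self._tables(6, rng)
        bad = VolatileTable(
            compounds=volatiles.compounds,
            samples=[SampleMeta(f"x{j}", float(j), 1) for j in range(14)],
            values=volatiles.values,
        )
        with pytest.raises(ValueError, match="mismatch"):
            flavor_associated_taxa(abundance, bad)
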