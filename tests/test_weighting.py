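import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from wppi import (
    build_weighted_network,
    combine_weights,
    compute_pcc,
    compute_wra,
    filter_negative_pcc,
    normalize_map,
)
from wppi.errors import ParameterError, ValidationError
from wppi.weighting import canonical_pair

from conftest import random_weighted_graph


def brute_force_wra(g: nx.Graph, include_endpoints: bool) -> dict:
    """Independent enumeration of the resource-allocation sum per edge."""
    out = {}
    for i, j in g.edges():
        closed_i = set(g[i]) | {i}
        closed_j = set(g[j]) | {j}
        common = closed_i & closed_j
        if not include_endpoints:
            common -= {i, j}
        out[canonical_pair(i, j)] = sum(1.0 / (g.degree(u) + 1) for u in common)
    return out


class TestWRA:
    def test_triangle_third_party_convention(self, unit_triangle):
        # sole third-party common neighbor has closed neighborhood size 3
        wra = compute_wra(unit_triangle, include_endpoints=False)
        assert wra[("a", "b")] == pytest.approx(1 / 3)

    def test_triangle_closed_convention_saturates(self, unit_triangle):
        # 1/3 from the third party plus 1/3 from each endpoint
        wra = compute_wra(unit_triangle)
        assert wra[("a", "b")] == pytest.approx(1.0)

    def test_isolated_edge(self):
        g = nx.Graph([("a", "b")])
        assert compute_wra(g, include_endpoints=False)[("a", "b")] == 0.0
        # endpoints each have closed neighborhood {a, b}
        assert compute_wra(g)[("a", "b")] == pytest.approx(1.0)

    def test_four_clique(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(4)})
        key = canonical_pair("n0", "n1")
        assert compute_wra(g, include_endpoints=False)[key] == pytest.approx(0.5)
        assert compute_wra(g)[key] == pytest.approx(1.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            compute_wra(nx.Graph())

    @pytest.mark.parametrize("include_endpoints", [True, False])
    def test_matches_brute_force_on_random_graphs(self, include_endpoints):
        rng = np.random.default_rng(7)
        for _ in range(25):
            g = random_weighted_graph(rng, int(rng.integers(4, 25)), 0.3)
            if g.number_of_edges() == 0:
                continue
            got = compute_wra(g, include_endpoints=include_endpoints)
            assert got == pytest.approx(brute_force_wra(g, include_endpoints))

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(11)
        g = random_weighted_graph(rng, 15, 0.3)
        mapping = {n: f"z{idx}" for idx, n in enumerate(sorted(g.nodes, reverse=True))}
        h = nx.relabel_nodes(g, mapping)
        wra_g = compute_wra(g)
        wra_h = compute_wra(h)
        for (u, v), val in wra_g.items():
            assert wra_h[canonical_pair(mapping[u], mapping[v])] == pytest.approx(val)


class TestPCC:
    def _expr(self, **profiles):
        return pd.DataFrame({k: pd.Series(v) for k, v in profiles.items()}).T

    def test_perfect_correlation(self):
        e = self._expr(x=[1, 2, 3], y=[2, 4, 6])
        assert compute_pcc(e, [("x", "y")])[("x", "y")] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        e = self._expr(x=[1, 2, 3], y=[3, 2, 1])
        assert compute_pcc(e, [("x", "y")])[("x", "y")] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # covariance sum 4 over sqrt(5) * sqrt(5)
        e = self._expr(x=[1, 2, 3, 4], y=[1, 3, 2, 4])
        assert compute_pcc(e, [("x", "y")])[("x", "y")] == pytest.approx(0.8)

    def test_missing_gene_marked_nan(self):
        e = self._expr(x=[1, 2, 3])
        assert math.isnan(compute_pcc(e, [("x", "absent")])[("absent", "x")])

    def test_zero_variance_marked_nan(self):
        e = self._expr(x=[1, 2, 3], y=[5, 5, 5])
        assert math.isnan(compute_pcc(e, [("x", "y")])[("x", "y")])

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            x, y = rng.normal(size=(2, 36))
            e = self._expr(x=x, y=y)
            got = compute_pcc(e, [("x", "y")])[("x", "y")]
            xb, yb = x.mean(), y.mean()
            expected = ((x - xb) * (y - yb)).sum() / (
                math.sqrt(((x - xb) ** 2).sum()) * math.sqrt(((y - yb) ** 2).sum())
            )
            assert got == pytest.approx(expected, abs=1e-12)


class TestNegativeFilter:
    def test_negative_removed_zero_and_nan_kept(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        pcc = {("a", "b"): -0.4, ("b", "c"): 0.0, ("c", "d"): math.nan}
        out = filter_negative_pcc(g, pcc)
        assert not out.has_edge("a", "b")
        assert out.has_edge("b", "c")
        assert out.has_edge("c", "d")
        assert set(out.nodes) == set(g.nodes)

    def test_all_non_negative_is_identity(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        out = filter_negative_pcc(g, {("a", "b"): 0.5, ("b", "c"): 0.2})
        assert nx.utils.graphs_equal(out, g)


class TestNormalizeCombine:
    def test_min_max_rescaling(self):
        w = {("a", "b"): 0.2, ("b", "c"): 0.6, ("c", "d"): 1.0}
        assert normalize_map(w) == pytest.approx(
            {("a", "b"): 0.0, ("b", "c"): 0.5, ("c", "d"): 1.0}
        )

    def test_constant_map_becomes_ones(self):
        w = {("a", "b"): 0.7, ("b", "c"): 0.7}
        assert normalize_map(w) == {("a", "b"): 1.0, ("b", "c"): 1.0}

    def test_full_span_unchanged(self):
        w = {("a", "b"): 0.0, ("b", "c"): 0.25, ("c", "d"): 1.0}
        assert normalize_map(w) == pytest.approx(w)

    def test_blend_arithmetic(self):
        # anchor edges at 0 and 1 make the final min-max a no-op
        wn = {("a", "b"): 0.5, ("c", "d"): 0.0, ("e", "f"): 1.0}
        wp = {("a", "b"): 0.9, ("c", "d"): 0.0, ("e", "f"): 1.0}
        out = combine_weights(wn, wp, alpha=0.3)
        assert out[("a", "b")] == pytest.approx(0.3 * 0.9 + 0.7 * 0.5)

    def test_alpha_monotonicity(self):
        wn = {("a", "b"): 0.5, ("c", "d"): 0.0, ("e", "f"): 1.0}
        wp = {("a", "b"): 0.9, ("c", "d"): 0.0, ("e", "f"): 1.0}
        vals = [combine_weights(wn, wp, a)[("a", "b")] for a in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert vals == sorted(vals)  # wp > wn on this edge

    def test_alpha_out_of_range(self):
        with pytest.raises(ParameterError):
            combine_weights({("a", "b"): 0.5}, {("a", "b"): 0.5}, alpha=1.5)

    def test_domain_mismatch(self):
        with pytest.raises(ValidationError):
            combine_weights({("a", "b"): 0.5}, {("c", "d"): 0.5}, alpha=0.5)

    def test_missing_pcc_contributes_zero(self):
        wn = {("a", "b"): 1.0, ("c", "d"): 0.0}
        wp = {("a", "b"): math.nan, ("c", "d"): 0.0}
        out = combine_weights(wn, wp, alpha=0.3)
        assert out[("a", "b")] == pytest.approx(1.0)  # (1 - alpha) * 1 is the max


class TestBuildWeightedNetwork:
    def _inputs(self, seed=5):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        nodes = [f"g{i}" for i in range(12)]
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.35:
                    g.add_edge(nodes[i], nodes[j])
        expr = pd.DataFrame(rng.normal(size=(12, 36)), index=nodes)
        return g, expr

    def test_weights_in_unit_interval(self):
        g, expr = self._inputs()
        w = build_weighted_network(g, expr, alpha=0.3)
        for _, _, d in w.edges(data=True):
            assert 0.0 <= d["weight"] <= 1.0

    def test_alpha_zero_is_topology_only(self):
        g, expr = self._inputs()
        w0 = build_weighted_network(g, expr, alpha=0.0)
        pcc = compute_pcc(expr, list(g.edges()))
        filt = filter_negative_pcc(g, pcc)
        expected = normalize_map(
            {k: min(v, 1.0) for k, v in compute_wra(filt).items()}
        )
        for (u, v), val in expected.items():
            assert w0[u][v]["weight"] == val  # bit-exact

    def test_alpha_one_matches_ra_disabled(self):
        g, expr = self._inputs()
        w1 = build_weighted_network(g, expr, alpha=1.0)
        woff = build_weighted_network(g, expr, alpha=0.3, ra_enabled=False)
        for u, v, d in w1.edges(data=True):
            assert woff[u][v]["weight"] == d["weight"]  # bit-exact

    def test_all_negative_pcc_empties_network(self):
        g = nx.Graph([("x", "y")])
        expr = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["x", "y"])
        w = build_weighted_network(g, expr, alpha=0.3)
        assert w.number_of_edges() == 0
        assert set(w.nodes) == {"x", "y"}

    def test_deterministic(self):
        g, expr = self._inputs()
        w1 = build_weighted_network(g, expr, alpha=0.3)
        w2 = build_weighted_network(g, expr, alpha=0.3)
        assert nx.utils.graphs_equal(w1, w2)
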