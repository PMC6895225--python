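import math

import numpy as np
import pytest

from focs.core import (
    focs_score,
    min_order_cdf,
    node_pvalues,
    score_collection,
    single_f,
    stability_cv,
)
from focs.errors import ParameterError, ValidationError
from focs.graph import (
    BipartiteCommunity,
    Community,
    Graph,
    community_in_degree,
    external_view,
)
from focs.null_model import corrected_quantile


class TestMinOrderCdf:
    def test_lower_endpoint(self):
        assert min_order_cdf(0.3, 0.3, 50) == 0.0

    def test_upper_endpoint(self):
        assert min_order_cdf(1.0, 0.3, 50) == 1.0

    def test_min_of_two_uniforms(self):
        assert min_order_cdf(0.5, 0.0, 2) == pytest.approx(0.75, rel=1e-12)

    def test_identity_at_m1(self):
        for x in (0.1, 0.5, 0.9):
            assert min_order_cdf(x, 0.0, 1) == pytest.approx(x, rel=1e-12)

    def test_degenerate_range(self):
        assert min_order_cdf(1.0, 1.0, 10) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            min_order_cdf(0.2, 0.3, 10)
        with pytest.raises(ParameterError):
            min_order_cdf(0.5, -0.1, 10)
        with pytest.raises(ParameterError):
            min_order_cdf(0.5, 0.2, 0)

    def test_tiny_gap_accuracy(self):
        # exact value via expm1/log1p identity at small gap
        x, a, m = 1e-9, 0.0, 10**6
        expected = -math.expm1(m * math.log1p(-x))
        assert min_order_cdf(x, a, m) == pytest.approx(expected, rel=1e-12)
        assert 0 < min_order_cdf(1e-12 + 0.5, 0.5, 10**8) <= 1

    def test_monotone_in_x(self):
        vals = [min_order_cdf(x, 0.1, 37) for x in np.linspace(0.1, 1.0, 50)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestNodePvalues:
    def test_sorted_descending_and_complementary(self, random_graph_20):
        c = Community(frozenset(["v00", "v01", "v02", "v03", "v04"]), id="c")
        scores = node_pvalues(random_graph_20, c, np.random.default_rng(0))
        ps = [s.pvalue for s in scores]
        assert ps == sorted(ps, reverse=True)
        for s in scores:
            assert s.pvalue == pytest.approx(1.0 - s.quantile)
            assert 0.0 <= s.pvalue <= 1.0

    def test_two_clique_community(self):
        g = Graph([("a", "b"), ("a", "c"), ("b", "d"), ("c", "d"), ("c", "e")])
        scores = node_pvalues(g, Community({"a", "b"}), np.random.default_rng(1))
        assert len(scores) == 2
        assert all(s.in_degree == 1 for s in scores)

    def test_oracle_recomputation_with_fixed_deviates(self, random_graph_20):
        c = Community(frozenset(["v05", "v06", "v07", "v08"]), id="c")
        deviates = {u: d for u, d in zip(sorted(c.members), (0.1, 0.4, 0.7, 0.9))}
        scores = node_pvalues(random_graph_20, c, deviates=deviates)
        for s in scores:
            params = external_view(random_graph_20, c, s.node)
            a = community_in_degree(random_graph_20, c, s.node)
            cq = corrected_quantile(params, a, None, deviate=deviates[s.node])
            assert s.quantile == pytest.approx(cq.value, abs=1e-15)
            assert s.in_degree == a

    def test_requires_rng_or_deviates(self, random_graph_20):
        with pytest.raises(ValueError):
            node_pvalues(random_graph_20, Community({"v00", "v01"}))


class TestSingleF:
    def test_composition_oracle(self, random_graph_20):
        c = Community(frozenset(["v00", "v03", "v05", "v09", "v11"]), id="c")
        deviates = {u: d for u, d in
                    zip(sorted(c.members), (0.15, 0.35, 0.55, 0.75, 0.95))}
        f = single_f(random_graph_20, c, deviates=deviates)
        scores = node_pvalues(random_graph_20, c, deviates=deviates)
        m = random_graph_20.n_nodes - c.size + 1
        expected = min_order_cdf(scores[0].pvalue, scores[1].pvalue, m)
        assert f == pytest.approx(expected, abs=1e-15)

    def test_equal_top_pvalues_give_zero(self, random_graph_20):
        c = Community(frozenset(["v00", "v01"]), id="c")
        deviates = {u: 0.5 for u in c.members}
        scores = node_pvalues(random_graph_20, c, deviates=deviates)
        if scores[0].pvalue == scores[1].pvalue:
            assert single_f(random_graph_20, c, deviates=deviates) == 0.0

    def test_range_is_valid(self, random_graph_20):
        for seed in range(10):
            c = Community(frozenset(["v02", "v04", "v06", "v08", "v10"]), id="c")
            f = single_f(random_graph_20, c, np.random.default_rng(seed))
            assert 0.0 <= f <= 1.0


class TestFocsScore:
    def test_iteration_count_small_community(self, random_graph_20):
        c = Community(frozenset(["v00", "v01", "v02"]), id="c")
        r = focs_score(random_graph_20, c, rho=0.25, seed=0)
        assert r.n_tested == 1  # max(1, floor(0.75))

    def test_iteration_count_size_eight(self, random_graph_20):
        c = Community(frozenset([f"v{i:02d}" for i in range(8)]), id="c")
        r = focs_score(random_graph_20, c, rho=0.25, seed=0)
        assert r.n_tested == 2
        assert len(r.removal_order) == 2

    def test_score_is_min_of_iterations(self, random_graph_20):
        c = Community(frozenset([f"v{i:02d}" for i in range(10)]), id="c")
        r = focs_score(random_graph_20, c, rho=0.5, seed=3)
        assert r.score == min(r.iteration_f)
        assert r.score <= r.iteration_f[0]
        assert 0.0 <= r.score <= 1.0

    def test_seed_determinism(self, random_graph_20):
        c = Community(frozenset([f"v{i:02d}" for i in range(6)]), id="c")
        a = focs_score(random_graph_20, c, seed=11)
        b = focs_score(random_graph_20, c, seed=11)
        assert a == b

    def test_rho_validation(self, random_graph_20):
        c = Community(frozenset(["v00", "v01", "v02"]), id="c")
        for rho in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                focs_score(random_graph_20, c, rho=rho, seed=0)

    def test_single_member_rejected(self, random_graph_20):
        with pytest.raises(ValidationError):
            focs_score(random_graph_20, Community({"v00"}), seed=0)

    def test_two_member_community_stops_after_one(self, random_graph_20):
        c = Community(frozenset(["v00", "v01"]), id="c")
        r = focs_score(random_graph_20, c, rho=1.0, seed=0)
        assert r.n_tested == 1  # would drop below 2 members

    def test_monotone_under_common_random_numbers(self):
        # rewiring one external edge of the worst node into the community
        # weakly decreases its p-value and the statistic
        base = Graph([
            ("a", "b"), ("a", "c"), ("b", "c"), ("a", "x"), ("x", "y"),
            ("y", "z"), ("z", "x"), ("b", "y"), ("c", "z"), ("x", "w"),
            ("w", "y"),
        ])
        rewired = Graph([
            ("a", "b"), ("a", "c"), ("b", "c"), ("a", "b"), ("x", "y"),
            ("y", "z"), ("z", "x"), ("b", "y"), ("c", "z"), ("x", "w"),
            ("w", "y"),
        ])  # a's edge to x redirected to community member b
        c = Community({"a", "b", "c"}, id="c")
        deviates = {"a": 0.5, "b": 0.5, "c": 0.5}
        pa_base = next(
            s for s in node_pvalues(base, c, deviates=deviates) if s.node == "a"
        )
        pa_rew = next(
            s for s in node_pvalues(rewired, c, deviates=deviates) if s.node == "a"
        )
        assert pa_rew.pvalue <= pa_base.pvalue

    def test_crn_mode_reuses_deviates(self, random_graph_20):
        c = Community(frozenset([f"v{i:02d}" for i in range(12)]), id="c")
        r = focs_score(random_graph_20, c, rho=0.5, seed=4, redraw_deviates=False)
        assert r.score == min(r.iteration_f)
        assert 0.0 <= r.score <= 1.0


class TestBipartiteScoring:
    def test_smoke(self, bipartite_graph):
        c = BipartiteCommunity({"u0", "u1"}, {"w0", "w1"}, id="c")
        r = focs_score(bipartite_graph, c, seed=0)
        assert 0.0 <= r.score <= 1.0
        assert r.n_tested == 1

    def test_empty_side_is_validation_error(self, bipartite_graph):
        with pytest.raises(ValidationError):
            focs_score(bipartite_graph, BipartiteCommunity(frozenset(), {"w0", "w1"}), seed=0)

    def test_merged_worst_node_pool(self, bipartite_graph):
        c = BipartiteCommunity({"u0", "u1", "u2"}, {"w0", "w1", "w2"}, id="c")
        scores = node_pvalues(bipartite_graph, c, np.random.default_rng(0))
        assert {s.node for s in scores} == c.members  # both sides in one list

    def test_m_counts_both_external_sides(self, bipartite_graph):
        c = BipartiteCommunity({"u0", "u1"}, {"w0", "w1"}, id="c")
        deviates = {u: 0.5 for u in c.members}
        f = single_f(bipartite_graph, c, deviates=deviates)
        scores = node_pvalues(bipartite_graph, c, deviates=deviates)
        m = (5 - 2) + (4 - 2) + 1
        assert f == pytest.approx(
            min_order_cdf(scores[0].pvalue, scores[1].pvalue, m), abs=1e-15
        )


class TestScoreCollection:
    def test_empty_list(self, random_graph_20):
        res = score_collection(random_graph_20, [], seed=0)
        assert len(res.table) == 0
        assert math.isnan(res.proportion_significant)

    def test_all_above_threshold(self, random_graph_20):
        comms = [Community(frozenset([f"v{i:02d}" for i in range(5)]), id="c1")]
        res = score_collection(random_graph_20, comms, seed=0, alpha=1e-12)
        assert res.proportion_significant == 0.0

    def test_failure_recorded_per_row(self, random_graph_20):
        comms = [
            Community(frozenset(["v00", "v01", "v02"]), id="ok"),
            Community(frozenset(["v03"]), id="bad"),
        ]
        res = score_collection(random_graph_20, comms, seed=0)
        bad = res.table[res.table.community_id == "bad"].iloc[0]
        assert bad.error != ""
        assert math.isnan(bad.focs_score)
        ok = res.table[res.table.community_id == "ok"].iloc[0]
        assert 0.0 <= ok.focs_score <= 1.0

    def test_trivial_flag(self, random_graph_20):
        comms = [Community(frozenset(["v00", "v01"]), id="tiny")]
        res = score_collection(random_graph_20, comms, seed=0)
        assert bool(res.table.iloc[0].trivial)

    def test_deterministic_per_community_seeds(self, random_graph_20):
        comms = [Community(frozenset([f"v{i:02d}" for i in range(6)]), id="c")]
        t1 = score_collection(random_graph_20, comms, seed=5).table
        t2 = score_collection(random_graph_20, comms, seed=5).table
        assert t1.equals(t2)


class TestStabilityCv:
    def test_finite_nonnegative(self, random_graph_20):
        c = Community(frozenset([f"v{i:02d}" for i in range(6)]), id="c")
        cv = stability_cv(random_graph_20, c, n_runs=10, seed=0)
        assert cv >= 0.0 and math.isfinite(cv)

    def test_identical_streams_have_zero_cv(self, random_graph_20):
        c = Community(frozenset([f"v{i:02d}" for i in range(6)]), id="c")
        s1 = focs_score(random_graph_20, c, seed=7).score
        s2 = focs_score(random_graph_20, c, seed=7).score
        scores = np.array([s1, s2])
        assert scores.std(ddof=1) == 0.0

    def test_n_runs_validation(self, random_graph_20):
        c = Community(frozenset(["v00", "v01", "v02"]), id="c")
        with pytest.raises(ParameterError):
            stability_cv(random_graph_20, c, n_runs=1, seed=0)
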