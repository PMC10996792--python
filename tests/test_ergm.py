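"""Dyad-independent ERGM statistics, identifiability and exact-MLE checks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logit

import presnet as pn
from presnet.ergm import TermSpec, dyad_change_matrix


def graph_with_attrs(edges, attrs):
    g = nx.Graph()
    g.add_nodes_from(attrs)
    g.add_edges_from(edges)
    for name in next(iter(attrs.values())):
        nx.set_node_attributes(g, {v: a[name] for v, a in attrs.items()}, name)
    return g


class TestNetworkStatistics:
    def test_path_with_binary_attribute(self):
        g = graph_with_attrs([(1, 2), (2, 3)], {1: {"x": 1}, 2: {"x": 1}, 3: {"x": 0}})
        terms = [
            TermSpec("edges"),
            TermSpec("nodefactor", "x", 1),
            TermSpec("nodematch_diff", "x", 1),
            TermSpec("absdiff", "x"),
        ]
        np.testing.assert_allclose(pn.network_statistics(g, terms), [2, 3, 1, 1])

    def test_empty_graph_all_zero(self):
        g = graph_with_attrs([], {i: {"x": i} for i in range(4)})
        terms = [TermSpec("edges"), TermSpec("nodecov", "x"), TermSpec("absdiff", "x")]
        np.testing.assert_allclose(pn.network_statistics(g, terms), [0, 0, 0])

    def test_uniform_match_on_homogeneous_triangle(self):
        g = graph_with_attrs(
            [(0, 1), (1, 2), (0, 2)], {i: {"x": "a"} for i in range(3)}
        )
        stats = pn.network_statistics(g, [TermSpec("edges"), TermSpec("nodematch", "x")])
        assert stats[0] == stats[1] == 3

    def test_row_sums_over_edges_reproduce_statistics(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = int(rng.integers(4, 12))
            g = nx.gnp_random_graph(n, 0.4, seed=trial)
            nx.set_node_attributes(g, {v: float(rng.uniform()) for v in g.nodes}, "u")
            nx.set_node_attributes(
                g, {v: str(rng.integers(0, 3)) for v in g.nodes}, "c"
            )
            terms = [
                TermSpec("edges"),
                TermSpec("nodecov", "u"),
                TermSpec("absdiff", "u"),
                TermSpec("nodefactor", "c", "0"),
                TermSpec("nodematch", "c"),
                TermSpec("nodematch_diff", "c", "1"),
            ]
            X, a, _ = pn.dyad_design(g, terms)
            np.testing.assert_allclose(
                X[a == 1].sum(axis=0), pn.network_statistics(g, terms), atol=1e-12
            )

    def test_dyad_dependent_term_rejected(self):
        with pytest.raises(ValueError, match="dyad-dependent|unsupported"):
            TermSpec("triangle")


class TestIdentifiability:
    def binary_design(self, x, terms):
        attrs = pd.DataFrame({"b": x})
        X, _ = dyad_change_matrix(list(attrs.index), attrs, terms)
        return X

    def full_set(self):
        return [
            TermSpec("edges"),
            TermSpec("nodefactor", "b", 1),
            TermSpec("nodematch_diff", "b", 0),
            TermSpec("nodematch_diff", "b", 1),
        ]

    def test_binary_attribute_deficiency_always_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            x = rng.integers(0, 2, n)
            # the exact-deficiency-one result needs a dyad of every type,
            # i.e. at least two nodes at each level
            x[:2], x[2:4] = 0, 1
            X = self.binary_design(x, self.full_set())
            rep = pn.check_identifiability(X, [t.name for t in self.full_set()])
            assert rep.deficiency == 1
            assert len(rep.collinear_sets) == 1

    def test_dropping_either_differential_term_restores_rank(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            x = rng.integers(0, 2, n)
            x[:2], x[2:4] = 0, 1
            for drop in (2, 3):
                terms = [t for i, t in enumerate(self.full_set()) if i != drop]
                X = self.binary_design(x, terms)
                assert pn.check_identifiability(X, [t.name for t in terms]).full_rank

    def test_level0_match_is_signed_sum_of_other_columns(self):
        # the linear dependence itself: match0 = edges - nodefactor + match1
        x = np.array([0, 1, 1, 0, 1, 0, 0, 1])
        X = self.binary_design(x, self.full_set())
        np.testing.assert_allclose(X[:, 2], X[:, 0] - X[:, 1] + X[:, 3], atol=1e-12)

    def test_three_level_attribute_generic_full_rank(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 20)
        terms = [TermSpec("edges")]
        terms += [TermSpec("nodefactor", "b", k) for k in (1, 2)]
        terms += [TermSpec("nodematch_diff", "b", k) for k in (0, 1, 2)]
        X = self.binary_design(x, terms)
        assert pn.check_identifiability(X, [t.name for t in terms]).full_rank

    def test_fit_refuses_rank_deficient_design(self):
        g = nx.gnp_random_graph(12, 0.5, seed=0)
        nx.set_node_attributes(g, {v: v % 2 for v in g.nodes}, "b")
        with pytest.raises(ValueError, match="rank deficient"):
            pn.fit_ergm(g, self.full_set())


def exact_enumeration_mle(g, terms, x0=None):
    """Independent oracle: maximize the exactly enumerated ERGM likelihood
    of the observed graph over eta (no per-dyad factorization used)."""
    nodes = sorted(g.nodes)
    attrs = pd.DataFrame(
        {name: [g.nodes[v][name] for v in nodes]
         for name in {t.attr for t in terms if t.attr}},
        index=nodes,
    )
    observed = np.array(
        [1.0 if g.has_edge(i, j) else 0.0 for i, j in itertools.combinations(nodes, 2)]
    ).astype(bool)

    def neg_loglik(eta):
        logp, masks = pn.exact_small_graph_loglik(nodes, attrs, terms, eta)
        idx = int(np.flatnonzero((masks == observed).all(axis=1))[0])
        return -logp[idx]

    p = len(terms)
    res = minimize(neg_loglik, x0 if x0 is not None else np.zeros(p), method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000})
    return res.x


class TestExactEnumeration:
    def test_eta_zero_is_uniform(self):
        attrs = pd.DataFrame({"x": [0.0, 1.0, 0.5]})
        logp, masks = pn.exact_small_graph_loglik(
            [0, 1, 2], attrs, [TermSpec("edges")], [0.0]
        )
        assert len(logp) == 8
        np.testing.assert_allclose(np.exp(logp), np.full(8, 1 / 8), atol=1e-12)

    def test_probabilities_sum_to_one(self):
        attrs = pd.DataFrame({"x": np.linspace(0, 1, 5)})
        logp, _ = pn.exact_small_graph_loglik(
            list(range(5)), attrs,
            [TermSpec("edges"), TermSpec("absdiff", "x")], [-0.7, 1.3],
        )
        assert abs(np.exp(logp).sum() - 1.0) < 1e-12

    def test_edges_only_depends_on_edge_count_alone(self):
        attrs = pd.DataFrame({"x": [0.0, 1.0, 0.5]})
        logp, masks = pn.exact_small_graph_loglik(
            [0, 1, 2], attrs, [TermSpec("edges")], [0.8]
        )
        counts = masks.sum(axis=1)
        for m in range(4):
            vals = logp[counts == m]
            np.testing.assert_allclose(vals, vals[0], atol=1e-12)

    def test_enumeration_matches_per_dyad_factorization(self):
        rng = np.random.default_rng(6)
        attrs = pd.DataFrame({"x": rng.uniform(size=4)})
        terms = [TermSpec("edges"), TermSpec("nodecov", "x"), TermSpec("absdiff", "x")]
        eta = np.array([-0.5, 0.8, -1.1])
        logp, masks = pn.exact_small_graph_loglik(list(range(4)), attrs, terms, eta)
        X, dyads = dyad_change_matrix(list(range(4)), attrs, terms)
        from scipy.special import expit

        p = expit(X @ eta)
        direct = masks @ np.log(p) + (~masks) @ np.log1p(-p)
        np.testing.assert_allclose(logp, direct, atol=1e-10)


class TestFitErgm:
    def test_edges_only_mle_is_logit_density(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 3)])
        g.add_nodes_from(range(4))
        fit = pn.fit_ergm(g, [TermSpec("edges")])
        assert fit.coefficients.loc["edges", "estimate"] == pytest.approx(
            logit(3 / 6), abs=1e-8
        )

    def test_complete_graph_diverges(self):
        fit = pn.fit_ergm(nx.complete_graph(5), [TermSpec("edges")])
        assert fit.diverged == ["edges"]
        assert fit.coefficients.loc["edges", "estimate"] == np.inf

    def test_empty_graph_diverges_negative(self):
        fit = pn.fit_ergm(nx.empty_graph(5), [TermSpec("edges")])
        assert fit.coefficients.loc["edges", "estimate"] == -np.inf

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_exact_enumeration_mle(self, n):
        rng = np.random.default_rng(100 + n)
        term_menu = [
            [TermSpec("edges")],
            [TermSpec("edges"), TermSpec("nodecov", "x")],
            [TermSpec("edges"), TermSpec("absdiff", "x")],
            [TermSpec("edges"), TermSpec("nodecov", "x"), TermSpec("absdiff", "x")],
        ]
        checked = 0
        attempts = 0
        while checked < 3 and attempts < 40:
            attempts += 1
            terms = term_menu[int(rng.integers(len(term_menu)))]
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            nx.set_node_attributes(g, {v: float(rng.uniform()) for v in g.nodes}, "x")
            try:
                fit = pn.fit_ergm(g, terms)
            except ValueError:
                continue
            if fit.diverged or np.abs(fit.eta).max() > 8:
                continue
            oracle = exact_enumeration_mle(g, terms, x0=fit.eta + 0.25)
            np.testing.assert_allclose(fit.eta, oracle, atol=1e-6)
            checked += 1
        assert checked == 3


class TestSimulationRecovery:
    def test_absdiff_sign_recovered(self):
        rng = np.random.default_rng(1)
        attrs = pd.DataFrame({"x": rng.uniform(size=200)}, index=range(200))
        terms = [TermSpec("edges"), TermSpec("nodecov", "x"), TermSpec("absdiff", "x")]
        ests = []
        for s in range(10):
            g = pn.generate_dyad_independent_network(attrs, terms, [-1.5, 0.5, -2.0], seed=s)
            ests.append(pn.fit_ergm(g, terms).coefficients.loc["absdiff.x", "estimate"])
        assert np.mean(ests) < 0
        assert np.mean(ests) == pytest.approx(-2.0, abs=0.5)

    def test_recovery_within_two_se(self):
        rng = np.random.default_rng(2)
        attrs = pd.DataFrame({"x": rng.uniform(size=300)}, index=range(300))
        terms = [TermSpec("edges"), TermSpec("absdiff", "x")]
        hits = 0
        for s in range(20):
            g = pn.generate_dyad_independent_network(attrs, terms, [-1.0, -2.0], seed=s)
            fit = pn.fit_ergm(g, terms)
            row = fit.coefficients.loc["absdiff.x"]
            hits += abs(row["estimate"] - (-2.0)) <= 2 * row["se"]
        assert hits >= 16
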