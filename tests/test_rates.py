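"""Substitution models, gamma discretization, pruning likelihoods,
empirical Bayes posterior rates — each checked against an independent
oracle (closed forms, quadrature, exhaustive state enumeration)."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist
from scipy.stats import spearmanr

from evorate.phylogeny import reroot_on_edge
from evorate.rates import (
    build_model,
    category_log_likelihoods,
    discretize_gamma,
    encode_alignment,
    estimate_alpha,
    posterior_rates,
    site_log_likelihood,
    sitewise_log_likelihoods,
    transition_matrix,
)
from evorate.simulate import SimulationSpec, simulate_dataset

from conftest import make_alignment


def newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration over internal-node states


def brute_force_site_likelihood(tree, column, model, rate):
    """Sum over every assignment of states to internal nodes (and to
    missing leaves) of pi(root) * prod over edges of P(r*b)[parent, child]."""
    nodes = list(tree.preorder_node_iter())
    idx = model.state_index()
    n_states = model.n_states
    P = {}
    for node in nodes[1:]:
        P[id(node)] = transition_matrix(model, rate * (node.edge.length or 0.0))

    free = []
    fixed = {}
    for node in nodes:
        if node.is_leaf():
            c = idx.get(column[node.taxon.label].upper(), -1)
            if c >= 0:
                fixed[id(node)] = c
            else:
                free.append(node)
        else:
            free.append(node)
    total = 0.0
    for combo in itertools.product(range(n_states), repeat=len(free)):
        states = dict(fixed)
        for node, s in zip(free, combo):
            states[id(node)] = s
        prob = model.pi[states[id(nodes[0])]]
        for node in nodes[1:]:
            prob *= P[id(node)][states[id(node.parent_node)], states[id(node)]]
        total += prob
    return math.log(total)


ALL_SMALL_TREES = [
    "(A:0.2,B:0.5);",
    "(A:0.2,B:0.5,C:0.9);",
    "((A:0.2,B:0.5):0.3,C:0.9);",
    "((A:0.2,B:0.5):0.3,(C:0.9,D:0.1):0.4);",
    "(((A:0.2,B:0.5):0.3,C:0.9):0.4,D:0.1);",
    "((A:0.2,C:0.9):0.3,(B:0.5,D:0.1):0.4);",
    "(A:0.2,B:0.5,C:0.9,D:0.1);",
]


class TestTransitionMatrix:
    def test_t_zero_is_identity(self):
        for alphabet in ("nucleotide", "protein"):
            m = build_model(alphabet)
            assert np.allclose(transition_matrix(m, 0.0), np.eye(m.n_states), atol=1e-12)

    def test_long_branch_reaches_stationarity(self):
        for alphabet in ("nucleotide", "protein"):
            m = build_model(alphabet)
            P = transition_matrix(m, 50.0)
            assert np.allclose(P, np.tile(m.pi, (m.n_states, 1)), atol=1e-6)

    def test_jc_closed_form(self):
        m = build_model("nucleotide")
        t = 0.3
        P = transition_matrix(m, t)
        p_same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
        p_diff = 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)
        assert P[0, 0] == pytest.approx(p_same, abs=1e-12)
        assert P[0, 1] == pytest.approx(p_diff, abs=1e-12)

    def test_rows_are_distributions(self):
        m = build_model("protein")
        for t in (0.01, 0.5, 2.0):
            P = transition_matrix(m, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P >= 0).all()

    def test_model_invariants(self):
        for alphabet in ("nucleotide", "protein"):
            m = build_model(alphabet)
            assert m.pi.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-10)
            assert -np.sum(m.pi * np.diag(m.Q)) == pytest.approx(1.0, abs=1e-10)
            # detailed balance
            flux = m.pi[:, None] * m.Q
            assert np.allclose(flux, flux.T, atol=1e-12)


class TestGammaDiscretization:
    def test_single_category(self):
        g = discretize_gamma(2.3, 1)
        assert g.rates.tolist() == [1.0]

    def test_concentration_limit(self):
        g = discretize_gamma(1e6, 16)
        assert np.all(np.abs(g.rates - 1.0) < 1e-2)

    @pytest.mark.parametrize("alpha,K", [(1.0, 4), (0.5, 8), (2.0, 16)])
    def test_quadrature_oracle(self, alpha, K):
        g = discretize_gamma(alpha, K)
        dist = gamma_dist(alpha, scale=1.0 / alpha)
        bounds = [0.0] + [dist.ppf(k / K) for k in range(1, K)] + [np.inf]
        for k in range(K):
            mean_k, _ = quad(
                lambda x: x * dist.pdf(x), bounds[k], bounds[k + 1], limit=200
            )
            assert g.rates[k] == pytest.approx(mean_k * K, abs=1e-6)

    def test_mean_one_and_increasing(self):
        for alpha in (0.1, 0.8, 5.0):
            g = discretize_gamma(alpha, 16)
            assert g.weights @ g.rates == pytest.approx(1.0, abs=1e-6)
            assert np.all(np.diff(g.rates) > 0)
            assert np.all(g.rates >= 0)


class TestPruning:
    def test_single_leaf_base_case(self):
        tree = newick("A:0.0;")
        m = build_model("nucleotide")
        for i, s in enumerate("ACGT"):
            ll = site_log_likelihood(tree, {"A": s}, m, 1.0)
            assert ll == pytest.approx(math.log(m.pi[i]), abs=1e-12)

    @pytest.mark.parametrize("newick_str", ALL_SMALL_TREES)
    @pytest.mark.parametrize("rate", [0.3, 1.0, 2.5])
    def test_matches_enumeration_oracle(self, newick_str, rate):
        m = build_model("nucleotide")
        tree = newick(newick_str)
        leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        chars = "ACGT-"
        rng = np.random.default_rng(1)
        for _ in range(6):
            column = {t: chars[rng.integers(5)] for t in leaves}
            got = site_log_likelihood(tree, column, m, rate)
            want = brute_force_site_likelihood(tree, column, m, rate)
            assert got == pytest.approx(want, abs=1e-12)

    def test_all_gap_column_has_likelihood_one(self):
        tree = newick("((A:0.2,B:0.5):0.3,C:0.9);")
        m = build_model("protein")
        ll = site_log_likelihood(tree, {"A": "-", "B": "X", "C": "-"}, m, 1.0)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_rerooting_invariance(self):
        m = build_model("nucleotide")
        tree = newick("((A:0.2,B:0.5):0.3,(C:0.9,D:0.1):0.4);")
        column = {"A": "A", "B": "C", "C": "A", "D": "T"}
        base = site_log_likelihood(tree, column, m, 1.3)
        for leaf in ("A", "C", "D"):
            rerooted = reroot_on_edge(tree, leaf)
            assert site_log_likelihood(rerooted, column, m, 1.3) == pytest.approx(
                base, abs=1e-10
            )

    def test_duplicate_taxon_at_zero_length_is_neutral(self):
        m = build_model("nucleotide")
        t1 = newick("((A:0.2,B:0.5):0.3,C:0.9);")
        # replace leaf A by a cherry of two zero-length copies with equal state
        t2 = newick("(((A:0.0,A2:0.0):0.2,B:0.5):0.3,C:0.9);")
        col1 = {"A": "A", "B": "C", "C": "G"}
        col2 = {"A": "A", "A2": "A", "B": "C", "C": "G"}
        assert site_log_likelihood(t2, col2, m, 1.0) == pytest.approx(
            site_log_likelihood(t1, col1, m, 1.0), abs=1e-12
        )

    def test_deep_tree_does_not_underflow(self):
        ds = simulate_dataset(
            SimulationSpec(n_leaves=150, n_sites=20, alphabet="protein", alpha=1.0, seed=5)
        )
        m = build_model("protein")
        enc = encode_alignment(ds.alignment, m)
        ll = sitewise_log_likelihoods(ds.tree, enc, ds.alignment.ids, m, 1.0)
        assert np.all(np.isfinite(ll))


class TestEstimateAlpha:
    def test_profile_unimodal_and_recovery(self, recovery_dataset):
        ds = recovery_dataset
        m = build_model("protein")
        enc = encode_alignment(ds.alignment, m)
        grid = np.array([0.2, 0.4, 0.6, 0.8, 1.2, 2.0, 4.0])
        logliks = []
        for a in grid:
            g = discretize_gamma(float(a), 8)
            ll = category_log_likelihoods(ds.tree, enc, ds.alignment.ids, m, g)
            from scipy.special import logsumexp

            logliks.append(float(np.sum(logsumexp(ll - np.log(8), axis=1))))
        k = int(np.argmax(logliks))
        # unimodal: increasing up to the peak, decreasing after
        assert all(x < y for x, y in zip(logliks[:k], logliks[1 : k + 1]))
        assert all(x > y for x, y in zip(logliks[k:], logliks[k + 1 :]))
        assert 0.3 < grid[k] < 2.1  # peak near the generating shape 0.8

    def test_invariant_alignment_hits_bound(self):
        rows = {f"s{i}": "MMMM" for i in range(6)}
        aln = make_alignment(rows, "s0")
        tree = newick("((s0:0.2,s1:0.2):0.1,(s2:0.2,s3:0.2):0.1,(s4:0.2,s5:0.2):0.1);")
        m = build_model("protein")
        a = estimate_alpha(aln, tree, m, K=8)
        assert 0.05 <= a <= 20.0
        assert a < 0.1  # no variation -> shape pushed to the lower bound


class TestPosteriorRates:
    def test_all_missing_column_gets_prior(self):
        rows = {"a": "M-", "b": "M-", "c": "MX", "d": "M-", "e": "M-"}
        aln = make_alignment(rows, "a")
        tree = newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1,e:0.3);")
        m = build_model("protein")
        g = discretize_gamma(1.0, 16)
        res = posterior_rates(aln, tree, m, g)
        site = res[1]
        assert site.prior_only
        assert np.allclose(site.posterior_weights, g.weights)
        assert site.rate_hat == pytest.approx(1.0, abs=1e-9)
        lo, hi = g.rates[0], g.rates[15]
        assert site.ci_low == pytest.approx(g.rates[0])
        assert site.ci_high == pytest.approx(g.rates[15])

    def test_weights_sum_to_one_and_rate_in_range(self, small_dataset):
        ds = small_dataset
        m = build_model("protein")
        g = discretize_gamma(0.8, 16)
        res = posterior_rates(ds.alignment, ds.tree, m, g)
        for r in res:
            assert r.posterior_weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert g.rates[0] <= r.rate_hat <= g.rates[-1]
            assert r.ci_low <= r.rate_hat <= r.ci_high

    def test_conserved_column_below_average_rate(self):
        ds = simulate_dataset(
            SimulationSpec(
                n_leaves=30,
                n_sites=40,
                alphabet="protein",
                alpha=None,
                rates=tuple([0.0] * 10 + [1.5] * 30),
                branch_scale=0.3,
                seed=9,
            )
        )
        m = build_model("protein")
        g = discretize_gamma(1.0, 16)
        res = posterior_rates(ds.alignment, ds.tree, m, g)
        est = np.array([r.rate_hat for r in res])
        assert est[:10].mean() < est.mean()
        assert est[:10].max() < est[10:].mean()

    def test_parameter_recovery_spearman(self, recovery_dataset):
        ds = recovery_dataset
        m = build_model("protein")
        alpha = estimate_alpha(ds.alignment, ds.tree, m, K=16)
        g = discretize_gamma(alpha, 16)
        res = posterior_rates(ds.alignment, ds.tree, m, g)
        est = [r.rate_hat for r in res]
        assert spearmanr(ds.true_rates, est).statistic >= 0.8

    def test_ci_covers_generating_category(self):
        """Sites simulated at known category rates: the 95% discrete CI
        contains the generating category >= 90% of the time."""
        g = discretize_gamma(0.8, 16)
        rng = np.random.default_rng(21)
        cats = rng.integers(0, 16, size=200)
        rates = g.rates[cats]
        from evorate.simulate import random_tree, simulate_alignment

        tree = random_tree(40, scale=0.15, seed=rng)
        m = build_model("protein")
        aln, _ = simulate_alignment(tree, m, rates, rng)
        res = posterior_rates(aln, tree, m, g)
        covered = sum(
            1
            for r, c in zip(res, cats)
            if r.ci_low - 1e-12 <= g.rates[c] <= r.ci_high + 1e-12
        )
        assert covered / len(res) >= 0.90
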