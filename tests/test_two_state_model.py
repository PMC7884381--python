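"""Two-state symmetric model: pmf, derivatives, divergences, Fisher metric."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from waldspace.cli_fixtures import random_tree
from waldspace.forest_core import parse_newick
from waldspace.two_state_model import (
    character_pmf,
    character_pmf_derivatives,
    christoffel_two_state,
    f_divergence,
    fisher_information_two_state,
    hellinger_metric,
    js_metric,
    kl_divergence,
    leaf_covariance,
    metric_and_derivative_two_state,
    simulate_characters,
    transition_same_prob,
)


def brute_force_pmf(forest):
    """Independent oracle: for each character, sum the joint probability
    over every assignment of states to the internal vertices.  One
    stationary Bern(1/2) factor per component, one transition factor per
    edge."""
    n = forest.n_leaves
    internal = [v for v in forest.graph.nodes if not isinstance(v, int)]
    ncomp = forest.n_components
    edges = [(u, v, forest.graph.edges[u, v]["length"])
             for u, v in forest.graph.edges]
    out = np.zeros(2 ** n)
    for s in range(2 ** n):
        state = {leaf: (s >> (n - leaf)) & 1 for leaf in range(1, n + 1)}
        total = 0.0
        for assign in itertools.product((0, 1), repeat=len(internal)):
            state.update(zip(internal, assign))
            p = 0.5 ** ncomp
            for u, v, l in edges:
                ps = transition_same_prob(l)
                p *= ps if state[u] == state[v] else 1 - ps
            total += p
        out[s] = total
    return out


class TestTransitionAndPmf:
    def test_transition_probability_values(self):
        assert transition_same_prob(0.0) == 1.0
        assert transition_same_prob(math.inf) == 0.5
        assert transition_same_prob(math.log(2)) == pytest.approx(0.75)

    def test_two_leaf_closed_form(self):
        l = 0.7
        t = parse_newick(f"(1:{l/2},2:{l/2});")
        p = character_pmf(t)
        same = (1 + math.exp(-l)) / 4
        diff = (1 - math.exp(-l)) / 4
        assert p == pytest.approx([same, diff, diff, same])

    @pytest.mark.parametrize("newick", [
        "((1:0.1,2:0.2):0.15,3:0.3,(4:0.25,5:0.1):0.2);",
        "(1:0.3,2:0.1,3:0.4,4:0.2);",
        "(1:0.2,2:0.3);\n(3:0.5,4:0.1);",
        "((1:0.2,2:0.3):0.4,(4:0.1,5:0.4));\n3;",
    ])
    def test_pmf_matches_brute_force(self, newick):
        f = parse_newick(newick)
        p = character_pmf(f)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p > 0)
        assert np.allclose(p, brute_force_pmf(f), atol=1e-12)

    def test_equivalent_forests_same_pmf(self):
        a = parse_newick("((1:0.1,2:0.1):0.0,3:0.1,4:0.1);")
        b = parse_newick("(1:0.1,2:0.1,3:0.1,4:0.1);")
        assert np.allclose(character_pmf(a), character_pmf(b))
        c = parse_newick("((1:0.2,2:0.3):0.25,3:inf,(4:0.1,5:0.4):0.15);")
        d = parse_newick("((1:0.2,2:0.3):0.4,(4:0.1,5:0.4));\n3;")
        assert np.allclose(character_pmf(c), character_pmf(d))


class TestDerivatives:
    def test_gradient_sums_to_zero(self, caterpillar5):
        _, grad, hess = character_pmf_derivatives(caterpillar5)
        assert np.allclose(grad.sum(axis=1), 0, atol=1e-12)
        assert np.allclose(hess.sum(axis=2), 0, atol=1e-12)

    def test_two_leaf_gradient_closed_form(self):
        l = 0.9
        t = parse_newick(f"(1:{l/2},2:{l/2});")
        _, grad, _ = character_pmf_derivatives(t)
        # d p(00) / d l = -exp(-l)/4
        assert grad[0, 0] == pytest.approx(-math.exp(-l) / 4)

    def test_gradient_and_hessian_match_finite_differences(self, rng):
        t = random_tree(5, rng=rng)
        lv = t.length_vector()
        p, grad, hess = character_pmf_derivatives(t)
        eps = 1e-5
        for i in (0, 3, 6):
            lp, lm = lv.copy(), lv.copy()
            lp[i] += eps
            lm[i] -= eps
            fd = (character_pmf(t.with_lengths(lp))
                  - character_pmf(t.with_lengths(lm))) / (2 * eps)
            assert np.abs(fd - grad[i]).max() < 1e-7
        eps = 1e-4
        for i, j in ((0, 5), (5, 6), (2, 2)):
            ei = np.eye(7)[i] * eps
            ej = np.eye(7)[j] * eps
            fd2 = (character_pmf(t.with_lengths(lv + ei + ej))
                   - character_pmf(t.with_lengths(lv + ei - ej))
                   - character_pmf(t.with_lengths(lv - ei + ej))
                   + character_pmf(t.with_lengths(lv - ei - ej))) / (4 * eps * eps)
            assert np.abs(fd2 - hess[i, j]).max() < 1e-6


class TestMomentsAndSimulation:
    def test_leaf_covariance_closed_form(self, caterpillar5):
        from waldspace.forest_core import leaf_distance_matrix

        d = leaf_distance_matrix(caterpillar5)
        for u, v in ((1, 2), (1, 4), (3, 5)):
            assert leaf_covariance(caterpillar5, u, v) == pytest.approx(
                0.25 * math.exp(-d[u - 1, v - 1]))
        assert leaf_covariance(caterpillar5, 2, 2) == pytest.approx(0.25)

    def test_leaf_covariance_matches_pmf_moments(self, caterpillar5):
        p = character_pmf(caterpillar5)
        n = caterpillar5.n_leaves
        chars = np.array([[(s >> (n - 1 - i)) & 1 for i in range(n)]
                          for s in range(2 ** n)])
        mean = p @ chars
        for u, v in ((1, 3), (2, 5)):
            cov = p @ (chars[:, u - 1] * chars[:, v - 1]) - mean[u - 1] * mean[v - 1]
            assert cov == pytest.approx(leaf_covariance(caterpillar5, u, v),
                                        abs=1e-12)

    def test_cross_component_independence(self):
        f = parse_newick("(1:0.2,2:0.3);\n(3:0.5,4:0.1);")
        assert leaf_covariance(f, 1, 3) == 0.0

    def test_simulation_reproducible_and_calibrated(self, f1_tree):
        n = 100_000
        x = simulate_characters(f1_tree, n, seed=7)
        assert np.array_equal(x, simulate_characters(f1_tree, n, seed=7))
        # stationary marginals within a 4-sigma binomial band
        assert np.all(np.abs(x.mean(axis=0) - 0.5) < 4 * 0.5 / math.sqrt(n))
        # pairwise covariance vs exp(-l_uv)/4, MC tolerance
        emp = np.cov(x.T, bias=True)
        for u, v in ((1, 2), (1, 4)):
            assert emp[u - 1, v - 1] == pytest.approx(
                leaf_covariance(f1_tree, u, v), abs=5e-3)

    def test_simulation_chi_square_goodness_of_fit(self):
        t = parse_newick("(1:0.3,2:0.1,3:0.4,4:0.2);")
        n = 100_000
        x = simulate_characters(t, n, seed=11)
        idx = x @ (1 << np.arange(3, -1, -1))
        observed = np.bincount(idx, minlength=16)
        expected = character_pmf(t) * n
        stat = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(stat, df=15) > 0.01


class TestDivergences:
    def test_f_divergence_zero_at_equal(self, caterpillar5, rng):
        p = character_pmf(caterpillar5)
        for f in (lambda t: t * np.log(t), lambda t: -np.log(t),
                  lambda t: (np.sqrt(t) - 1) ** 2):
            assert f_divergence(p, p, f) == pytest.approx(0, abs=1e-14)

    def test_hellinger_two_routes_agree(self, rng):
        p = rng.dirichlet(np.ones(16))
        q = rng.dirichlet(np.ones(16))
        via_f = f_divergence(p, q, lambda t: (np.sqrt(t) - 1) ** 2)
        assert math.sqrt(via_f) == pytest.approx(hellinger_metric(p, q))

    def test_js_symmetric_and_nonnegative(self, rng):
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8))
        assert js_metric(p, q) == pytest.approx(js_metric(q, p))
        assert js_metric(p, q) > 0
        assert kl_divergence(p, q) > 0


class TestFisherMetric:
    def test_positive_definite_on_random_trees(self, rng):
        for _ in range(25):
            t = random_tree(5, rng=rng)
            g = fisher_information_two_state(t)
            assert np.linalg.eigvalsh(g).min() > 0

    def test_two_leaf_scalar_closed_form(self):
        l = 0.8
        t = parse_newick(f"(1:{l/2},2:{l/2});")
        g = fisher_information_two_state(t)[0, 0]
        # four pmf entries (1 +/- e^-l)/4, derivative -/+ e^-l / 4
        e = math.exp(-l)
        expected = 2 * (e / 4) ** 2 / ((1 + e) / 4) + 2 * (e / 4) ** 2 / ((1 - e) / 4)
        assert g == pytest.approx(expected)

    def test_kl_expansion_for_two_f_divergences(self, f1_tree, rng):
        # the quadratic form of g equals (2/f''(1)) D_f to third order,
        # for any f-divergence; checked with t log t (f''(1)=1) and
        # -log t (f''(1)=1)
        g = fisher_information_two_state(f1_tree)
        lv = f1_tree.length_vector()
        p0 = character_pmf(f1_tree)
        dl = rng.normal(size=7)
        dl *= 1e-3 / np.linalg.norm(dl)
        p1 = character_pmf(f1_tree.with_lengths(lv + dl))
        quad = dl @ g @ dl
        for f in (lambda t: t * np.log(t), lambda t: -np.log(t)):
            df = f_divergence(p1, p0, f)
            assert 2 * df == pytest.approx(quad, rel=1e-2)

    def test_saturation_drives_metric_to_zero(self):
        # increasing one edge length monotonically kills its own metric entry
        base = parse_newick("((1:0.1,2:0.1):0.3,3:0.1,(4:0.1,5:0.1):0.2);")
        lv = base.length_vector()
        vals = []
        for l6 in (0.5, 1.0, 2.0, 4.0, 8.0):
            lv2 = lv.copy()
            lv2[5] = l6
            g = fisher_information_two_state(base.with_lengths(lv2))
            vals.append(g[5, 5])
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-5


class TestChristoffel:
    def test_symmetry_and_fd_consistency(self, caterpillar5):
        gamma = christoffel_two_state(caterpillar5)
        assert np.allclose(gamma, gamma.transpose(0, 2, 1))
        g, dg = metric_and_derivative_two_state(caterpillar5)
        lv = caterpillar5.length_vector()
        eps = 1e-4
        for k in (1, 5):
            lp, lm = lv.copy(), lv.copy()
            lp[k] += eps
            lm[k] -= eps
            fd = (fisher_information_two_state(caterpillar5.with_lengths(lp))
                  - fisher_information_two_state(caterpillar5.with_lengths(lm))
                  ) / (2 * eps)
            assert np.abs(fd - dg[k]).max() < 1e-5
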