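"""NB dispersion estimation, exact test, BH adjustment and DE calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import binom

from cagepeaks import (
    bh_adjust,
    call_de_clusters,
    call_de_genes,
    estimate_common_dispersion,
    exact_test_nb,
)


def dirichlet_multinomial_pvalue(y1, y2, n1, n2, phi):
    """Independent closed-form oracle for the conditional NB test: given the
    total, the split follows a Dirichlet-multinomial law."""
    s = y1 + y2
    r1, r2 = n1 / phi, n2 / phi
    ys = np.arange(s + 1)
    lp = (
        gammaln(ys + r2) - gammaln(ys + 1) - gammaln(r2)
        + gammaln(s - ys + r1) - gammaln(s - ys + 1) - gammaln(r1)
        - (gammaln(s + r1 + r2) - gammaln(s + 1) - gammaln(r1 + r2))
    )
    pr = np.exp(lp)
    pr /= pr.sum()
    return min(1.0, pr[pr <= pr[y2] * (1 + 1e-10)].sum())


class TestDispersion:
    def test_poisson_data_gives_near_zero(self, rng):
        mu = np.exp(rng.uniform(np.log(5), np.log(500), 2000))
        y = rng.poisson(mu[:, None] * np.ones(4)[None, :])
        fit = estimate_common_dispersion(y, ["a", "a", "b", "b"], np.full(4, 1e6))
        assert fit.phi < 0.02

    def test_nb_dispersion_recovered(self):
        phis = []
        for seed in range(3):
            r = np.random.default_rng(100 + seed)
            mu = np.exp(r.uniform(np.log(5), np.log(500), 2000))
            g = r.gamma(1 / 0.2, 0.2, size=(2000, 4))
            y = r.poisson(g * mu[:, None])
            phis.append(
                estimate_common_dispersion(y, ["a", "a", "b", "b"], np.full(4, 1e6)).phi
            )
        assert 0.15 <= np.mean(phis) <= 0.25

    def test_identical_columns_zero(self, rng):
        y = np.tile(rng.integers(1, 100, 200)[:, None], (1, 4))
        fit = estimate_common_dispersion(y, ["a", "a", "b", "b"], np.full(4, 1e6))
        assert fit.phi == 0.0

    def test_single_replicate_default(self, rng):
        y = rng.poisson(50, size=(100, 2))
        with pytest.warns(UserWarning, match="one replicate"):
            fit = estimate_common_dispersion(y, ["a", "b"], np.full(2, 1e4))
        assert fit.phi == 0.1


class TestExactTest:
    def test_symmetric_counts(self):
        p, lfc, _ = exact_test_nb([5, 5], [5, 5], None, None, 0.1)
        assert lfc == 0.0
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_poisson_limit_conditional_binomial(self):
        # 0 vs 10, equal libraries: Binomial(10, 1/2) two-tail = 2/1024
        p, lfc, _ = exact_test_nb([0], [10], [100], [100], 0.0)
        assert p == pytest.approx(2 / 1024, abs=1e-12)
        assert lfc > 0

    def test_library_scale_invariance(self):
        # the conditional law depends on library-size proportions, not on the
        # absolute scale of the libraries
        p1, _, _ = exact_test_nb([3], [12], [1000], [1000], 0.0)
        p2, _, _ = exact_test_nb([3], [12], [2000], [2000], 0.0)
        assert p1 == pytest.approx(p2, rel=1e-9)
        p3, lfc3, _ = exact_test_nb([3, 4], [12, 9], [1000, 1500], [900, 1100], 0.1)
        p4, lfc4, _ = exact_test_nb([3, 4], [12, 9], [2000, 3000], [1800, 2200], 0.1)
        assert p3 == pytest.approx(p4, rel=1e-9)
        assert lfc3 == pytest.approx(lfc4, rel=1e-9)

    def test_matches_enumeration_at_phi_zero(self):
        for s in (1, 7, 23, 50):
            for y2 in range(s + 1):
                p, _, _ = exact_test_nb([s - y2], [y2], [500], [500], 0.0)
                pm = binom.pmf(np.arange(s + 1), s, 0.5)
                oracle = min(1.0, pm[pm <= pm[y2] * (1 + 1e-10)].sum())
                assert p == pytest.approx(oracle, abs=1e-9)

    def test_matches_dirichlet_multinomial_at_positive_phi(self):
        for s in (5, 17, 30):
            for y2 in range(s + 1):
                p, _, _ = exact_test_nb([s - y2], [y2], None, None, 0.25)
                assert p == pytest.approx(
                    dirichlet_multinomial_pvalue(s - y2, y2, 1, 1, 0.25), abs=1e-9
                )

    def test_zero_total(self):
        p, lfc, _ = exact_test_nb([0, 0], [0, 0], None, None, 0.1)
        assert (p, lfc) == (1.0, 0.0)

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            exact_test_nb([1], [2], None, None, -0.1)

    def test_power_monotone_in_fold_and_replicates(self):
        # detection rate should not decrease with the planted fold change or
        # with the number of replicates
        def rate(fold, n_rep, seed=0):
            r = np.random.default_rng(seed)
            hits = 0
            for _ in range(200):
                y1 = r.poisson(50, n_rep)
                y2 = r.poisson(50 * fold, n_rep)
                p, _, _ = exact_test_nb(y1, y2, None, None, 0.05)
                hits += p < 0.01
            return hits / 200

        assert rate(1.5, 2) <= rate(3, 2) <= rate(6, 2)
        assert rate(2, 2) <= rate(2, 4)


class TestBH:
    def test_step_up_example(self):
        assert list(bh_adjust([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_bounds_and_order(self, rng):
        p = rng.random(100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1)
        assert np.array_equal(np.argsort(p, kind="mergesort").argsort() >= 0,
                              np.ones(100, bool))
        # rank order preserved
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCalls:
    @pytest.mark.parametrize(
        "lfc,padj,sig",
        [(2.0, 0.01, False), (2.5, 0.05, False), (2.5, 0.01, True), (-2.5, 0.01, True)],
    )
    def test_strict_boundaries(self, lfc, padj, sig):
        res = pd.DataFrame({"logFC": [lfc], "padj": [padj]})
        assert bool(call_de_clusters(res)["significant"].iloc[0]) is sig

    def test_gene_calls_with_trigger(self):
        calls = pd.DataFrame(
            {
                "significant": [True, False, False],
                "peak_class": ["top", "bottom", "top"],
            },
            index=["t1", "b1", "t2"],
        )
        assignments = pd.DataFrame(
            {
                "cluster": ["t1", "b1", "t2", "t1"],
                "gene": ["gA", "gA", "gB", "gC"],
                "distance": [0, 0, 0, 10],
            }
        )
        genes = call_de_genes(calls, assignments).set_index("gene")
        assert bool(genes.loc["gA", "called"]) and genes.loc["gA", "trigger"] == "top"
        assert not genes.loc["gB", "called"]
        assert bool(genes.loc["gC", "called"])  # shared cluster calls both genes
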