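"""DFE mixtures, bootstrap null, KS comparison, causal probability, carriers."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_point_posterior, make_spread_posterior
from lofsel.dfe import (
    CohortCounts,
    GeneWeights,
    bootstrap_null_pvalue,
    build_dfe,
    carrier_rates,
    causal_probability,
    compare_dfes,
    dfe_by_frequency_bin,
    dfe_exceedance,
)


@pytest.fixture()
def two_point_dfe():
    posts = [make_point_posterior("hi", 0.5, 0.4), make_point_posterior("lo", 0.5, 0.002)]
    weights = GeneWeights({"hi": 0.25, "lo": 0.75})
    return build_dfe(posts, weights), posts, weights


class TestBuildAndExceedance:
    def test_point_mass_arithmetic(self, two_point_dfe):
        dfe, _, _ = two_point_dfe
        assert dfe_exceedance(dfe, 0.1) == pytest.approx(0.25)
        assert dfe_exceedance(dfe, 0.0005) == pytest.approx(1.0)

    def test_single_gene_mixture_is_that_posterior(self):
        post = make_spread_posterior("g", 0.01, seed=1)
        dfe = build_dfe([post], GeneWeights({"g": 1.0}))
        assert np.allclose(np.sort(dfe.hs), np.sort(post.hs))
        assert dfe.mean_hs() == pytest.approx(post.mean_hs())

    def test_exceedance_matches_brute_force_pooling(self):
        rng = np.random.default_rng(2)
        posts = [make_spread_posterior(f"g{i}", 10 ** rng.uniform(-4, -0.5), seed=i)
                 for i in range(20)]
        w = rng.uniform(0.1, 1, 20)
        weights = GeneWeights({f"g{i}": w[i] for i in range(20)})
        dfe = build_dfe(posts, weights)
        # oracle: pool every particle into one flat list with explicit weights
        pool_hs, pool_w = [], []
        for i, p in enumerate(posts):
            pool_hs.append(p.hs)
            pool_w.append(np.full(p.hs.size, w[i] / w.sum() / p.hs.size))
        pool_hs, pool_w = np.concatenate(pool_hs), np.concatenate(pool_w)
        for t in (0.001, 0.01, 0.1):
            assert dfe_exceedance(dfe, t) == pytest.approx(
                float(pool_w[pool_hs > t].sum()), rel=1e-9
            )

    def test_exceedance_monotone_in_threshold(self, two_point_dfe):
        dfe, _, _ = two_point_dfe
        ts = np.logspace(-5, 0, 30)
        vals = [dfe_exceedance(dfe, t) for t in ts]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_missing_posterior_rejected(self):
        with pytest.raises(KeyError):
            build_dfe([make_point_posterior("a", 0.5, 0.1)], GeneWeights({"a": 1, "b": 1}))


class TestBootstrapNullPvalue:
    def _setup(self, n_genes=30, seed=3):
        rng = np.random.default_rng(seed)
        posts = [make_spread_posterior(f"g{i}", 10 ** rng.uniform(-4, -0.5), seed=100 + i)
                 for i in range(n_genes)]
        opp = GeneWeights({f"g{i}": rng.uniform(0.5, 2.0) for i in range(n_genes)})
        return posts, opp

    def test_extreme_cohort_gets_minimal_pvalue(self):
        posts, opp = self._setup()
        means = {p.gene_id: p.mean_hs() for p in posts}
        top = max(means, key=means.get)
        cohort = CohortCounts({top: 10})
        p, nulls = bootstrap_null_pvalue(cohort, opp, posts, B=200, seed=4)
        assert p == pytest.approx(1 / 201)
        assert nulls.size == 200

    def test_enumeration_on_three_gene_panel(self):
        # tiny panel with cohort size 1: the null means are gene means drawn
        # by weight, so the p-value is enumerable
        posts = [make_point_posterior(g, 0.5, s) for g, s in
                 [("a", 0.002), ("b", 0.02), ("c", 0.2)]]
        opp = GeneWeights({"a": 1.0, "b": 1.0, "c": 1.0})
        p, nulls = bootstrap_null_pvalue(CohortCounts({"b": 1}), opp, posts, B=3000, seed=5)
        # observed mean 0.01: nulls >= 0.01 are draws of b or c (~2/3)
        expected = (1 + np.sum(nulls >= 0.01)) / 3001
        assert p == pytest.approx(expected)
        assert p == pytest.approx(2 / 3, abs=0.05)

    def test_null_cohorts_give_uniformish_pvalues(self):
        posts, opp = self._setup()
        ids = [p.gene_id for p in posts]
        probs = np.array([w for _, w in opp.items()])
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(60):
            draw = rng.choice(ids, size=25, p=probs)
            counts = pd.Series(draw).value_counts().to_dict()
            p, _ = bootstrap_null_pvalue(CohortCounts(counts), opp, posts, B=99, seed=rep)
            ps.append(p)
        ps = np.asarray(ps)
        # under the null the rejection rate at 5% stays near 5%
        assert np.mean(ps <= 0.05) < 0.2
        assert 0.25 < ps.mean() < 0.75

    def test_relabeling_invariance(self):
        posts, opp = self._setup(n_genes=8)
        cohort = CohortCounts({"g0": 3, "g5": 2})
        p1, _ = bootstrap_null_pvalue(cohort, opp, posts, B=200, seed=7)
        mapping = {f"g{i}": f"x{i}" for i in range(8)}
        posts2 = [make_spread_posterior(mapping[p.gene_id], 1, seed=0) for p in posts]
        # rebuild with renamed ids but identical content
        for p_old, p_new in zip(posts, posts2):
            p_new.h, p_new.s, p_new.weight = p_old.h, p_old.s, p_old.weight
        opp2 = GeneWeights({mapping[g]: w for g, w in opp.items()})
        cohort2 = CohortCounts({"x0": 3, "x5": 2})
        p2, _ = bootstrap_null_pvalue(cohort2, opp2, posts2, B=200, seed=7)
        assert p1 == p2

    def test_rejects_empty_cohort_and_zero_bootstrap(self):
        posts, opp = self._setup(n_genes=3)
        with pytest.raises(ValueError):
            bootstrap_null_pvalue(CohortCounts({}), opp, posts, B=10)
        with pytest.raises(ValueError):
            bootstrap_null_pvalue(CohortCounts({"g0": 1}), opp, posts, B=0)


class TestCompareDfes:
    def test_self_comparison_not_significant(self):
        rng = np.random.default_rng(8)
        posts = [make_spread_posterior(f"g{i}", 10 ** rng.uniform(-3, -0.3), seed=200 + i)
                 for i in range(25)]
        w = GeneWeights({f"g{i}": 1.0 for i in range(25)})
        dfe = build_dfe(posts, w)
        ps = [compare_dfes(dfe, dfe, B=200, seed=k) for k in range(7)]
        assert np.median(ps) > 0.1

    def test_distinct_point_masses_give_minimal_ks_pvalue(self):
        a = build_dfe([make_point_posterior("a", 0.5, 0.4)], GeneWeights({"a": 1}))
        b = build_dfe([make_point_posterior("b", 0.5, 0.02)], GeneWeights({"b": 1}))
        # areas are the constants 1 and 0: KS statistic is 1, p at its floor
        p = compare_dfes(a, b, B=100, seed=9)
        assert p < 1e-6

    def test_interval_is_open_at_lower_bound(self):
        at_boundary = build_dfe([make_point_posterior("a", 0.5, 0.2)], GeneWeights({"a": 1}))
        assert at_boundary.interval_mass(0.1, 1.0) == 0.0  # hs exactly 0.1 excluded
        above = build_dfe([make_point_posterior("b", 0.5, 0.21)], GeneWeights({"b": 1}))
        assert above.interval_mass(0.1, 1.0) == pytest.approx(1.0)


class TestCausalProbability:
    def test_enrichment_value(self):
        assert causal_probability(0.2, 0.5) == pytest.approx(0.6)

    def test_no_enrichment_is_zero(self):
        assert causal_probability(0.3, 0.3) == pytest.approx(0.0)

    def test_depleted_cohort_warns_negative(self):
        with pytest.warns(UserWarning):
            assert causal_probability(0.4, 0.2) == pytest.approx(-1.0)

    def test_zero_cohort_mass_rejected(self):
        with pytest.raises(ValueError):
            causal_probability(0.2, 0.0)

    @pytest.mark.parametrize("k", [1.5, 2.0, 10.0])
    def test_enrichment_identity(self, k):
        p = 0.05
        assert causal_probability(p, p * k) / (1 - 1 / k) == pytest.approx(1.0)


class TestCarrierRates:
    def test_population_rates(self):
        x, y = carrier_rates(70, 1e-3, 0.2)
        assert x == pytest.approx(14.29, rel=1e-3)
        assert y == pytest.approx(71.4, rel=1e-3)

    def test_zero_dnm_rate_rejected(self):
        with pytest.raises(ZeroDivisionError):
            carrier_rates(0, 1e-3, 0.2)


class TestDfeByFrequencyBin:
    def test_single_gene_bins_equal_gene_posterior(self):
        post = make_spread_posterior("g", 0.01, seed=10)
        variants = pd.DataFrame({"gene_id": ["g"] * 4,
                                 "allele_freq": [1e-5, 1e-4, 1e-3, 1e-2]})
        out = dfe_by_frequency_bin(variants, [1e-4, 1e-2], [post])
        for dfe in out.values():
            assert dfe.mean_hs() == pytest.approx(post.mean_hs())

    def test_empty_bin_warns_and_returns_none(self):
        post = make_point_posterior("g", 0.5, 0.1)
        variants = pd.DataFrame({"gene_id": ["g"], "allele_freq": [0.5]})
        with pytest.warns(UserWarning):
            out = dfe_by_frequency_bin(variants, [1e-4, 1.0], [post])
        assert out[1e-4] is None
        assert out[1.0] is not None

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            dfe_by_frequency_bin(pd.DataFrame({"gene_id": [], "allele_freq": []}),
                                 [0.1, 0.01], [])
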