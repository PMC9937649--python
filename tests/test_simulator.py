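"""Wright-Fisher simulator: mutation-rate algebra, oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lofsel.demography import constant_schedule
from lofsel.simulator import (
    SampleSpec,
    SimParams,
    deterministic_recursion,
    simulate_lof_frequency,
    simulate_sample_counts,
    split_x_mutation_rates,
)


class TestSplitXMutationRates:
    def test_symmetric_at_alpha_one(self):
        r = split_x_mutation_rates(1e-6, alpha=1.0)
        assert r.mu_m == pytest.approx(1e-6)
        assert r.mu_f == pytest.approx(1e-6)

    def test_default_male_bias(self):
        r = split_x_mutation_rates(1e-6, alpha=3.5)
        assert r.mu_m == pytest.approx(1.9091e-6, rel=1e-4)
        assert r.mu_f == pytest.approx(5.4545e-7, rel=1e-4)

    @given(
        mu=st.floats(1e-12, 1e-3),
        alpha=st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_total_input_conserved(self, mu, alpha):
        # two maternal transmissions per paternal one: 2*mu_f + mu_m == 3*mu
        r = split_x_mutation_rates(mu, alpha)
        assert 2 * r.mu_f + r.mu_m == pytest.approx(3 * mu, rel=1e-12)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            split_x_mutation_rates(1e-6, alpha=0.0)


class TestDeterministicRecursion:
    def test_mutation_selection_balance(self):
        # equilibrium ~ mu / hs for partially dominant deleterious alleles
        traj = deterministic_recursion(SimParams(mu=1e-6, h=0.5, s=0.02), 20_000)
        assert traj[-1] == pytest.approx(1e-4, rel=0.01)

    def test_heterozygote_lethal_equilibrium_is_mu(self):
        traj = deterministic_recursion(SimParams(mu=1e-6, h=1.0, s=1.0), 1000)
        assert traj[-1] == pytest.approx(1e-6, rel=0.02)

    def test_neutral_two_way_mutation_limit(self):
        # stationary mean u / (u + v) with v = 0.01 u
        p = SimParams(mu=1e-4, h=0.0, s=0.0)  # large mu so the horizon is short
        traj = deterministic_recursion(p, 200_000)
        assert traj[-1] == pytest.approx(1 / 1.01, rel=1e-3)

    def test_x_equilibrium_matches_classic_formula(self):
        # hemizygous-selection balance: q ~ 3 mu / (s (2h + 1))
        p = SimParams(mu=1e-6, h=0.5, s=0.02, mode="x_nonpar")
        traj = deterministic_recursion(p, 20_000)
        qf, qm = traj[-1]
        expected = 3e-6 / (0.02 * 2.0)
        assert qf == pytest.approx(expected, rel=0.05)
        assert qm == pytest.approx(expected, rel=0.05)


class TestStochasticSimulator:
    def test_no_mutation_means_no_alleles(self, tiny_schedule):
        res = simulate_lof_frequency(
            SimParams(mu=0.0, h=0.5, s=0.1), tiny_schedule, SampleSpec(100), 50, seed=1
        )
        assert all(r.pop_freq == 0.0 and r.sample_count == 0 for r in res)

    def test_seed_determinism(self, tiny_schedule):
        args = (SimParams(mu=1e-5, h=0.5, s=0.01), tiny_schedule, SampleSpec(500), 30)
        a = simulate_lof_frequency(*args, seed=42)
        b = simulate_lof_frequency(*args, seed=42)
        c = simulate_lof_frequency(*args, seed=43)
        assert a == b
        assert a != c

    def test_frequencies_within_bounds(self, tiny_schedule):
        res = simulate_lof_frequency(
            SimParams(mu=1e-3, h=0.0, s=0.0), tiny_schedule, SampleSpec(200), 200, seed=2
        )
        for r in res:
            assert 0.0 <= r.pop_freq <= 1.0
            assert 0 <= r.sample_count <= 200

    def test_mean_matches_recursion_under_selection(self):
        # mutation-selection-drift balance at 2N*hs >> 1: the stochastic mean
        # equals the deterministic fixed point within 3 Monte-Carlo SE
        sched = constant_schedule(10_000, span=5, burnin_generations=5000)
        params = SimParams(mu=1e-6, h=0.5, s=0.02)
        res = simulate_lof_frequency(params, sched, SampleSpec(20_000), 6000, seed=3)
        freqs = np.array([r.pop_freq for r in res])
        expected = deterministic_recursion(params, 5000)[-1]
        se = freqs.std(ddof=1) / np.sqrt(freqs.size)
        assert abs(freqs.mean() - expected) < 3 * se

    def test_neutral_mean_matches_two_way_recursion(self):
        # with hs = 0 the mean trajectory is the deterministic mutation
        # recursion E[q_{t+1}] = E[q_t](1-v) + (1-E[q_t])u
        sched = constant_schedule(20_000, span=5, burnin_generations=2000)
        params = SimParams(mu=5e-5, h=0.0, s=0.0)
        res = simulate_lof_frequency(params, sched, SampleSpec(1000), 4000, seed=4)
        freqs = np.array([r.pop_freq for r in res])
        expected = deterministic_recursion(params, 2005)[-1]
        se = freqs.std(ddof=1) / np.sqrt(freqs.size)
        assert abs(freqs.mean() - expected) < 3 * se

    def test_par_mode_distributionally_identical_to_autosome(self, small_schedule):
        pa = SimParams(mu=2e-5, h=0.5, s=0.05, mode="autosome")
        pp = SimParams(mu=2e-5, h=0.5, s=0.05, mode="par")
        a = simulate_lof_frequency(pa, small_schedule, SampleSpec(2000), 40, seed=9)
        b = simulate_lof_frequency(pp, small_schedule, SampleSpec(2000), 40, seed=9)
        assert a == b  # same code path, same seed

    def test_x_mean_matches_two_sex_recursion(self):
        sched = constant_schedule(10_000, span=5, burnin_generations=4000)
        params = SimParams(mu=2e-6, h=0.5, s=0.05, mode="x_nonpar")
        res = simulate_lof_frequency(params, sched, SampleSpec(9000), 5000, seed=5)
        wavg = np.array([r.pop_freq for r in res])
        qf, qm = deterministic_recursion(params, 4000)[-1]
        expected = (2 * qf + qm) / 3.0
        se = wavg.std(ddof=1) / np.sqrt(wavg.size)
        assert abs(wavg.mean() - expected) < 3 * se

    def test_x_viability_toggle_within_noise(self):
        # the fertility-stage mutation variant must not discernibly shift
        # the equilibrium frequency
        sched = constant_schedule(5000, span=5, burnin_generations=3000)
        base = dict(mu=5e-6, h=0.5, s=0.05, mode="x_nonpar")
        a = simulate_lof_frequency(SimParams(**base), sched, SampleSpec(5000), 4000, seed=6)
        b = simulate_lof_frequency(
            SimParams(**base, x_parental_mutation=True), sched, SampleSpec(5000), 4000, seed=7
        )
        fa = np.array([r.pop_freq for r in a])
        fb = np.array([r.pop_freq for r in b])
        se = np.sqrt(fa.var(ddof=1) / fa.size + fb.var(ddof=1) / fb.size)
        assert abs(fa.mean() - fb.mean()) < 3 * se

    def test_sample_spec_sex_counts_validated(self):
        with pytest.raises(ValueError):
            SampleSpec(100, n_female=10, n_male=5)
        spec = SampleSpec(100, n_female=40, n_male=20)
        assert spec.x_chromosome_split() == (80, 20)
        assert SampleSpec(90).x_chromosome_split() == (60, 30)

    def test_neutral_sfs_matches_coalescent_oracle(self):
        # singleton fraction of segregating neutral sites under a constant-N
        # model, forward simulation vs an independent msprime branch-length
        # frequency spectrum
        import msprime

        n_pop, n_sample = 2000, 200
        sched = constant_schedule(n_pop, span=5, burnin_generations=25_000)
        reps = 20_000
        counts = simulate_sample_counts(
            1e-6, np.zeros(reps), np.zeros(reps), "autosome",
            sched, SampleSpec(n_sample), seed=21,
        )
        # restrict to derived counts <= n/2: the forward model's two-way
        # mutation keeps a class of sites barely polymorphic near fixation
        # that infinite-sites theory lacks
        low = counts[(counts >= 1) & (counts <= n_sample // 2)]
        forward = float(np.mean(low == 1))

        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=n_pop)
        sing = total = 0.0
        for ts in msprime.sim_ancestry(
            samples=n_sample // 2, demography=dem, ploidy=2,
            num_replicates=400, random_seed=22,
        ):
            afs = ts.allele_frequency_spectrum(
                mode="branch", polarised=True, span_normalise=False
            )
            sing += afs[1]
            total += afs[1 : n_sample // 2 + 1].sum()
        oracle = sing / total
        se = math.sqrt(forward * (1 - forward) / low.size)
        assert forward == pytest.approx(oracle, abs=max(3 * se, 0.015))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(mu=-1e-9, h=0.5, s=0.1)
        with pytest.raises(ValueError):
            SimParams(mu=1e-6, h=1.5, s=0.1)
        with pytest.raises(ValueError):
            SimParams(mu=1e-6, h=0.5, s=0.1, mode="y")
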