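"""Shared fixtures: small demographic models and reusable posteriors."""

import numpy as np
import pytest

from lofsel.demography import Epoch, EpochSchedule, constant_schedule
from lofsel.inference import PosteriorSample


@pytest.fixture(scope="session")
def tiny_schedule():
    """Constant N=1000, short burn-in: cheap drift-dominated model."""
    return constant_schedule(1000, span=5, burnin_generations=5000)


@pytest.fixture(scope="session")
def small_schedule():
    """Constant N=2000 with a full 10N burn-in: equilibrated test model."""
    return constant_schedule(2000, span=5, burnin_generations=20_000)


@pytest.fixture(scope="session")
def growth_schedule():
    """A scaled-down two-epoch growth history (ancestral 2000, recent 50000)."""
    return EpochSchedule(
        epochs=(Epoch(60, 10, 2000), Epoch(10, 0, 50_000)),
        burnin_generations=20_000,
        burnin_size=2000,
    )


def make_point_posterior(gene_id, h, s, n=100):
    """Degenerate posterior concentrated at a single (h, s)."""
    return PosteriorSample(
        gene_id=gene_id,
        h=np.full(n, h),
        s=np.full(n, s),
        weight=np.ones(n),
        mode="autosome",
        epsilons=(0.0,),
        acceptance_counts=(n,),
    )


def make_spread_posterior(gene_id, hs_center, rel_spread=0.3, n=400, seed=0):
    """Posterior with log-normal spread around hs_center (h fixed at 0.5)."""
    rng = np.random.default_rng(seed)
    hs = hs_center * np.exp(rng.normal(0, rel_spread, n))
    hs = np.clip(hs, 1e-8, 1.0)
    return PosteriorSample(
        gene_id=gene_id,
        h=np.full(n, 0.5),
        s=np.clip(hs / 0.5, 0, 1),
        weight=np.ones(n),
        mode="autosome",
        epsilons=(0.0,),
        acceptance_counts=(n,),
    )
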