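"""ABC-SMC inference of the heterozygous fitness cost hs per gene.

The observable is the aggregate LOF allele frequency ``q`` of a gene in a
sample of ``2n`` chromosomes.  Proposals (h, s) are drawn from the prior
h ~ U(0, 1), log10(s) ~ U(-6, 0); each proposal is pushed through the forward
Wright-Fisher simulator to produce a simulated sample frequency ``q_i``, and
is retained when ``|q_i - q| <= eps``.  The tolerance follows the schedule
[10/2n, 5/2n, 2/2n, 0]: the first stage proposes from the prior, later stages
from weight-resampled, kernel-perturbed particles of the previous stage with
standard sequential-Monte-Carlo importance weights, and the final stage
(eps = 0, exact match of sampled allele counts) yields draws from the
posterior P(h, s | q).

Only the product hs is identifiable from autosomal data; h and s are sampled
separately so that autosomal and X-linked results (where males are hemizygous
and s enters on its own) share a prior on hs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom as _binom
from scipy.stats import gaussian_kde

from .demography import EpochSchedule
from .simulator import SampleSpec, simulate_pop_freqs, simulate_sample_counts

__all__ = [
    "PriorSpec",
    "ToleranceSchedule",
    "PosteriorSample",
    "PosteriorSummary",
    "sample_prior",
    "prior_exceedance",
    "prior_median_hs",
    "default_tolerance_schedule",
    "abc_smc_infer",
    "rejection_abc",
    "summarize_posterior",
    "sex_averaged_selection",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors: h uniform, s log10-uniform."""

    log10_s_bounds: tuple[float, float] = (-6.0, 0.0)
    h_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.log10_s_bounds, self.h_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("prior bounds must be finite with lower < upper")


@dataclass(frozen=True)
class ToleranceSchedule:
    """Strictly decreasing frequency tolerances, ending at exactly 0."""

    epsilons: tuple[float, ...]

    def __post_init__(self) -> None:
        eps = tuple(float(e) for e in self.epsilons)
        object.__setattr__(self, "epsilons", eps)
        if not eps or eps[-1] != 0.0:
            raise ValueError("tolerance schedule must end at 0")
        if any(a <= b for a, b in zip(eps, eps[1:])):
            raise ValueError("tolerance schedule must be strictly decreasing")


def default_tolerance_schedule(n_individuals: int) -> ToleranceSchedule:
    """[10/2n, 5/2n, 2/2n, 0] for a sample of ``n_individuals`` diploids.

    For X-linked genes pass the chromosome count divided by two is not
    meaningful; use ``tolerance_schedule_for_chromosomes`` instead.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    return tolerance_schedule_for_chromosomes(2 * n_individuals)


def tolerance_schedule_for_chromosomes(n_chrom: int) -> ToleranceSchedule:
    return ToleranceSchedule(tuple(k / n_chrom for k in (10.0, 5.0, 2.0)) + (0.0,))


def sample_prior(prior: PriorSpec, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw (h, s) pairs from the prior; s = 10**u with u uniform."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    h = rng.uniform(*prior.h_bounds, size=n)
    s = 10.0 ** rng.uniform(*prior.log10_s_bounds, size=n)
    return h, s


def prior_exceedance(t: float) -> float:
    """P(h*s > t) under the default prior, in closed form.

    With h ~ U(0,1) and log10 s ~ U(-6, 0):
    P(hs > t) = (1/6) * (-log10 t - (1 - t) / ln 10) for t in [1e-6, 1].
    (Integrate P(s > t/h) = -log10(t/h)/6 over h in (t, 1).)
    """
    if not (1e-6 <= t <= 1.0):
        raise ValueError("t must be in [1e-6, 1]")
    return (1.0 / 6.0) * (-math.log10(t) - (1.0 - t) / LN10)


def prior_median_hs() -> float:
    """Median of h*s under the default prior (root of exceedance = 1/2)."""
    from scipy.optimize import brentq

    return float(brentq(lambda t: prior_exceedance(t) - 0.5, 1e-6, 1.0, xtol=1e-12))


def sex_averaged_selection(h: float, s: float) -> float:
    """Average fitness cost of losing one copy on the X: (hs + s) / 2."""
    return (h * s + s) / 2.0


@dataclass
class PosteriorSample:
    """Accepted (h, s) particles for one gene."""

    gene_id: str
    h: np.ndarray
    s: np.ndarray
    weight: np.ndarray
    mode: str
    epsilons: tuple[float, ...]
    acceptance_counts: tuple[int, ...]
    n_proposals: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        if w.size != self.h.size or self.s.size != self.h.size:
            raise ValueError("h, s, weight must have equal length")
        if self.h.size == 0:
            raise ValueError("empty particle set")
        self.weight = w / w.sum()

    @property
    def hs(self) -> np.ndarray:
        return self.h * self.s

    def mean_hs(self) -> float:
        return float(np.sum(self.weight * self.hs))


@dataclass(frozen=True)
class PosteriorSummary:
    gene_id: str
    map_hs: float
    ci95: tuple[float, float]
    p_hs_gt: dict[float, float]
    mean_hs: float
    sex_averaged_map: float | None = None
    sex_averaged_ci95: tuple[float, float] | None = None


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(np.atleast_1d(q), cw, x)


def _kde_map(values: np.ndarray, weights: np.ndarray, support: tuple[float, float]) -> float:
    """Mode of a weighted Gaussian KDE on log10(values) over ``support``."""
    logv = np.log10(np.clip(values, 10.0 ** support[0], 10.0 ** support[1]))
    if np.ptp(logv) < 1e-12:  # degenerate posterior: KDE undefined
        return float(10.0 ** logv[0])
    kde = gaussian_kde(logv, bw_method="silverman", weights=weights)
    grid = np.linspace(support[0], support[1], 512)
    dens = kde(grid)
    return float(10.0 ** grid[np.argmax(dens)])


def summarize_posterior(
    post: PosteriorSample,
    thresholds: tuple[float, ...] = (0.01, 0.1),
    prior: PriorSpec = PriorSpec(),
) -> PosteriorSummary:
    """MAP (KDE mode on log10 hs), 95% CI, and exceedance probabilities.

    For non-PAR X genes the sex-averaged cost (hs + s)/2 is summarized too.
    """
    hs = post.hs
    w = post.weight
    # density evaluated on log10(hs) over the prior's log10(s) support;
    # particles with hs below the floor are clipped onto the boundary
    support = prior.log10_s_bounds
    map_hs = _kde_map(hs, w, support)
    ci = _weighted_quantile(hs, w, [0.025, 0.975])
    map_hs = float(np.clip(map_hs, ci[0], ci[1]))
    p_gt = {t: float(np.sum(w[hs > t])) for t in thresholds}
    out = dict(
        gene_id=post.gene_id,
        map_hs=map_hs,
        ci95=(float(ci[0]), float(ci[1])),
        p_hs_gt=p_gt,
        mean_hs=post.mean_hs(),
    )
    if post.mode == "x_nonpar":
        sa = (post.h * post.s + post.s) / 2.0
        sa_map = _kde_map(sa, w, (support[0], math.log10(1.0)))
        sa_ci = _weighted_quantile(sa, w, [0.025, 0.975])
        out["sex_averaged_map"] = float(np.clip(sa_map, sa_ci[0], sa_ci[1]))
        out["sex_averaged_ci95"] = (float(sa_ci[0]), float(sa_ci[1]))
    return PosteriorSummary(**out)


def _snap_to_grid(q_obs: float, n_chrom: int) -> int:
    count = int(round(q_obs * n_chrom))
    if abs(count / n_chrom - q_obs) > 1e-12:
        logger.warning(
            "q_obs=%g is not on the %d-chromosome frequency grid; snapped to %d/%d",
            q_obs, n_chrom, count, n_chrom,
        )
    return count


def abc_smc_infer(
    q_obs: float,
    mu: float,
    mode: str,
    schedule: EpochSchedule,
    sample: SampleSpec,
    prior: PriorSpec = PriorSpec(),
    tolerances: ToleranceSchedule | None = None,
    n_accept: int = 50_000,
    seed: int = 0,
    *,
    gene_id: str = "gene",
    alpha: float = 3.5,
    back_mu_factor: float = 0.01,
    burnin_with_selection: bool = True,
    batch_size: int | None = None,
    max_proposals_per_stage: int = 20_000_000,
) -> PosteriorSample:
    """Sequential-Monte-Carlo ABC posterior for one gene.

    At each tolerance, particles are accumulated until ``n_accept``
    acceptances.  Stage 0 proposes from the prior; stage k > 0 resamples the
    previous particles by weight and perturbs them with a component-wise
    uniform kernel on (log10 s, h) of width half the previous particle range,
    reflected at the prior bounds; importance weights are prior density over
    the kernel mixture.  ``eps = 0`` requires exact equality of sampled
    allele counts, so ``q_obs`` is snapped to the nearest count / 2n (with a
    warning when it is off-grid).

    Raises ``ValueError`` for ``mu <= 0`` (genes with no LOF mutation rate
    carry no information and are excluded upstream, mirroring the exclusion
    of zero-rate genes from the analysis).
    """
    if mu <= 0:
        raise ValueError("mu must be > 0; zero-rate genes are excluded from inference")
    if not 0.0 <= q_obs <= 1.0:
        raise ValueError("q_obs must be in [0, 1]")
    if n_accept < 1:
        raise ValueError("n_accept must be >= 1")
    if tolerances is None:
        tolerances = tolerance_schedule_for_chromosomes(sample.n_chrom)
    obs_count = _snap_to_grid(q_obs, sample.n_chrom)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xABC]))
    if batch_size is None:
        batch_size = max(2 * n_accept, 1000)

    lo_ls, hi_ls = prior.log10_s_bounds
    lo_h, hi_h = prior.h_bounds

    def log_prior_ok(ls, hh):
        return (ls >= lo_ls) & (ls <= hi_ls) & (hh >= lo_h) & (hh <= hi_h)

    # On autosomes/PAR the terminal sampling stage (count ~ Binomial(2n,
    # q_pop)) is integrated out analytically: a proposal is accepted with
    # probability P(|count - obs| <= band | q_pop) / M, with M the maximum of
    # that probability over q_pop.  This targets exactly the same posterior
    # as simulating the count and comparing it, but keeps acceptance rates
    # workable when the observed count is large.  On the X the count is a sum
    # of two binomials and is simulated literally.
    analytic_sampling = mode in ("autosome", "par")

    def _band_prob(q: np.ndarray, k: int) -> np.ndarray:
        n = sample.n_chrom
        if k == 0:
            return _binom.pmf(obs_count, n, q)
        hi = min(obs_count + k, n)
        lo = obs_count - k - 1
        upper = _binom.cdf(hi, n, q)
        lower = _binom.cdf(lo, n, q) if lo >= 0 else 0.0
        return upper - lower

    prev_ls = prev_h = prev_w = None
    acc_counts: list[int] = []
    n_props: list[int] = []
    for stage, eps in enumerate(tolerances.epsilons):
        tol_counts = eps * sample.n_chrom + 1e-9  # acceptance band in counts
        if analytic_sampling:
            k_band = int(round(eps * sample.n_chrom))
            qgrid = np.unique(
                np.clip(
                    np.linspace(
                        (obs_count - k_band - 2) / sample.n_chrom,
                        (obs_count + k_band + 2) / sample.n_chrom,
                        65,
                    ),
                    0.0,
                    1.0,
                )
            )
            band_max = float(_band_prob(qgrid, k_band).max()) * (1.0 + 1e-9)
        got_ls = np.empty(0)
        got_h = np.empty(0)
        got_w = np.empty(0)
        n_prop = 0
        if stage > 0:
            span_ls = max(np.ptp(prev_ls), 1e-3)
            span_h = max(np.ptp(prev_h), 1e-3)
            half_ls, half_h = span_ls / 4.0, span_h / 4.0  # kernel half-width
        while got_ls.size < n_accept:
            if n_prop >= max_proposals_per_stage:
                raise RuntimeError(
                    f"acceptance budget exhausted at eps={eps} "
                    f"({got_ls.size}/{n_accept} after {n_prop} proposals)"
                )
            m = batch_size
            if stage == 0:
                ls = rng.uniform(lo_ls, hi_ls, m)
                hh = rng.uniform(lo_h, hi_h, m)
            else:
                idx = rng.choice(prev_ls.size, size=m, p=prev_w)
                ls = prev_ls[idx] + rng.uniform(-half_ls, half_ls, m)
                hh = prev_h[idx] + rng.uniform(-half_h, half_h, m)
                ls = _reflect(ls, lo_ls, hi_ls)
                hh = _reflect(hh, lo_h, hi_h)
            if analytic_sampling:
                pop = simulate_pop_freqs(
                    mu, hh, 10.0 ** ls, mode, schedule,
                    int(rng.integers(2**31 - 1)),
                    back_mu_factor=back_mu_factor,
                    burnin_with_selection=burnin_with_selection,
                )
                p_acc = _band_prob(pop, k_band)
                ok = rng.random(m) * band_max < p_acc
            else:
                counts = simulate_sample_counts(
                    mu, hh, 10.0 ** ls, mode, schedule, sample,
                    int(rng.integers(2**31 - 1)),
                    alpha=alpha, back_mu_factor=back_mu_factor,
                    burnin_with_selection=burnin_with_selection,
                )
                ok = np.abs(counts - obs_count) <= tol_counts
            n_prop += m
            if not ok.any():
                continue
            a_ls, a_h = ls[ok], hh[ok]
            if stage == 0:
                w = np.ones(a_ls.size)
            else:
                # prior is uniform on (log10 s, h): weight = 1 / kernel mixture
                dls = np.abs(a_ls[:, None] - prev_ls[None, :])
                dh = np.abs(a_h[:, None] - prev_h[None, :])
                k = ((dls <= half_ls + 1e-12) & (dh <= half_h + 1e-12)).astype(float)
                mix = k @ prev_w
                w = np.where(mix > 0, 1.0 / np.maximum(mix, 1e-300), 0.0)
            got_ls = np.concatenate([got_ls, a_ls])
            got_h = np.concatenate([got_h, a_h])
            got_w = np.concatenate([got_w, w])
        got_ls, got_h, got_w = got_ls[:n_accept], got_h[:n_accept], got_w[:n_accept]
        got_w = got_w / got_w.sum()
        prev_ls, prev_h, prev_w = got_ls, got_h, got_w
        acc_counts.append(int(got_ls.size))
        n_props.append(n_prop)
        # adapt batch size to the observed acceptance rate
        rate = max(got_ls.size / n_prop, 1e-4)
        batch_size = int(np.clip(n_accept / rate * 1.2, 1000, 500_000))
    return PosteriorSample(
        gene_id=gene_id,
        h=prev_h,
        s=10.0 ** prev_ls,
        weight=prev_w,
        mode=mode,
        epsilons=tolerances.epsilons,
        acceptance_counts=tuple(acc_counts),
        n_proposals=tuple(n_props),
    )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def rejection_abc(
    q_obs: float,
    mu: float,
    mode: str,
    schedule: EpochSchedule,
    sample: SampleSpec,
    prior: PriorSpec = PriorSpec(),
    n_accept: int = 50_000,
    seed: int = 0,
    *,
    gene_id: str = "gene",
    eps: float = 0.0,
    max_proposals: int = 50_000_000,
    **sim_kwargs,
) -> PosteriorSample:
    """Plain rejection ABC at a single tolerance (the SMC cross-check)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    obs_count = _snap_to_grid(q_obs, sample.n_chrom)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x8E1]))
    got_h, got_s = np.empty(0), np.empty(0)
    n_prop = 0
    batch = max(4 * n_accept, 1000)
    tol_counts = eps * sample.n_chrom + 1e-9
    while got_h.size < n_accept:
        if n_prop >= max_proposals:
            raise RuntimeError("rejection-ABC proposal budget exhausted")
        hh = rng.uniform(*prior.h_bounds, size=batch)
        ss = 10.0 ** rng.uniform(*prior.log10_s_bounds, size=batch)
        counts = simulate_sample_counts(
            mu, hh, ss, mode, schedule, sample, int(rng.integers(2**31 - 1)), **sim_kwargs
        )
        ok = np.abs(counts - obs_count) <= tol_counts
        n_prop += batch
        got_h = np.concatenate([got_h, hh[ok]])
        got_s = np.concatenate([got_s, ss[ok]])
    got_h, got_s = got_h[:n_accept], got_s[:n_accept]
    return PosteriorSample(
        gene_id=gene_id,
        h=got_h,
        s=got_s,
        weight=np.ones(n_accept),
        mode=mode,
        epsilons=(eps,),
        acceptance_counts=(n_accept,),
        n_proposals=(n_prop,),
    )
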