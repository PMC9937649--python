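"""Forward Wright-Fisher simulation of a single loss-of-function locus.

A gene is modelled as one non-recombining biallelic locus.  LOF alleles arise
by mutation at a per-gene rate ``mu`` (only on backgrounds free of other LOF
variants), revert by back mutation at ``back_mu_factor * mu``, and are removed
by selection against carriers: genotype fitnesses are 1, 1-hs, 1-s on
autosomes and in females on the X, and 1, 1-s for hemizygous males.  Each
generation is formed by selection on parents, mutation in transmission, and
binomial resampling at the next generation's size, through a burn-in followed
by a piecewise-constant demographic history.  At the end, ``2n`` chromosomes
are drawn binomially from the final population frequency (sex-stratified on
the X).

Three experiment wrappers are provided besides plain frequency simulation:
a deterministic (infinite-population) recursion sharing the same operators,
used as an oracle; allele-age simulation conditioned on segregating at
present; and the neutral singleton-fraction calibration of the demographic
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .demography import EpochSchedule

__all__ = [
    "SimParams",
    "SexSpecificRates",
    "SampleSpec",
    "SimResult",
    "AgeSample",
    "split_x_mutation_rates",
    "simulate_lof_frequency",
    "simulate_sample_counts",
    "simulate_pop_freqs",
    "deterministic_recursion",
    "simulate_allele_age",
    "singleton_fraction",
]

MODES = ("autosome", "par", "x_nonpar")


@dataclass(frozen=True)
class SimParams:
    """Per-locus simulation settings.

    ``mu`` is the sex-averaged LOF mutation rate per gene per generation;
    ``h`` the dominance coefficient; ``s`` the homozygous (or hemizygous)
    fitness cost; ``alpha`` the male-to-female germline mutation rate ratio
    (used only on the non-PAR X); back mutation occurs at
    ``back_mu_factor * mu``.
    """

    mu: float
    h: float
    s: float
    mode: str = "autosome"
    alpha: float = 3.5
    back_mu_factor: float = 0.01
    burnin_with_selection: bool = True
    x_parental_mutation: bool = False

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 0 <= self.h <= 1:
            raise ValueError("h must be in [0, 1]")
        if not 0 <= self.s <= 1:
            raise ValueError("s must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.back_mu_factor < 0:
            raise ValueError("back_mu_factor must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def hs(self) -> float:
        return self.h * self.s


@dataclass(frozen=True)
class SexSpecificRates:
    mu_m: float
    mu_f: float


def split_x_mutation_rates(mu: float, alpha: float = 3.5) -> SexSpecificRates:
    """Sex-specific X-chromosome rates from the sex-averaged rate.

    mu_m = 3 mu alpha / (2 + alpha), mu_f = 3 mu / (2 + alpha), which satisfy
    2 mu_f + mu_m = 3 mu: two thirds of X transmissions are maternal, so the
    total mutational input on the X is unchanged by the male bias alpha.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return SexSpecificRates(mu_m=3.0 * mu * alpha / (2.0 + alpha), mu_f=3.0 * mu / (2.0 + alpha))


@dataclass(frozen=True)
class SampleSpec:
    """Chromosomes sampled at present.  ``n_chrom`` is 2n.

    On the non-PAR X, ``n_female``/``n_male`` individual counts may be given
    (2 * n_female + n_male == n_chrom); otherwise chromosomes are split with
    the expected 2:1 female:male origin.
    """

    n_chrom: int
    n_female: int | None = None
    n_male: int | None = None

    def __post_init__(self) -> None:
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        if (self.n_female is None) != (self.n_male is None):
            raise ValueError("give both n_female and n_male or neither")
        if self.n_female is not None:
            if 2 * self.n_female + self.n_male != self.n_chrom:
                raise ValueError("2*n_female + n_male must equal n_chrom")

    def x_chromosome_split(self) -> tuple[int, int]:
        """(female chromosomes, male chromosomes) for X sampling."""
        if self.n_female is not None:
            return 2 * self.n_female, self.n_male
        nf = int(round(2 * self.n_chrom / 3))
        return nf, self.n_chrom - nf


@dataclass(frozen=True)
class SimResult:
    """One replicate: final population frequency and the sampled counts."""

    pop_freq: float
    sample_count: int
    sample_freq: float
    pop_freq_female: float | None = None
    pop_freq_male: float | None = None


@dataclass(frozen=True)
class AgeSample:
    """Ages (generations since last invariant) of alleles segregating at present."""

    ages: np.ndarray
    attempts: int

    def median(self) -> float:
        return float(np.median(self.ages))


def _seed_for(seed: int, salt: int = 0) -> int:
    # numba's legacy RNG seeds are uint32
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31 - 1))


def _check(schedule: EpochSchedule, reps: int) -> tuple[np.ndarray, np.ndarray]:
    if reps < 1:
        raise ValueError("reps must be >= 1")
    lengths, sizes = schedule.as_arrays()
    if lengths.sum() < 1:
        raise ValueError("schedule must span at least one generation")
    return lengths, sizes


def simulate_sample_counts(
    mu: float,
    h: np.ndarray,
    s: np.ndarray,
    mode: str,
    schedule: EpochSchedule,
    sample: SampleSpec,
    seed: int,
    *,
    alpha: float = 3.5,
    back_mu_factor: float = 0.01,
    burnin_with_selection: bool = True,
    x_parental_mutation: bool = False,
) -> np.ndarray:
    """Sampled LOF allele counts for a batch of (h, s) proposals.

    The low-level entry point used by ABC: one replicate per (h[i], s[i])
    pair, all at the same mutation rate and sample size.  Returns integer
    counts out of ``sample.n_chrom``.
    """
    h = np.ascontiguousarray(h, dtype=np.float64)
    s = np.ascontiguousarray(s, dtype=np.float64)
    lengths, sizes = _check(schedule, h.shape[0])
    kseed = _seed_for(seed)
    if mode in ("autosome", "par"):
        u = np.full(h.shape[0], mu)
        v = u * back_mu_factor
        _, counts = _kernels._wf_autosome_batch(
            kseed, lengths, sizes, u, v, h, s, sample.n_chrom, burnin_with_selection
        )
        return counts
    rates = split_x_mutation_rates(mu, alpha)
    u_f = np.full(h.shape[0], rates.mu_f)
    u_m = np.full(h.shape[0], rates.mu_m)
    nf_chrom, nm_chrom = sample.x_chromosome_split()
    _, _, counts = _kernels._wf_x_batch(
        kseed, lengths, sizes, u_f, u_f * back_mu_factor, u_m, u_m * back_mu_factor,
        h, s, nf_chrom, nm_chrom, x_parental_mutation, burnin_with_selection,
    )
    return counts


def simulate_pop_freqs(
    mu: float,
    h: np.ndarray,
    s: np.ndarray,
    mode: str,
    schedule: EpochSchedule,
    seed: int,
    *,
    back_mu_factor: float = 0.01,
    burnin_with_selection: bool = True,
) -> np.ndarray:
    """Final population LOF frequencies for a batch of (h, s) proposals.

    Autosome/PAR only: the sampling stage is omitted so callers can integrate
    it out analytically (the sample count is Binomial(2n, q_pop)).
    """
    if mode not in ("autosome", "par"):
        raise ValueError("simulate_pop_freqs supports autosome/par modes only")
    h = np.ascontiguousarray(h, dtype=np.float64)
    s = np.ascontiguousarray(s, dtype=np.float64)
    lengths, sizes = _check(schedule, h.shape[0])
    u = np.full(h.shape[0], mu)
    v = u * back_mu_factor
    pop, _ = _kernels._wf_autosome_batch(
        _seed_for(seed), lengths, sizes, u, v, h, s, 1, burnin_with_selection
    )
    return pop


def simulate_lof_frequency(
    params: SimParams,
    schedule: EpochSchedule,
    sample: SampleSpec,
    reps: int,
    seed: int,
) -> list[SimResult]:
    """Replicate forward simulations of one gene; see module docstring.

    Deterministic given identical arguments and seed.
    """
    lengths, sizes = _check(schedule, reps)
    kseed = _seed_for(seed)
    if params.mode in ("autosome", "par"):
        u = np.full(reps, params.mu)
        v = u * params.back_mu_factor
        hh = np.full(reps, params.h)
        ss = np.full(reps, params.s)
        pop, counts = _kernels._wf_autosome_batch(
            kseed, lengths, sizes, u, v, hh, ss, sample.n_chrom,
            params.burnin_with_selection,
        )
        return [
            SimResult(float(p), int(c), c / sample.n_chrom)
            for p, c in zip(pop, counts)
        ]
    rates = split_x_mutation_rates(params.mu, params.alpha)
    u_f = np.full(reps, rates.mu_f)
    u_m = np.full(reps, rates.mu_m)
    hh = np.full(reps, params.h)
    ss = np.full(reps, params.s)
    nf_chrom, nm_chrom = sample.x_chromosome_split()
    qf, qm, counts = _kernels._wf_x_batch(
        kseed, lengths, sizes,
        u_f, u_f * params.back_mu_factor, u_m, u_m * params.back_mu_factor,
        hh, ss, nf_chrom, nm_chrom,
        params.x_parental_mutation, params.burnin_with_selection,
    )
    return [
        SimResult(
            pop_freq=float((2.0 * f + m) / 3.0),
            sample_count=int(c),
            sample_freq=c / sample.n_chrom,
            pop_freq_female=float(f),
            pop_freq_male=float(m),
        )
        for f, m, c in zip(qf, qm, counts)
    ]


def deterministic_recursion(
    params: SimParams, generations: int, q0: float = 0.0
) -> np.ndarray:
    """Infinite-population frequency trajectory with the simulator's operators.

    Returns an array of length ``generations + 1`` (the LOF frequency each
    generation, starting at ``q0``).  For ``x_nonpar`` the array has shape
    ``(generations + 1, 2)`` with columns (female frequency, male frequency).
    There is no drift; selection and two-way mutation act exactly as in the
    stochastic simulator, so the fixed point is the classic
    mutation-selection balance (q* ~ mu/hs for partially dominant alleles).
    """
    u = params.mu
    v = params.mu * params.back_mu_factor
    h, s = params.h, params.s
    if params.mode in ("autosome", "par"):
        traj = np.empty(generations + 1)
        q = q0
        traj[0] = q
        for t in range(1, generations + 1):
            qs = _sel_freq_py(q, h, s)
            q = qs * (1.0 - v) + (1.0 - qs) * u
            traj[t] = q
        return traj
    rates = split_x_mutation_rates(u, params.alpha)
    u_f, u_m = rates.mu_f, rates.mu_m
    v_f, v_m = u_f * params.back_mu_factor, u_m * params.back_mu_factor
    hs = h * s
    faa, fAa = q0 * q0, 2 * q0 * (1 - q0)
    qm = q0
    traj = np.empty((generations + 1, 2))
    traj[0] = (faa + fAa / 2.0, qm)
    for t in range(1, generations + 1):
        fAA = 1.0 - faa - fAa
        wf = faa * (1 - s) + fAa * (1 - hs) + fAA
        qe = (faa * (1 - s) + 0.5 * fAa * (1 - hs)) / wf
        qs_ = qm * (1 - s) / (qm * (1 - s) + (1 - qm))
        qe = qe * (1 - v_f) + (1 - qe) * u_f
        qs_ = qs_ * (1 - v_m) + (1 - qs_) * u_m
        faa = qe * qs_
        fAa = qe * (1 - qs_) + (1 - qe) * qs_
        qm = qe
        traj[t] = (faa + fAa / 2.0, qm)
    return traj


def _sel_freq_py(q: float, h: float, s: float) -> float:
    if q <= 0.0 or q >= 1.0 or s == 0.0:
        return q
    hs = h * s
    num = q * q * (1 - s) + q * (1 - q) * (1 - hs)
    den = q * q * (1 - s) + 2 * q * (1 - q) * (1 - hs) + (1 - q) ** 2
    return num / den


def _window_arrays(schedule: EpochSchedule, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Epoch arrays for the most recent ``window`` generations only."""
    lengths, sizes = schedule.as_arrays()
    out_l, out_s = [], []
    remaining = window
    for ln, sz in zip(lengths[::-1], sizes[::-1]):
        take = min(int(ln), remaining)
        out_l.append(take)
        out_s.append(int(sz))
        remaining -= take
        if remaining == 0:
            break
    return (
        np.asarray(out_l[::-1], dtype=np.int64),
        np.asarray(out_s[::-1], dtype=np.int64),
    )


def simulate_allele_age(
    params: SimParams,
    schedule: EpochSchedule,
    reps_conditioned: int,
    seed: int,
    *,
    window: int | None = None,
    max_attempt_factor: int = 200,
) -> AgeSample:
    """Ages of alleles segregating at present, conditioned replicates.

    Single-copy mutations arise only while the locus is invariant, with
    probability min(1, 2N mu) per generation; the age of a replicate that
    segregates at present is the number of generations since the locus was
    last invariant.  For hs >= 1e-3 the run starts (by default) 5,000
    generations before present, far longer than any surviving excursion at
    that strength of selection; pass ``window=0`` to force the full history.

    Raises ``RuntimeError`` if the attempt budget
    (``max_attempt_factor * reps_conditioned``) is exhausted first, which
    signals a near-zero probability of segregating at present.
    """
    if reps_conditioned < 1:
        raise ValueError("reps_conditioned must be >= 1")
    if params.mode == "x_nonpar":
        raise NotImplementedError("allele-age simulation is autosomal/PAR only")
    if window is None:
        window = 5000 if params.hs >= 1e-3 else 0
    if window and window < schedule.total_span:
        lengths, sizes = _window_arrays(schedule, window)
    else:
        lengths, sizes = schedule.as_arrays()
    max_attempts = max_attempt_factor * reps_conditioned
    ages, attempts = _kernels._wf_allele_age_batch(
        _seed_for(seed), lengths, sizes, params.mu, params.h, params.s,
        reps_conditioned, max_attempts,
    )
    if ages.shape[0] < reps_conditioned:
        raise RuntimeError(
            f"only {ages.shape[0]}/{reps_conditioned} replicates segregated at present "
            f"within {max_attempts} attempts; segregation probability is near zero"
        )
    return AgeSample(ages=ages, attempts=int(attempts))


def singleton_fraction(
    mu_site: float,
    schedule: EpochSchedule,
    sample: SampleSpec,
    reps: int,
    seed: int,
    *,
    back_mu_factor: float = 0.01,
) -> float:
    """Fraction of segregating neutral sites that are sample singletons.

    Simulates ``reps`` independent neutral sites at per-site rate
    ``mu_site``; among replicates whose sampled count is polymorphic
    (1 <= count <= 2n - 1), returns the fraction with count exactly 1.  Used
    to calibrate the demographic model against the observed synonymous
    non-CpG-transversion frequency spectrum.
    """
    counts = simulate_sample_counts(
        mu_site, np.zeros(reps), np.zeros(reps), "autosome", schedule, sample, seed,
        back_mu_factor=back_mu_factor,
    )
    seg = counts[(counts >= 1) & (counts <= sample.n_chrom - 1)]
    if seg.size == 0:
        raise RuntimeError("no segregating replicates; increase reps or mu_site")
    return float(np.mean(seg == 1))
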