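"""Distributions of fitness effects (DFEs) over sets of LOF mutations.

A DFE here is a weighted mixture of per-gene posterior samples of hs: every
possible (or observed) LOF mutation in a gene is assumed to share the gene's
posterior, so the DFE of a mutation set is the mixture of gene posteriors
weighted by each gene's share of the set — mutational opportunities for the
genome-wide DFE of all possible de novo LOF mutations, observed mutation
counts for a cohort DFE.

Exceedance probabilities P(hs > t) are always computed by pooled weighted
particle counting, never from a smoothed density.  Null calibration of a
cohort against chance uses rank-based bootstrap (cohorts of the same size
resampled from the mutational opportunities); pairs of DFEs are compared by
bootstrapping the area above hs = 0.1 and applying a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .inference import PosteriorSample

__all__ = [
    "GeneWeights",
    "DFE",
    "CohortCounts",
    "build_dfe",
    "dfe_exceedance",
    "bootstrap_null_pvalue",
    "compare_dfes",
    "causal_probability",
    "carrier_rates",
    "dfe_by_frequency_bin",
]


@dataclass(frozen=True)
class GeneWeights:
    """Normalized non-negative weights over gene ids."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        w = {k: float(v) for k, v in self.weights.items()}
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be non-negative")
        total = sum(w.values())
        if total <= 0:
            raise ValueError("weights must not all be zero")
        object.__setattr__(self, "weights", {k: v / total for k, v in w.items()})

    @classmethod
    def from_opportunities(cls, panel) -> "GeneWeights":
        """Weights proportional to each gene's count of LOF mutational opportunities."""
        return cls({g.gene_id: float(g.n_opportunities) for g in panel.included_genes()})

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "GeneWeights":
        return cls({k: float(v) for k, v in counts.items() if v > 0})

    def items(self):
        return self.weights.items()


@dataclass(frozen=True)
class CohortCounts:
    """Observed DNM (or variant) counts per gene."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        c = {k: int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in c.values()):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass
class DFE:
    """Weighted mixture of per-gene hs posteriors, stored as pooled particles."""

    gene_ids: tuple[str, ...]
    gene_weights: np.ndarray  # normalized, aligned to gene_ids
    hs: np.ndarray  # pooled particle hs values
    weight: np.ndarray  # pooled particle weights (sum to 1)
    gene_mean_hs: np.ndarray  # per-gene posterior mean of hs
    blocks: tuple[tuple[int, int], ...] = ()  # per-gene slices into hs/weight

    @property
    def is_empty(self) -> bool:
        return self.hs.size == 0

    def exceedance(self, t: float) -> float:
        return dfe_exceedance(self, t)

    def mean_hs(self) -> float:
        return float(np.sum(self.weight * self.hs))

    def interval_mass(self, lo: float, hi: float) -> float:
        """P(lo < hs <= hi); open at ``lo``, closed at ``hi``."""
        sel = (self.hs > lo) & (self.hs <= hi)
        return float(np.sum(self.weight[sel]))


def build_dfe(posteriors: Sequence[PosteriorSample], weights: GeneWeights) -> DFE:
    """Mix per-gene posteriors with the given gene weights.

    Every gene with positive weight must have a posterior; genes with zero
    weight are dropped.
    """
    by_id = {p.gene_id: p for p in posteriors}
    ids, gw = [], []
    for gid, w in weights.items():
        if w == 0:
            continue
        if gid not in by_id:
            raise KeyError(f"no posterior for weighted gene {gid!r}")
        ids.append(gid)
        gw.append(w)
    gw = np.asarray(gw, dtype=float)
    gw /= gw.sum()
    hs_parts, w_parts, means, blocks = [], [], [], []
    pos = 0
    for gid, w in zip(ids, gw):
        p = by_id[gid]
        hs_parts.append(p.hs)
        w_parts.append(p.weight * w)
        means.append(p.mean_hs())
        blocks.append((pos, pos + p.hs.size))
        pos += p.hs.size
    return DFE(
        gene_ids=tuple(ids),
        gene_weights=gw,
        hs=np.concatenate(hs_parts) if hs_parts else np.empty(0),
        weight=np.concatenate(w_parts) if w_parts else np.empty(0),
        gene_mean_hs=np.asarray(means),
        blocks=tuple(blocks),
    )


def dfe_exceedance(dfe: DFE, t: float) -> float:
    """Weighted posterior mass with hs strictly above ``t``."""
    if not 0.0 < t <= 1.0:
        raise ValueError("t must be in (0, 1]")
    if dfe.is_empty:
        raise ValueError("empty DFE")
    return float(np.sum(dfe.weight[dfe.hs > t]))


def bootstrap_null_pvalue(
    cohort: CohortCounts,
    opportunity_weights: GeneWeights,
    posteriors: Sequence[PosteriorSample],
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Rank p-value of a cohort DFE mean against opportunity-matched null draws.

    Draws ``B`` null cohorts of the observed size from the mutational
    opportunities (with replacement), computes each null DFE's mean hs, and
    returns ``(p, null_means)`` with p = r / (B + 1) where r is the rank of
    the observed mean from the top (so an observed mean above every null mean
    gives 1 / (B + 1); the convention never returns 0).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if cohort.n < 1:
        raise ValueError("cohort must contain at least one mutation")
    by_id = {p.gene_id: p for p in posteriors}
    obs = build_dfe(posteriors, GeneWeights.from_counts(cohort.counts))
    obs_mean = float(np.sum(obs.gene_weights * obs.gene_mean_hs))

    ids = [gid for gid, _ in opportunity_weights.items()]
    probs = np.asarray([w for _, w in opportunity_weights.items()])
    mean_by_gene = np.asarray([by_id[g].mean_hs() for g in ids])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0]))
    draws = rng.choice(mean_by_gene.size, size=(B, cohort.n), p=probs)
    null_means = mean_by_gene[draws].mean(axis=1)
    r = 1 + int(np.sum(null_means >= obs_mean))
    return r / (B + 1), null_means


def compare_dfes(
    dfe_a: DFE,
    dfe_b: DFE,
    B: int = 500,
    interval: tuple[float, float] = (0.1, 1.0),
    seed: int = 0,
    n_mutations: tuple[int, int] | None = None,
) -> float:
    """KS p-value comparing the strongly deleterious mass of two DFEs.

    For each DFE, draws ``B`` bootstrap resamples of its mutations (gene
    draws with replacement, probabilities = gene weights; resample size
    defaults to the number of component genes) and computes the area of each
    resampled DFE in ``interval`` (open at the lower end, closed at the
    upper).  Returns the two-sample Kolmogorov-Smirnov p-value over the two
    sets of B areas.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if dfe_a.is_empty or dfe_b.is_empty:
        raise ValueError("cannot compare empty DFEs")
    lo, hi = interval
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCD]))
    pa = _bootstrap_areas(dfe_a, B, lo, hi, rng, None if n_mutations is None else n_mutations[0])
    pb = _bootstrap_areas(dfe_b, B, lo, hi, rng, None if n_mutations is None else n_mutations[1])
    return float(ks_2samp(pa, pb).pvalue)


def _per_gene_mass(dfe: DFE, lo: float, hi: float) -> np.ndarray:
    """P(lo < hs <= hi) under each component gene's own posterior."""
    mass = np.empty(dfe.gene_weights.size)
    for i, (a, b) in enumerate(dfe.blocks):
        hs = dfe.hs[a:b]
        w = dfe.weight[a:b]
        w = w / w.sum()
        mass[i] = float(np.sum(w[(hs > lo) & (hs <= hi)]))
    return mass


def _bootstrap_areas(dfe: DFE, B, lo, hi, rng, m=None):
    """Interval areas of ``B`` mutation-resampled versions of the DFE."""
    k = dfe.gene_weights.size
    if m is None:
        m = max(k, 2)
    mass = _per_gene_mass(dfe, lo, hi)
    draws = rng.choice(k, size=(B, m), p=dfe.gene_weights)
    return mass[draws].mean(axis=1)


def causal_probability(p_pop: float, p_cohort: float) -> float:
    """P(a strongly deleterious DNM seen in the cohort is causal).

    With the cohort DFE a mixture of causal and background mutations, the
    enrichment p_cohort / p_pop of strongly deleterious mass implies a causal
    probability 1 - p_pop / p_cohort.  Negative values (a depleted cohort)
    are returned as-is with a warning.
    """
    if not 0.0 <= p_pop <= 1.0:
        raise ValueError("p_pop must be in [0, 1]")
    if p_cohort <= 0.0:
        raise ValueError("p_cohort must be > 0")
    out = 1.0 - p_pop / p_cohort
    if out < 0:
        warnings.warn("cohort is depleted of deleterious mutations; causal probability < 0")
    return out


def carrier_rates(
    dnm_per_person: float, lof_fraction: float, p_deleterious: float
) -> tuple[float, float]:
    """(X, Y): 1 in X newborns carries an LOF DNM; 1 in Y a deleterious one.

    X = 1 / (dnm_per_person * lof_fraction); Y = X / p_deleterious.  With ~70
    DNMs per person and ~1/1000 of DNMs creating an LOF, X is about 14; if
    20% of LOF opportunities have hs > 10%, Y is about 71.
    """
    if dnm_per_person < 0 or lof_fraction < 0 or p_deleterious < 0:
        raise ValueError("inputs must be >= 0")
    denom = dnm_per_person * lof_fraction
    if denom == 0:
        raise ZeroDivisionError("dnm_per_person * lof_fraction must be > 0")
    x = 1.0 / denom
    if p_deleterious == 0:
        raise ZeroDivisionError("p_deleterious must be > 0")
    return x, x / p_deleterious


def dfe_by_frequency_bin(
    variants: pd.DataFrame,
    thresholds: Sequence[float],
    posteriors: Sequence[PosteriorSample],
) -> dict[float, DFE | None]:
    """One DFE per allele-frequency threshold.

    For each threshold t, genes are weighted by their number of segregating
    variants with allele_freq <= t.  Empty bins yield None with a warning.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be increasing")
    out: dict[float, DFE | None] = {}
    for t in thresholds:
        sub = variants[variants["allele_freq"] <= t]
        counts = sub.groupby("gene_id").size().to_dict()
        if not counts:
            warnings.warn(f"no variants at allele_freq <= {t}; empty DFE")
            out[t] = None
            continue
        out[t] = build_dfe(posteriors, GeneWeights.from_counts(counts))
    return out
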