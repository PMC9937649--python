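"""Synthetic gene panels, DNM cohorts, and segregating-variant tables.

Every pipeline stage can be exercised without external exome data: the
generator draws per-gene LOF mutation rates and true (h, s) values, produces
"observed" sample LOF frequencies by running the same forward simulator that
inference assumes, and fabricates disease-cohort DNM tables as mixtures of a
causal component (genes with true hs above a cutoff, drawn by mutational
opportunity) and an opportunity-weighted background.

Ground truth is returned as a separate table so it can be kept away from
anything the inference machinery consumes.

Defaults: per-gene LOF rates are log-normal with median 1e-6 per generation
(the order of typical per-gene high-confidence LOF rates) and sigma 1 on the
natural-log scale; opportunity counts are proportional to the rate (one
opportunity per ~2e-9 of rate, a typical per-site rate) with Poisson noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import EpochSchedule
from .gene_panel import GenePanel, GeneRecord
from .inference import PriorSpec
from .simulator import SampleSpec, simulate_sample_counts

__all__ = [
    "SyntheticPanelSpec",
    "CohortSpec",
    "generate_panel",
    "generate_dnm_cohort",
    "generate_segregating_variants",
]

#: nominal per-site LOF rate used to convert per-gene rates to opportunity counts
MU_PER_OPPORTUNITY = 2e-9


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Recipe for a synthetic gene panel with known truth."""

    n_genes: int
    mu_median: float = 1e-6
    mu_sigma: float = 1.0  # natural-log scale
    hs_truth: PriorSpec | Sequence[tuple[float, float]] = field(default_factory=PriorSpec)
    n_chrom: int = 2 * 56_855
    chrom_class: str = "autosome"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.mu_median <= 0 or self.mu_sigma < 0:
            raise ValueError("mutation-rate law parameters must be positive")
        if not isinstance(self.hs_truth, PriorSpec) and len(self.hs_truth) != self.n_genes:
            raise ValueError("explicit hs_truth list must have n_genes entries")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a DNM cohort: causal/background mixture."""

    n_dnm: int
    f_causal: float = 0.0
    causal_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dnm < 0:
            raise ValueError("n_dnm must be >= 0")
        if not 0.0 <= self.f_causal <= 1.0:
            raise ValueError("f_causal must be in [0, 1]")


def generate_panel(
    spec: SyntheticPanelSpec,
    schedule: EpochSchedule,
    **sim_kwargs,
) -> tuple[GenePanel, pd.DataFrame]:
    """Synthesize a gene panel and its hidden truth table.

    For each gene, draws (mu, h, s), runs one forward replicate to obtain the
    observed sample LOF frequency at ``spec.n_chrom`` chromosomes, and draws
    an opportunity count.  Returns ``(panel, truth)`` where ``truth`` has
    columns gene_id, h, s, hs.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5E1]))
    n = spec.n_genes
    if n == 0:
        return GenePanel(genes=[], metadata={"synthetic": True}), pd.DataFrame(
            columns=["gene_id", "h", "s", "hs"]
        )
    mu = spec.mu_median * np.exp(rng.normal(0.0, spec.mu_sigma, size=n))
    if isinstance(spec.hs_truth, PriorSpec):
        h = rng.uniform(*spec.hs_truth.h_bounds, size=n)
        s = 10.0 ** rng.uniform(*spec.hs_truth.log10_s_bounds, size=n)
    else:
        h = np.asarray([x[0] for x in spec.hs_truth], dtype=float)
        s = np.asarray([x[1] for x in spec.hs_truth], dtype=float)
    opp = 1 + rng.poisson(mu / MU_PER_OPPORTUNITY)
    sample = SampleSpec(spec.n_chrom)
    mode = "x_nonpar" if spec.chrom_class in ("x_nonpar", "x_y_homolog") else (
        "par" if spec.chrom_class == "par" else "autosome"
    )
    genes = []
    for i in range(n):
        count = simulate_sample_counts(
            float(mu[i]), np.array([h[i]]), np.array([s[i]]), mode, schedule, sample,
            int(rng.integers(2**31 - 1)), **sim_kwargs,
        )[0]
        genes.append(
            GeneRecord(
                gene_id=f"G{i:04d}",
                mu_lof=float(mu[i]),
                n_opportunities=int(opp[i]),
                obs_lof_freq=count / spec.n_chrom,
                chrom_class=spec.chrom_class,
                n_chrom=spec.n_chrom,
            )
        )
    truth = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "h": h, "s": s, "hs": h * s}
    )
    panel = GenePanel(
        genes=genes,
        metadata={"synthetic": True, "seed": spec.seed, "n_chrom": spec.n_chrom},
    )
    return panel, truth


def generate_dnm_cohort(
    panel: GenePanel, truth: pd.DataFrame, spec: CohortSpec
) -> dict[str, int]:
    """Draw a DNM cohort as a causal/background mixture; returns gene counts.

    Each of ``n_dnm`` mutations is causal with probability ``f_causal``
    (its gene drawn with probability proportional to mutational opportunity
    among genes with true hs > ``causal_threshold``), otherwise background
    (opportunity-weighted over all genes).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0]))
    ids = [g.gene_id for g in panel.genes]
    opp = np.asarray([g.n_opportunities for g in panel.genes], dtype=float)
    if opp.sum() <= 0:
        raise ValueError("panel has no mutational opportunities")
    p_bg = opp / opp.sum()
    hs_true = truth.set_index("gene_id").loc[ids, "hs"].to_numpy()
    causal_mask = hs_true > spec.causal_threshold
    if spec.f_causal > 0 and not causal_mask.any():
        raise ValueError(
            f"no genes with true hs > {spec.causal_threshold}; cannot draw causal mutations"
        )
    counts = {g: 0 for g in ids}
    if spec.n_dnm == 0:
        return counts
    is_causal = rng.random(spec.n_dnm) < spec.f_causal
    n_causal = int(is_causal.sum())
    if n_causal:
        p_c = np.where(causal_mask, opp, 0.0)
        p_c /= p_c.sum()
        for idx in rng.choice(len(ids), size=n_causal, p=p_c):
            counts[ids[idx]] += 1
    for idx in rng.choice(len(ids), size=spec.n_dnm - n_causal, p=p_bg):
        counts[ids[idx]] += 1
    return counts


def generate_segregating_variants(
    panel: GenePanel,
    truth: pd.DataFrame,
    schedule: EpochSchedule,
    reps_per_gene: int,
    seed: int,
    *,
    max_attempt_factor: int = 50,
) -> pd.DataFrame:
    """Sample segregating-variant rows (gene_id, allele_freq) per gene.

    For each gene, runs forward replicates at the gene's true (h, s) and
    keeps sample frequencies conditioned on segregating (0 < count < 2n);
    strongly selected genes therefore contribute fewer rows.  At most
    ``max_attempt_factor * reps_per_gene`` replicates are attempted per gene.
    """
    tr = truth.set_index("gene_id")
    rows = []
    for i, g in enumerate(panel.genes):
        h, s = float(tr.loc[g.gene_id, "h"]), float(tr.loc[g.gene_id, "s"])
        sample = SampleSpec(g.n_chrom)
        got = 0
        attempts = 0
        batch = max(reps_per_gene, 16)
        sub_seed = np.random.SeedSequence([seed, i])
        salt = 0
        while got < reps_per_gene and attempts < max_attempt_factor * reps_per_gene:
            counts = simulate_sample_counts(
                g.mu_lof, np.full(batch, h), np.full(batch, s), g.sim_mode,
                schedule, sample,
                int(sub_seed.generate_state(salt + 1)[-1] % (2**31 - 1)),
            )
            salt += 1
            attempts += batch
            for c in counts[(counts >= 1) & (counts <= g.n_chrom - 1)]:
                if got >= reps_per_gene:
                    break
                rows.append(dict(gene_id=g.gene_id, allele_freq=c / g.n_chrom))
                got += 1
    return pd.DataFrame(rows, columns=["gene_id", "allele_freq"])
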