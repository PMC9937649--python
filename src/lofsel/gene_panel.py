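"""Per-gene observed LOF frequencies from variant tables, and the neutral screen.

Variant tables arrive pre-annotated (high-confidence LOF status in the
canonical transcript is decided upstream).  Aggregation applies the coverage
and annotation filters, sums the surviving allele frequencies per gene, and
flags genes whose aggregate frequency is inconsistent with any amount of
purifying selection: a gene whose observed LOF frequency sits at or above the
90th percentile of its own neutral (hs = 0) simulated distribution is treated
as model-misspecified (e.g. underestimated mutation rate, balancing
selection, annotation error) and excluded from inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import math

import numpy as np
import pandas as pd

from .demography import EpochSchedule
from .simulator import SampleSpec, simulate_sample_counts

__all__ = [
    "GeneRecord",
    "GenePanel",
    "VARIANT_COLUMNS",
    "allele_number_stats",
    "aggregate_lof_frequency",
    "neutral_screen",
    "screen_panel",
]

VARIANT_COLUMNS = (
    "gene_id",
    "allele_freq",
    "allele_number",
    "is_hc_lof",
    "is_indel",
    "passes_qc",
)

CHROM_CLASSES = ("autosome", "par", "x_nonpar", "x_y_homolog")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    mu_lof: float
    n_opportunities: int
    obs_lof_freq: float
    chrom_class: str = "autosome"
    n_chrom: int = 2 * 56_855
    included: bool = True
    flagged_neutral_outlier: bool = False

    def __post_init__(self) -> None:
        if self.mu_lof < 0:
            raise ValueError("mu_lof must be >= 0")
        if self.obs_lof_freq < 0:
            raise ValueError("obs_lof_freq must be >= 0")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(f"chrom_class must be one of {CHROM_CLASSES}")

    @property
    def sim_mode(self) -> str:
        """Simulation mode for this gene (X genes with a Y homolog are
        still hemizygous in males and simulated as non-PAR X)."""
        if self.chrom_class in ("x_nonpar", "x_y_homolog"):
            return "x_nonpar"
        return "autosome" if self.chrom_class == "autosome" else "par"


@dataclass
class GenePanel:
    """Ordered gene records plus provenance metadata."""

    genes: list[GeneRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_ids must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def included_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.included and not g.flagged_neutral_outlier]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(g) for g in self.genes])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "GenePanel":
        genes = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            genes.append(
                GeneRecord(
                    gene_id=str(d["gene_id"]),
                    mu_lof=float(d["mu_lof"]),
                    n_opportunities=int(d.get("n_opportunities", 0)),
                    obs_lof_freq=float(d["obs_lof_freq"]),
                    chrom_class=str(d.get("chrom_class", "autosome")),
                    n_chrom=int(d.get("n_chrom", 2 * 56_855)),
                    included=bool(d.get("included", True)),
                    flagged_neutral_outlier=bool(d.get("flagged_neutral_outlier", False)),
                )
            )
        return cls(genes=genes, metadata=metadata or {})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenePanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"), metadata={"source": str(path)})


def allele_number_stats(variants: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Mean and SD of allele number, separately for {autosome, par} and non-PAR X.

    Computed across variants (not sites).  Requires a ``chrom_class`` column;
    variants without one are treated as autosomal.
    """
    df = variants.copy()
    if "chrom_class" not in df:
        df["chrom_class"] = "autosome"
    grp = df["chrom_class"].map(
        lambda c: "x_nonpar" if c in ("x_nonpar", "x_y_homolog") else "autosome_par"
    )
    out = {}
    for name, sub in df.groupby(grp):
        out[name] = (float(sub["allele_number"].mean()), float(sub["allele_number"].std(ddof=0)))
    return out


def aggregate_lof_frequency(
    variants: pd.DataFrame,
    an_mean: float,
    an_sd: float,
    *,
    mu_lof: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate variant-level frequencies into per-gene observed LOF frequency.

    Filters, per variant: failed QC; indels; not high-confidence LOF in the
    canonical transcript; allele number below ``an_mean - 2 * an_sd``.  The
    surviving allele frequencies are summed per gene.  A gene is excluded
    when fewer than 50% of its high-confidence LOF variants pass the
    allele-number threshold, or when its LOF mutation rate is 0 (if a
    ``mu_lof`` mapping is supplied).  Genes with no surviving variants get
    q = 0 and stay included.

    Returns a frame with columns gene_id, obs_lof_freq, n_variants_used,
    included, exclusion_reason.
    """
    missing = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if an_mean < 0 or an_sd < 0:
        raise ValueError("an_mean and an_sd must be >= 0")
    df = variants.copy()
    hc = df[df["passes_qc"] & ~df["is_indel"] & df["is_hc_lof"]]
    threshold = an_mean - 2.0 * an_sd
    passing = hc[hc["allele_number"] >= threshold]

    rows = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        gene_hc = hc[hc["gene_id"] == gene_id]
        gene_pass = passing[passing["gene_id"] == gene_id]
        q = float(gene_pass["allele_freq"].sum())
        included = True
        reason = ""
        if len(gene_hc) > 0 and len(gene_pass) / len(gene_hc) < 0.5:
            included = False
            reason = "low_allele_number_coverage"
        if mu_lof is not None and mu_lof.get(gene_id, 0.0) == 0.0:
            included = False
            reason = (reason + ";" if reason else "") + "zero_mutation_rate"
        rows.append(
            dict(
                gene_id=gene_id,
                obs_lof_freq=q,
                n_variants_used=len(gene_pass),
                included=included,
                exclusion_reason=reason,
            )
        )
    return pd.DataFrame(rows)


def neutral_screen(
    gene: GeneRecord,
    schedule: EpochSchedule,
    sample: SampleSpec | None = None,
    reps: int = 50_000,
    seed: int = 0,
) -> bool:
    """True when the gene's observed LOF frequency is implausibly high under hs = 0.

    Simulates ``reps`` neutral sample frequencies at the gene's mutation rate
    and sample size, and flags the gene when the observed frequency is >= the
    empirical 90th percentile (the order statistic of rank ceil(0.9 * reps);
    ties flag, the comparison being inclusive).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if gene.mu_lof <= 0:
        raise ValueError("neutral screen requires mu_lof > 0")
    if sample is None:
        sample = SampleSpec(gene.n_chrom)
    counts = simulate_sample_counts(
        gene.mu_lof,
        np.zeros(reps),
        np.zeros(reps),
        gene.sim_mode,
        schedule,
        sample,
        seed,
    )
    freqs = np.sort(counts / sample.n_chrom)
    rank = math.ceil(0.9 * reps)  # 1-based order statistic
    q90 = freqs[rank - 1]
    return bool(gene.obs_lof_freq >= q90)


def screen_panel(
    panel: GenePanel,
    schedule: EpochSchedule,
    reps: int = 50_000,
    seed: int = 0,
) -> GenePanel:
    """Apply the neutral screen to every included gene with mu > 0."""
    out = []
    for i, g in enumerate(panel.genes):
        if g.included and g.mu_lof > 0:
            flag = neutral_screen(
                g, schedule, SampleSpec(g.n_chrom), reps,
                int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31 - 1)),
            )
            out.append(replace(g, flagged_neutral_outlier=flag))
        else:
            out.append(g)
    meta = dict(panel.metadata)
    meta["neutral_screen_reps"] = reps
    return GenePanel(genes=out, metadata=meta)
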