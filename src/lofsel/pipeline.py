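"""End-to-end orchestration: panel -> neutral screen -> inference -> DFE.

A run is driven by a single YAML config and a base seed; every stage derives
its own child seeds from the base, so re-running an identical config
reproduces identical outputs.  Each run writes, under the output directory:

- ``panel_screened.tsv``     the gene panel with neutral-outlier flags
- ``posterior_<gene>.tsv``   accepted particles per gene (h, s, hs, weight)
- ``summary.tsv``            per-gene MAP, 95% CI and exceedance probabilities
- ``dfe.tsv``                opportunity-weighted DFE exceedance at thresholds
- ``manifest.json``          inputs, seeds, per-stage summaries
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demography import EpochSchedule, build_default_schedule, read_schedule_tsv
from .dfe import DFE, GeneWeights, build_dfe, dfe_exceedance
from .gene_panel import GenePanel, screen_panel
from .inference import (
    PriorSpec,
    ToleranceSchedule,
    abc_smc_infer,
    summarize_posterior,
    tolerance_schedule_for_chromosomes,
)
from .simulator import SampleSpec

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    panel_path: str
    out_dir: str
    schedule_variant: str = "modified"
    schedule_path: str | None = None
    burnin_generations: int | None = None
    burnin_size: int | None = None
    log10_s_bounds: tuple[float, float] = (-6.0, 0.0)
    h_bounds: tuple[float, float] = (0.0, 1.0)
    n_accept: int = 50_000
    tolerance_epsilons: tuple[float, ...] | None = None
    screen_reps: int = 50_000
    run_screen: bool = True
    dfe_thresholds: tuple[float, ...] = (0.01, 0.1)
    seed: int = 0
    burnin_scale: float = 1.0  # desk-scale runs shorten the burn-in

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("log10_s_bounds", "h_bounds", "tolerance_epsilons", "dfe_thresholds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def build_schedule(self) -> EpochSchedule:
        if self.schedule_path is not None:
            if self.burnin_generations is None or self.burnin_size is None:
                raise ValueError("schedule_path requires burnin_generations and burnin_size")
            sched = read_schedule_tsv(self.schedule_path, self.burnin_generations, self.burnin_size)
        else:
            sched = build_default_schedule(self.schedule_variant)
        if self.burnin_scale != 1.0:
            sched = sched.with_burnin(max(1, int(sched.burnin_generations * self.burnin_scale)))
        return sched


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    panel_path = Path(config.panel_path)
    if not panel_path.exists():
        raise FileNotFoundError(f"panel file not found: {panel_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = config.build_schedule()
    prior = PriorSpec(log10_s_bounds=config.log10_s_bounds, h_bounds=config.h_bounds)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {"panel": str(panel_path)},
        "stages": {},
        "outputs": [],
    }

    panel = GenePanel.from_tsv(panel_path)
    manifest["stages"]["load"] = {"n_genes": len(panel)}

    if config.run_screen:
        panel = screen_panel(panel, schedule, reps=config.screen_reps, seed=config.seed)
        n_flagged = sum(g.flagged_neutral_outlier for g in panel)
        manifest["stages"]["screen"] = {
            "reps": config.screen_reps,
            "n_flagged": n_flagged,
        }
        logger.info("neutral screen flagged %d/%d genes", n_flagged, len(panel))
    screened_path = out / "panel_screened.tsv"
    panel.to_tsv(screened_path)
    manifest["outputs"].append(str(screened_path))

    posteriors = []
    summaries = []
    for i, gene in enumerate(panel.included_genes()):
        tol = (
            ToleranceSchedule(config.tolerance_epsilons)
            if config.tolerance_epsilons is not None
            else tolerance_schedule_for_chromosomes(gene.n_chrom)
        )
        post = abc_smc_infer(
            gene.obs_lof_freq,
            gene.mu_lof,
            gene.sim_mode,
            schedule,
            SampleSpec(gene.n_chrom),
            prior=prior,
            tolerances=tol,
            n_accept=config.n_accept,
            seed=int(np.random.SeedSequence([config.seed, 1, i]).generate_state(1)[0] % (2**31 - 1)),
            gene_id=gene.gene_id,
        )
        posteriors.append(post)
        ppath = out / f"posterior_{gene.gene_id}.tsv"
        pd.DataFrame(
            {"h": post.h, "s": post.s, "hs": post.hs, "weight": post.weight}
        ).to_csv(ppath, sep="\t", index=False)
        manifest["outputs"].append(str(ppath))
        summ = summarize_posterior(post, thresholds=config.dfe_thresholds, prior=prior)
        row = {
            "gene_id": gene.gene_id,
            "map_hs": summ.map_hs,
            "ci_low": summ.ci95[0],
            "ci_high": summ.ci95[1],
            "mean_hs": summ.mean_hs,
        }
        for t, p in summ.p_hs_gt.items():
            row[f"p_gt_{t:g}"] = p
        summaries.append(row)
    summary_path = out / "summary.tsv"
    pd.DataFrame(summaries).to_csv(summary_path, sep="\t", index=False)
    manifest["outputs"].append(str(summary_path))
    manifest["stages"]["infer"] = {
        "n_genes": len(posteriors),
        "n_accept": config.n_accept,
    }

    if posteriors:
        weights = GeneWeights.from_opportunities(panel)
        mix = build_dfe(posteriors, weights)
        dfe_rows = [
            {"threshold": t, "p_exceed": dfe_exceedance(mix, t)}
            for t in config.dfe_thresholds
        ]
        dfe_path = out / "dfe.tsv"
        pd.DataFrame(dfe_rows).to_csv(dfe_path, sep="\t", index=False)
        manifest["outputs"].append(str(dfe_path))
        manifest["stages"]["dfe"] = {r["threshold"]: r["p_exceed"] for r in dfe_rows}

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
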