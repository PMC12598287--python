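"""End-to-end synthetic downsampling experiment.

Replicates, on simulated data, the design used to validate imputation of
low-coverage genomes: truth diploids are generated once, then for each
coverage on a ladder an imputed callset (coverage-dependent error, GP
triples) and a pseudohaploid callset (Poisson allele sampling) are derived,
and accuracy metrics are tabulated over GP thresholds, MAF tranches and
substitution classes.  The output is one tidy table with axes
coverage x GP x tranche x class x metric, plus a site-recovery table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import concordance as cc
from .gtio import GP_THRESHOLDS, apply_gp_filter
from .sim import ErrorModel, Panel, PanelConfig, PlantedSegment, TruthSet, pseudohaploidize, simulate_imputed, simulate_panel, simulate_truth

#: Coverage ladder of the downsampling design (x-fold).
DEFAULT_COVERAGES = (0.1, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0)


@dataclass
class ExperimentConfig:
    panel: PanelConfig = field(default_factory=PanelConfig)
    n_individuals: int = 4
    coverages: Sequence[float] = DEFAULT_COVERAGES
    gp_thresholds: Sequence[float] = GP_THRESHOLDS
    maf_min: float = 0.05
    error_model: ErrorModel = field(default_factory=ErrorModel)
    roh_plan: Sequence[PlantedSegment] = ()
    ibd_plan: Sequence[PlantedSegment] = ()
    seed: int = 0


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    recovery: pd.DataFrame
    truth: TruthSet
    panel: Panel


def run_experiment(config: Optional[ExperimentConfig] = None) -> ExperimentResult:
    cfg = config or ExperimentConfig()
    panel = simulate_panel(cfg.panel)
    truth = simulate_truth(
        panel, cfg.n_individuals, cfg.roh_plan, cfg.ibd_plan, seed=cfg.seed + 1
    )
    metric_frames = []
    recovery_frames = []
    rng = np.random.default_rng(cfg.seed + 2)
    for cov in cfg.coverages:
        for t_cs in truth.callsets:
            sub = int(rng.integers(0, 2**31 - 1))
            imp = simulate_imputed(t_cs, cfg.error_model, cov, seed=sub)
            pse = pseudohaploidize(t_cs, cov, seed=sub + 1)
            for gp in cfg.gp_thresholds:
                counts = cc.crosstab(t_cs, imp, gp_threshold=gp)
                mf = cc.metrics_frame(counts)
                mf.insert(1, "coverage", cov)
                metric_frames.append(mf)
                rec = cc.recovery_table(apply_gp_filter(imp, gp), pse, cfg.maf_min)
                rec.insert(1, "coverage", cov)
                rec.insert(2, "gp", gp)
                recovery_frames.append(rec)
    return ExperimentResult(
        metrics=pd.concat(metric_frames, ignore_index=True),
        recovery=pd.concat(recovery_frames, ignore_index=True),
        truth=truth,
        panel=panel,
    )
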