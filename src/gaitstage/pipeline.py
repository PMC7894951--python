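"""End-to-end workflows: diagnosis (healthy vs patient) and Hoehn-Yahr
staging, from a labeled feature table to persisted artifacts.

Both workflows share the shape: PCA feature pooling -> repeated
multi-topology training protocol on the full pool -> exhaustive minimal
subset search -> cumulative-index diagnostic statistics on the minimal
subset.  A single master seed determines every random draw.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, features as feat
from .evaluation import ProtocolConfig, run_protocol
from .subset_search import SubsetSearchReport, search_min_subset

__all__ = ["PipelineConfig", "PipelineResult", "run_diagnosis", "run_staging"]

log = logging.getLogger("gaitstage")

#: The Hoehn-Yahr pairings reported by default (worse stage is the positive
#: class of each comparison).
DEFAULT_STAGE_PAIRS: tuple[tuple[str, str], ...] = (
    ("HY2", "HY1"),
    ("HY3", "HY1"),
    ("HY4", "HY1"),
    ("HY4", "HY3"),
)


@dataclass
class PipelineConfig:
    """Configuration of a diagnosis or staging run."""

    pca_threshold: float = 0.98
    reps: int = 10
    max_iter: int = 1000
    alpha: float = 0.05
    margin: float = 2.0
    seed: int = 0
    subset_budget: int = 5000
    max_subset_size: int | None = None
    all_stage_pairs: bool = False
    out_dir: Path | None = None

    def protocol(self) -> ProtocolConfig:
        return ProtocolConfig(reps=self.reps, max_iter=self.max_iter, seed=self.seed)


@dataclass
class PipelineResult:
    task: str
    pool: list[str]
    protocol_result: object
    search_report: SubsetSearchReport
    diagnostic_reports: list[diagnostics.DiagnosticReport]
    artifacts: dict[str, Path] = field(default_factory=dict)

    @property
    def minimal_subset(self):
        return self.search_report.minimal_subset


def _persist(result: PipelineResult, cfg: PipelineConfig) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = out / f"{result.task}_protocol.csv"
    result.protocol_result.records.to_csv(rec, index=False)
    result.artifacts["protocol_records"] = rec
    topo = out / f"{result.task}_topologies.csv"
    result.protocol_result.topology_table().to_csv(topo, index=False)
    result.artifacts["topology_table"] = topo
    search = out / f"{result.task}_search.csv"
    result.search_report.records.to_csv(search, index=False)
    result.artifacts["search_records"] = search
    diag = out / f"{result.task}_diagnostics.csv"
    pd.DataFrame([r.as_row() for r in result.diagnostic_reports]).to_csv(
        diag, index=False
    )
    result.artifacts["diagnostics"] = diag
    manifest = out / f"{result.task}_manifest.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "task": result.task,
                "config": {
                    k: (str(v) if isinstance(v, Path) else v)
                    for k, v in dataclasses.asdict(cfg).items()
                },
                "pool": result.pool,
                "minimal_subset": list(result.minimal_subset or ()),
                "stopping_size": result.search_report.stopping_size,
                "n_combinations_visited": result.search_report.n_combinations_visited,
                "artifacts": {k: str(v) for k, v in result.artifacts.items()},
            },
            fh,
            indent=2,
        )
    result.artifacts["manifest"] = manifest


def run_diagnosis(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> PipelineResult:
    """Healthy-vs-patient workflow on a labeled feature table.

    All Hoehn-Yahr stages are pooled into a single patient class (2-class
    one-hot protocol).  Steps: PCA pool on all subjects -> protocol on the
    full pool -> minimal subset search -> cumulative-index ROC of the best
    minimal subset for HS vs patients.
    """
    cfg = config or PipelineConfig()
    feat.validate_feature_table(table)
    if "HS" not in set(table["label"]):
        raise ValueError("diagnosis requires an HS group")
    t0 = time.perf_counter()
    work = table.copy()
    work["label2"] = np.where(work["label"] == "HS", "HS", "PwPD")

    sel = feat.pca_select(work, threshold=cfg.pca_threshold)
    pool = sel.features
    log.info("diagnosis: PCA pool (%d features): %s", len(pool), pool)

    proto = run_protocol(work, pool, label_col="label2", config=cfg.protocol())
    log.info("diagnosis: full-pool mean P = %.1f%%", proto.mean_P)

    report = search_min_subset(
        work,
        pool,
        protocol_config=cfg.protocol(),
        alpha=cfg.alpha,
        margin=cfg.margin,
        label_col="label2",
        max_size=cfg.max_subset_size,
        budget=cfg.subset_budget,
    )
    subset = list(report.minimal_subset)
    log.info("diagnosis: minimal subset %s (size %s)", subset, report.stopping_size)

    diag = diagnostics.diagnostic_report(
        work, subset, positive_label="PwPD", negative_label="HS",
        label_col="label2", comparison="HS vs PwPD",
    )
    result = PipelineResult(
        task="diagnosis",
        pool=pool,
        protocol_result=proto,
        search_report=report,
        diagnostic_reports=[diag],
    )
    _persist(result, cfg)
    log.info("diagnosis: done in %.1f s", time.perf_counter() - t0)
    return result


def run_staging(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> PipelineResult:
    """Hoehn-Yahr staging workflow (4-class one-hot protocol).

    The feature pool is the PCA selection plus walking speed
    (force-included); diagnostics are pairwise cumulative-index reports for
    the default stage pairings (all pairs with ``all_stage_pairs``).
    """
    cfg = config or PipelineConfig()
    feat.validate_feature_table(table)
    stages = ("HY1", "HY2", "HY3", "HY4")
    present = set(table["label"])
    missing = [s for s in stages if s not in present]
    if missing:
        raise ValueError(f"staging requires all HY1-HY4 groups; missing {missing}")
    t0 = time.perf_counter()

    sel = feat.pca_select(table, threshold=cfg.pca_threshold)
    pool = list(sel.features)
    if "gait_speed" not in pool:
        pool.append("gait_speed")
    log.info("staging: pool (%d features, speed force-included): %s", len(pool), pool)

    work = table[table["label"].isin(stages)].copy()
    proto = run_protocol(work, pool, label_col="label", config=cfg.protocol())
    log.info("staging: full-pool mean P = %.1f%%", proto.mean_P)

    report = search_min_subset(
        work,
        pool,
        protocol_config=cfg.protocol(),
        alpha=cfg.alpha,
        margin=cfg.margin,
        label_col="label",
        max_size=cfg.max_subset_size,
        budget=cfg.subset_budget,
    )
    subset = list(report.minimal_subset)
    log.info("staging: minimal subset %s (size %s)", subset, report.stopping_size)

    if cfg.all_stage_pairs:
        pairs = [
            (b, a)
            for i, a in enumerate(stages)
            for b in stages[i + 1 :]
        ]
    else:
        pairs = list(DEFAULT_STAGE_PAIRS)
    reports = [
        diagnostics.diagnostic_report(
            work, subset, positive_label=worse, negative_label=better,
            comparison=f"{worse} vs {better}",
        )
        for worse, better in pairs
    ]
    result = PipelineResult(
        task="staging",
        pool=pool,
        protocol_result=proto,
        search_report=report,
        diagnostic_reports=reports,
    )
    _persist(result, cfg)
    log.info("staging: done in %.1f s", time.perf_counter() - t0)
    return result
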