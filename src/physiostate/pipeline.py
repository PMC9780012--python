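"""End-to-end orchestration: extract -> select -> tune -> evaluate.

The four stages mirror the hybrid prediction scheme: (1) RCMSE entropy
features are extracted per epoch and channel, (2) the reconstructed
features are ranked by a mutual-information criterion (CR-MIFS by default)
and the top k kept, (3) the RBF-SVM hyperparameters (C, g) are tuned by the
SA-gated particle swarm with cross-validated accuracy as fitness on the
training partition, and (4) the tuned classifier is fit on the training
partition and scored on the held-out test partition.

Every stage's artifact (feature table, selection trace, optimizer result,
evaluation report) is written as delimited text, together with a run
manifest recording the full configuration and seed; identical manifests
yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .entropy import EntropyParams
from .evaluation import EvalReport, evaluate_split
from .exceptions import ConfigError
from .features import FeatureTable, MultichannelRecord, build_feature_table, write_feature_table
from .mi_selection import CRITERIA, SelectionTrace, rank_features
from .sapso_svm import OptimResult, SapsoConfig, sapso_optimize

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults: m = 2, r = 0.2 sigma, scales (1, 2, 3, 5), entropies in
    bits, CR-MIFS keeping the top k = 8 features, a 0.7/0.2 stratified
    train/test split and fivefold CV fitness.

    The swarm defaults (12 particles, 15 iterations) are a desk-scale
    budget; raise them for harder surfaces.
    """

    entropy: EntropyParams = field(default_factory=EntropyParams)
    criterion: str = "CR-MIFS"
    k: int = 8
    n_bins: int | None = None
    beta: float = 0.5
    sapso: SapsoConfig = field(default_factory=lambda: SapsoConfig(swarm_size=12, n_iter=15))
    train_frac: float = 0.7
    test_frac: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise ConfigError(f"unknown criterion {self.criterion!r}")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not (0 < self.train_frac < 1 and 0 < self.test_frac < 1
                and self.train_frac + self.test_frac <= 1):
            raise ConfigError("split fractions must be positive and sum to <= 1")

    def manifest(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj

        return {"physiostate_version": __version__, "config": enc(self)}


@dataclass
class PipelineResult:
    table: FeatureTable
    trace: SelectionTrace
    optim: OptimResult
    report: EvalReport
    selected: list[str]
    timings_s: dict[str, float]


def _train_indices(table: FeatureTable, train_frac: float, seed: int) -> np.ndarray:
    from sklearn.model_selection import train_test_split

    idx = np.arange(table.n_cases)
    y = table.labels.to_numpy(dtype=object)
    train_idx, _ = train_test_split(idx, train_size=train_frac, stratify=y, random_state=seed)
    return train_idx


def run_pipeline(
    config: PipelineConfig,
    record: MultichannelRecord | None = None,
    table: FeatureTable | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run all four stages on a raw record or a precomputed feature table.

    Exactly one of ``record`` / ``table`` must be given.  When ``out_dir``
    is set, all stage artifacts and the run manifest are written there
    (partial artifacts are retained if a later stage fails).
    """
    if (record is None) == (table is None):
        raise ConfigError("pass exactly one of record= or table=")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(config.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    try:
        if record is not None:
            t0 = stage("extract")
            table = build_feature_table(record, config.entropy)
            timings["extract"] = time.perf_counter() - t0
            log.info("extract: %d cases x %d features in %.1fs",
                     table.n_cases, table.n_features, timings["extract"])
        if out is not None:
            write_feature_table(table, out / "feature_table.csv")

        t0 = stage("select")
        trace = rank_features(table, config.criterion, k=None,
                              beta=config.beta, n_bins=config.n_bins)
        selected = trace.order[: config.k]
        timings["select"] = time.perf_counter() - t0
        log.info("select (%s): %s", config.criterion, ", ".join(selected))
        if out is not None:
            trace.to_csv(out / "selection_trace.csv")

        t0 = stage("tune")
        train_idx = _train_indices(table, config.train_frac, config.seed)
        x_train = table.features.iloc[train_idx][selected].to_numpy(dtype=float)
        y_train = table.labels.iloc[train_idx].to_numpy(dtype=object)
        sapso = dataclasses.replace(config.sapso, seed=config.seed)
        optim = sapso_optimize(x_train, y_train, sapso)
        timings["tune"] = time.perf_counter() - t0
        log.info("tune: C=%.4g g=%.4g cv-fitness=%.4f (%.1fs)",
                 optim.best_c, optim.best_g, optim.best_fitness, timings["tune"])
        if out is not None:
            optim.to_csv(out / "optim_result.csv")

        t0 = stage("evaluate")
        report = evaluate_split(
            table, selected, optim.best_c, optim.best_g,
            config.train_frac, config.test_frac, config.seed,
        )
        timings["evaluate"] = time.perf_counter() - t0
        if out is not None:
            report.to_csv(out / "report.csv")
            with open(out / "report.txt", "w") as fh:
                fh.write(report.summary() + "\n")
    except Exception:
        done = ", ".join(timings) or "none"
        log.error("pipeline failed after stage(s): %s; partial artifacts retained", done)
        raise

    return PipelineResult(table, trace, optim, report, selected, timings)
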