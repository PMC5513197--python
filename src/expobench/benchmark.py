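"""Benchmark orchestration: scenarios x methods x replicates.

Every replicate simulates one training set (N=1200) and one validation set
(N=10000) from the same true model; all requested methods see *identical*
data (replicate-level sub-seeds are shared across methods), are fitted on
the training set and scored with the 13 performance measures.  Results are
collected long-format -- one row per (scenario, method, replicate, metric)
-- and aggregated as the arithmetic mean over non-missing replicates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation import CorrelationModel, GeneratorConfig, build_correlation_model
from .metrics import METRIC_NAMES, evaluate
from .scenarios import SCENARIOS, resolve_sigma, simulate_study
from .selectors import (BRT, DSA, EWAS2, GroupLassoInteractions, Lasso,
                        Sun3Step)
from .selectors.base import SelectionResults
from .selectors.dsa import DSAConfig
from .selectors.sun3step import Sun3StepConfig

__all__ = ["BenchmarkConfig", "ResultsTable", "run_benchmark",
           "ratio_report", "METHODS"]

METHODS = ("EWAS2", "DSA1", "DSA2", "Sun3step", "LASSO", "GLINTERNET", "BRT")


@dataclass(frozen=True)
class BenchmarkConfig:
    scenario_ids: Sequence[str] = ("1a",)
    methods: Sequence[str] = METHODS
    n_replicates: int = 100
    n_train: int = 1200
    n_valid: int = 10000
    master_seed: int = 0
    output_dir: str | None = None
    generator: GeneratorConfig | None = None
    # per-method keyword overrides, e.g. {"BRT": {"max_trees": 300}}
    method_options: Mapping[str, Mapping] = field(default_factory=dict)

    def validate(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        unknown = set(self.scenario_ids) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")


def _fit_method(name: str, study, families, seed: int,
                options: Mapping) -> SelectionResults:
    E, Y = study.train_exposures, study.train_outcome
    opts = dict(options.get(name, {}))
    if name == "EWAS2":
        return EWAS2(E, Y, **opts).fit()
    if name == "DSA1":
        return DSA(E, Y, config=DSAConfig(maxorder=1, seed=seed, **opts)).fit()
    if name == "DSA2":
        return DSA(E, Y, config=DSAConfig(maxorder=2, seed=seed, **opts)).fit()
    if name == "Sun3step":
        dsa_opts = {k[4:]: v for k, v in opts.items() if k.startswith("dsa_")}
        other = {k: v for k, v in opts.items() if not k.startswith("dsa_")}
        cfg = Sun3StepConfig(seed=seed,
                             dsa=DSAConfig(maxorder=2, seed=seed, **dsa_opts),
                             **other)
        return Sun3Step(E, Y, families, config=cfg).fit()
    if name == "LASSO":
        return Lasso(E, Y, seed=seed, **opts).fit()
    if name == "GLINTERNET":
        return GroupLassoInteractions(E, Y, seed=seed, **opts).fit()
    if name == "BRT":
        return BRT(E, Y, seed=seed, **opts).fit()
    raise ValueError(f"unknown method {name}")


@dataclass
class ResultsTable:
    """Long-format benchmark results plus aggregation helpers."""

    records: pd.DataFrame   # scenario_id, method, replicate, metric, value, missing, failed

    def aggregate(self) -> pd.DataFrame:
        df = self.records
        ok = df[~df["failed"]]
        grouped = ok.groupby(["scenario_id", "method", "metric"], sort=True)
        out = grouped.agg(
            mean=("value", lambda v: float(np.nanmean(v))
                  if np.isfinite(v).any() else np.nan),
            n=("value", lambda v: int(np.isfinite(v).sum())),
        ).reset_index()
        return out

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResultsTable":
        return cls(pd.read_csv(path))


def run_benchmark(config: BenchmarkConfig,
                  model: CorrelationModel | None = None) -> ResultsTable:
    """Execute the full experiment loop; resumable per (scenario, replicate).

    When ``output_dir`` is set, each completed (scenario, replicate) chunk
    is written to disk and skipped on re-run, so an interrupted run resumes
    to an identical final table.
    """
    config.validate()
    gen = config.generator or GeneratorConfig(seed=config.master_seed)
    if model is None:
        model = build_correlation_model(gen)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for sid in config.scenario_ids:
        spec = SCENARIOS[sid]
        sigma = resolve_sigma(spec, model, seed=config.master_seed)
        for rep in range(config.n_replicates):
            chunk_path = out_dir / f"chunk_{sid}_{rep:04d}.csv" if out_dir else None
            if chunk_path and chunk_path.exists():
                rows.append(pd.read_csv(chunk_path))
                continue
            sid_tag = zlib.crc32(sid.encode()) % 1009
            rep_seed = (config.master_seed * 9973 + sid_tag
                        + 131 * rep) % (2**31)
            study = simulate_study(spec, model, rep, seed=rep_seed,
                                   n_train=config.n_train,
                                   n_valid=config.n_valid, sigma=sigma)
            chunk_rows = []
            for name in config.methods:
                try:
                    res = _fit_method(name, study, model.family_labels,
                                      rep_seed, config.method_options)
                    report = evaluate(res, study, model)
                    failed = False
                    values = report.as_dict()
                except Exception:   # a single failing fit must not abort
                    failed = True
                    values = {m: np.nan for m in METRIC_NAMES}
                for metric, value in values.items():
                    chunk_rows.append({
                        "scenario_id": sid, "method": name,
                        "replicate": rep, "metric": metric,
                        "value": value,
                        "missing": bool(not np.isfinite(value)),
                        "failed": failed,
                    })
            chunk = pd.DataFrame(chunk_rows)
            if chunk_path:
                chunk.to_csv(chunk_path, index=False)
            rows.append(chunk)
    records = pd.concat(rows, ignore_index=True)
    table = ResultsTable(records)
    if out_dir:
        table.to_csv(out_dir / "results_long.csv")
        table.aggregate().to_csv(out_dir / "results_aggregated.csv",
                                 index=False)
    return table


def ratio_report(results: ResultsTable,
                 pairs: Sequence[tuple] = (("DSA2", "DSA1"),
                                           ("GLINTERNET", "LASSO")),
                 metrics: Sequence[str] = ("sens", "fdp")) -> pd.DataFrame:
    """Scenario-level mean-metric ratios (interaction-capable / mains-only).

    Mirrors the cost-of-searching-for-interactions comparison: each cell is
    the ratio of the scenario-level mean of a measure for the
    interaction-capable method to that of its mains-only counterpart.
    """
    agg = results.aggregate().set_index(["scenario_id", "method", "metric"])
    rows = []
    scenarios = sorted(results.records["scenario_id"].unique())
    for num, den in pairs:
        for sid in scenarios:
            row = {"scenario_id": sid, "numerator": num, "denominator": den}
            for metric in metrics:
                try:
                    a = agg.loc[(sid, num, metric), "mean"]
                    b = agg.loc[(sid, den, metric), "mean"]
                except KeyError:
                    row[metric] = np.nan
                    continue
                row[metric] = a / b if (np.isfinite(b) and b != 0) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
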