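"""End-to-end study orchestration.

Stage order is fixed: validate -> relevancy -> split -> tune (kernel x CV
cells) -> evaluate -> rank -> diagnose -> report.  Every stage's table is
written as CSV into the output directory and listed, with a content hash, in
``manifest.csv``; a fixed config (including seeds) reproduces the run
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, SplitDataset, fit_scaling, read_dataset, split, write_dataset
from .diagnostics import ResidualReport, ValidityReport, hat_diagonal, residual_report, williams_classify
from .evaluation import MetricReport, RankTable, STAGES, metric_report, metrics, rank_models, select_best
from .model import LSSVR
from .relevancy import RelevancyReport, relevancy_report
from .synthetic import GeneratorConfig, generate_corpus, literature_like_corpus
from .tuning import AnnealSchedule, CVScheme, SearchSpace, TuneResult, tune

log = logging.getLogger("polysol")

KERNELS = ("linear", "polynomial", "gaussian")
SCHEMES = ("loo", "kfold10")


@dataclass
class RunConfig:
    """Configuration of one full study run."""

    input_csv: str | None = None          # CSV path; None -> synthetic corpus
    synthetic: str = "literature"         # "literature" or "random" when no CSV
    n_systems: int = 20                   # random-generator settings
    points_per_system: int = 8
    noise_sd: float = 5.0
    ratio: float = 0.85
    seed: int = 0
    kernels: tuple[str, ...] = KERNELS
    schemes: tuple[str, ...] = SCHEMES
    sa_iterations: int = 100
    nm_maxiter: int = 100
    n_iv: int = 3                         # independent variables for the Williams plot
    outdir: str | None = None

    def load_dataset(self) -> Dataset:
        if self.input_csv is not None:
            return read_dataset(self.input_csv)
        if self.synthetic == "literature":
            return literature_like_corpus(self.seed)
        return generate_corpus(GeneratorConfig(
            n_systems=self.n_systems, points_per_system=self.points_per_system,
            noise_sd=self.noise_sd, seed=self.seed))

    def cv_scheme(self, name: str) -> CVScheme:
        if name == "loo":
            return CVScheme("leave_one_out", seed=self.seed)
        if name == "kfold10":
            return CVScheme("kfold", k=10, seed=self.seed)
        raise ValueError(f"unknown CV scheme {name!r}")


@dataclass
class StudyResult:
    config: RunConfig
    dataset: Dataset
    split: SplitDataset
    relevancy: RelevancyReport
    tune_results: dict[tuple[str, str], TuneResult]       # (kernel, scheme) -> result
    metric_reports: dict[tuple[str, str], MetricReport]
    rank_tables: dict[str, RankTable]                     # stage -> table over all cells
    best_label: str
    residuals: ResidualReport
    validity: ValidityReport
    manifest: dict[str, str] = field(default_factory=dict)  # filename -> sha256

    @property
    def best_cell(self) -> tuple[str, str]:
        kernel, scheme = self.best_label.split("+")
        return kernel, scheme

    def best_model_results(self):
        tr = self.tune_results[self.best_cell]
        return LSSVR.from_dataset(self.split.train, tr.kernel, tr.gamma).fit()


def _cell_label(kernel: str, scheme: str) -> str:
    return f"{kernel}+{scheme}"


def run_study(config: RunConfig) -> StudyResult:
    t_start = time.time()
    dataset = config.load_dataset()
    log.info("stage=validate n=%d seed=%d", len(dataset), config.seed)

    rel = relevancy_report(dataset)
    log.info("stage=relevancy strongest=%s", rel.strongest_feature())

    sp = split(dataset, config.ratio, config.seed)
    log.info("stage=split train=%d test=%d ratio=%.2f", len(sp.train), len(sp.test), config.ratio)

    schedule = AnnealSchedule(iterations=config.sa_iterations)
    space = SearchSpace()
    tune_results: dict[tuple[str, str], TuneResult] = {}
    reports: dict[tuple[str, str], MetricReport] = {}
    for scheme_name in config.schemes:
        scheme = config.cv_scheme(scheme_name)
        for kernel in config.kernels:
            t0 = time.time()
            tr = tune(sp.train, kernel, scheme, space=space, seed=config.seed,
                      schedule=schedule, nm_maxiter=config.nm_maxiter)
            tune_results[(kernel, scheme_name)] = tr
            res = LSSVR.from_dataset(sp.train, tr.kernel, tr.gamma).fit()
            reports[(kernel, scheme_name)] = metric_report(
                _cell_label(kernel, scheme_name),
                sp.train.t_sol, res.predict(sp.train),
                sp.test.t_sol, res.predict(sp.test),
            )
            log.info("stage=tune cell=%s cv_error=%.4f evals=%d wall=%.1fs",
                     _cell_label(kernel, scheme_name), tr.cv_error,
                     tr.evaluation_count, time.time() - t0)

    all_reports = list(reports.values())
    rank_tables = {stage: rank_models(all_reports, stage) for stage in STAGES}
    best_label = select_best(all_reports)
    log.info("stage=rank best=%s", best_label)

    best_kernel, best_scheme = best_label.split("+")
    btr = tune_results[(best_kernel, best_scheme)]
    bres = LSSVR.from_dataset(sp.train, btr.kernel, btr.gamma).fit()
    y_all = dataset.t_sol
    yhat_all = bres.predict(dataset)
    residuals = residual_report(y_all, yhat_all)
    # leverage on the full pooled feature matrix, scaled, no intercept column
    scaling = fit_scaling(dataset)
    hat = hat_diagonal(scaling.transform(dataset.features))
    validity = williams_classify(residuals.ad, residuals.sd, hat, n_iv=config.n_iv)
    log.info("stage=diagnose ad_ave=%.2f sd=%.2f valid=%d outliers=%d wall=%.1fs",
             residuals.ad_ave, residuals.sd, validity.n_valid, validity.n_outliers,
             time.time() - t_start)

    result = StudyResult(
        config=config, dataset=dataset, split=sp, relevancy=rel,
        tune_results=tune_results, metric_reports=reports,
        rank_tables=rank_tables, best_label=best_label,
        residuals=residuals, validity=validity,
    )
    if config.outdir is not None:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    emit("dataset.csv", lambda p: write_dataset(result.dataset, p))
    emit("relevancy.csv", lambda p: result.relevancy.to_frame().to_csv(p, index=False))
    metrics_df = pd.concat([r.to_frame() for r in result.metric_reports.values()],
                           ignore_index=True)
    emit("metrics.csv", lambda p: metrics_df.to_csv(p, index=False))
    ranks_df = pd.concat([t.to_frame() for t in result.rank_tables.values()],
                         ignore_index=True)
    emit("ranks.csv", lambda p: ranks_df.to_csv(p, index=False))
    tuned_rows = [{
        "kernel": k, "scheme": s, "cv_error": tr.cv_error, "gamma": tr.gamma,
        **{key: v for key, v in tr.kernel.to_dict().items() if key != "kind"},
        "evaluations": tr.evaluation_count, "seed": tr.seed,
    } for (k, s), tr in result.tune_results.items()]
    emit("tuned_parameters.csv", lambda p: pd.DataFrame(tuned_rows).to_csv(p, index=False))
    resid_df = pd.DataFrame({"ad": result.residuals.ad})
    emit("residuals.csv", lambda p: resid_df.to_csv(p, index=False))
    emit("williams.csv", lambda p: result.validity.to_frame().to_csv(p, index=False))
    summary = {
        "seed": result.config.seed, "ratio": result.config.ratio,
        "best": result.best_label,
        "ad_ave": result.residuals.ad_ave, "sd": result.residuals.sd,
        "n_valid": result.validity.n_valid, "n_outliers": result.validity.n_outliers,
        "cl": result.validity.cl,
    }
    emit("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2)))
    manifest = pd.DataFrame(sorted(files.items()), columns=["file", "sha256"])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    result.manifest = files


def trend_profiles(results, dataset: Dataset, systems: list[tuple[str, str]],
                   load_grid) -> dict[tuple[str, str], pd.DataFrame]:
    """Predicted T_sol along a drug-load grid for named (drug, polymer) systems.

    Each frame holds the grid predictions; frame.attrs["mardp"] is the
    per-system MARDP of the model against that system's own records.
    """
    load_grid = np.asarray(load_grid, dtype=float)
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for drug_name, polymer_name in systems:
        sub = dataset.subset_system(drug_name, polymer_name)
        r0 = sub.records[0]
        X = np.column_stack([
            np.full(len(load_grid), r0.drug_mw),
            np.full(len(load_grid), r0.polymer_mw),
            load_grid,
        ])
        pred = results.predict(X)
        df = pd.DataFrame({"drug_load_wt": load_grid, "t_sol_pred": pred})
        m = metrics(sub.t_sol, results.predict(sub))
        df.attrs["mardp"] = m.mardp
        df.attrs["system"] = (drug_name, polymer_name)
        out[(drug_name, polymer_name)] = df
    return out
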