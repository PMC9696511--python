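"""The four accuracy metrics and averaged-rank model selection.

MARDP  mean absolute relative deviation percent, mean(100 |y - yhat| / y)
MADP   mean absolute deviation in degC (the relative/percent variant printed
       elsewhere is dimensionally inconsistent with reported values ~ 11 degC,
       so the plain absolute deviation is used)
RMSE   root mean squared error, degC
R      coefficient-of-determination-style score 1 - SSE/SST; <= 1, and
       negative whenever the model is worse than the mean predictor

Models are compared by ranking them on each of the four indexes (ascending
error, descending R), averaging the four ranks, and rounding half-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGES = ("training", "testing", "overall")
METRIC_NAMES = ("mardp", "madp", "rmse", "r_value")


@dataclass(frozen=True)
class Metrics:
    mardp: float   # %
    madp: float    # degC
    rmse: float    # degC
    r_value: float # dimensionless, <= 1

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mardp, self.madp, self.rmse, self.r_value)


def metrics(y_true, y_pred) -> Metrics:
    y = np.asarray(y_true, dtype=float).ravel()
    yhat = np.asarray(y_pred, dtype=float).ravel()
    if len(y) != len(yhat):
        raise ValueError("y_true and y_pred lengths differ")
    if len(y) < 1:
        raise ValueError("need at least one observation")
    if np.any(y == 0):
        raise ValueError("MARDP undefined: y_true contains a zero entry")
    err = y - yhat
    mardp = float(np.mean(100.0 * np.abs(err) / np.abs(y)))
    madp = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        r = 1.0 if np.allclose(err, 0) else -np.inf
    else:
        r = 1.0 - float(np.sum(err**2)) / sst
    return Metrics(mardp, madp, rmse, r)


@dataclass(frozen=True)
class MetricReport:
    """Four metrics per stage for one fitted model."""

    label: str
    training: Metrics
    testing: Metrics
    overall: Metrics

    def stage(self, name: str) -> Metrics:
        if name not in STAGES:
            raise KeyError(f"unknown stage {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in STAGES:
            m = self.stage(s)
            rows.append({"model": self.label, "stage": s, **m.__dict__})
        return pd.DataFrame(rows)


def metric_report(label: str, y_train, yhat_train, y_test, yhat_test) -> MetricReport:
    y_all = np.concatenate([np.asarray(y_train, float).ravel(),
                            np.asarray(y_test, float).ravel()])
    yhat_all = np.concatenate([np.asarray(yhat_train, float).ravel(),
                               np.asarray(yhat_test, float).ravel()])
    return MetricReport(
        label=label,
        training=metrics(y_train, yhat_train),
        testing=metrics(y_test, yhat_test),
        overall=metrics(y_all, yhat_all),
    )


def _rank_ascending(values: np.ndarray) -> np.ndarray:
    """Competition-free average ranks, 1..M, ties share the average rank."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class RankTable:
    """Per-model ranks on each index plus the rounded average rank, one stage."""

    stage: str
    labels: list[str]
    index_ranks: dict[str, np.ndarray]   # metric name -> rank per model
    mean_rank: np.ndarray                # unrounded average of the four ranks
    average_rank: np.ndarray             # rounded half-up

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"model": self.labels, "stage": self.stage})
        for name in METRIC_NAMES:
            df[f"rank_{name}"] = self.index_ranks[name]
        df["mean_rank"] = self.mean_rank
        df["average_rank"] = self.average_rank
        return df

    def rank_of(self, label: str) -> int:
        return int(self.average_rank[self.labels.index(label)])

    def winner(self) -> str:
        return self.labels[int(np.argmin(self.mean_rank))]


def rank_models(reports: list[MetricReport], stage: str) -> RankTable:
    """Rank >= 2 models on one stage: ascending in the three error metrics,
    descending in R, averaged and rounded half-up."""
    if len(reports) < 2:
        raise ValueError("ranking needs at least 2 models")
    labels = [r.label for r in reports]
    vals = {name: np.array([getattr(r.stage(stage), name) for r in reports])
            for name in METRIC_NAMES}
    index_ranks = {
        "mardp": _rank_ascending(vals["mardp"]),
        "madp": _rank_ascending(vals["madp"]),
        "rmse": _rank_ascending(vals["rmse"]),
        "r_value": _rank_ascending(-vals["r_value"]),
    }
    stacked = np.vstack([index_ranks[n] for n in METRIC_NAMES])
    mean_rank = stacked.mean(axis=0)
    avg = np.array([_round_half_up(v) for v in mean_rank])
    return RankTable(stage=stage, labels=labels, index_ranks=index_ranks,
                     mean_rank=mean_rank, average_rank=avg)


def select_best(reports: list[MetricReport]) -> str:
    """Pick the best model by overall-stage mean rank.

    Ties on the overall stage are broken by the testing-stage mean rank
    (generalization first), then by overall MARDP.
    """
    overall = rank_models(reports, "overall")
    testing = rank_models(reports, "testing")
    mardp = np.array([r.overall.mardp for r in reports])
    keys = list(zip(overall.mean_rank, testing.mean_rank, mardp))
    best = min(range(len(reports)), key=lambda i: keys[i])
    return reports[best].label
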