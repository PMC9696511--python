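"""Feature relevancy: Pearson and Spearman association of each feature with T_sol.

A positive coefficient marks a direct (increasing) relationship between the
feature and the solubility temperature, a negative one an indirect
(decreasing) relationship; the magnitude orders the features by strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset, FEATURE_COLUMNS

METHODS = ("pearson", "spearman")


class UndefinedCoefficientError(ValueError):
    """Correlation undefined: one of the variables has zero variance."""


def _validate(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCoefficientError("zero variance in one of the variables")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation: sum of co-deviations over the norm product."""
    x, y = _validate(x, y)
    dx = x - x.mean()
    dy = y - y.mean()
    return float(np.dot(dx, dy) / np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))


def _average_ranks(v: np.ndarray) -> np.ndarray:
    """Ranks 1..N with tied values sharing their average rank."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    sv = v[order]
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x, y) -> float:
    """Rank correlation.

    With no ties this is the classical 1 - 6*sum(d^2)/(N^3 - N); with ties,
    average ranks are assigned and the Pearson coefficient of the ranks is
    returned (the two coincide in the tie-free case).
    """
    x, y = _validate(x, y)
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    n = len(x)
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if no_ties:
        d = rx - ry
        return float(1.0 - 6.0 * np.sum(d * d) / (n ** 3 - n))
    return pearson(rx, ry)


@dataclass(frozen=True)
class RelevancyReport:
    """Coefficient per (feature, method) for the three model features vs T_sol."""

    coefficients: dict[tuple[str, str], float]  # (feature, method) -> value

    def coefficient(self, feature: str, method: str) -> float:
        return self.coefficients[(feature, method)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": f, "method": m, "coefficient": v}
            for (f, m), v in self.coefficients.items()
        ]
        return pd.DataFrame(rows)

    def strongest_feature(self, method: str = "pearson") -> str:
        """Feature with the maximum (signed) coefficient under ``method``."""
        items = {f: v for (f, m), v in self.coefficients.items() if m == method}
        return max(items, key=items.get)


def relevancy_report(dataset: Dataset) -> RelevancyReport:
    X = dataset.features
    y = dataset.t_sol
    coeffs: dict[tuple[str, str], float] = {}
    for j, feature in enumerate(FEATURE_COLUMNS):
        coeffs[(feature, "pearson")] = pearson(X[:, j], y)
        coeffs[(feature, "spearman")] = spearman(X[:, j], y)
    return RelevancyReport(coeffs)
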