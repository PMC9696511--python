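"""Residual statistics and leverage-based data-validity (Williams) analysis.

The actual difference AD_n = y_n - yhat_n (degC) is summarised by its mean
and population standard deviation and binned into a histogram centred at
zero.  Data validity uses the Williams plot: the standard residual
SR = AD / SD against the leverage (the diagonal of the projection matrix of
the independent-variable design), with a record flagged as an outlier when
its leverage exceeds the critical value CL = 3 (NIV + 1) / N or |SR| > 3.
Following the source convention, the design matrix carries no intercept
column while CL still counts NIV + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ResidualReport:
    ad: np.ndarray        # per-record actual difference, degC
    ad_ave: float         # mean AD, degC
    sd: float             # population standard deviation of AD, degC
    bin_edges: np.ndarray
    counts: np.ndarray


def residual_report(y_true, y_pred, bin_width: float = 10.0) -> ResidualReport:
    y = np.asarray(y_true, dtype=float).ravel()
    yhat = np.asarray(y_pred, dtype=float).ravel()
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    ad = y - yhat
    ad_ave = float(np.mean(ad))
    sd = float(np.sqrt(np.mean((ad - ad_ave) ** 2)))  # 1/N normalisation
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    # symmetric bins centred on zero: edges at (k + 1/2) * bin_width
    extent = max(np.max(np.abs(ad)), bin_width / 2.0)
    k = int(np.ceil((extent - bin_width / 2.0) / bin_width))
    edges = (np.arange(-k - 1, k + 1) + 0.5) * bin_width
    counts, _ = np.histogram(ad, bins=edges)
    return ResidualReport(ad=ad, ad_ave=ad_ave, sd=sd, bin_edges=edges, counts=counts)


def hat_diagonal(miv: np.ndarray) -> np.ndarray:
    """Leverages: diagonal of MIV (MIV' MIV)^-1 MIV', computed via QR."""
    X = np.atleast_2d(np.asarray(miv, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank-deficient")
    Q, _ = np.linalg.qr(X, mode="reduced")
    return np.sum(Q * Q, axis=1)


@dataclass(frozen=True)
class ValidityReport:
    hat: np.ndarray       # leverage per record
    sr: np.ndarray        # standard residual per record
    flags: np.ndarray     # "valid" / "outlier"
    cl: float             # critical leverage 3 (NIV + 1) / N

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.flags == "valid"))

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.flags == "outlier"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "record": np.arange(len(self.hat)),
            "hat": self.hat,
            "sr": self.sr,
            "flag": self.flags,
            "cl": self.cl,
        })


def critical_leverage(n: int, n_iv: int) -> float:
    return 3.0 * (n_iv + 1) / n


def williams_classify(ad, sd: float, hat, n_iv: int) -> ValidityReport:
    """Flag each record valid/outlier from its standard residual and leverage."""
    ad = np.asarray(ad, dtype=float).ravel()
    hat = np.asarray(hat, dtype=float).ravel()
    if len(ad) != len(hat):
        raise ValueError("ad and hat lengths differ")
    if sd <= 0:
        raise ValueError("degenerate residuals: sd must be > 0")
    sr = ad / sd
    cl = critical_leverage(len(ad), n_iv)
    outlier = (hat > cl) | (np.abs(sr) > 3.0)
    flags = np.where(outlier, "outlier", "valid")
    return ValidityReport(hat=hat, sr=sr, flags=flags, cl=cl)
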