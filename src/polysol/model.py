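"""Least-squares support vector regression, statsmodels-style.

The model minimises

    OF(w, e) = 1/2 w'w + gamma/2 * sum_n e_n^2,    e_n = y_n - w'phi(x_n) - b,

over weights w in the kernel-induced feature space and bias b.  Because the
loss is squared, the optimum is the solution of one linear KKT system in the
dual variables alpha and the bias b (Suykens formulation with explicit bias):

    [ 0   1'          ] [ b     ]   [ 0 ]
    [ 1   K + I/gamma ] [ alpha ] = [ y ]

and predictions are yhat(x) = sum_i alpha_i K(x_i, x) + b.  The system is
solved exactly and deterministically; stochastic search is reserved for the
hyperparameters (see :mod:`polysol.tuning`).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import scipy.linalg

from .data import Dataset, ScalingParams, fit_scaling
from .kernels import KernelSpec, cross_gram, gram_matrix


class FitError(RuntimeError):
    """The KKT system could not be solved to acceptable accuracy."""


class LSSVR:
    """LS-SVR model specification bound to training data.

    Parameters
    ----------
    endog : (N,) array
        Observed solubility temperatures (degC).
    exog : (N, 3) array
        Raw features ``(drug_mw, polymer_mw, drug_load)``.
    kernel : KernelSpec
    gamma : float
        Regularization weight on the squared training errors, > 0.
        Larger gamma fits the data more closely.
    scaling : ScalingParams, "minmax", or None
        "minmax" (default) learns per-feature min-max scaling from ``exog``;
        pass an existing ScalingParams to reuse one, or None for raw features.
    """

    def __init__(self, endog, exog, kernel: KernelSpec, gamma: float,
                 scaling: ScalingParams | str | None = "minmax") -> None:
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if len(y) != X.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if len(y) < 2:
            raise ValueError("need at least 2 training samples")
        if not np.isfinite(gamma) or gamma <= 0:
            raise ValueError(f"gamma must be a positive finite number, got {gamma}")
        self.endog = y
        self.exog = X
        self.kernel = kernel
        self.gamma = float(gamma)
        if scaling == "minmax":
            self.scaling: ScalingParams | None = fit_scaling(X)
        elif isinstance(scaling, ScalingParams) or scaling is None:
            self.scaling = scaling
        else:
            raise ValueError(f"unknown scaling option {scaling!r}")

    @classmethod
    def from_dataset(cls, train: Dataset, kernel: KernelSpec, gamma: float,
                     scaling: ScalingParams | str | None = "minmax") -> "LSSVR":
        return cls(train.t_sol, train.features, kernel, gamma, scaling=scaling)

    def _scaled(self, X: np.ndarray) -> np.ndarray:
        return self.scaling.transform(X) if self.scaling is not None else np.atleast_2d(X)

    def fit(self) -> "LSSVRResults":
        """Solve the dual KKT system; exact minimiser of the LS-SVR objective."""
        Z = self._scaled(self.exog)
        y = self.endog
        n = len(y)
        K = gram_matrix(self.kernel, Z)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / self.gamma
        rhs = np.concatenate(([0.0], y))
        jitter_used = 0.0
        # conditioning is checked explicitly via the KKT residual below
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                sol = scipy.linalg.solve(A, rhs, assume_a="sym")
        except scipy.linalg.LinAlgError:
            sol = None
        if sol is None or not np.all(np.isfinite(sol)) or _rel_residual(A, sol, rhs) > 1e-8:
            # ill-conditioned: retry with a small diagonal jitter on the kernel block
            jitter_used = 1e-10
            A[1:, 1:] += jitter_used * np.eye(n)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                    sol = scipy.linalg.solve(A, rhs, assume_a="sym")
            except scipy.linalg.LinAlgError as exc:
                raise FitError(
                    "KKT system numerically singular even with 1e-10 jitter; "
                    "consider a larger 1/gamma"
                ) from exc
            if not np.all(np.isfinite(sol)) or _rel_residual(A, sol, rhs) > 1e-6:
                raise FitError(
                    "KKT system numerically singular; consider a larger 1/gamma"
                )
        return LSSVRResults(self, support=Z, alpha=sol[1:], bias=float(sol[0]),
                            jitter=jitter_used)


def _rel_residual(A: np.ndarray, sol: np.ndarray, rhs: np.ndarray) -> float:
    denom = max(np.linalg.norm(rhs), 1e-300)
    return float(np.linalg.norm(A @ sol - rhs) / denom)


class LSSVRResults:
    """Fitted LS-SVR: dual coefficients, bias, and prediction machinery."""

    def __init__(self, model: LSSVR, support: np.ndarray, alpha: np.ndarray,
                 bias: float, jitter: float = 0.0) -> None:
        self.model = model
        self.support = support          # scaled training features
        self.alpha = alpha
        self.bias = bias
        self.jitter = jitter

    # -- statsmodels-flavoured accessors ------------------------------------
    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        """Actual difference y - yhat on the training data (degC)."""
        return self.model.endog - self.fittedvalues

    def predict(self, exog) -> np.ndarray:
        """Predict T_sol for raw features or a Dataset."""
        if isinstance(exog, Dataset):
            exog = exog.features
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        Z = self.model._scaled(X)
        K = cross_gram(self.model.kernel, Z, self.support)
        return K @ self.alpha + self.bias

    def summary(self) -> str:
        from .evaluation import metrics  # local import to avoid a cycle

        m = metrics(self.model.endog, self.fittedvalues)
        k = self.model.kernel
        lines = [
            "LS-SVR results",
            "=" * 46,
            f"kernel:            {k.kind}",
        ]
        if k.kind == "polynomial":
            lines.append(f"  t (offset):      {k.t:.6g}")
            lines.append(f"  d (degree):      {k.d}")
        if k.kind == "gaussian":
            lines.append(f"  sigma2 (width):  {k.sigma2:.6g}")
        lines += [
            f"gamma:             {self.model.gamma:.6g}",
            f"n train samples:   {len(self.model.endog)}",
            f"bias b:            {self.bias:.6g}",
            f"train MARDP (%):   {m.mardp:.4f}",
            f"train MADP (degC): {m.madp:.4f}",
            f"train RMSE (degC): {m.rmse:.4f}",
            f"train R-value:     {m.r_value:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        scaling = self.model.scaling
        payload = {
            "kernel": self.model.kernel.to_dict(),
            "gamma": self.model.gamma,
            "alpha": self.alpha.tolist(),
            "bias": self.bias,
            "scaling": None if scaling is None else {
                "minimum": scaling.minimum.tolist(),
                "maximum": scaling.maximum.tolist(),
            },
            "exog": self.model.exog.tolist(),
            "endog": self.model.endog.tolist(),
        }
        return json.dumps(payload)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "LSSVRResults":
        d = json.loads(text)
        scaling = d["scaling"]
        params = None if scaling is None else ScalingParams(
            minimum=np.array(scaling["minimum"]), maximum=np.array(scaling["maximum"])
        )
        model = LSSVR(np.array(d["endog"]), np.array(d["exog"]),
                      KernelSpec.from_dict(d["kernel"]), d["gamma"], scaling=params)
        support = model._scaled(model.exog)
        return cls(model, support=support, alpha=np.array(d["alpha"]), bias=d["bias"])

    @classmethod
    def load(cls, path: str | Path) -> "LSSVRResults":
        return cls.from_json(Path(path).read_text())
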