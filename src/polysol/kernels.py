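"""Kernel functions for the LS-SVR: linear, polynomial and Gaussian."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

VALID_KINDS = ("linear", "polynomial", "gaussian")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice plus its parameters.

    linear:      K(x, x') = x.x'
    polynomial:  K(x, x') = (x.x' + t)^d   with offset t >= 0, integer degree d >= 1
    gaussian:    K(x, x') = exp(-||x - x'||^2 / (2 sigma2))   with width sigma2 > 0
    """

    kind: str
    t: float | None = None
    d: int | None = None
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; expected one of {VALID_KINDS}")
        if self.kind == "polynomial":
            if self.t is None or self.t < 0:
                raise ValueError("polynomial kernel requires offset t >= 0")
            if self.d is None or int(self.d) != self.d or self.d < 1:
                raise ValueError("polynomial kernel requires integer degree d >= 1")
            if self.sigma2 is not None:
                raise ValueError("sigma2 is not a polynomial-kernel parameter")
        elif self.kind == "gaussian":
            if self.sigma2 is None or self.sigma2 <= 0:
                raise ValueError("gaussian kernel requires sigma2 > 0")
            if self.t is not None or self.d is not None:
                raise ValueError("t/d are not gaussian-kernel parameters")
        else:  # linear
            if any(p is not None for p in (self.t, self.d, self.sigma2)):
                raise ValueError("linear kernel takes no parameters")

    @classmethod
    def linear(cls) -> "KernelSpec":
        return cls("linear")

    @classmethod
    def polynomial(cls, t: float, d: int) -> "KernelSpec":
        return cls("polynomial", t=float(t), d=int(d))

    @classmethod
    def gaussian(cls, sigma2: float) -> "KernelSpec":
        return cls("gaussian", sigma2=float(sigma2))

    def to_dict(self) -> dict:
        out = {"kind": self.kind}
        if self.kind == "polynomial":
            out.update(t=self.t, d=self.d)
        elif self.kind == "gaussian":
            out.update(sigma2=self.sigma2)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        kind = d["kind"]
        if kind == "polynomial":
            return cls.polynomial(d["t"], d["d"])
        if kind == "gaussian":
            return cls.gaussian(d["sigma2"])
        return cls.linear()


def kernel_eval(spec: KernelSpec, xi: np.ndarray, xj: np.ndarray) -> float:
    """Evaluate K(xi, xj) for a single pair of feature vectors."""
    xi = np.asarray(xi, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    if xi.shape != xj.shape:
        raise ValueError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    return float(cross_gram(spec, xi[None, :], xj[None, :])[0, 0])


def cross_gram(spec: KernelSpec, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Kernel matrix K[i, j] = K(X[i], Z[j]) between two sets of points."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if spec.kind == "linear":
        return X @ Z.T
    if spec.kind == "polynomial":
        return (X @ Z.T + spec.t) ** spec.d
    sq = cdist(X, Z, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * spec.sigma2))


def gram_matrix(spec: KernelSpec, X: np.ndarray) -> np.ndarray:
    """Symmetric Gram matrix of X under the kernel; symmetrized to kill round-off."""
    K = cross_gram(spec, X, X)
    return (K + K.T) / 2.0
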