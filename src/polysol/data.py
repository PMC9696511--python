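"""Dataset container, CSV I/O, train/test splitting and feature scaling.

The modelled system is a flat table of drug-polymer solubility observations:
each record gives a drug, a polymeric carrier, their molecular weights, the
drug load (wt%) and the measured solubility temperature T_sol (degC).  The
feature vector seen by the regression model is exactly
``(drug_mw, polymer_mw, drug_load)``; drug and polymer names are carried as
metadata only, so two species are distinguishable to the model only through
their molecular weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical CSV header, in order
COLUMNS = ["drug_name", "polymer_name", "drug_mw", "polymer_mw", "drug_load_wt", "t_sol_c"]

FEATURE_COLUMNS = ["drug_mw", "polymer_mw", "drug_load_wt"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A record violates a domain invariant (range, sign, finiteness)."""


@dataclass(frozen=True)
class SolubilityRecord:
    """One experimental observation of drug solubility in a polymer.

    ``drug_load == 100`` wt% denotes the pure drug, whose solubility
    temperature is its melting temperature.
    """

    drug_name: str
    polymer_name: str
    drug_mw: float      # g/mol, > 0
    polymer_mw: float   # g/mol, > 0
    drug_load: float    # wt%, in [0, 100]
    t_sol: float        # degC, finite

    def __post_init__(self) -> None:
        if not np.isfinite(self.drug_mw) or self.drug_mw <= 0:
            raise ValidationError(f"drug_mw must be > 0, got {self.drug_mw!r}")
        if not np.isfinite(self.polymer_mw) or self.polymer_mw <= 0:
            raise ValidationError(f"polymer_mw must be > 0, got {self.polymer_mw!r}")
        if not np.isfinite(self.drug_load) or not 0.0 <= self.drug_load <= 100.0:
            raise ValidationError(
                f"drug_load must lie in [0, 100] wt%, got {self.drug_load!r}"
            )
        if not np.isfinite(self.t_sol):
            raise ValidationError(f"t_sol must be finite, got {self.t_sol!r}")


class Dataset:
    """Ordered collection of :class:`SolubilityRecord` with array accessors."""

    def __init__(self, records: Iterable[SolubilityRecord], provenance: str = "") -> None:
        self.records: list[SolubilityRecord] = list(records)
        if not self.records:
            raise ValidationError("a Dataset must contain at least one record")
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return Dataset([self.records[i] for i in idx], self.provenance)
        return self.records[idx]

    def __eq__(self, other) -> bool:
        return isinstance(other, Dataset) and self.records == other.records

    @property
    def features(self) -> np.ndarray:
        """(N, 3) array of (drug_mw, polymer_mw, drug_load)."""
        return np.array(
            [[r.drug_mw, r.polymer_mw, r.drug_load] for r in self.records], dtype=float
        )

    @property
    def t_sol(self) -> np.ndarray:
        return np.array([r.t_sol for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_name": [r.drug_name for r in self.records],
                "polymer_name": [r.polymer_name for r in self.records],
                "drug_mw": [r.drug_mw for r in self.records],
                "polymer_mw": [r.polymer_mw for r in self.records],
                "drug_load_wt": [r.drug_load for r in self.records],
                "t_sol_c": [r.t_sol for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "Dataset":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            vals = {}
            for col in ["drug_mw", "polymer_mw", "drug_load_wt", "t_sol_c"]:
                raw = getattr(row, col)
                try:
                    vals[col] = float(raw)
                except (TypeError, ValueError) as exc:
                    raise ValidationError(
                        f"row {i}: non-numeric value {raw!r} in column {col}"
                    ) from exc
            try:
                records.append(
                    SolubilityRecord(
                        drug_name=str(row.drug_name),
                        polymer_name=str(row.polymer_name),
                        drug_mw=vals["drug_mw"],
                        polymer_mw=vals["polymer_mw"],
                        drug_load=vals["drug_load_wt"],
                        t_sol=vals["t_sol_c"],
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
        return cls(records, provenance)

    def systems(self) -> list[tuple[str, str]]:
        """Distinct (drug, polymer) pairs, first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for r in self.records:
            seen.setdefault((r.drug_name, r.polymer_name), None)
        return list(seen)

    def subset_system(self, drug_name: str, polymer_name: str) -> "Dataset":
        recs = [
            r for r in self.records
            if r.drug_name == drug_name and r.polymer_name == polymer_name
        ]
        if not recs:
            raise KeyError(f"no records for system ({drug_name!r}, {polymer_name!r})")
        return Dataset(recs, self.provenance)


def read_dataset(path: str | Path) -> Dataset:
    """Read a solubility CSV (comma-separated, UTF-8, '.' decimal, header required)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Dataset.from_frame(df, provenance=str(path))


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the canonical CSV; numeric text uses repr so read->write round-trips."""
    df = dataset.to_frame()
    # float_format=None + repr-stable values: pandas writes shortest round-trip repr
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class SplitDataset:
    train: Dataset
    test: Dataset
    ratio: float
    seed: int


def split(dataset: Dataset, ratio: float, seed: int) -> SplitDataset:
    """Uniform random train/test partition; train size = round(ratio * N)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie strictly in (0, 1), got {ratio}")
    n = len(dataset)
    if n < 2:
        raise ValidationError("need at least 2 records to split")
    n_train = int(np.floor(ratio * n + 0.5))  # round half-up
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return SplitDataset(
        train=dataset[train_idx], test=dataset[test_idx], ratio=ratio, seed=seed
    )


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature min-max scaling learned on training data only.

    Maps each of the three features affinely onto [0, 1] over the training
    range; out-of-range (test) values are transformed by the same affine map
    and are deliberately not clipped.
    """

    minimum: np.ndarray = field(repr=False)
    maximum: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lo = np.asarray(self.minimum, dtype=float)
        hi = np.asarray(self.maximum, dtype=float)
        object.__setattr__(self, "minimum", lo)
        object.__setattr__(self, "maximum", hi)
        if np.any(hi <= lo):
            bad = np.nonzero(hi <= lo)[0]
            raise ValidationError(
                f"degenerate feature(s) {bad.tolist()}: zero spread on training data"
            )

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.minimum) / (self.maximum - self.minimum)

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z * (self.maximum - self.minimum) + self.minimum


def fit_scaling(train: Dataset | np.ndarray) -> ScalingParams:
    X = train.features if isinstance(train, Dataset) else np.asarray(train, dtype=float)
    return ScalingParams(minimum=X.min(axis=0), maximum=X.max(axis=0))


def apply_scaling(params: ScalingParams, records: Dataset | Sequence[SolubilityRecord] | np.ndarray) -> np.ndarray:
    if isinstance(records, Dataset):
        X = records.features
    elif isinstance(records, np.ndarray):
        X = records
    else:
        X = Dataset(list(records)).features
    return params.transform(X)
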