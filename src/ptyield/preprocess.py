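"""Normalization, train/test splitting and the residual outlier filter.

The modelling pipeline min-max normalizes features and the target to [0,1],
splits cases 75/25, and — following an initial linear fit — removes cases
whose absolute residual on the normalized scale exceeds twice the maximum
residual of the bulk of the data (0.4 vs 0.2 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_data import SchemaError, ValidationError

__all__ = [
    "NormalizationParams",
    "SplitSpec",
    "minmax_normalize",
    "denormalize",
    "split_dataset",
    "pearson_residual_filter",
]


@dataclass
class NormalizationParams:
    """Per-column min/max of a fitted min-max transform."""

    minima: dict[str, float]
    maxima: dict[str, float]
    fitted_on: str = "full"

    @property
    def columns(self) -> list[str]:
        return list(self.minima)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"minima": self.minima, "maxima": self.maxima, "fitted_on": self.fitted_on},
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(minima=d["minima"], maxima=d["maxima"], fitted_on=d["fitted_on"])


@dataclass
class SplitSpec:
    """How to split cases into train and test."""

    train_fraction: float = 0.75
    seed: int = 0
    mode: str = "case"  # "case" or "sample-aware"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie strictly in (0, 1)")
        if self.mode not in ("case", "sample-aware"):
            raise ValidationError(f"unknown split mode {self.mode!r}")


def minmax_normalize(
    dataset: pd.DataFrame,
    columns: list[str] | None = None,
    params: NormalizationParams | None = None,
    fitted_on: str = "full",
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Map each column to [0,1] by (x - min) / (max - min).

    With ``params`` given, applies the stored transform (new data may fall
    outside [0,1]); otherwise fits on ``dataset``.  Constant columns cannot
    be normalized and raise an error naming the column.
    """
    if columns is None:
        columns = (
            params.columns
            if params is not None
            else [c for c in dataset.columns if pd.api.types.is_numeric_dtype(dataset[c])]
        )
    missing = [c for c in columns if c not in dataset.columns]
    if missing:
        raise SchemaError(f"columns absent from dataset: {', '.join(missing)}")
    if params is None:
        minima, maxima = {}, {}
        for c in columns:
            lo = float(dataset[c].min())
            hi = float(dataset[c].max())
            if not hi > lo:
                raise ValidationError(f"column {c!r} is constant and cannot be normalized")
            minima[c], maxima[c] = lo, hi
        params = NormalizationParams(minima=minima, maxima=maxima, fitted_on=fitted_on)
    else:
        unknown = [c for c in columns if c not in params.minima]
        if unknown:
            raise SchemaError(
                f"normalization params lack column(s): {', '.join(unknown)}"
            )
    out = dataset.copy()
    for c in columns:
        lo, hi = params.minima[c], params.maxima[c]
        out[c] = (dataset[c] - lo) / (hi - lo)
    return out, params


def denormalize(dataset: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Inverse of :func:`minmax_normalize` for the columns in ``params``."""
    out = dataset.copy()
    for c in params.columns:
        if c in out.columns:
            lo, hi = params.minima[c], params.maxima[c]
            out[c] = dataset[c] * (hi - lo) + lo
    return out


def split_dataset(dataset: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split of a case table.

    ``case`` mode permutes cases in a canonical order (sorted by
    (query_id, ref_id) when present, by position otherwise) so the membership
    depends only on the seed, not on input row order.  ``sample-aware`` mode
    holds out whole samples: every case whose query or reference touches a
    held-out sample goes to test, so no sample leaks across the split.
    """
    if len(dataset) < 4:
        raise ValidationError("need at least 4 cases to split")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "case":
        if {"query_id", "ref_id"} <= set(dataset.columns):
            order = dataset.sort_values(["query_id", "ref_id"], kind="mergesort").index
        else:
            order = dataset.index
        perm = rng.permutation(len(order))
        n_train = int(round(spec.train_fraction * len(order)))
        train_idx = pd.Index(order[perm[:n_train]])
        train = dataset.loc[dataset.index.isin(train_idx)]
        test = dataset.loc[~dataset.index.isin(train_idx)]
        return train, test
    # sample-aware
    if not {"query_id", "ref_id"} <= set(dataset.columns):
        raise SchemaError("sample-aware split needs query_id and ref_id columns")
    sample_ids = np.array(
        sorted(set(dataset["query_id"]).union(dataset["ref_id"]))
    )
    perm = rng.permutation(len(sample_ids))
    n_train_samples = int(round(spec.train_fraction * len(sample_ids)))
    train_samples = set(sample_ids[perm[:n_train_samples]])
    in_train = dataset["query_id"].isin(train_samples) & dataset["ref_id"].isin(train_samples)
    return dataset.loc[in_train], dataset.loc[~in_train]


def pearson_residual_filter(
    dataset: pd.DataFrame,
    fitted: np.ndarray | pd.Series,
    threshold: float = 0.4,
    target: str = "target",
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Partition cases by absolute residual against a linear fit.

    ``fitted`` are the model's fitted values for ``dataset`` on the same
    (normalized) scale as the target.  Cases with |observed - fitted| >
    ``threshold`` are removed.  Returns (kept, removed, removed_fraction);
    the fraction is exact — round at presentation.
    """
    if not threshold > 0:
        raise ValidationError("threshold must be positive")
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape[0] != len(dataset):
        raise SchemaError("fitted values must align with the dataset rows")
    resid = dataset[target].to_numpy() - fitted
    removed_mask = np.abs(resid) > threshold
    kept = dataset.loc[~removed_mask]
    removed = dataset.loc[removed_mask]
    fraction = float(removed_mask.mean()) if len(dataset) else 0.0
    return kept, removed, fraction
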