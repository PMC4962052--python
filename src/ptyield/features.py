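"""Moving-average condition operators and pairwise perturbation features.

The predictive model treats each experimental condition class — segment
(8 levels), postnatal day (7 levels), feeding system — as a source of
perturbations of the growth yield.  The moving-average (Box-Jenkins)
operator <V_g(c)> is simply the mean expression of gene g over every sample
sharing one level of one condition class; the perturbation term
dV_g(c) = V_g(query) - <V_g(level_c)> measures how far a query sample's
expression sits from that condition mean.

A modelling case is an ordered (query, reference) pair of samples: the
target is the query's observed yield, and the inputs are the expected yield
under the reference's exact condition triple plus the query's expressions
and their perturbation terms.  Two anchoring schemes are supported:
``reference`` (default; dV compares the query's expression against the MA of
the *reference's* condition level) and ``query`` (against the query's own
level).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_data import SEGMENTS, DAYS, ValidationError, SchemaError

__all__ = [
    "CONDITION_CLASSES",
    "PAIR_COLUMNS",
    "FEATURES_5",
    "FEATURES_10",
    "MATable",
    "PairDataset",
    "ma_table",
    "expected_yield_table",
    "featurize_pair",
    "build_pair_dataset",
    "expected_value_grid",
]

# condition class -> sample-table column
CONDITION_CLASSES = {"segment": "segment", "day": "day", "system": "system"}

PAIR_COLUMNS = (
    "query_id",
    "ref_id",
    "y_exp",
    "v1",
    "v2",
    "dv1_s",
    "dv1_t",
    "dv1_m",
    "dv2_s",
    "dv2_t",
    "dv2_m",
    "target",
)

#: the compact five-input view used by the published general linear model
FEATURES_5 = ("y_exp", "v1", "dv2_s", "dv2_t", "dv2_m")
#: the full expanded input set
FEATURES_10 = (
    "y_exp",
    "v1",
    "v2",
    "dv1_s",
    "dv1_t",
    "dv1_m",
    "dv2_s",
    "dv2_t",
    "dv2_m",
)

_CLASS_SUFFIX = {"segment": "s", "day": "t", "system": "m"}
_GENE_NUM = {"ghrelin": 1, "ghr": 2}


@dataclass
class MATable:
    """Moving-average operator: per-level mean expression of one gene."""

    gene: str
    condition_class: str
    means: pd.Series  # level -> mean expression
    counts: pd.Series  # level -> number of samples

    def __getitem__(self, level):
        if level not in self.means.index:
            raise ValidationError(
                f"level {level!r} absent from MA table over {self.condition_class}"
            )
        return float(self.means.loc[level])

    @property
    def grand_mean(self) -> float:
        return float((self.means * self.counts).sum() / self.counts.sum())


@dataclass
class PairDataset:
    """Pairwise perturbation cases plus how they were drawn."""

    cases: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cases)


def ma_table(samples: pd.DataFrame, gene: str, condition_class: str) -> MATable:
    """Mean expression of ``gene`` per level of one condition class.

    Satisfies the conservation identity: the count-weighted mean over levels
    equals the grand mean of the samples.
    """
    if condition_class not in CONDITION_CLASSES:
        raise ValidationError(
            f"condition class must be one of {sorted(CONDITION_CLASSES)}, "
            f"got {condition_class!r}"
        )
    col = _gene_col(gene)
    by = CONDITION_CLASSES[condition_class]
    grouped = samples.groupby(by, observed=True)[col]
    return MATable(
        gene=col,
        condition_class=condition_class,
        means=grouped.mean(),
        counts=grouped.count(),
    )


def _gene_col(gene: str) -> str:
    g = str(gene).lower()
    if g in ("ghrelin", "v1", "1"):
        return "ghrelin"
    if g in ("ghr", "v2", "2"):
        return "ghr"
    raise ValidationError(f"unknown gene {gene!r}")


def expected_yield_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Expected yield per exact condition triple (segment, day, system).

    Mean observed yield and sample count over each triple present in the
    data; triples with no samples are simply absent.
    """
    if samples["yield"].isna().any():
        raise ValidationError("all samples need a yield to build the expected table")
    g = samples.groupby(["segment", "day", "system"], observed=True)["yield"]
    out = g.agg(y_exp="mean", count="count")
    return out


def _ma_lookup(tables: dict, gene_col: str, cls: str, level):
    tab = tables[(gene_col, cls)]
    if level not in tab.means.index:
        raise ValidationError(
            f"level {level!r} of class {cls!r} absent from MA table for {gene_col}"
        )
    return float(tab.means.loc[level])


def featurize_pair(
    query: pd.Series,
    reference: pd.Series,
    ma_tables: dict,
    ey_table: pd.DataFrame,
    scheme: str = "reference",
) -> dict:
    """Build one perturbation case from a (query, reference) sample pair.

    ``ma_tables`` maps (gene_column, condition_class) -> :class:`MATable`.
    ``y_exp`` is the expected yield under the reference's condition triple;
    each dV term subtracts the MA of the anchoring sample's level from the
    query's expression.
    """
    if scheme not in ("reference", "query"):
        raise ValidationError(f"unknown anchoring scheme {scheme!r}")
    anchor = reference if scheme == "reference" else query
    key = (reference["segment"], reference["day"], reference["system"])
    try:
        y_exp = float(ey_table.loc[key, "y_exp"])
    except KeyError as exc:
        raise ValidationError(f"no expected yield for triple {key!r}") from exc
    case = {
        "query_id": query.name,
        "ref_id": reference.name,
        "y_exp": y_exp,
        "v1": float(query["ghrelin"]),
        "v2": float(query["ghr"]),
    }
    for gene_col, g in (("ghrelin", 1), ("ghr", 2)):
        for cls, suffix in _CLASS_SUFFIX.items():
            ma = _ma_lookup(ma_tables, gene_col, cls, anchor[CONDITION_CLASSES[cls]])
            case[f"dv{g}_{suffix}"] = float(query[gene_col]) - ma
    case["target"] = float(query["yield"])
    return case


def _decode_pairs(codes: np.ndarray, n: int, allow_self: bool) -> tuple[np.ndarray, np.ndarray]:
    """Map flat pair codes to (query, reference) index arrays."""
    if allow_self:
        return codes // n, codes % n
    q = codes // (n - 1)
    rem = codes % (n - 1)
    r = rem + (rem >= q)
    return q, r


def build_pair_dataset(
    samples: pd.DataFrame,
    n_pairs="all",
    seed: int = 0,
    scheme: str = "reference",
    allow_self_pairs: bool = False,
) -> PairDataset:
    """Draw ordered (query, reference) pairs and featurize them.

    Pairs are drawn uniformly without replacement from the N*(N-1) ordered
    non-self pairs (or N^2 with ``allow_self_pairs``); ``n_pairs="all"``
    enumerates every pair.  Fully vectorized; deterministic under ``seed``.
    """
    if scheme not in ("reference", "query"):
        raise ValidationError(f"unknown anchoring scheme {scheme!r}")
    if samples["yield"].isna().any():
        raise ValidationError("all samples need a yield to build pair cases")
    df = samples.reset_index(drop=True)
    n = len(df)
    capacity = n * n if allow_self_pairs else n * (n - 1)
    if n_pairs == "all":
        codes = np.arange(capacity, dtype=np.int64)
    else:
        n_pairs = int(n_pairs)
        if n_pairs > capacity:
            raise ValidationError(
                f"requested {n_pairs} pairs but only {capacity} ordered pairs exist"
            )
        rng = np.random.default_rng(seed)
        codes = rng.choice(capacity, size=n_pairs, replace=False)
        codes.sort()
    qi, ri = _decode_pairs(codes, n, allow_self_pairs)

    tables = {
        (g, cls): ma_table(df, g, cls)
        for g in ("ghrelin", "ghr")
        for cls in CONDITION_CLASSES
    }
    ey = expected_yield_table(df)

    anchor_idx = ri if scheme == "reference" else qi
    ref_triples = pd.MultiIndex.from_frame(
        df.loc[ri, ["segment", "day", "system"]].reset_index(drop=True)
    )
    y_exp = ey["y_exp"].reindex(ref_triples).to_numpy()

    out = pd.DataFrame(
        {
            "query_id": qi,
            "ref_id": ri,
            "y_exp": y_exp,
            "v1": df["ghrelin"].to_numpy()[qi],
            "v2": df["ghr"].to_numpy()[qi],
        }
    )
    for gene_col, g in (("ghrelin", 1), ("ghr", 2)):
        vq = df[gene_col].to_numpy()[qi]
        for cls, suffix in _CLASS_SUFFIX.items():
            col = CONDITION_CLASSES[cls]
            ma = tables[(gene_col, cls)].means
            ma_vals = ma.reindex(df[col].to_numpy()[anchor_idx]).to_numpy()
            out[f"dv{g}_{suffix}"] = vq - ma_vals
    out["target"] = df["yield"].to_numpy()[qi]

    digest = hashlib.sha256(
        pd.util.hash_pandas_object(df[["animal", "segment", "day", "system"]], index=False)
        .to_numpy()
        .tobytes()
    ).hexdigest()[:16]
    prov = {
        "n_samples": n,
        "n_requested": "all" if isinstance(n_pairs, str) else int(n_pairs),
        "n_cases": len(out),
        "seed": int(seed),
        "scheme": scheme,
        "allow_self_pairs": bool(allow_self_pairs),
        "source_hash": digest,
    }
    return PairDataset(cases=out[list(PAIR_COLUMNS)], provenance=prov)


def expected_value_grid(
    samples: pd.DataFrame, gene: str = "ghr", rel_tol: float = 0.0
) -> pd.DataFrame:
    """Segment x feeding-phase grid of condition-level means with sign codes.

    Phases: lactation (d 0-14, pooled), S and G (d 28-70).  Each cell holds
    the MA of ``gene`` over the samples in that (segment, phase) stratum and
    a code: +1 if the cell sits above the grand mean (by more than
    ``rel_tol`` relatively), -1 if below, 0 if within tolerance.
    """
    col = _gene_col(gene)
    df = samples.copy()
    df["phase"] = np.where(df["day"] <= 14, "lactation", df["system"])
    grand = float(df[col].mean())
    grid = (
        df.groupby(["segment", "phase"], observed=True)[col]
        .mean()
        .unstack("phase")
        .reindex(index=list(SEGMENTS))
    )
    cols = [c for c in ("lactation", "S", "G") if c in grid.columns]
    grid = grid[cols]
    tol = abs(grand) * rel_tol
    diff = grid - grand
    codes = np.sign(diff.mask(diff.abs() <= tol, 0.0))
    codes.columns = [f"{c}_code" for c in codes.columns]
    return pd.concat([grid, codes], axis=1)
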