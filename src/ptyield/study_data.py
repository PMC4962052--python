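"""Sample data model, I/O and descriptive statistics for the expression study.

The experimental unit is a mucosa sample: one animal, one gastrointestinal
segment (8 longitudinal levels, rumen to rectum), one slaughter day
(d 0-70 postnatal) and one feeding system.  Before d 28 all kids suckle
("L", lactation); from d 28 each animal belongs to either the Supplemental
(S) or Grazing (G) system.  Each sample carries relative mRNA expression of
Ghrelin (v1) and the growth hormone receptor GHR (v2), measured by qPCR as
2^-ddCT fold changes against beta-actin with the duodenum-d0 sample as
calibrator, plus the animal's live and carcass weights from which the
growth yield Y (dressing ratio, in (0,1)) derives.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._tables import DAYS, GENES, PRE_SPLIT_DAYS, SEGMENTS, STAGES, SYSTEMS

__all__ = [
    "SEGMENTS",
    "DAYS",
    "SYSTEMS",
    "STAGES",
    "GENES",
    "SAMPLE_COLUMNS",
    "ConditionTriple",
    "ExpressionSample",
    "QpcrMeasurement",
    "StageSummary",
    "ContrastResult",
    "SchemaError",
    "ValidationError",
    "read_sample_table",
    "write_sample_table",
    "samples_to_frame",
    "frame_to_samples",
    "relative_expression_ddct",
    "carcass_yield",
    "stage_summary",
    "age_trend_contrasts",
    "feeding_effect_anova",
    "round_half_away",
]

SAMPLE_COLUMNS = (
    "animal",
    "segment",
    "day",
    "system",
    "ghrelin",
    "ghr",
    "live_weight",
    "carcass_weight",
    "yield",
)
_REQUIRED_COLUMNS = SAMPLE_COLUMNS[:6]


class SchemaError(ValueError):
    """A table is missing required structure (columns, feature names)."""


class ValidationError(ValueError):
    """A value violates a domain constraint."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (presentation convention, e.g. 0.375 -> 0.38)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class ConditionTriple:
    """One experimental condition: (segment, postnatal day, feeding system)."""

    segment: str
    day: int
    system: str

    def __post_init__(self) -> None:
        seg = self.segment.lower()
        sys_ = self.system.upper()
        if seg not in SEGMENTS:
            raise ValidationError(f"unknown segment {self.segment!r}")
        if self.day not in DAYS:
            raise ValidationError(f"day must be one of {DAYS}, got {self.day!r}")
        if sys_ not in SYSTEMS:
            raise ValidationError(f"unknown system {self.system!r}")
        object.__setattr__(self, "segment", seg)
        object.__setattr__(self, "system", sys_)

    @property
    def segment_index(self) -> int:
        """1-based anatomical index, rumen=1 ... rectum=8."""
        return SEGMENTS.index(self.segment) + 1

    @property
    def day_index(self) -> int:
        return DAYS.index(self.day) + 1


@dataclass
class ExpressionSample:
    """One mucosa sample with its expression levels and animal weights."""

    animal_id: str
    triple: ConditionTriple
    v1: float  # Ghrelin relative expression (fold change)
    v2: float  # GHR relative expression
    live_weight: float | None = None  # kg
    carcass_weight: float | None = None  # kg
    yield_y: float | None = None  # growth yield, in (0, 1)

    def __post_init__(self) -> None:
        for name, v in (("ghrelin", self.v1), ("ghr", self.v2)):
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{name} expression must be finite and non-negative, got {v!r}"
                )
        if self.live_weight is not None and self.live_weight <= 0:
            raise ValidationError("live_weight must be positive")
        if self.carcass_weight is not None and self.carcass_weight <= 0:
            raise ValidationError("carcass_weight must be positive")
        if (
            self.live_weight is not None
            and self.carcass_weight is not None
            and not self.carcass_weight < self.live_weight
        ):
            raise ValidationError("carcass_weight must be below live_weight")
        if self.yield_y is not None and not 0 < self.yield_y < 1:
            raise ValidationError("yield must lie strictly in (0, 1)")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds for one target-gene reaction and its controls."""

    ct_target: float
    ct_actin: float
    calibrator_ct_target: float
    calibrator_ct_actin: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target,
            self.ct_actin,
            self.calibrator_ct_target,
            self.calibrator_ct_actin,
        ):
            if not np.isfinite(v):
                raise ValidationError("CT values must be finite")


@dataclass
class StageSummary:
    """Mean +/- SEM of relative expression for one segment x stage cell."""

    gene: str
    segment: str
    stage: str
    mean: float
    sem: float
    n_cells: int
    missing: bool = False


@dataclass
class ContrastResult:
    """Orthogonal linear/quadratic age-trend contrasts for one data channel."""

    days: tuple[int, ...]
    counts: tuple[int, ...]
    coefficients: dict[str, np.ndarray]
    estimates: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    df_resid: int


# ---------------------------------------------------------------------------
# I/O


def read_sample_table(source) -> list[ExpressionSample]:
    """Read a long-format sample table (CSV) into validated samples.

    ``source`` is a path or text stream.  Required columns:
    ``animal, segment, day, system, ghrelin, ghr``; optional
    ``live_weight, carcass_weight, yield``.  Row order is preserved.
    """
    df = pd.read_csv(source)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    samples: list[ExpressionSample] = []
    # dict records rather than itertuples: "yield" is a keyword column name
    for i, row in enumerate(df.to_dict("records"), start=2):  # header is line 1
        try:
            triple = ConditionTriple(str(row["segment"]), int(row["day"]), str(row["system"]))
            v1 = float(row["ghrelin"])
            v2 = float(row["ghr"])
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc

        def _opt(name: str) -> float | None:
            v = row.get(name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        try:
            samples.append(
                ExpressionSample(
                    animal_id=str(row["animal"]),
                    triple=triple,
                    v1=v1,
                    v2=v2,
                    live_weight=_opt("live_weight"),
                    carcass_weight=_opt("carcass_weight"),
                    yield_y=_opt("yield"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return samples


def samples_to_frame(samples: Iterable[ExpressionSample]) -> pd.DataFrame:
    """Tidy DataFrame view of samples (the package's working currency)."""
    rows = [
        {
            "animal": s.animal_id,
            "segment": s.triple.segment,
            "day": s.triple.day,
            "system": s.triple.system,
            "ghrelin": s.v1,
            "ghr": s.v2,
            "live_weight": s.live_weight,
            "carcass_weight": s.carcass_weight,
            "yield": s.yield_y,
        }
        for s in samples
    ]
    df = pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))
    if df.empty:
        df = pd.DataFrame(columns=list(SAMPLE_COLUMNS))
    return df


def frame_to_samples(df: pd.DataFrame) -> list[ExpressionSample]:
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_sample_table(buf)


def write_sample_table(samples: Sequence[ExpressionSample] | pd.DataFrame, sink) -> int:
    """Write samples as CSV; returns the number of data rows written.

    Values round-trip exactly through :func:`read_sample_table` (floats are
    printed at full shortest-repr precision).
    """
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    df.to_csv(sink, index=False)
    return len(df)


# ---------------------------------------------------------------------------
# qPCR and yield


def relative_expression_ddct(m: QpcrMeasurement) -> float:
    """Relative expression 2^-ddCT against beta-actin and the d0-duodenum calibrator.

    ddCT = (CT_target - CT_actin) - (CT_target^cal - CT_actin^cal); the
    calibrator sample itself therefore maps to exactly 1.0.
    """
    d_ct = m.ct_target - m.ct_actin
    d_ct_cal = m.calibrator_ct_target - m.calibrator_ct_actin
    return float(2.0 ** -(d_ct - d_ct_cal))


def carcass_yield(live_weight: float, carcass_weight: float) -> float:
    """Growth yield Y as the dressing ratio carcass/live weight, in (0,1)."""
    if not (np.isfinite(live_weight) and np.isfinite(carcass_weight)):
        raise ValidationError("weights must be finite")
    if live_weight <= 0 or carcass_weight <= 0:
        raise ValidationError("weights must be positive")
    if carcass_weight >= live_weight:
        raise ValidationError("carcass_weight must be strictly below live_weight")
    return carcass_weight / live_weight


# ---------------------------------------------------------------------------
# Descriptive statistics


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    return samples_to_frame(samples)


def _gene_column(gene: str) -> str:
    g = gene.lower()
    if g in ("ghrelin", "v1"):
        return "ghrelin"
    if g in ("ghr", "v2"):
        return "ghr"
    raise ValidationError(f"unknown gene {gene!r}")


def stage_summary(samples, gene: str) -> list[StageSummary]:
    """Per segment x developmental stage mean and SEM of relative expression.

    The stage mean is the unweighted mean of the per-(day, system) cell means
    inside the stage: pre-rumination pools the three suckling days, transition
    and rumination each pool 2 days x 2 feeding systems.  The SEM derives from
    the pooled within-cell residual variance divided by the average cell size;
    with one observation per cell it is undefined (NaN).  A stage with no data
    for a segment is returned flagged ``missing`` rather than as zero.
    """
    df = _as_frame(samples)
    col = _gene_column(gene)
    out: list[StageSummary] = []
    for segment in SEGMENTS:
        seg_df = df[df["segment"] == segment]
        for stage, stage_days in STAGES.items():
            cell_df = seg_df[seg_df["day"].isin(stage_days)]
            if cell_df.empty:
                out.append(StageSummary(col, segment, stage, math.nan, math.nan, 0, True))
                continue
            cells = cell_df.groupby(["day", "system"], observed=True)[col]
            cell_means = cells.mean()
            mean = float(cell_means.mean())
            n = len(cell_df)
            n_cells = len(cell_means)
            df_resid = n - n_cells
            if df_resid > 0:
                resid_ss = float(
                    ((cell_df[col] - cells.transform("mean")) ** 2).sum()
                )
                pooled_var = resid_ss / df_resid
                sem = math.sqrt(pooled_var / (n / n_cells))
            else:
                sem = math.nan
            out.append(StageSummary(col, segment, stage, mean, sem, n_cells))
    return out


def _orthogonal_poly_contrasts(days: np.ndarray, counts: np.ndarray) -> dict[str, np.ndarray]:
    """Linear and quadratic contrast vectors orthogonal under the cell-count
    weighted inner product (and hence under the plain one when cells are
    balanced), for arbitrary day spacing."""
    w = counts / counts.sum()
    x = days.astype(float)
    basis = np.column_stack([np.ones_like(x), x, x * x])
    # weighted Gram-Schmidt against lower-order terms
    q = basis.copy()
    for j in range(1, 3):
        for i in range(j):
            proj = np.sum(w * q[:, j] * q[:, i]) / np.sum(w * q[:, i] ** 2)
            q[:, j] = q[:, j] - proj * q[:, i]
    lin = q[:, 1] / np.sqrt(np.sum(q[:, 1] ** 2))
    quad = q[:, 2] / np.sqrt(np.sum(q[:, 2] ** 2))
    return {"linear": lin, "quadratic": quad}


def age_trend_contrasts(samples, gene: str, segment: str, system: str) -> ContrastResult:
    """Orthogonal linear/quadratic age contrasts for one segment and system.

    The channel for system S (or G) includes the shared suckling samples of
    d 0-14 (system L), which precede the group split.  Contrast estimates are
    linear combinations of per-day means; their standard errors use the pooled
    within-day variance, with df = N - (number of days).
    """
    df = _as_frame(samples)
    col = _gene_column(gene)
    segment = segment.lower()
    sys_ = system.upper()
    sel = df[
        (df["segment"] == segment)
        & (df["system"].isin([sys_, "L"]) if sys_ in ("S", "G") else (df["system"] == sys_))
    ]
    day_groups = sel.groupby("day", observed=True)[col]
    days = np.array(sorted(sel["day"].unique()))
    if len(days) < 3:
        raise ValidationError(
            f"age trend needs >=3 distinct days, found {len(days)}"
        )
    means = day_groups.mean().reindex(days).to_numpy()
    counts = day_groups.count().reindex(days).to_numpy().astype(float)
    coeffs = _orthogonal_poly_contrasts(days, counts)
    n_total = int(counts.sum())
    df_resid = n_total - len(days)
    if df_resid > 0:
        resid_ss = float(((sel[col] - day_groups.transform("mean")) ** 2).sum())
        sigma2 = resid_ss / df_resid
    else:
        sigma2 = math.nan
    est, se, tval, pval = {}, {}, {}, {}
    for name, c in coeffs.items():
        est[name] = float(c @ means)
        var = sigma2 * float(np.sum(c * c / counts))
        se[name] = math.sqrt(var) if var == var else math.nan
        if se[name] and se[name] > 0:
            tval[name] = est[name] / se[name]
            pval[name] = float(
                2 * scipy.stats.t.sf(abs(tval[name]), df_resid)
            )
        else:
            tval[name] = math.inf if est[name] != 0 else 0.0
            pval[name] = 0.0 if est[name] != 0 else 1.0
    return ContrastResult(
        days=tuple(int(d) for d in days),
        counts=tuple(int(c) for c in counts),
        coefficients=coeffs,
        estimates=est,
        std_errors=se,
        t_values=tval,
        p_values=pval,
        df_resid=df_resid,
    )


def feeding_effect_anova(samples, gene: str, segment: str) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of feeding system, age and their interaction.

    Restricted to d 28-70 where both systems exist; the animal is the
    experimental unit (one sample per animal per segment).  Returns the
    sequential ANOVA table with sum_sq, df, F and p per term plus residual;
    term sums of squares and the residual add up to the total.
    """
    df = _as_frame(samples)
    col = _gene_column(gene)
    segment = segment.lower()
    sel = df[
        (df["segment"] == segment)
        & (df["day"] >= 28)
        & (df["system"].isin(["S", "G"]))
    ].copy()
    systems = set(sel["system"])
    if systems != {"S", "G"}:
        raise ValidationError(
            f"both feeding systems required from d 28 on, found {sorted(systems)}"
        )
    cell_counts = sel.groupby(["system", "day"], observed=True)[col].count()
    if (cell_counts < 2).any():
        raise ValidationError("each system x day cell needs >=2 animals")
    sel = sel.rename(columns={col: "value"})
    model = smf.ols("value ~ C(system) * C(day)", data=sel).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table.index = ["system", "age", "system:age", "Residual"]
    # degenerate variance ratios: a zero-SS term has no effect (F=0); a
    # non-zero term over a zero residual is an exact effect (F=inf)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    scale = max(float(table["sum_sq"].sum()), 1.0)
    for term in ("system", "age", "system:age"):
        term_ss = float(table.loc[term, "sum_sq"])
        if term_ss <= 1e-12 * scale:
            table.loc[term, ["F", "PR(>F)"]] = 0.0, 1.0
        elif resid_ss <= 1e-12 * scale:
            table.loc[term, ["F", "PR(>F)"]] = math.inf, 0.0
    return table
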