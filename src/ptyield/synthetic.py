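"""Synthetic study generator with planted ground truth.

Emulates the deposited study's shape — 44 kid goats, each slaughtered at one
of seven postnatal days and sampled at all eight gastrointestinal segments
(352 rows) — with expression magnitudes patterned on the published
spatiotemporal mean grids and a growth yield planted as a known function of
condition-level GHR means and sample-level Ghrelin.  Because every
coefficient and noise draw is reproducible from (config, seed), downstream
stages (featurization, filtering, regression) can be tested for parameter
recovery rather than merely for shape.

Yield model
-----------
For animal *i* slaughtered at day *t* under system *m*::

    logit(Y_i) = b0 + bt * u_t + bm * u_m + bv * w_i
                 + gamma * 1[t >= 42] * u_m + sigma_y * eps_i

where ``u_t`` / ``u_m`` are the standardized condition-level (moving-average)
GHR template means for the animal's day and system, and ``w_i`` is the
standardized log2 abomasal Ghrelin of the animal (a sample-level covariate).
The gated term makes the feeding-system effect kick in only late in
development — an interaction a linear model in the perturbation features
cannot represent, so tree ensembles hold a genuine advantage.  With
``interaction = 0`` the model is exactly linear on the logit scale and OLS on
the planted covariates is unbiased for every coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from ._tables import (
    DAYS,
    GENES,
    PRE_SPLIT_DAYS,
    SEGMENTS,
    SPLIT_DAYS,
    template_frame,
    template_mean,
)
from .study_data import ValidationError

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "template_means",
    "generate_study",
    "generate_qpcr",
    "inject_case_outliers",
]


def _default_allocation() -> dict:
    """4 animals per suckling day; 4 per system per split day (3*4 + 4*8 = 44)."""
    alloc: dict[int, dict[str, int]] = {}
    for day in PRE_SPLIT_DAYS:
        alloc[day] = {"L": 4}
    for day in SPLIT_DAYS:
        alloc[day] = {"S": 4, "G": 4}
    return alloc


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the emulated study design."""

    n_animals: int = 44
    allocation: dict = field(default_factory=_default_allocation)
    expression_sd_log2: float = 0.25  # lognormal noise, sd on the log2 scale
    expression_floor: float = 0.001  # smallest template mean (printed zeros)
    yield_intercept: float = -0.12  # logit of a 0.47 dressing ratio
    yield_coef_day_ghr: float = 0.20  # on standardized day-level GHR mean
    yield_coef_system_ghr: float = 0.12  # on standardized system-level GHR mean
    yield_coef_ghrelin: float = 0.08  # on standardized log2 abomasal Ghrelin
    yield_interaction: float = 0.5  # late-gated system term (0 => purely linear)
    yield_sd: float = 0.12  # logit-scale noise
    outlier_fraction: float = 0.0  # fraction of animals given off-model yields
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(sum(d.values()) for d in self.allocation.values())
        if total != self.n_animals:
            raise ValidationError(
                f"allocation sums to {total}, expected n_animals={self.n_animals}"
            )
        for name in ("expression_sd_log2", "yield_sd", "outlier_fraction"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What was actually planted: coefficients and per-animal covariates."""

    coefficients: dict[str, float]
    covariates: pd.DataFrame  # per animal: u_t, u_m, w, gate, eta, yield
    template: pd.DataFrame  # floored template grid used for generation
    seed: int


def template_means(floor: float = 0.0) -> pd.DataFrame:
    """The embedded template grid, optionally floored at a positive value."""
    df = template_frame()
    if floor > 0:
        df = df.assign(value=df["value"].clip(lower=floor))
    return df


def _condition_scores(tmpl: pd.DataFrame) -> tuple[dict, dict, float, float]:
    """Standardized condition-level GHR means and the Ghrelin-log2 scale."""
    ghr = tmpl[tmpl["gene"] == "ghr"]
    day_means = ghr.groupby("day")["value"].mean()
    u_t = ((day_means - day_means.mean()) / day_means.std(ddof=0)).to_dict()
    phase = ghr.assign(
        phase=np.where(ghr["day"].isin(PRE_SPLIT_DAYS), "L", ghr["system"])
    )
    sys_means = phase.groupby("phase")["value"].mean()
    u_m = ((sys_means - sys_means.mean()) / sys_means.std(ddof=0)).to_dict()
    abo = tmpl[(tmpl["gene"] == "ghrelin") & (tmpl["segment"] == "abomasum")]
    logv = np.log2(abo["value"].to_numpy() + 1.0)
    return u_t, u_m, float(logv.mean()), float(logv.std(ddof=0))


def generate_study(config: GeneratorConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one study: a 352-row sample table plus its ground truth.

    Deterministic under ``config.seed``.  Each animal carries its yield on
    all 8 of its rows; live weight follows a crude growth line and carcass
    weight is back-solved so that the dressing ratio equals the planted Y.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    tmpl = template_means(cfg.expression_floor)
    u_t, u_m, w_center, w_scale = _condition_scores(tmpl)

    animals = []
    idx = 0
    for day in sorted(cfg.allocation):
        for system in sorted(cfg.allocation[day]):
            for _ in range(cfg.allocation[day][system]):
                idx += 1
                animals.append((f"A{idx:03d}", day, system))

    rows = []
    truth_rows = []
    for animal_id, day, system in animals:
        v1 = {}
        v2 = {}
        for segment in SEGMENTS:
            m1 = max(template_mean("ghrelin", segment, day, system), cfg.expression_floor)
            m2 = max(template_mean("ghr", segment, day, system), cfg.expression_floor)
            v1[segment] = m1 * 2.0 ** (cfg.expression_sd_log2 * rng.standard_normal())
            v2[segment] = m2 * 2.0 ** (cfg.expression_sd_log2 * rng.standard_normal())
        phase = "L" if day in PRE_SPLIT_DAYS else system
        ut = u_t[day]
        um = u_m[phase]
        w = (math.log2(v1["abomasum"] + 1.0) - w_center) / w_scale
        gate = float(day >= 42) * um
        eps = rng.standard_normal()
        eta = (
            cfg.yield_intercept
            + cfg.yield_coef_day_ghr * ut
            + cfg.yield_coef_system_ghr * um
            + cfg.yield_coef_ghrelin * w
            + cfg.yield_interaction * gate
            + cfg.yield_sd * eps
        )
        y = float(expit(eta))
        live = 1.35 + 0.15 * day * (1.0 + 0.08 * rng.standard_normal())
        live = max(live, 0.5)
        truth_rows.append(
            {
                "animal": animal_id,
                "day": day,
                "system": system,
                "u_t": ut,
                "u_m": um,
                "w": w,
                "gate": gate,
                "eta": eta,
                "yield": y,
            }
        )
        for segment in SEGMENTS:
            rows.append(
                {
                    "animal": animal_id,
                    "segment": segment,
                    "day": day,
                    "system": system,
                    "ghrelin": v1[segment],
                    "ghr": v2[segment],
                    "live_weight": live,
                    "carcass_weight": y * live,
                    "yield": y,
                }
            )
    df = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truth_rows)

    if cfg.outlier_fraction > 0:
        n_out = int(round(cfg.outlier_fraction * len(animals)))
        chosen = rng.choice(len(animals), size=n_out, replace=False)
        for j in chosen:
            aid = animals[j][0]
            y_out = _extreme_yield(rng)
            truth_df.loc[truth_df["animal"] == aid, "yield"] = y_out
            mask = df["animal"] == aid
            df.loc[mask, "yield"] = y_out
            df.loc[mask, "carcass_weight"] = y_out * df.loc[mask, "live_weight"]

    truth = GroundTruth(
        coefficients={
            "intercept": cfg.yield_intercept,
            "u_t": cfg.yield_coef_day_ghr,
            "u_m": cfg.yield_coef_system_ghr,
            "w": cfg.yield_coef_ghrelin,
            "interaction": cfg.yield_interaction,
            "sd": cfg.yield_sd,
        },
        covariates=truth_df,
        template=tmpl,
        seed=cfg.seed,
    )
    return df, truth


def _extreme_yield(rng: np.random.Generator) -> float:
    """Off-model yield near a boundary of (0,1), far outside the inlier band."""
    lo = rng.uniform(0.01, 0.05)
    hi = rng.uniform(0.95, 0.99)
    return float(lo if rng.random() < 0.5 else hi)


def generate_qpcr(samples: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Invert expression values into plausible qPCR cycle thresholds.

    Returns one row per (sample, gene) with target and beta-actin CTs plus the
    calibrator CTs, such that the 2^-ddCT transform reproduces each expression
    value to floating-point accuracy.  Actin CTs sit in the 15-25 cycle range.
    """
    from .study_data import samples_to_frame

    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    rng = np.random.default_rng(seed)
    cal_dct = {"ghrelin": rng.uniform(3.0, 8.0), "ghr": rng.uniform(3.0, 8.0)}
    cal_ct_actin = {g: rng.uniform(15.0, 25.0) for g in GENES}
    out = []
    for row in df.itertuples(index=False):
        for gene, col in (("ghrelin", "ghrelin"), ("ghr", "ghr")):
            v = getattr(row, col)
            if v <= 0:
                raise ValidationError(
                    f"expression must be positive to invert to CT values, got {v}"
                )
            ddct = -math.log2(v)
            ct_actin = rng.uniform(15.0, 25.0)
            out.append(
                {
                    "animal": row.animal,
                    "segment": row.segment,
                    "day": row.day,
                    "system": row.system,
                    "gene": gene,
                    "ct_target": ct_actin + ddct + cal_dct[gene],
                    "ct_actin": ct_actin,
                    "calibrator_ct_target": cal_ct_actin[gene] + cal_dct[gene],
                    "calibrator_ct_actin": cal_ct_actin[gene],
                }
            )
    return pd.DataFrame(out)


def inject_case_outliers(
    cases: pd.DataFrame,
    fraction: float,
    seed: int = 0,
    target: str = "target",
    reference=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Replace a fraction of case targets with boundary-extreme values.

    Operates on a pairwise case table with a target on a (0,1)-bounded
    scale; returns the modified copy and the boolean mask of injected rows.
    Each injected target is placed at the boundary *opposite* its
    ``reference`` value (a fitted-value array when testing a residual
    filter, the case's own target by default), so planted cases are
    unambiguously off-model rather than accidentally close to the fit.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = cases.copy()
    n = len(out)
    ref = np.asarray(out[target] if reference is None else reference, dtype=float)
    if ref.shape[0] != n:
        raise ValidationError("reference must align with the case rows")
    n_out = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        mask[idx] = True
        midpoint = 0.5 * (float(np.min(ref)) + float(np.max(ref)))
        vals = np.where(
            ref[mask] >= midpoint,
            rng.uniform(0.01, 0.05, size=n_out),
            rng.uniform(0.95, 0.99, size=n_out),
        )
        out.loc[out.index[mask], target] = vals
    return out, mask
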