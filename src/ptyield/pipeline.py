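"""End-to-end orchestration: data -> features -> preprocessing -> models -> report.

A run executes the full modelling chain on either a sample table from disk
or a freshly generated synthetic study, fits the regression suite on the
unfiltered cases and (optionally) on the residual-filtered cases, and writes
every intermediate and result table as CSV under one output directory.  All
randomness is seeded through the config, so identical configs produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import FEATURES_5, FEATURES_10, build_pair_dataset, expected_value_grid
from .preprocess import (
    NormalizationParams,
    SplitSpec,
    minmax_normalize,
    pearson_residual_filter,
    split_dataset,
)
from .regress import (
    METHODS,
    FitResult,
    compare_models,
    evaluate,
    feature_importance,
    fit_ols,
    fit_suite,
    resample_rmse,
)
from .study_data import GENES, SEGMENTS, ValidationError, read_sample_table, samples_to_frame, stage_summary
from .synthetic import GeneratorConfig, generate_study

logger = logging.getLogger("ptyield.pipeline")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline",
           "render_results_table", "render_spatiotemporal_surface"]


@dataclass
class PipelineConfig:
    """Everything a run needs; schema-validated before any stage executes."""

    input_path: str | None = None  # CSV sample table; None => synthetic
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    n_pairs: int | str = 20_000
    scheme: str = "reference"
    allow_self_pairs: bool = False
    feature_set: str = "compact"  # "compact" (5 inputs) or "full" (9 inputs)
    normalization_fit: str = "full"  # "full" or "train"
    train_fraction: float = 0.75
    split_mode: str = "case"
    filter_threshold: float = 0.4
    filter_enabled: bool = True
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    grids: dict | None = None
    tune: bool = True
    cv: tuple[int, int] = (5, 3)
    compare: bool = False
    importance: bool = True
    make_figures: bool = False
    outdir: str = "ptyield_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in ("compact", "full"):
            raise ValidationError("feature_set must be 'compact' or 'full'")
        if self.normalization_fit not in ("full", "train"):
            raise ValidationError("normalization_fit must be 'full' or 'train'")
        for m in self.methods:
            if m not in METHODS:
                raise ValidationError(f"unknown method {m!r}; choose from {METHODS}")
        if not self.filter_threshold > 0:
            raise ValidationError("filter_threshold must be positive")
        self.cv = tuple(self.cv)  # type: ignore[assignment]

    @property
    def feature_cols(self) -> list[str]:
        return list(FEATURES_5 if self.feature_set == "compact" else FEATURES_10)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cv"] = list(self.cv)
        return d


@dataclass
class ReportBundle:
    """In-memory view of everything a run wrote."""

    samples: pd.DataFrame
    pairs: pd.DataFrame
    evaluations: dict[str, pd.DataFrame]  # pass name -> results table
    fits: dict[str, dict[str, FitResult]]  # pass name -> method -> fit
    stage_summaries: dict[str, pd.DataFrame]
    grid: pd.DataFrame
    comparison: pd.DataFrame | None
    provenance: dict
    outdir: Path


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


def render_results_table(
    fits: dict[str, FitResult],
    train: pd.DataFrame,
    test: pd.DataFrame,
    target_col: str = "target",
) -> pd.DataFrame:
    """One row per method with train/test RMSE, R^2 and R; best method flagged.

    Best = max test R^2, ties broken by min test RMSE, then method name.
    """
    rows = []
    for name, fit in fits.items():
        ev_tr = evaluate(fit, train, target_col, "train")
        ev_te = evaluate(fit, test, target_col, "test")
        sel = fit.selected_features
        rows.append(
            {
                "method": name,
                "n_features": len(sel),
                "features": "+".join(sel),
                "rmse_train": ev_tr.rmse,
                "r2_train": ev_tr.r2,
                "rmse_test": ev_te.rmse,
                "r2_test": ev_te.r2,
                "r_test": ev_te.r,
            }
        )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["r2_test", "rmse_test", "method"], ascending=[False, True, True]
    )
    table["best"] = table["method"] == ranked.iloc[0]["method"]
    return table


def render_spatiotemporal_surface(samples: pd.DataFrame, gene: str, path) -> Path:
    """Segment x day surface of mean expression, saved as an image file.

    Cells average over feeding systems; rendering interpolates bilinearly on
    the ordered segment index (recorded in the figure metadata) and is
    presentational only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gene = gene.lower()
    grid = (
        samples.groupby(["segment", "day"], observed=True)[gene]
        .mean()
        .unstack("day")
        .reindex(index=list(SEGMENTS))
    )
    if grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValidationError("surface needs >=2 segments and >=2 days")
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(
        grid.to_numpy(),
        aspect="auto",
        origin="upper",
        interpolation="bilinear",
        cmap="viridis",
    )
    ax.set_xticks(range(grid.shape[1]), [str(d) for d in grid.columns])
    ax.set_yticks(range(grid.shape[0]), list(grid.index))
    ax.set_xlabel("postnatal day")
    ax.set_title(f"mean relative {gene} expression")
    fig.colorbar(im, ax=ax, label="fold change")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, metadata={"Description": "bilinear interpolation on segment index"})
    plt.close(fig)
    return path


def _suite_pass(
    name: str,
    cases: pd.DataFrame,
    cfg: PipelineConfig,
    outdir: Path,
    provenance: dict,
) -> tuple[pd.DataFrame, dict[str, FitResult], pd.DataFrame, pd.DataFrame]:
    spec = SplitSpec(cfg.train_fraction, seed=cfg.seed, mode=cfg.split_mode)
    train, test = split_dataset(cases, spec)
    fits = fit_suite(
        train,
        target_col="target",
        feature_cols=cfg.feature_cols,
        methods=cfg.methods,
        grids=cfg.grids,
        seed=cfg.seed,
        cv=cfg.cv,
        tune=cfg.tune,
    )
    table = render_results_table(fits, train, test)
    _write_csv(table, outdir / f"results_{name}.csv")
    membership = pd.DataFrame(
        {
            "case": np.concatenate([train.index.to_numpy(), test.index.to_numpy()]),
            "subset": ["train"] * len(train) + ["test"] * len(test),
        }
    ).sort_values("case", kind="mergesort")
    _write_csv(membership, outdir / f"split_{name}.csv")
    provenance["passes"][name] = {
        "n_cases": len(cases),
        "n_train": len(train),
        "n_test": len(test),
    }
    logger.info("pass %s: %d cases -> %d train / %d test", name, len(cases),
                len(train), len(test))
    if cfg.importance:
        best = table.loc[table["best"], "method"].iloc[0]
        imp = feature_importance(fits[best], test, seed=cfg.seed)
        _write_csv(
            imp.rename("importance").rename_axis("feature").reset_index(),
            outdir / f"importance_{name}.csv",
        )
    return table, fits, train, test


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full chain and write all artifacts under ``config.outdir``.

    Stages: sample table (load or generate) -> descriptive summaries ->
    pairwise perturbation cases -> min-max normalization -> split -> model
    suite on the unfiltered cases -> residual filter -> model suite on the
    filtered cases -> optional resampled model comparison.
    """
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_echo = cfg.to_dict()
    config_echo.pop("outdir", None)  # location must not affect report content
    provenance: dict = {
        "version": __version__,
        "config": config_echo,
        "passes": {},
    }

    if cfg.input_path:
        samples = samples_to_frame(read_sample_table(cfg.input_path))
        logger.info("loaded %d samples from %s", len(samples), cfg.input_path)
    else:
        gen_cfg = GeneratorConfig(**{"seed": cfg.seed, **cfg.generator})
        samples, _truth = generate_study(gen_cfg)
        logger.info("generated %d synthetic samples (seed %d)", len(samples),
                    gen_cfg.seed)
    _write_csv(samples, outdir / "samples.csv")
    provenance["n_samples"] = len(samples)
    provenance["n_animals"] = int(samples["animal"].nunique())

    summaries = {}
    for gene in GENES:
        summ = pd.DataFrame([dataclasses.asdict(s) for s in stage_summary(samples, gene)])
        summaries[gene] = summ
        _write_csv(summ, outdir / f"stage_summary_{gene}.csv")
    grid = expected_value_grid(samples, "ghr")
    _write_csv(grid, outdir / "expected_value_grid.csv", index=True)

    pairset = build_pair_dataset(
        samples,
        n_pairs=cfg.n_pairs,
        seed=cfg.seed,
        scheme=cfg.scheme,
        allow_self_pairs=cfg.allow_self_pairs,
    )
    cases = pairset.cases
    _write_csv(cases, outdir / "pairs.csv")
    with open(outdir / "pairs_provenance.json", "w") as fh:
        json.dump(pairset.provenance, fh, indent=2, sort_keys=True)
    provenance["n_cases"] = len(cases)
    logger.info("built %d perturbation cases", len(cases))

    norm_cols = cfg.feature_cols + ["target"]
    if cfg.normalization_fit == "full":
        normed, params = minmax_normalize(cases, norm_cols, fitted_on="full")
    else:
        spec = SplitSpec(cfg.train_fraction, seed=cfg.seed, mode=cfg.split_mode)
        train0, _ = split_dataset(cases, spec)
        _, params = minmax_normalize(train0, norm_cols, fitted_on="train")
        normed, _ = minmax_normalize(cases, norm_cols, params=params)
    params.to_json(outdir / "normalization.json")

    evaluations: dict[str, pd.DataFrame] = {}
    all_fits: dict[str, dict[str, FitResult]] = {}
    table, fits, train_u, test_u = _suite_pass(
        "unfiltered", normed, cfg, outdir, provenance
    )
    evaluations["unfiltered"] = table
    all_fits["unfiltered"] = fits

    train_f = test_f = None
    if cfg.filter_enabled:
        base = fit_ols(normed[cfg.feature_cols], normed["target"], seed=cfg.seed)
        kept, removed, fraction = pearson_residual_filter(
            normed, base.predict(normed), threshold=cfg.filter_threshold
        )
        provenance["filter"] = {
            "threshold": cfg.filter_threshold,
            "n_removed": len(removed),
            "removed_fraction": round(fraction, 4),
        }
        logger.info("residual filter removed %d/%d cases (%.4f)", len(removed),
                    len(normed), fraction)
        table_f, fits_f, train_f, test_f = _suite_pass(
            "filtered", kept, cfg, outdir, provenance
        )
        evaluations["filtered"] = table_f
        all_fits["filtered"] = fits_f

    comparison = None
    if cfg.compare:
        final = "filtered" if cfg.filter_enabled else "unfiltered"
        train_c = train_f if cfg.filter_enabled else train_u
        res = resample_rmse(
            all_fits[final], train_c, n_splits=cfg.cv[0], n_repeats=cfg.cv[1],
            seed=cfg.seed,
        )
        comp = compare_models(res)
        comparison = comp.pairs
        _write_csv(comp.means, outdir / "comparison_means.csv")
        _write_csv(comp.pairs, outdir / "comparison_pairs.csv")

    if cfg.make_figures:
        for gene in GENES:
            render_spatiotemporal_surface(samples, gene, outdir / f"surface_{gene}.png")

    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    return ReportBundle(
        samples=samples,
        pairs=cases,
        evaluations=evaluations,
        fits=all_fits,
        stage_summaries=summaries,
        grid=grid,
        comparison=comparison,
        provenance=provenance,
        outdir=outdir,
    )
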