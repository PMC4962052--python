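"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ptyield.study_data import SAMPLE_COLUMNS
from ptyield.synthetic import GeneratorConfig, generate_study, template_means


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (352 samples, 44 animals) plus its truth."""
    return generate_study(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def samples(study):
    return study[0]


@pytest.fixture(scope="session")
def template_wide():
    """The embedded published cell-mean grid as a one-row-per-cell sample table."""
    tmpl = template_means()
    wide = (
        tmpl.pivot_table(index=["segment", "day", "system"], columns="gene", values="value")
        .reset_index()
    )
    wide["animal"] = [f"cell{i:02d}" for i in range(len(wide))]
    for c in ("live_weight", "carcass_weight", "yield"):
        wide[c] = np.nan
    return wide[list(SAMPLE_COLUMNS)]


def ols_oracle(X: np.ndarray, y: np.ndarray) -> dict:
    """Normal-equations least squares with textbook inference formulas.

    Deliberately independent of the package's fitting path: solves
    (X'X) b = X'y directly and derives every statistic from first
    principles.
    """
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    fitted = design @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    df_model, df_resid = p, n - p - 1
    sigma2 = ss_res / df_resid
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * scipy.stats.t.sf(np.abs(tvals), df_resid)
    f = (ss_tot - ss_res) / df_model / sigma2
    f_p = float(scipy.stats.f.sf(f, df_model, df_resid))
    return {
        "beta": beta,
        "se": se,
        "t": tvals,
        "p": pvals,
        "r2": r2,
        "ss_residual": ss_res,
        "f": float(f),
        "f_p": f_p,
        "df_model": df_model,
    }


def featurize_oracle(df: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Loop-and-average reference implementation of pair featurization.

    Every mean is recomputed with explicit Python loops; no shared code with
    the package's vectorized path.
    """
    classes = {"s": "segment", "t": "day", "m": "system"}
    rows = []
    n = len(df)
    recs = df.to_dict("records")
    for qi in range(n):
        for ri in range(n):
            if qi == ri:
                continue
            q, r = recs[qi], recs[ri]
            anchor = r if scheme == "reference" else q
            same_triple = [
                x["yield"]
                for x in recs
                if (x["segment"], x["day"], x["system"])
                == (r["segment"], r["day"], r["system"])
            ]
            row = {
                "query_id": qi,
                "ref_id": ri,
                "y_exp": sum(same_triple) / len(same_triple),
                "v1": q["ghrelin"],
                "v2": q["ghr"],
            }
            for g, gene in ((1, "ghrelin"), (2, "ghr")):
                for suffix, col in classes.items():
                    level_vals = [x[gene] for x in recs if x[col] == anchor[col]]
                    row[f"dv{g}_{suffix}"] = q[gene] - sum(level_vals) / len(level_vals)
            row["target"] = q["yield"]
            rows.append(row)
    return pd.DataFrame(rows)


def random_sample_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A small random sample table with a handful of condition levels."""
    segs = rng.choice(["rumen", "abomasum", "duodenum"], size=n)
    days = rng.choice([0, 28, 70], size=n)
    systems = rng.choice(["S", "G"], size=n)
    return pd.DataFrame(
        {
            "animal": [f"a{i}" for i in range(n)],
            "segment": segs,
            "day": days,
            "system": systems,
            "ghrelin": rng.uniform(0.01, 5.0, size=n),
            "ghr": rng.uniform(0.01, 2.0, size=n),
            "live_weight": 10.0,
            "carcass_weight": 5.0,
            "yield": rng.uniform(0.3, 0.7, size=n),
        }
    )
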