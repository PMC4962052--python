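"""Published spatiotemporal mean relative expression of Ghrelin and GHR.

Cell means (2^-ddCT fold changes, calibrated on duodenum at d 0) per
gastrointestinal segment and postnatal day.  Before the feeding-system split
(d 0-14) all kids are suckling ("lactation"); from d 28 onward each day has a
Supplemental (S) and a Grazing (G) cell.  These grids drive the synthetic
study generator and the descriptive-statistics fixtures.
"""

from __future__ import annotations

import pandas as pd

SEGMENTS = (
    "rumen",
    "abomasum",
    "duodenum",
    "jejunum",
    "ileum",
    "cecum",
    "colon",
    "rectum",
)
DAYS = (0, 7, 14, 28, 42, 56, 70)
PRE_SPLIT_DAYS = (0, 7, 14)
SPLIT_DAYS = (28, 42, 56, 70)
SYSTEMS = ("S", "G", "L")

# Developmental stages by rumen maturation.
STAGES = {
    "pre-rumination": (0, 7, 14),
    "transition": (28, 42),
    "rumination": (56, 70),
}

# Per segment: 7 lactation/S-row values (d 0,7,14,28,42,56,70) then 4 G-row
# values (d 28,42,56,70).
_GHRELIN = {
    "rumen": ((0.004, 0.003, 0.002, 0.002, 0.004, 0.000, 0.002), (0.002, 0.004, 0.003, 0.004)),
    "abomasum": ((1.80, 31.15, 49.92, 61.64, 252.26, 438.34, 567.67), (85.12, 308.01, 564.58, 629.26)),
    "duodenum": ((1.00, 1.11, 1.33, 2.22, 0.74, 1.46, 0.99), (2.20, 2.98, 1.30, 1.57)),
    "jejunum": ((0.13, 0.21, 0.36, 0.31, 0.16, 0.17, 0.18), (0.43, 0.34, 0.33, 0.24)),
    "ileum": ((0.03, 0.02, 0.001, 0.00, 0.01, 0.01, 0.02), (0.01, 0.01, 0.01, 0.01)),
    "cecum": ((0.01, 0.03, 0.05, 0.02, 0.01, 0.01, 0.01), (0.03, 0.01, 0.03, 0.01)),
    "colon": ((0.02, 0.04, 0.03, 0.05, 0.05, 0.05, 0.05), (0.05, 0.04, 0.04, 0.06)),
    "rectum": ((0.02, 0.01, 0.02, 0.03, 0.06, 0.04, 0.02), (0.05, 0.04, 0.15, 0.14)),
}

_GHR = {
    "rumen": ((0.26, 0.31, 0.46, 0.37, 0.15, 0.03, 0.11), (0.03, 0.03, 0.03, 0.05)),
    "abomasum": ((0.85, 1.08, 1.16, 1.12, 0.64, 0.47, 0.46), (0.52, 0.41, 0.33, 0.24)),
    "duodenum": ((1.00, 0.75, 1.02, 0.97, 0.47, 0.49, 0.45), (0.28, 0.15, 0.17, 0.11)),
    "jejunum": ((1.21, 0.73, 0.77, 0.22, 0.36, 0.31, 0.27), (0.11, 0.13, 0.16, 0.16)),
    "ileum": ((0.89, 0.55, 0.25, 0.15, 0.15, 0.27, 0.12), (0.10, 0.10, 0.11, 0.09)),
    "cecum": ((0.43, 0.17, 0.33, 0.19, 0.11, 0.10, 0.12), (0.08, 0.05, 0.06, 0.07)),
    "colon": ((0.49, 0.33, 0.44, 0.80, 0.52, 0.41, 0.33), (0.38, 0.36, 0.29, 0.16)),
    "rectum": ((0.39, 0.45, 0.31, 0.40, 0.57, 0.34, 0.33), (0.29, 0.20, 0.22, 0.26)),
}

_GENES = {"ghrelin": _GHRELIN, "ghr": _GHR}
GENES = ("ghrelin", "ghr")


def template_frame() -> pd.DataFrame:
    """Long-format template grid.

    Columns ``gene, segment, day, system, value``; one row per printed cell.
    Pre-split days carry system ``L`` (lactation); d 28-70 have one S and one
    G row each, so the grid holds 2 genes x 8 segments x (3 + 4 x 2) cells.
    """
    rows = []
    for gene, table in _GENES.items():
        for segment, (s_row, g_row) in table.items():
            for day, value in zip(DAYS, s_row):
                system = "L" if day in PRE_SPLIT_DAYS else "S"
                rows.append((gene, segment, day, system, value))
            for day, value in zip(SPLIT_DAYS, g_row):
                rows.append((gene, segment, day, "G", value))
    return pd.DataFrame(rows, columns=["gene", "segment", "day", "system", "value"])


def template_mean(gene: str, segment: str, day: int, system: str) -> float:
    """Template cell mean for one condition triple.

    For pre-split days the lactation value answers for any of L/S/G, since
    the groups do not exist yet and the published tables print the pooled
    suckling value once.
    """
    gene = gene.lower()
    segment = segment.lower()
    if gene not in _GENES:
        raise KeyError(f"unknown gene {gene!r}")
    if segment not in _GENES[gene]:
        raise KeyError(f"unknown segment {segment!r}")
    if day not in DAYS:
        raise KeyError(f"unknown day {day!r}")
    s_row, g_row = _GENES[gene][segment]
    if day in PRE_SPLIT_DAYS:
        return s_row[DAYS.index(day)]
    if system.upper() == "G":
        return g_row[SPLIT_DAYS.index(day)]
    return s_row[DAYS.index(day)]
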