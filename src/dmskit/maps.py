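"""Shared variant-effect score-map table format.

A score map is a tidy table with one row per amino-acid substitution:

    gene, position, wt_aa, mut_aa, score, sd, se, df, provenance

``score`` is on the anchored scale (0 = null-like, 1 = wild-type-like),
``sd`` the standard deviation, ``se`` the (regularized) standard error,
``df`` the degrees of freedom behind it, and ``provenance`` one of
measured / refined / imputed / joint.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCORE_MAP_COLUMNS = [
    "gene",
    "position",
    "wt_aa",
    "mut_aa",
    "score",
    "sd",
    "se",
    "df",
    "provenance",
]


def validate_score_map(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCORE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score map missing columns {missing}")
    return df


def write_score_map(df: pd.DataFrame, path: str | Path) -> None:
    extra = [c for c in df.columns if c not in SCORE_MAP_COLUMNS]
    validate_score_map(df)[SCORE_MAP_COLUMNS + extra].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_score_map(path: str | Path) -> pd.DataFrame:
    return validate_score_map(pd.read_csv(path, sep="\t"))


def map_completeness(n_measured: int, n_possible: int) -> int:
    """Map coverage as a whole-number percentage."""
    if n_possible <= 0 or n_measured < 0:
        raise ValueError("counts must be positive")
    return round(100.0 * n_measured / n_possible)


def variant_key(df: pd.DataFrame) -> pd.Series:
    """Compact string key (e.g. ``K48E``) for joining tables."""
    return df["wt_aa"] + df["position"].astype(int).astype(str) + df["mut_aa"]
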