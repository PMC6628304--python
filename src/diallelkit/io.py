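"""Typed CSV readers/writers for the pipeline's table formats.

All tables are plain CSV.  The plot table is tidy (block, parent_a,
parent_b, trait, value); the SNP matrix has marker rows and parent columns
with calls in {0, 1, 2} and ``NA`` for missing; distance matrices are
square with labels in both header and first column.  Readers validate the
schema and report offending columns or rows by name/number rather than
failing downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gdist import DistanceMatrix
from .simulate import PLOT_COLUMNS

__all__ = [
    "write_plot_table", "load_plot_table",
    "write_snp_matrix", "load_snp_matrix",
    "write_distance_matrix", "load_distance_matrix",
]


def write_plot_table(plots: pd.DataFrame, path) -> None:
    missing = [c for c in PLOT_COLUMNS if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table missing columns: {missing}")
    plots[PLOT_COLUMNS].to_csv(path, index=False)


def load_plot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"parent_a": str, "parent_b": str, "trait": str})
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[df["value"].isna() | df["block"].isna()]
    if not bad.empty:
        lines = (bad.index + 2).tolist()[:10]  # +2: header and 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    df["block"] = df["block"].astype(int)
    return df[PLOT_COLUMNS]


def write_snp_matrix(snps: pd.DataFrame, path) -> None:
    out = snps.copy()
    out.index.name = "marker"
    # integer-looking calls, NA for missing
    out.to_csv(path, na_rep="NA", float_format="%.0f")


def load_snp_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    arr = df.to_numpy(dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        rows = sorted(set(np.where(~ok)[0].tolist()))[:10]
        raise ValueError(
            f"{path}: calls outside {{0,1,2,NA}} at marker rows {rows}")
    return df.astype(float)


def write_distance_matrix(dist: DistanceMatrix | pd.DataFrame, path) -> None:
    d = dist.d if isinstance(dist, DistanceMatrix) else dist
    d.to_csv(path)


def load_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return DistanceMatrix(d=df)
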