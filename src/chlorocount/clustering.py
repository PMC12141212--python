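"""Cell-type clustering in (cell area, chloroplast count) feature space.

Plotting per-cell chloroplast count against cell area separates
morphologically distinct cell populations.  The feature table is a plain
DataFrame so users can apply their own method; the built-in clustering is
k-means on per-column standardized features, which makes the result
invariant to the area unit (px^2 vs um^2).
"""

from __future__ import annotations

import os
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import InvalidInputError
from .singlecell import CellProfile

__all__ = ["build_feature_table", "cluster_cells", "export_scatter"]

FEATURE_COLUMNS = ["area_px", "chloroplast_count"]


def build_feature_table(profiles: list[CellProfile], sample_id: str) -> pd.DataFrame:
    """One row per cell: (cell_id, sample_id, area_px, chloroplast_count)."""
    ids = [p.cell_id for p in profiles]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidInputError(f"duplicate cell_id within sample {sample_id!r}: {dupes}")
    return pd.DataFrame(
        {
            "cell_id": ids,
            "sample_id": sample_id,
            "area_px": [p.area_px for p in profiles],
            "chloroplast_count": [p.chloroplast_count for p in profiles],
        }
    )


def cluster_cells(table: pd.DataFrame, k: int = 2, seed: int = 0) -> pd.DataFrame:
    """Append a ``cluster`` label column from k-means on standardized features.

    Deterministic for fixed (table, k, seed).  Requires at least k rows.
    """
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")
    if len(table) < k:
        raise InvalidInputError(f"k={k} exceeds the {len(table)} rows available")
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    std = X.std(axis=0)
    std[std == 0.0] = 1.0  # constant column: leave centered values at 0
    Z = (X - X.mean(axis=0)) / std
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(Z)
    out = table.copy()
    out["cluster"] = labels
    return out


def export_scatter(table: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Scatter of chloroplast count vs cell area, colored by cluster or sample.

    Writes the plot plus a CSV sidecar holding the exact plotted coordinates.
    Returns the plot path.
    """
    if table.empty:
        raise InvalidInputError("cannot plot an empty feature table")
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    color_col = "cluster" if "cluster" in table.columns else "sample_id"
    fig, ax = plt.subplots(figsize=(5, 4))
    for key, group in table.groupby(color_col, sort=True):
        ax.scatter(
            group["chloroplast_count"], group["area_px"], s=18, alpha=0.8, label=str(key)
        )
    ax.set_xlabel("chloroplast count per cell")
    ax.set_ylabel("cell area (px$^2$)")
    ax.legend(title=color_col, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    sidecar = path.with_suffix(".csv")
    table.to_csv(sidecar, index=False)
    return path
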