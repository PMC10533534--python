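"""Result tables: pivot the tidy benchmark records into method x metric
matrices with the per-row best marked, and summarize few-shot sweeps as
n-vs-AUC tables per exposed class set."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["method_metric_table", "sweep_table"]


def method_metric_table(records: pd.DataFrame, value: str = "near_auc",
                        mark_best: bool = True) -> pd.DataFrame:
    """Pivot records into a method x metric matrix of ``value``.

    Cells are formatted to three decimals; the best value of each row is
    marked with a trailing ``*``. Missing cells stay blank (never 0).
    """
    if value not in records.columns:
        raise ValueError(f"column {value!r} not present in records")
    pivot = records.pivot_table(index="method", columns="metric",
                                values=value, aggfunc="mean", sort=False)
    out = pd.DataFrame("", index=pivot.index, columns=pivot.columns)
    for method in pivot.index:
        row = pivot.loc[method]
        best = row.max()
        for metric in pivot.columns:
            v = row[metric]
            if pd.isna(v):
                continue
            cell = f"{v:.3f}"
            if mark_best and np.isclose(v, best, atol=1e-12):
                cell += "*"
            out.loc[method, metric] = cell
    return out


def sweep_table(sweep: pd.DataFrame, metric: str = "cosine") -> pd.DataFrame:
    """Mean balanced near-OOD AUC per (method, exposed classes, n),
    averaged over replicates."""
    col = f"near_auc_{metric}"
    if col not in sweep.columns:
        raise ValueError(f"column {col!r} not present in sweep records")
    return (sweep.groupby(["method", "exposed_classes", "n_exposed"])[col]
            .mean().unstack("n_exposed"))
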