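"""Volcano-style classification of a protein quantification table.

Given per-protein log2 fold changes (positive = higher in the
hyaluronan-based minimal medium) and p-values, p-values are adjusted for
multiple testing with the Benjamini–Hochberg step-up procedure and each
protein is assigned one of four classes:

* ``up``                   - log2 FC >= fc_threshold and adjusted p <= p_threshold
* ``down``                 - log2 FC <= -fc_threshold and adjusted p <= p_threshold
* ``significant_small_fc`` - adjusted p <= p_threshold but |log2 FC| < fc_threshold
* ``not_significant``      - otherwise

Threshold comparisons are inclusive.  Defaults: fc_threshold 1 (two-fold),
p_threshold 0.05.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DE_CLASSES",
    "bh_adjust",
    "classify_volcano",
    "classify_table",
]

DE_CLASSES = ("up", "down", "significant_small_fc", "not_significant")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_volcano(
    log2fc: float,
    adjusted_p: float,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> str:
    """Four-way volcano class of one protein (inclusive thresholds)."""
    if not (np.isfinite(log2fc) and np.isfinite(adjusted_p)):
        raise ValueError("log2fc and adjusted_p must be finite")
    if adjusted_p > p_threshold:
        return "not_significant"
    if log2fc >= fc_threshold:
        return "up"
    if log2fc <= -fc_threshold:
        return "down"
    return "significant_small_fc"


def classify_table(
    table: pd.DataFrame,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    log2fc_col: str = "log2fc",
    pvalue_col: str = "pvalue",
) -> pd.DataFrame:
    """Add ``padj`` and ``de_class`` columns to a quantification table.

    The input needs a protein identifier column plus ``log2fc`` and
    ``pvalue`` columns; the original is not modified.
    """
    for col in (log2fc_col, pvalue_col):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    out = table.copy()
    out["padj"] = bh_adjust(out[pvalue_col].to_numpy())
    out["de_class"] = [
        classify_volcano(fc, q, fc_threshold, p_threshold)
        for fc, q in zip(out[log2fc_col], out["padj"])
    ]
    return out


def classify_file(
    in_path: str | Path,
    out_path: str | Path,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    sep: str = "\t",
) -> pd.DataFrame:
    """Classify a delimited (protein_id, log2fc, pvalue) file on disk."""
    table = pd.read_csv(in_path, sep=sep)
    out = classify_table(table, fc_threshold, p_threshold)
    out.to_csv(out_path, sep=sep, index=False)
    return out
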