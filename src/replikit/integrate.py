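"""Integrate replication-timing changes with ChIP enrichment and expression.

Per-segment timing deltas are related to per-segment ChIP enrichment changes
(scatter correlation, class-wise box summaries, top-percentile gain/loss
sets) and to per-gene expression changes (genes mapped to segments by TSS,
fold-change summaries by switch class, and a Fisher exact test for the
enrichment of strongly regulated genes in switching regions).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout

__all__ = [
    "correlate_deltas",
    "summarize_by_class",
    "top_percentile_segments",
    "assign_genes_to_segments",
    "fold_enrichment_test",
]

CLASS_ORDER = ("EtoL", "LtoE", "EtoE", "LtoL")


def correlate_deltas(rt_delta: np.ndarray, omics_delta: np.ndarray) -> tuple[float, int]:
    """Pearson correlation between timing and omics deltas over joint support.

    NaN entries on either side are treated as masked and excluded.
    """
    x = np.asarray(rt_delta, dtype=float)
    y = np.asarray(omics_delta, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need at least 3 jointly unmasked segments, got {n}")
    r = float(stats.pearsonr(x[ok], y[ok]).statistic)
    return r, n


def summarize_by_class(values: np.ndarray, classes: Sequence[str]) -> pd.DataFrame:
    """Five-number (Tukey) summaries of values per switch class.

    Whiskers extend to the most extreme data point within 1.5·IQR of the
    nearer quartile. Empty classes are reported with n = 0 and NaN summaries.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes, dtype=object)
    if values.shape != classes.shape:
        raise ValueError("values and classes must align")
    rows = []
    for cls in CLASS_ORDER:
        sel = values[(classes == cls) & np.isfinite(values)]
        if sel.size == 0:
            rows.append({"class": cls, "n": 0, "median": np.nan, "q1": np.nan,
                         "q3": np.nan, "whisker_lo": np.nan, "whisker_hi": np.nan})
            continue
        q1, med, q3 = np.percentile(sel, [25, 50, 75])
        iqr = q3 - q1
        lo = sel[sel >= q1 - 1.5 * iqr].min()
        hi = sel[sel <= q3 + 1.5 * iqr].max()
        rows.append({"class": cls, "n": int(sel.size), "median": med, "q1": q1,
                     "q3": q3, "whisker_lo": lo, "whisker_hi": hi})
    return pd.DataFrame(rows)


def top_percentile_segments(
    deltas: np.ndarray,
    percent: float,
    direction: str = "gain",
) -> np.ndarray:
    """Indices of the ⌈percent/100·n⌉ most extreme unmasked segments.

    ``direction='gain'`` takes the largest deltas, ``'loss'`` the most
    negative. Ties are broken by coordinate (index) order so the selection is
    deterministic. Returned indices are sorted by coordinate.
    """
    if not 0 < percent < 100:
        raise ValueError("percent must lie in (0, 100)")
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    deltas = np.asarray(deltas, dtype=float)
    valid = np.flatnonzero(np.isfinite(deltas))
    n = valid.size
    if n == 0:
        return np.empty(0, dtype=int)
    k = int(np.ceil(percent / 100.0 * n))
    key = -deltas[valid] if direction == "gain" else deltas[valid]
    # lexsort: primary key = delta magnitude in direction, ties by coordinate
    order = np.lexsort((valid, key))
    return np.sort(valid[order[:k]])


def assign_genes_to_segments(genes: pd.DataFrame, layout: GenomeLayout) -> np.ndarray:
    """Segment index per gene from its TSS (half-open segment intervals)."""
    out = np.empty(len(genes), dtype=int)
    for i, (gid, chrom, tss) in enumerate(
        zip(genes["gene_id"], genes["chrom"], genes["tss"])
    ):
        try:
            out[i] = layout.segment_index(str(chrom), int(tss))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"gene {gid}: {exc}") from None
    return out


def fold_enrichment_test(
    in_set: np.ndarray,
    in_class: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Fisher exact test: is a gene set enriched in a region class?

    ``in_set`` and ``in_class`` are boolean per gene (e.g. fold change > 2;
    TSS inside an LtoE region). Returns the 2×2 table
    [[set∩class, set∩¬class], [¬set∩class, ¬set∩¬class]], the odds ratio
    (Haldane 0.5 correction when any cell is zero) and the two-sided p.
    """
    in_set = np.asarray(in_set, dtype=bool)
    in_class = np.asarray(in_class, dtype=bool)
    if in_set.size == 0:
        raise ValueError("empty gene list")
    if in_set.shape != in_class.shape:
        raise ValueError("predicates must align")
    a = int(np.sum(in_set & in_class))
    b = int(np.sum(in_set & ~in_class))
    c = int(np.sum(~in_set & in_class))
    d = int(np.sum(~in_set & ~in_class))
    table = np.array([[a, b], [c, d]])
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return table, float(odds), p
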