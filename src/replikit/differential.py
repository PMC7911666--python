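"""Replication-timing switching segments: replicate-calibrated empirical test.

The statistic follows the replicate-difference logic of two-fraction RT
analysis: for each fixed 200-kb segment the between-group distance (control
vs. mutant replicate means) is compared against a genome-wide pool of
within-group replicate differences, which serves as the empirical null.
Pooled null ranks give per-segment p-values; Storey q-values convert them to
per-segment false-discovery-rate estimates; segments significant at the
chosen q cutoff are classified as early-to-late (EtoL) or late-to-early
(LtoE) switches by the sign of their timing endpoints.

Because the between statistic is a difference of group *means* while the
null entries are single replicate pairs, the null pool is variance-calibrated
by default: each within-pair difference is scaled by sqrt((1/n_A + 1/n_B)/2)
so that, under the null, the between statistic and the pool entries share the
same per-segment sampling scale. Without this the pool is stochastically
larger and p-values are conservative rather than uniform.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout, SegmentTrack

__all__ = [
    "segment_distances",
    "empirical_pvalues",
    "storey_qvalues",
    "call_switches",
    "merge_to_domains",
    "overlap_test",
    "switch_analysis",
]

CLASSES = ("EtoL", "LtoE", "EtoE", "LtoL", "masked")


def _stack(tracks: Sequence[SegmentTrack]) -> tuple[np.ndarray, np.ndarray]:
    vals = np.vstack([t.values for t in tracks])
    masked = np.vstack([t.masked for t in tracks]).any(axis=0)
    return vals, masked


def segment_distances(
    group_a: Sequence[SegmentTrack],
    group_b: Sequence[SegmentTrack],
    calibrate: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Between-group distance per segment and the pooled within-group null.

    Returns ``(d, null_pool, masked)``: ``d[i]`` is the absolute difference of
    replicate-mean timing between the two groups at segment ``i``; the null
    pool collects |rep_j − rep_k| over all within-group replicate pairs, both
    groups, all unmasked segments. ``calibrate=True`` applies the
    variance-matching factor sqrt((1/n_A + 1/n_B)/2) to the pool entries.
    A segment masked in any replicate is excluded from both outputs.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one replicate")
    va, ma = _stack(group_a)
    vb, mb = _stack(group_b)
    masked = ma | mb
    n_a, n_b = len(group_a), len(group_b)
    if n_a < 2 and n_b < 2:
        raise ValueError("no within-group replicate pair available: null undefined")
    d = np.abs(va.mean(axis=0) - vb.mean(axis=0))
    d = np.where(masked, np.nan, d)
    scale = np.sqrt((1.0 / n_a + 1.0 / n_b) / 2.0) if calibrate else 1.0
    pool = []
    for vals in (va, vb):
        for j, k in combinations(range(vals.shape[0]), 2):
            pool.append(np.abs(vals[j] - vals[k])[~masked] * scale)
    null_pool = np.concatenate(pool) if pool else np.empty(0)
    return d, null_pool, masked


def empirical_pvalues(d: np.ndarray, null_pool: np.ndarray) -> np.ndarray:
    """Add-one empirical p-values: p_i = (1 + #{null >= d_i}) / (1 + N).

    NaN entries (masked segments) stay NaN.
    """
    null_pool = np.asarray(null_pool, dtype=float)
    if null_pool.size == 0:
        raise ValueError("empty null pool")
    d = np.asarray(d, dtype=float)
    srt = np.sort(null_pool)
    n = srt.size
    ge = n - np.searchsorted(srt, d, side="left")
    p = (1.0 + ge) / (1.0 + n)
    return np.where(np.isnan(d), np.nan, p)


def storey_qvalues(p: np.ndarray, pi0_method: str = "fixed_lambda", lam: float = 0.5) -> np.ndarray:
    """Storey q-values by the step-up rule on sorted p-values.

    ``pi0_method='fixed_lambda'`` estimates the null proportion as
    #{p > lam} / ((1 − lam)·m), capped at 1; ``'bh'`` fixes pi0 = 1, which
    reduces the procedure to Benjamini–Hochberg adjusted p-values. NaN entries
    pass through as NaN and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    finite = ~np.isnan(p)
    pv = p[finite]
    if pv.size == 0:
        return np.full_like(p, np.nan)
    if np.any((pv <= 0) | (pv > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = pv.size
    if pi0_method == "bh":
        pi0 = 1.0
    elif pi0_method == "fixed_lambda":
        if not 0 < lam < 1:
            raise ValueError("lambda must be in (0, 1)")
        pi0 = min(1.0, np.count_nonzero(pv > lam) / ((1.0 - lam) * m))
        pi0 = max(pi0, 1.0 / m)  # guard against a degenerate all-signal input
    else:
        raise ValueError(f"unknown pi0_method {pi0_method!r}")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    out = np.full_like(p, np.nan)
    out[finite] = q
    return out


def call_switches(
    layout: GenomeLayout,
    ctrl_mean: np.ndarray,
    mut_mean: np.ndarray,
    d: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    masked: np.ndarray,
    q_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Classify every segment as EtoL / LtoE / EtoE / LtoL / masked.

    Significance is q <= q_cutoff. A significant segment that was early in
    control (mean > 0 on the log2 early/late scale) and moved later
    (delta < 0) is EtoL; late-to-earlier is LtoE. Significant segments whose
    change does not cross the pattern (e.g. early -> even earlier), and all
    non-significant segments, are labelled by their endpoint signs (EtoE /
    LtoL, non-significant mixed-sign segments by the control sign).
    """
    delta = mut_mean - ctrl_mean
    n = layout.n_segments
    classes = np.full(n, "masked", dtype=object)
    sig = np.zeros(n, dtype=bool)
    valid = ~np.asarray(masked, dtype=bool)
    sig[valid] = q[valid] <= q_cutoff
    for i in np.flatnonzero(valid):
        c, m_ = ctrl_mean[i], mut_mean[i]
        if sig[i] and c > 0 and delta[i] < 0:
            classes[i] = "EtoL"
        elif sig[i] and c < 0 and delta[i] > 0:
            classes[i] = "LtoE"
        elif c > 0 and m_ > 0:
            classes[i] = "EtoE"
        elif c < 0 and m_ < 0:
            classes[i] = "LtoL"
        else:
            classes[i] = "EtoE" if c >= 0 else "LtoL"
    chrom_names = np.asarray(layout.names)[layout.segment_chrom_indices()]
    return pd.DataFrame(
        {
            "chrom": chrom_names,
            "start": layout.segment_starts(),
            "end": layout.segment_ends(),
            "ctrl_mean": np.where(valid, ctrl_mean, np.nan),
            "mut_mean": np.where(valid, mut_mean, np.nan),
            "delta": np.where(valid, delta, np.nan),
            "d": np.where(valid, d, np.nan),
            "p": np.where(valid, p, np.nan),
            "q": np.where(valid, q, np.nan),
            "class": classes,
            "significant": sig,
        }
    )


def merge_to_domains(calls: pd.DataFrame, classes: Sequence[str] | None = None) -> pd.DataFrame:
    """Merge runs of adjacent segments sharing class and significance.

    Returns BED-like rows (chrom, start, end, name=class, score, q,
    n_segments); the domain q is the minimum member q and the BED score is
    round(1000·(1 − q)). ``classes`` restricts the output (e.g. to the
    significant switch classes) after merging.
    """
    cols = ["chrom", "start", "end", "name", "score", "q", "n_segments", "significant"]
    if calls.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    cur = None
    for rec in calls.to_dict("records"):
        joinable = (
            cur is not None
            and rec["chrom"] == cur["chrom"]
            and rec["start"] == cur["end"]
            and rec["class"] == cur["name"]
            and bool(rec["significant"]) == cur["significant"]
        )
        if joinable:
            cur["end"] = rec["end"]
            cur["q"] = np.nanmin([cur["q"], rec["q"]])
            cur["n_segments"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": rec["chrom"],
                "start": rec["start"],
                "end": rec["end"],
                "name": rec["class"],
                "q": rec["q"],
                "n_segments": 1,
                "significant": bool(rec["significant"]),
            }
    if cur is not None:
        rows.append(cur)
    out = pd.DataFrame(rows)
    q = out["q"].to_numpy(dtype=float)
    score = np.where(np.isnan(q), 0, np.rint(1000 * (1 - np.where(np.isnan(q), 1, q))))
    out["score"] = score.astype(int)
    if classes is not None:
        out = out[out["name"].isin(list(classes))].reset_index(drop=True)
    return out[cols]


def overlap_test(set_a, set_b, universe_size: int) -> tuple[int, float, float]:
    """Hypergeometric upper-tail test for the overlap of two segment sets.

    Returns ``(overlap, expected, p)`` where expected = |A|·|B|/universe and p
    is the probability of an overlap at least this large when B is drawn
    uniformly from the universe.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than universe")
    k = len(a & b)
    expected = len(a) * len(b) / universe_size
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, expected, min(p, 1.0)


def switch_analysis(
    ctrl_tracks: Sequence[SegmentTrack],
    mut_tracks: Sequence[SegmentTrack],
    q_cutoff: float = 0.01,
    pi0_method: str = "fixed_lambda",
    calibrate: bool = True,
) -> pd.DataFrame:
    """Full switching-segment pipeline on replicate segment tracks."""
    layout = ctrl_tracks[0].layout
    d, pool, masked = segment_distances(ctrl_tracks, mut_tracks, calibrate=calibrate)
    p = empirical_pvalues(d, pool)
    q = storey_qvalues(p, pi0_method=pi0_method)
    ctrl_mean = np.vstack([t.values for t in ctrl_tracks]).mean(axis=0)
    mut_mean = np.vstack([t.values for t in mut_tracks]).mean(axis=0)
    return call_switches(layout, ctrl_mean, mut_mean, d, p, q, masked, q_cutoff=q_cutoff)
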