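"""Replication-timing profiles from early/late S-phase count tracks.

The measurement model: reads from BrdU-labelled, FACS-sorted early and late
S-phase fractions are counted in 5-kb bins, each library is normalized per
million reads, and the per-bin log2(early/late) ratio estimates replication
timing (positive = early replicating, negative = late). Profiles for display
are LOESS-smoothed over a fixed 300-kb genomic span; for segment-level
statistics the ratios are averaged into fixed-position 200-kb windows.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import correlate1d

from .genome import BinTrack, CountTrack, SegmentTrack

__all__ = [
    "normalize_per_million",
    "log2_ratio",
    "loess_smooth",
    "average_into_segments",
    "rt_differential",
    "profile_pipeline",
]

log = logging.getLogger("replikit")


def normalize_per_million(track: CountTrack) -> BinTrack:
    """Scale counts so the track totals one million; keeps raw counts attached."""
    total = track.total
    if total <= 0:
        raise ValueError("cannot normalize a track with zero total count")
    values = track.counts * (1e6 / total)
    out = BinTrack(
        track.layout,
        values,
        np.zeros(track.layout.n_bins, dtype=bool),
        sample_id=track.sample_id,
    )
    out.raw_total = float(total)
    out.raw_counts = track.counts
    return out


def log2_ratio(
    early: BinTrack,
    late: BinTrack,
    pseudocount: float = 1.0,
    min_raw_total: float = 10.0,
) -> BinTrack:
    """Per-bin log2((early + c) / (late + c)) on per-million-scaled tracks.

    Bins whose combined *raw* read count falls below ``min_raw_total`` are
    masked as unreliable (the masking is skipped when raw counts are not
    attached, e.g. for tracks read back from bedGraph).
    """
    if early.layout is not late.layout and early.layout != late.layout:
        raise ValueError("early and late tracks have mismatched layouts")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2((early.values + pseudocount) / (late.values + pseudocount))
    masked = early.masked | late.masked
    if early.raw_counts is not None and late.raw_counts is not None:
        masked = masked | ((early.raw_counts + late.raw_counts) < min_raw_total)
    values = np.where(masked, np.nan, values)
    return BinTrack(early.layout, values, masked, sample_id=early.sample_id)


def _loess_kernels(half_span_bp: float, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Tricube weights and bin offsets for a fixed genomic half-span."""
    J = int(half_span_bp // bin_size)
    offsets = np.arange(-J, J + 1)
    d = np.abs(offsets * bin_size) / half_span_bp
    w = np.where(d < 1.0, (1.0 - d**3) ** 3, 0.0)
    return w, offsets


def loess_smooth(track: BinTrack, span_kb: float = 300.0) -> BinTrack:
    """LOESS (degree-1, tricube) smoothing over a fixed genomic span.

    At each bin the fit window is the ``span_kb`` neighbourhood centred on it
    (half the span on either side); bin positions are taken on the uniform
    nominal grid ``index * bin_size``. Masked bins are excluded from every fit
    and stay masked in the output. The local weighted-least-squares solution
    is evaluated by exact moving sums, so it matches a per-bin WLS fit to
    machine precision.
    """
    layout = track.layout
    if span_kb <= 0:
        raise ValueError("span_kb must be positive")
    half = span_kb * 1000.0 / 2.0
    w, offsets = _loess_kernels(half, layout.bin_size)
    x = offsets.astype(float) * layout.bin_size
    k0, k1, k2 = w, w * x, w * x * x

    out = np.full(layout.n_bins, np.nan)
    out_masked = np.ones(layout.n_bins, dtype=bool)
    offs = layout.bin_offsets
    for ci, (name, _) in enumerate(layout.chroms):
        sl = slice(offs[ci], offs[ci + 1])
        valid = (~track.masked[sl]).astype(float)
        n_valid = int(valid.sum())
        if n_valid < 2:
            log.warning("chromosome %s has <2 unmasked bins; output fully masked", name)
            continue
        y = np.where(track.masked[sl], 0.0, track.values[sl])
        # moving weighted moments; zero-padding outside the chromosome is
        # equivalent to excluding out-of-range points from the window
        S0 = correlate1d(valid, k0, mode="constant")
        S1 = correlate1d(valid, k1, mode="constant")
        S2 = correlate1d(valid, k2, mode="constant")
        T0 = correlate1d(y * valid, k0, mode="constant")
        T1 = correlate1d(y * valid, k1, mode="constant")
        denom = S0 * S2 - S1 * S1
        scale = np.maximum(S0 * S2, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            linear = (S2 * T0 - S1 * T1) / denom
            mean_only = T0 / np.maximum(S0, 1e-300)
        # fall back to the local weighted mean when the design is degenerate
        # (a single usable point in the window)
        est = np.where(denom > 1e-10 * scale, linear, mean_only)
        ok = (~track.masked[sl]) & (S0 > 0)
        out[sl][ok] = est[ok]
        out_masked[sl][ok] = False
    return BinTrack(layout, out, out_masked, sample_id=track.sample_id)


def average_into_segments(track: BinTrack, min_valid_fraction: float = 0.5) -> SegmentTrack:
    """Mean of unmasked bin values per fixed 200-kb segment.

    A segment is masked when fewer than ``min_valid_fraction`` of its bins
    carry values.
    """
    layout = track.layout
    seg_of = layout.bin_to_segment()
    nseg = layout.n_segments
    valid = ~track.masked
    n_bins_per_seg = np.bincount(seg_of, minlength=nseg)
    n_valid = np.bincount(seg_of, weights=valid.astype(float), minlength=nseg)
    sums = np.bincount(seg_of[valid], weights=track.values[valid], minlength=nseg)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / n_valid
        frac = n_valid / n_bins_per_seg
    masked = (frac < min_valid_fraction) | (n_valid == 0)
    means = np.where(masked, np.nan, means)
    return SegmentTrack(layout, means, masked, sample_id=track.sample_id, valid_fraction=frac)


def rt_differential(seg_mut: SegmentTrack, seg_ctrl: SegmentTrack) -> SegmentTrack:
    """Replication-timing differential per segment: mutant minus control."""
    if seg_mut.layout != seg_ctrl.layout:
        raise ValueError("segment tracks have mismatched layouts")
    masked = seg_mut.masked | seg_ctrl.masked
    delta = np.where(masked, np.nan, seg_mut.values - seg_ctrl.values)
    return SegmentTrack(seg_mut.layout, delta, masked, sample_id=f"{seg_mut.sample_id}-{seg_ctrl.sample_id}")


def profile_pipeline(
    early: CountTrack,
    late: CountTrack,
    span_kb: float = 300.0,
    pseudocount: float = 1.0,
    min_raw_total: float = 10.0,
    smooth: bool = True,
) -> BinTrack:
    """Counts -> per-million -> log2 ratio -> (optionally) LOESS profile."""
    ratio = log2_ratio(
        normalize_per_million(early),
        normalize_per_million(late),
        pseudocount=pseudocount,
        min_raw_total=min_raw_total,
    )
    if not smooth:
        return ratio
    return loess_smooth(ratio, span_kb=span_kb)
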