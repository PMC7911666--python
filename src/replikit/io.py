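"""Readers and writers for the plain-text genomics formats the pipeline touches.

All interval I/O is 0-based half-open (BED/bedGraph convention). Helpers are
provided for converting a 1-based fully-closed dialect (e.g. GFF-style
coordinates) so that the conversion round-trips exactly.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import BinTrack, CountTrack, GenomeLayout

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_table",
    "write_bed",
    "to_one_based_closed",
    "from_one_based_closed",
]


def read_chrom_sizes(path, bin_size: int = 5_000, segment_size: int = 200_000) -> GenomeLayout:
    """Read a 2-column ``chrom.sizes`` TSV into a :class:`GenomeLayout`."""
    chroms = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            chroms.append((name, int(length)))
    return GenomeLayout(chroms, bin_size=bin_size, segment_size=segment_size)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chroms:
            fh.write(f"{name}\t{length}\n")


def _parse_bedgraph_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            yield lineno, parts[0], int(parts[1]), int(parts[2]), float(parts[3])


def read_bedgraph(
    path, layout: GenomeLayout, sample_id: str = "", mask_uncovered: bool = False
) -> BinTrack:
    """Map a 4-column bedGraph onto the layout's bin grid.

    The value of an interval is treated as a quantity spread uniformly along
    it: intervals not aligned to the bin grid are length-weighted onto the
    bins they overlap, so totals are conserved. Overlapping intervals and
    chromosomes absent from the layout are rejected. Bins no interval touches
    read as 0, or as masked when ``mask_uncovered`` is set (appropriate for
    value tracks written with masked bins omitted).
    """
    values = np.zeros(layout.n_bins, dtype=float)
    covered = np.zeros(layout.n_bins, dtype=bool)
    seen: dict[str, list[tuple[int, int]]] = {}
    bs = layout.bin_size
    for lineno, chrom, start, end, value in _parse_bedgraph_lines(path):
        if chrom not in layout.names:
            raise ValueError(f"unknown chromosome {chrom}")
        ci = layout.chrom_index(chrom)
        if start < 0:
            raise ValueError(f"{path}:{lineno}: negative coordinate {start}")
        if end <= start:
            raise ValueError(f"{path}:{lineno}: empty or inverted interval")
        if end > layout.lengths[ci]:
            raise ValueError(f"{path}:{lineno}: interval beyond end of {chrom}")
        seen.setdefault(chrom, []).append((start, end))
        off = layout.bin_offsets[ci]
        first = start // bs
        last = (end - 1) // bs
        covered[off + first:off + last + 1] = True
        if first == last:
            values[off + first] += value
        else:
            span = end - start
            for b in range(first, last + 1):
                lo = max(start, b * bs)
                hi = min(end, (b + 1) * bs)
                values[off + b] += value * (hi - lo) / span
    for chrom, ivals in seen.items():
        ivals.sort()
        for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping intervals on {chrom} near {s1}")
    masked = ~covered if mask_uncovered else np.zeros(layout.n_bins, dtype=bool)
    values = np.where(masked, np.nan, values)
    return BinTrack(layout, values, masked, sample_id=sample_id)


def read_bedgraph_counts(path, layout: GenomeLayout, sample_id: str = "", fraction: str = "early") -> CountTrack:
    """Read a bedGraph of integer read counts into a :class:`CountTrack`."""
    track = read_bedgraph(path, layout, sample_id=sample_id)
    counts = np.rint(track.values).astype(np.int64)
    return CountTrack(layout, counts, sample_id=sample_id, fraction=fraction)


def write_bedgraph(track, path, name: str = "") -> None:
    """Write a bin track (or count track) as bedGraph; masked bins are omitted."""
    layout = track.layout
    if hasattr(track, "counts"):
        values = track.counts.astype(float)
        masked = np.zeros(layout.n_bins, dtype=bool)
    else:
        values = track.values
        masked = track.masked
    starts = layout.bin_starts()
    ends = layout.bin_ends()
    chrom_of = layout.bin_chrom_indices()
    names = layout.names
    label = name or getattr(track, "sample_id", "") or "track"
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{label}"\n')
        for i in range(layout.n_bins):
            if masked[i]:
                continue
            fh.write(f"{names[chrom_of[i]]}\t{starts[i]}\t{ends[i]}\t{values[i]:.6g}\n")


def read_table(path, schema: Mapping[str, type] | Sequence[str]) -> pd.DataFrame:
    """Read a tab-separated table with a header, enforcing required columns.

    ``schema`` maps required column names to types (``float``, ``int`` or
    ``str``); a plain sequence of names means all-string. Values of ``NA`` or
    empty in numeric columns become NaN (flagged missing, never dropped);
    anything else unparseable raises with its line number. Extra columns are
    preserved as strings.
    """
    if not isinstance(schema, Mapping):
        schema = {name: str for name in schema}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in schema:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    for col, typ in schema.items():
        if typ is str:
            continue
        raw = df[col].str.strip()
        missing = raw.isin(["", "NA", "NaN", "nan", "na"])
        parsed = pd.to_numeric(raw.where(~missing), errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}:{row + 2}: cannot parse {col}={raw.iloc[row]!r} as {typ.__name__}"
            )
        if typ is int and not missing.any():
            parsed = parsed.astype(np.int64)
        df[col] = parsed
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write a BED6 file from columns chrom/start/end/name[/score/strand]."""
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            score = int(row["score"]) if "score" in row else 0
            strand = row.get("strand", ".")
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{row['name']}\t{score}\t{strand}\n"
            )


def to_one_based_closed(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based fully-closed [start+1, end]."""
    return start + 1, end


def from_one_based_closed(first: int, last: int) -> tuple[int, int]:
    """1-based fully-closed [first, last] -> 0-based half-open [first-1, last)."""
    return first - 1, last
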