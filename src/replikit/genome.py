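"""Genome layout: fixed-position bin and segment tilings.

Replication timing is measured on a 5-kb bin grid and tested on a 200-kb
segment grid. Both tilings are 0-based half-open intervals ``[k*size,
(k+1)*size)`` per chromosome, with a final partial interval retained (and
flagged) so that genome coverage accounting is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = ["GenomeLayout", "BinTrack", "CountTrack", "SegmentTrack"]


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with derived bin and segment tilings.

    Parameters
    ----------
    chroms
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Width of the fine measurement bins in bp (default 5 kb).
    segment_size
        Width of the fixed-position analysis segments in bp (default 200 kb);
        must be a multiple of ``bin_size``.
    """

    chroms: tuple[tuple[str, int], ...]
    bin_size: int = 5_000
    segment_size: int = 200_000

    def __init__(
        self,
        chroms: Iterable[tuple[str, int]],
        bin_size: int = 5_000,
        segment_size: int = 200_000,
    ) -> None:
        chroms = tuple((str(n), int(l)) for n, l in chroms)
        if not chroms:
            raise ValueError("layout needs at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if bin_size <= 0 or segment_size <= 0:
            raise ValueError("bin_size and segment_size must be positive")
        if segment_size % bin_size != 0:
            raise ValueError("bin_size must divide segment_size")
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "bin_size", int(bin_size))
        object.__setattr__(self, "segment_size", int(segment_size))

    # ---- chromosome helpers -------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chroms)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(l for _, l in self.chroms)

    def chrom_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name}") from None

    # ---- bin tiling ---------------------------------------------------------

    def n_bins_of(self, name: str) -> int:
        return _ceil_div(self.lengths[self.chrom_index(name)], self.bin_size)

    @property
    def bins_per_chrom(self) -> np.ndarray:
        return np.array([_ceil_div(l, self.bin_size) for l in self.lengths])

    @property
    def bin_offsets(self) -> np.ndarray:
        """Global bin index of the first bin of each chromosome (plus total)."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)])

    @property
    def n_bins(self) -> int:
        return int(self.bin_offsets[-1])

    def bin_chrom_indices(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.chroms)), self.bins_per_chrom)

    def bin_starts(self) -> np.ndarray:
        """Per-bin start coordinate (bp, chromosome-local)."""
        out = np.empty(self.n_bins, dtype=np.int64)
        offs = self.bin_offsets
        for ci in range(len(self.chroms)):
            n = offs[ci + 1] - offs[ci]
            out[offs[ci]:offs[ci + 1]] = np.arange(n) * self.bin_size
        return out

    def bin_ends(self) -> np.ndarray:
        starts = self.bin_starts()
        lens = np.asarray(self.lengths)[self.bin_chrom_indices()]
        return np.minimum(starts + self.bin_size, lens)

    def partial_bins(self) -> np.ndarray:
        """Boolean flag per bin: True where the bin is a short final interval."""
        return (self.bin_ends() - self.bin_starts()) < self.bin_size

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos`` (0-based)."""
        ci = self.chrom_index(chrom)
        if pos < 0 or pos >= self.lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.bin_offsets[ci] + pos // self.bin_size)

    # ---- segment tiling -----------------------------------------------------

    @property
    def segments_per_chrom(self) -> np.ndarray:
        return np.array([_ceil_div(l, self.segment_size) for l in self.lengths])

    @property
    def segment_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.segments_per_chrom)])

    @property
    def n_segments(self) -> int:
        return int(self.segment_offsets[-1])

    def segment_chrom_indices(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.chroms)), self.segments_per_chrom)

    def segment_starts(self) -> np.ndarray:
        out = np.empty(self.n_segments, dtype=np.int64)
        offs = self.segment_offsets
        for ci in range(len(self.chroms)):
            n = offs[ci + 1] - offs[ci]
            out[offs[ci]:offs[ci + 1]] = np.arange(n) * self.segment_size
        return out

    def segment_ends(self) -> np.ndarray:
        starts = self.segment_starts()
        lens = np.asarray(self.lengths)[self.segment_chrom_indices()]
        return np.minimum(starts + self.segment_size, lens)

    def partial_segments(self) -> np.ndarray:
        return (self.segment_ends() - self.segment_starts()) < self.segment_size

    def bin_to_segment(self) -> np.ndarray:
        """Global segment index for each global bin."""
        seg_local = self.bin_starts() // self.segment_size
        return self.segment_offsets[self.bin_chrom_indices()] + seg_local

    def segment_index(self, chrom: str, pos: int) -> int:
        ci = self.chrom_index(chrom)
        if pos < 0 or pos >= self.lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.segment_offsets[ci] + pos // self.segment_size)


def _validate_arrays(layout: GenomeLayout, values: np.ndarray, masked: np.ndarray, n: int):
    values = np.asarray(values, dtype=float)
    if masked is None:
        masked = ~np.isfinite(values)
    masked = np.asarray(masked, dtype=bool)
    if values.shape != (n,) or masked.shape != (n,):
        raise ValueError(f"expected arrays of length {n}, got {values.shape}/{masked.shape}")
    return values, masked


@dataclass
class BinTrack:
    """One real value per bin of a :class:`GenomeLayout`, with a mask.

    ``masked`` is True where the bin carries no usable value (the stored value
    at masked bins is ignored; NaN by convention).
    """

    layout: GenomeLayout
    values: np.ndarray
    masked: np.ndarray = None
    sample_id: str = ""
    raw_total: float | None = None  # pre-scaling read total, if derived from counts
    raw_counts: np.ndarray | None = None

    def __post_init__(self):
        self.values, self.masked = _validate_arrays(
            self.layout, self.values, self.masked, self.layout.n_bins
        )

    def finite_values(self) -> np.ndarray:
        out = np.array(self.values, dtype=float)
        out[self.masked] = np.nan
        return out


@dataclass
class CountTrack:
    """Non-negative integer read counts per bin for one sample/fraction."""

    layout: GenomeLayout
    counts: np.ndarray
    sample_id: str = ""
    fraction: str = "early"

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (self.layout.n_bins,):
            raise ValueError("counts length must equal number of bins")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.fraction not in ("early", "late"):
            raise ValueError("fraction must be 'early' or 'late'")
        self.counts = counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SegmentTrack:
    """One value per 200-kb segment of a :class:`GenomeLayout`."""

    layout: GenomeLayout
    values: np.ndarray
    masked: np.ndarray = None
    sample_id: str = ""
    valid_fraction: np.ndarray | None = None

    def __post_init__(self):
        self.values, self.masked = _validate_arrays(
            self.layout, self.values, self.masked, self.layout.n_segments
        )
        if self.valid_fraction is not None:
            self.valid_fraction = np.asarray(self.valid_fraction, dtype=float)
            if self.valid_fraction.shape != (self.layout.n_segments,):
                raise ValueError("valid_fraction length must equal number of segments")

    def finite_values(self) -> np.ndarray:
        out = np.array(self.values, dtype=float)
        out[self.masked] = np.nan
        return out
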