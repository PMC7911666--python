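"""DNA-combing fiber analysis: stretch calibration, fork speed, origin spacing.

Cells are pulse-labelled with two thymidine analogues (IdU then CldU, 20 min
each by default); stretched DNA molecules carry ordered runs of first- and
second-label tracks. λ-phage DNA (48.5 kb) combed on the same surface
calibrates the stretch factor in kb per µm of measured length. An origin
fired during the first pulse leaves the bidirectional signature
second–first–second; the midpoint of the central first-label track marks the
origin, and a second-label track laid down by a single fork measures fork
progression over the second pulse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LAMBDA_GENOME_KB",
    "FiberTrack",
    "FiberMolecule",
    "calibrate_stretch",
    "fork_speed",
    "find_origins",
    "interorigin_distances",
    "analyze_fibers",
    "compare_conditions",
]

LAMBDA_GENOME_KB = 48.5  # λ phage genome length


@dataclass
class FiberTrack:
    label: str  # 'first' or 'second'
    length_um: float
    start_um: float = np.nan  # position along the molecule; NaN if unknown

    def __post_init__(self):
        if self.label not in ("first", "second"):
            raise ValueError("label must be 'first' or 'second'")
        if self.length_um <= 0:
            raise ValueError("track length must be positive")

    @property
    def end_um(self) -> float:
        return self.start_um + self.length_um

    @property
    def mid_um(self) -> float:
        return self.start_um + self.length_um / 2.0


@dataclass
class FiberMolecule:
    """One combed DNA molecule with its ordered labelled tracks."""

    molecule_id: str
    tracks: list[FiberTrack]
    total_length_um: float

    def __post_init__(self):
        if self.total_length_um <= 0:
            raise ValueError("molecule length must be positive")
        # tracks without positions are laid contiguously from 0
        pos = 0.0
        for t in self.tracks:
            if np.isnan(t.start_um):
                t.start_um = pos
            pos = t.end_um
        self.tracks = sorted(self.tracks, key=lambda t: t.start_um)
        if sum(t.length_um for t in self.tracks) > self.total_length_um * (1 + 1e-6):
            raise ValueError("track lengths exceed molecule length")


def calibrate_stretch(lambda_lengths_um: Iterable[float]) -> tuple[float, float]:
    """Stretch factor (kb/µm) and its s.d. from combed λ-DNA lengths.

    factor = 48.5 / mean(lengths); the s.d. is propagated from the length
    s.d. by the delta method: sd(f) = 48.5 · sd(len) / mean(len)².
    """
    lengths = np.asarray(list(lambda_lengths_um), dtype=float)
    if lengths.size == 0 or np.any(lengths <= 0):
        raise ValueError("lambda lengths must be a non-empty set of positive values")
    mean = lengths.mean()
    sd = lengths.std(ddof=1) if lengths.size > 1 else 0.0
    factor = LAMBDA_GENOME_KB / mean
    return factor, LAMBDA_GENOME_KB * sd / mean**2


def fork_speed(track_length_um, factor_kb_per_um: float, label_minutes: float = 20.0):
    """Fork progression rate (kb/min) from a single-fork track length."""
    lengths = np.asarray(track_length_um, dtype=float)
    if factor_kb_per_um <= 0 or label_minutes <= 0 or np.any(lengths <= 0):
        raise ValueError("track length, stretch factor and label time must be positive")
    speed = lengths * factor_kb_per_um / label_minutes
    return float(speed) if np.isscalar(track_length_um) else speed


def _touches_end(track: FiberTrack, total_um: float, end_tol_um: float) -> bool:
    return track.start_um <= end_tol_um or track.end_um >= total_um - end_tol_um


def _contiguous(a: FiberTrack, b: FiberTrack, gap_tol_um: float) -> bool:
    return abs(b.start_um - a.end_um) <= gap_tol_um


def find_origins(
    molecule: FiberMolecule,
    gap_tol_um: float = 1.0,
    end_tol_um: float = 0.5,
) -> list[float]:
    """Origin positions (µm) from second–first–second bidirectional signatures.

    A first-label track counts as an origin when a second-label track abuts it
    on both sides (within ``gap_tol_um``); signatures whose tracks touch a
    molecule end (within ``end_tol_um``) are discarded as censored.
    """
    tr = molecule.tracks
    origins = []
    for i in range(1, len(tr) - 1):
        left, mid, right = tr[i - 1], tr[i], tr[i + 1]
        if mid.label != "first" or left.label != "second" or right.label != "second":
            continue
        if not (_contiguous(left, mid, gap_tol_um) and _contiguous(mid, right, gap_tol_um)):
            continue
        if any(_touches_end(t, molecule.total_length_um, end_tol_um) for t in (left, mid, right)):
            continue
        origins.append(mid.mid_um)
    return origins


def interorigin_distances(
    origins_per_molecule: Sequence[Sequence[float]],
    factor_kb_per_um: float,
) -> tuple[np.ndarray, dict]:
    """Adjacent origin centre-to-centre distances in kb, pooled over molecules."""
    if factor_kb_per_um <= 0:
        raise ValueError("stretch factor must be positive")
    dists = []
    for origins in origins_per_molecule:
        o = np.sort(np.asarray(origins, dtype=float))
        if o.size >= 2:
            dists.append(np.diff(o) * factor_kb_per_um)
    pooled = np.concatenate(dists) if dists else np.empty(0)
    summary = {
        "n": int(pooled.size),
        "mean_kb": float(pooled.mean()) if pooled.size else np.nan,
        "median_kb": float(np.median(pooled)) if pooled.size else np.nan,
        "sd_kb": float(pooled.std(ddof=1)) if pooled.size > 1 else np.nan,
    }
    return pooled, summary


def _speed_tracks(molecule: FiberMolecule, gap_tol_um: float, end_tol_um: float) -> list[float]:
    """Second-label tracks measuring exactly one fork over the full pulse.

    Eligible tracks abut a first-label track on exactly one side (a track
    bridging two first-label tracks contains two converged forks) and do not
    touch a molecule end (censored length).
    """
    tr = molecule.tracks
    out = []
    for i, t in enumerate(tr):
        if t.label != "second" or _touches_end(t, molecule.total_length_um, end_tol_um):
            continue
        left_first = i > 0 and tr[i - 1].label == "first" and _contiguous(tr[i - 1], t, gap_tol_um)
        right_first = (
            i + 1 < len(tr) and tr[i + 1].label == "first" and _contiguous(t, tr[i + 1], gap_tol_um)
        )
        if left_first != right_first:  # exactly one first-label neighbour
            out.append(t.length_um)
    return out


def analyze_fibers(
    molecules: Sequence[FiberMolecule],
    lambda_lengths_um: Iterable[float],
    label_minutes: float = 20.0,
    gap_tol_um: float = 1.0,
    end_tol_um: float = 0.5,
) -> dict:
    """Full fiber workup: calibration, fork speeds, inter-origin distances."""
    factor, factor_sd = calibrate_stretch(lambda_lengths_um)
    speed_lengths = []
    origins = []
    for mol in molecules:
        speed_lengths.extend(_speed_tracks(mol, gap_tol_um, end_tol_um))
        origins.append(find_origins(mol, gap_tol_um, end_tol_um))
    speeds = (
        fork_speed(np.array(speed_lengths), factor, label_minutes)
        if speed_lengths
        else np.empty(0)
    )
    dists, dist_summary = interorigin_distances(origins, factor)
    return {
        "stretch_kb_per_um": factor,
        "stretch_sd": factor_sd,
        "fork_speeds_kb_min": speeds,
        "fork_speed_mean": float(speeds.mean()) if speeds.size else np.nan,
        "fork_speed_sd": float(speeds.std(ddof=1)) if speeds.size > 1 else np.nan,
        "interorigin_kb": dists,
        "interorigin_summary": dist_summary,
        "n_molecules": len(molecules),
    }


def compare_conditions(values_a, values_b) -> dict:
    """Rank-sum (Mann–Whitney U) comparison of two fiber measurement sets."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both conditions need measurements")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "u_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }
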