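"""Synthetic Repli-seq, omics and combed-fiber data with known ground truth.

The generator emulates the structure of a two-condition replication-timing
study: a domain-organized timing landscape (Mb-sized early and late
replication domains), whole 200-kb segments switched between conditions,
early/late read-count libraries with biological replicate noise, ChIP
enrichment and expression changes coupled to the timing changes at a chosen
correlation, and dual-labelled combed DNA fibers with λ-DNA calibration
molecules.

Count model: a bin's latent timing value ``rt`` (log2 early/late scale) maps
to the probability that a read from that bin is an early-fraction read via
the logit-base-2 link ``p = 1 / (1 + 2**(-rt))``, i.e. ``rt =
log2(p / (1 - p))``; early and late libraries then draw Poisson counts
proportional to ``p`` and ``1 - p``. At high depth the library-normalized
log2(early/late) per bin converges to ``rt``, which makes parameter recovery
directly checkable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fibers import LAMBDA_GENOME_KB, FiberMolecule, FiberTrack
from .genome import CountTrack, GenomeLayout

__all__ = [
    "RTTruth",
    "SwitchTruth",
    "simulate_rt_landscape",
    "plant_switches",
    "simulate_counts",
    "simulate_omics",
    "simulate_fibers",
    "recover_switch_truth",
]


@dataclass
class RTTruth:
    """True per-bin timing landscape: piecewise constant over domains."""

    layout: GenomeLayout
    rt: np.ndarray
    domain_bounds: np.ndarray  # global bin indices where a new domain starts

    def segment_means(self) -> np.ndarray:
        seg_of = self.layout.bin_to_segment()
        n = self.layout.n_segments
        return np.bincount(seg_of, weights=self.rt, minlength=n) / np.bincount(
            seg_of, minlength=n
        )


@dataclass
class SwitchTruth:
    """Bookkeeping of planted switches: which segments, direction, size."""

    segment_ids: np.ndarray
    directions: np.ndarray  # 'EtoL' or 'LtoE' per planted segment
    deltas: np.ndarray  # signed rt_B − rt_A applied inside each segment


def _default_levels(rng: np.random.Generator, n: int) -> np.ndarray:
    """Two-component mixture of early (+1.5) and late (−1.5) domain levels."""
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * 1.5 + rng.normal(0.0, 0.5, size=n)


def simulate_rt_landscape(
    layout: GenomeLayout,
    mean_domain_kb: float = 1_000.0,
    rt_levels=None,
    seed: int | np.random.Generator = 0,
) -> RTTruth:
    """Draw a domain-structured timing landscape.

    Domain boundaries follow a Poisson process with mean inter-boundary
    distance ``mean_domain_kb`` along each chromosome; each domain's timing
    level is drawn from ``rt_levels(rng, n)`` (default: equal mixture of
    Normal(+1.5, 0.5) and Normal(−1.5, 0.5), the early/late dichotomy).
    """
    if mean_domain_kb * 1000.0 < 2 * layout.segment_size:
        raise ValueError("mean_domain_kb must be at least two segments wide")
    rng = np.random.default_rng(seed)
    levels_fn = rt_levels if rt_levels is not None else _default_levels
    rt = np.empty(layout.n_bins)
    bounds = [0]
    offs = layout.bin_offsets
    mean_bp = mean_domain_kb * 1000.0
    for ci, (_, length) in enumerate(layout.chroms):
        cuts = [0.0]
        while cuts[-1] < length:
            cuts.append(cuts[-1] + rng.exponential(mean_bp))
        cuts = np.array(cuts[:-1] + [length])
        n_domains = len(cuts) - 1
        levels = np.asarray(levels_fn(rng, n_domains), dtype=float)
        starts = (cuts[:-1] // layout.bin_size).astype(int)
        n_bins_c = offs[ci + 1] - offs[ci]
        dom_of_bin = np.searchsorted(starts, np.arange(n_bins_c), side="right") - 1
        rt[offs[ci]:offs[ci + 1]] = levels[dom_of_bin]
        bounds.extend((offs[ci] + s) for s in starts if s > 0)
        if ci + 1 < len(layout.chroms):
            bounds.append(int(offs[ci + 1]))
    return RTTruth(layout, rt, np.unique(np.array(bounds, dtype=int)))


def plant_switches(
    truth: RTTruth,
    n_switch: int,
    delta_magnitude: float = 1.5,
    seed: int | np.random.Generator = 0,
    min_abs_rt: float = 0.5,
) -> tuple[RTTruth, SwitchTruth]:
    """Shift whole 200-kb segments to create the condition-B landscape.

    Early segments are eligible for EtoL (shift by −delta_magnitude), late
    segments for LtoE (+delta_magnitude); ``n_switch`` segments are drawn
    uniformly from the eligible pool and their direction follows their
    starting state. All other bins are untouched. Eligibility requires
    |segment mean rt| >= ``min_abs_rt``: a segment sitting at the early/late
    boundary has no well-defined switch direction, so the planted ground
    truth is restricted to unambiguously early or late segments.
    """
    rng = np.random.default_rng(seed)
    seg_means = truth.segment_means()
    eligible = np.flatnonzero(np.abs(seg_means) >= min_abs_rt)
    if n_switch > eligible.size:
        raise ValueError(f"n_switch={n_switch} exceeds {eligible.size} eligible segments")
    chosen = np.sort(rng.choice(eligible, size=n_switch, replace=False))
    directions = np.where(seg_means[chosen] > 0, "EtoL", "LtoE")
    deltas = np.where(directions == "EtoL", -delta_magnitude, delta_magnitude)
    rt_b = truth.rt.copy()
    seg_of = truth.layout.bin_to_segment()
    for seg, dlt in zip(chosen, deltas):
        rt_b[seg_of == seg] += dlt
    truth_b = RTTruth(truth.layout, rt_b, truth.domain_bounds.copy())
    return truth_b, SwitchTruth(chosen, directions, deltas)


def recover_switch_truth(truth_a: RTTruth, truth_b: RTTruth, atol: float = 1e-9) -> SwitchTruth:
    """Recover the planted edits by diffing two truth landscapes."""
    seg_of = truth_a.layout.bin_to_segment()
    diff = truth_b.rt - truth_a.rt
    n = truth_a.layout.n_segments
    seg_delta = np.bincount(seg_of, weights=diff, minlength=n) / np.bincount(seg_of, minlength=n)
    ids = np.flatnonzero(np.abs(seg_delta) > atol)
    return SwitchTruth(ids, np.where(seg_delta[ids] < 0, "EtoL", "LtoE"), seg_delta[ids])


def simulate_counts(
    truth: RTTruth,
    depth_per_bin: float = 20.0,
    replicate_noise_sd: float = 0.3,
    n_replicates: int = 2,
    seed: int | np.random.Generator = 0,
    sample_prefix: str = "rep",
) -> list[tuple[CountTrack, CountTrack]]:
    """Early/late Poisson count libraries per replicate.

    Each replicate perturbs the latent per-bin timing with iid
    Normal(0, replicate_noise_sd) noise (biological replicate variation),
    converts it to an early-read weight through the logit link, and draws
    Poisson counts at a library size of ``depth_per_bin`` reads per bin per
    fraction, jittered uniformly within ±20% per library.
    """
    if depth_per_bin <= 0:
        raise ValueError("depth_per_bin must be positive")
    rng = np.random.default_rng(seed)
    layout = truth.layout
    n = layout.n_bins
    out = []
    for r in range(n_replicates):
        rt_rep = truth.rt + (
            rng.normal(0.0, replicate_noise_sd, size=n) if replicate_noise_sd > 0 else 0.0
        )
        p = 1.0 / (1.0 + np.exp2(-rt_rep))
        d_early = depth_per_bin * n * rng.uniform(0.8, 1.2)
        d_late = depth_per_bin * n * rng.uniform(0.8, 1.2)
        lam_early = d_early * p / p.sum()
        lam_late = d_late * (1.0 - p) / (1.0 - p).sum()
        sid = f"{sample_prefix}{r + 1}"
        early = CountTrack(layout, rng.poisson(lam_early), sample_id=sid, fraction="early")
        late = CountTrack(layout, rng.poisson(lam_late), sample_id=sid, fraction="late")
        out.append((early, late))
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_omics(
    rt_delta: np.ndarray,
    layout: GenomeLayout,
    coupling_r: float = 0.0,
    n_genes: int = 2_000,
    fc_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-segment ChIP deltas and a gene table coupled to the RT deltas.

    The ChIP delta at segment i is ``r·z_i + sqrt(1−r²)·ε`` with ``z`` the
    standardized RT delta and ε standard normal, so its population Pearson
    correlation with the RT delta is exactly ``coupling_r``. Genes get uniform
    TSS positions; their log2 fold change uses the same construction scaled
    by ``fc_sd``, taking ``z`` from the gene's segment.
    """
    if not -1.0 <= coupling_r <= 1.0:
        raise ValueError("coupling_r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    rt_delta = np.asarray(rt_delta, dtype=float)
    nseg = layout.n_segments
    if rt_delta.shape != (nseg,):
        raise ValueError("rt_delta must have one value per segment")
    z = _standardize(np.nan_to_num(rt_delta))
    resid = np.sqrt(max(0.0, 1.0 - coupling_r**2))
    chip_delta = coupling_r * z + resid * rng.normal(size=nseg)
    chrom_names = np.asarray(layout.names)[layout.segment_chrom_indices()]
    chip = pd.DataFrame(
        {
            "chrom": chrom_names,
            "start": layout.segment_starts(),
            "end": layout.segment_ends(),
            "chip_delta": chip_delta,
        }
    )
    # genes: uniform positions along the concatenated genome
    total = sum(layout.lengths)
    gpos = np.sort(rng.uniform(0, total, size=n_genes))
    cum = np.concatenate([[0], np.cumsum(layout.lengths)])
    gchrom_idx = np.searchsorted(cum, gpos, side="right") - 1
    tss = (gpos - cum[gchrom_idx]).astype(np.int64)
    seg_idx = layout.segment_offsets[gchrom_idx] + tss // layout.segment_size
    lfc = fc_sd * (coupling_r * z[seg_idx] + resid * rng.normal(size=n_genes))
    base = rng.normal(5.0, 2.0, size=n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": np.asarray(layout.names)[gchrom_idx],
            "tss": tss,
            "expr_ctrl": 2.0**base,
            "expr_mut": 2.0 ** (base + lfc),
            "log2_fc": lfc,
        }
    )
    return chip, genes


def simulate_fibers(
    fork_speed_kb_min: float = 1.2,
    ori_spacing_kb: float = 120.0,
    label_minutes: tuple[float, float] = (20.0, 20.0),
    stretch_kb_per_um: float = 2.32,
    n_molecules: int = 200,
    molecule_len_kb: float = 800.0,
    lambda_n: int = 100,
    lambda_len_sd_um: float = 1.0,
    jitter_um: float = 0.15,
    spacing_cv: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> tuple[list[FiberMolecule], np.ndarray]:
    """Dual-labelled combed fibers plus λ-DNA calibration molecules.

    Every origin fires at the start of the first label pulse: it lays down a
    central first-label track of ``2·v·t1`` kb (two diverging forks) flanked
    by one second-label track of ``v·t2`` kb on each side. Converging forks
    from adjacent origins stop at their midpoint, merging tracks when origins
    sit closer than the label distances. Inter-origin spacings are drawn from
    a Gamma distribution with mean ``ori_spacing_kb`` and coefficient of
    variation ``spacing_cv`` (origin interference makes real spacings far
    more regular than a memoryless process). Track lengths are reported in µm
    at ``stretch_kb_per_um`` with Normal(0, jitter_um) measurement noise; λ
    molecules are Normal(48.5/stretch, lambda_len_sd_um).
    """
    for val, name in [
        (fork_speed_kb_min, "fork_speed_kb_min"),
        (ori_spacing_kb, "ori_spacing_kb"),
        (stretch_kb_per_um, "stretch_kb_per_um"),
        (molecule_len_kb, "molecule_len_kb"),
    ]:
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    t1, t2 = label_minutes
    v = fork_speed_kb_min
    shape = 1.0 / spacing_cv**2
    scale = ori_spacing_kb / shape
    molecules: list[FiberMolecule] = []
    for mi in range(n_molecules):
        # origins over a margin-extended region so edge forks can enter the molecule
        margin = 2 * v * (t1 + t2) + 3 * ori_spacing_kb
        pos = -margin + rng.gamma(shape, scale)
        origins = []
        while pos < molecule_len_kb + margin:
            origins.append(pos)
            pos += rng.gamma(shape, scale)
        intervals = []  # (start_kb, end_kb, label)
        for k, o in enumerate(origins):
            left_stop = -np.inf if k == 0 else (origins[k - 1] + o) / 2.0
            right_stop = np.inf if k == len(origins) - 1 else (o + origins[k + 1]) / 2.0
            l1 = max(o - v * t1, left_stop)
            r1 = min(o + v * t1, right_stop)
            l2 = max(o - v * (t1 + t2), left_stop)
            r2 = min(o + v * (t1 + t2), right_stop)
            if l2 < l1:
                intervals.append((l2, l1, "second"))
            if l1 < r1:
                intervals.append((l1, r1, "first"))
            if r1 < r2:
                intervals.append((r1, r2, "second"))
        intervals.sort()
        merged = []
        for s, e, lab in intervals:
            if merged and lab == merged[-1][2] and s <= merged[-1][1] + 1e-9:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e, lab])
        tracks = []
        for s, e, lab in merged:
            s_c, e_c = max(s, 0.0), min(e, molecule_len_kb)
            if e_c - s_c <= 1e-9:
                continue
            start_um = s_c / stretch_kb_per_um + (rng.normal(0, jitter_um) if jitter_um else 0.0)
            length_um = (e_c - s_c) / stretch_kb_per_um + (
                rng.normal(0, jitter_um) if jitter_um else 0.0
            )
            tracks.append(FiberTrack(lab, max(length_um, 0.01), max(start_um, 0.0)))
        total_um = molecule_len_kb / stretch_kb_per_um
        overshoot = sum(t.length_um for t in tracks)
        if overshoot > total_um:  # jitter on a fully-labelled molecule
            for t in tracks:
                t.length_um *= total_um / overshoot
        molecules.append(FiberMolecule(f"mol{mi:04d}", tracks, total_um))
    lam = rng.normal(LAMBDA_GENOME_KB / stretch_kb_per_um, lambda_len_sd_um, size=lambda_n)
    return molecules, lam
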