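"""Self-contained evaluation runs at the study's simulation conditions.

Each function simulates data with the generator defaults that mirror the
study design — fixed 200-kb segments over a multi-chromosome genome, two
conditions with two replicates each, 20 reads/bin/fraction, replicate noise
sd 0.3, 5% of segments switched by |Δ| = 1.5 — runs the full pipeline on it,
and scores the result against the planted ground truth. These are the
quantities the package's claims rest on (FDR control, null calibration,
power, parameter recovery), computed from scratch on every call.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import differential, fibers, integrate, profile, simulate
from .genome import GenomeLayout

__all__ = [
    "study_layout",
    "switching_run",
    "null_calibration_run",
    "profile_recovery_run",
    "omics_recovery_run",
    "fiber_recovery_run",
]


def study_layout(n_chroms: int = 20, chrom_mb: int = 100) -> GenomeLayout:
    """Mouse-scale toy genome: 20 x 100 Mb = 2 Gb -> 10,000 200-kb segments."""
    return GenomeLayout([(f"chr{i + 1}", chrom_mb * 1_000_000) for i in range(n_chroms)])


def _replicate_segments(truth, depth, noise_sd, n_replicates, rng):
    return [
        profile.average_into_segments(profile.profile_pipeline(e, l, smooth=False))
        for e, l in simulate.simulate_counts(truth, depth, noise_sd, n_replicates, seed=rng)
    ]


def switching_run(
    seed: int,
    layout: GenomeLayout | None = None,
    planted_fraction: float = 0.05,
    delta_magnitude: float = 1.5,
    depth_per_bin: float = 20.0,
    replicate_noise_sd: float = 0.3,
    n_replicates: int = 2,
) -> dict:
    """One full switching analysis against planted truth.

    Returns false-discovery proportion and power at q <= 0.01 and 0.05, and
    the fraction of true-positive calls whose class matches the planted
    direction.
    """
    layout = layout or study_layout()
    rng = np.random.default_rng(seed)
    truth_a = simulate.simulate_rt_landscape(layout, seed=rng)
    n_switch = int(round(planted_fraction * layout.n_segments))
    truth_b, sw = simulate.plant_switches(truth_a, n_switch, delta_magnitude, seed=rng)
    ctrl = _replicate_segments(truth_a, depth_per_bin, replicate_noise_sd, n_replicates, rng)
    mut = _replicate_segments(truth_b, depth_per_bin, replicate_noise_sd, n_replicates, rng)
    calls = differential.switch_analysis(ctrl, mut)
    truth_dir = dict(zip(sw.segment_ids.tolist(), sw.directions.tolist()))
    q = calls["q"].to_numpy()
    out = {"seed": seed, "n_segments": layout.n_segments, "n_planted": n_switch}
    for cutoff, tag in ((0.01, "q01"), (0.05, "q05")):
        called = np.flatnonzero(np.nan_to_num(q, nan=1.0) <= cutoff)
        tp = [i for i in called if i in truth_dir]
        fp = len(called) - len(tp)
        out[f"n_called_{tag}"] = len(called)
        out[f"fdp_{tag}"] = fp / len(called) if len(called) else 0.0
        out[f"power_{tag}"] = len(tp) / n_switch
        out[f"direction_match_{tag}"] = (
            float(np.mean([calls["class"][i] == truth_dir[i] for i in tp])) if tp else 1.0
        )
    return out


def null_calibration_run(
    seed: int,
    layout: GenomeLayout | None = None,
    depth_per_bin: float = 20.0,
    replicate_noise_sd: float = 0.3,
) -> dict:
    """No planted switches: p-value uniformity (KS) and calls at q <= 0.01."""
    layout = layout or study_layout()
    rng = np.random.default_rng(seed)
    truth = simulate.simulate_rt_landscape(layout, seed=rng)
    ctrl = _replicate_segments(truth, depth_per_bin, replicate_noise_sd, 2, rng)
    mut = _replicate_segments(truth, depth_per_bin, replicate_noise_sd, 2, rng)
    d, pool, masked = differential.segment_distances(ctrl, mut)
    p = differential.empirical_pvalues(d, pool)
    q = differential.storey_qvalues(p)
    pv = p[~np.isnan(p)]
    ks = stats.kstest(pv, "uniform")
    return {
        "seed": seed,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_called_q01": int(np.nansum(q <= 0.01)),
        "n_segments": int(pv.size),
    }


def profile_recovery_run(
    seed: int,
    layout: GenomeLayout | None = None,
    depth_per_bin: float = 10.0,
    replicate_noise_sd: float = 0.3,
) -> dict:
    """Pearson r between the LOESS profile and the simulated truth."""
    layout = layout or study_layout(n_chroms=4, chrom_mb=50)
    rng = np.random.default_rng(seed)
    truth = simulate.simulate_rt_landscape(layout, seed=rng)
    ((early, late),) = simulate.simulate_counts(
        truth, depth_per_bin, replicate_noise_sd, 1, seed=rng
    )
    prof = profile.profile_pipeline(early, late)
    ok = ~prof.masked
    r = float(np.corrcoef(prof.values[ok], truth.rt[ok])[0, 1])
    return {"seed": seed, "pearson_r": r, "n_bins": int(ok.sum())}


def omics_recovery_run(seed: int, coupling_r: float, layout: GenomeLayout | None = None) -> dict:
    """Recover a planted ChIP-vs-RT coupling from simulated segment deltas."""
    layout = layout or study_layout()
    rng = np.random.default_rng(seed)
    rt_delta = rng.normal(0, 0.5, size=layout.n_segments)
    chip, _ = simulate.simulate_omics(rt_delta, layout, coupling_r=coupling_r, seed=rng)
    r, n = integrate.correlate_deltas(rt_delta, chip["chip_delta"].to_numpy())
    se = (1.0 - coupling_r**2) / np.sqrt(n)
    return {"seed": seed, "planted_r": coupling_r, "recovered_r": r, "n": n, "se": se}


def fiber_recovery_run(
    seed: int,
    fork_speed_kb_min: float = 1.2,
    ori_spacing_kb: float = 120.0,
    n_molecules: int = 150,
    lambda_n: int = 100,
) -> dict:
    """Recover stretch factor, fork speed and origin spacing from fibers."""
    mols, lam = simulate.simulate_fibers(
        fork_speed_kb_min=fork_speed_kb_min,
        ori_spacing_kb=ori_spacing_kb,
        n_molecules=n_molecules,
        lambda_n=lambda_n,
        seed=seed,
    )
    res = fibers.analyze_fibers(mols, lam, label_minutes=20.0)
    speeds = res["fork_speeds_kb_min"]
    dists = res["interorigin_kb"]
    return {
        "seed": seed,
        "stretch_kb_per_um": res["stretch_kb_per_um"],
        "fork_speed_mean": res["fork_speed_mean"],
        "fork_speed_se": float(speeds.std(ddof=1) / np.sqrt(speeds.size)),
        "n_speed_tracks": int(speeds.size),
        "interorigin_mean_kb": res["interorigin_summary"]["mean_kb"],
        "interorigin_se": float(dists.std(ddof=1) / np.sqrt(dists.size)),
        "n_distances": int(dists.size),
        "true_fork_speed": fork_speed_kb_min,
        "true_spacing": ori_spacing_kb,
    }
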