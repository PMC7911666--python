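import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from replikit import (
    GenomeLayout,
    call_switches,
    empirical_pvalues,
    merge_to_domains,
    overlap_test,
    segment_distances,
    storey_qvalues,
    switch_analysis,
)
from replikit.genome import SegmentTrack


LAY3 = GenomeLayout([("chr1", 600_000)])


def seg(layout, values):
    return SegmentTrack(layout, values)


class TestSegmentDistances:
    def test_between_is_absolute_difference_of_group_means(self):
        a = [seg(LAY3, [0.5, 0, 0]), seg(LAY3, [0.7, 0, 0])]
        b = [seg(LAY3, [-0.2, 0, 0]), seg(LAY3, [-0.4, 0, 0])]
        d, pool, masked = segment_distances(a, b, calibrate=False)
        assert d[0] == pytest.approx(0.9)

    def test_identical_groups_give_zero_distance(self):
        a = [seg(LAY3, [0.5, 1.0, -1.0]), seg(LAY3, [0.7, 1.2, -0.8])]
        d, _, _ = segment_distances(a, a)
        np.testing.assert_allclose(d, 0.0)

    def test_within_pair_contribution(self):
        a = [seg(LAY3, [0.5, 0, 0]), seg(LAY3, [0.7, 0, 0])]
        b = [seg(LAY3, [0.0, 0, 0])]
        _, pool, _ = segment_distances(a, b, calibrate=False)
        assert pytest.approx(0.2) in pool.tolist()

    def test_calibration_matches_group_mean_variance(self):
        # two reps per group: scale sqrt((1/2+1/2)/2) = 1/sqrt(2)
        a = [seg(LAY3, [0.5, 0, 0]), seg(LAY3, [0.7, 0, 0])]
        b = [seg(LAY3, [0.1, 0, 0]), seg(LAY3, [0.1, 0, 0])]
        _, pool, _ = segment_distances(a, b, calibrate=True)
        assert pytest.approx(0.2 / np.sqrt(2)) in pool.tolist()

    def test_no_within_pair_is_an_error(self):
        with pytest.raises(ValueError, match="null undefined"):
            segment_distances([seg(LAY3, [0.5, 0, 0])], [seg(LAY3, [0.1, 0, 0])])

    def test_masked_segments_excluded_from_both(self):
        m = np.array([False, True, False])
        a = [
            SegmentTrack(LAY3, [0.5, np.nan, 0.1], m),
            SegmentTrack(LAY3, [0.7, np.nan, 0.3], m),
        ]
        b = [seg(LAY3, [0.0, 1.0, 0.2]), seg(LAY3, [0.2, 1.0, 0.2])]
        d, pool, masked = segment_distances(a, b)
        assert np.isnan(d[1]) and masked[1]
        assert pool.size == 2 * 2  # 2 unmasked segments x one pair per group


class TestEmpiricalPvalues:
    def test_add_one_formula_extreme(self):
        null = np.linspace(0.001, 0.999, 999)
        p = empirical_pvalues(np.array([2.0]), null)
        assert p[0] == pytest.approx(1 / 1000)

    def test_zero_statistic_gives_p_one(self):
        null = np.array([0.1, 0.2, 0.3])
        assert empirical_pvalues(np.array([0.0]), null)[0] == 1.0

    def test_ties_counted_as_at_least(self):
        null = np.array([0.5, 0.5, 1.0])
        # #{null >= 0.5} = 3 -> p = 4/4
        assert empirical_pvalues(np.array([0.5]), null)[0] == 1.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty null pool"):
            empirical_pvalues(np.array([1.0]), np.array([]))


class TestStoreyQvalues:
    def test_all_ones_stay_one(self):
        q = storey_qvalues(np.ones(5))
        np.testing.assert_allclose(q, 1.0)

    def test_hand_computed_step_up(self):
        # pi0 = 1: q_(i) = min over j>=i of m*p_(j)/j -> all 0.04
        q = storey_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0_method="bh")
        np.testing.assert_allclose(q, 0.04)

    def test_matches_benjamini_hochberg_oracle(self, rng):
        p = rng.uniform(size=500)
        q = storey_qvalues(p, pi0_method="bh")
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_pi0_estimate_shrinks_q(self, rng):
        # half the p-values tiny -> pi0 ~ 0.5 under fixed lambda
        p = np.concatenate([rng.uniform(0, 1e-4, 500), rng.uniform(size=500)])
        q_fixed = storey_qvalues(p, pi0_method="fixed_lambda")
        q_bh = storey_qvalues(p, pi0_method="bh")
        assert (q_fixed <= q_bh + 1e-12).all()
        assert q_fixed[0] < q_bh[0]

    def test_order_invariance(self, rng):
        p = rng.uniform(size=200)
        perm = rng.permutation(200)
        q = storey_qvalues(p)
        np.testing.assert_allclose(storey_qvalues(p[perm]), q[perm], atol=1e-14)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.5, 1.5]))

    def test_nan_passthrough(self):
        q = storey_qvalues(np.array([0.5, np.nan, 0.7]))
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestCallSwitches:
    def call_one(self, ctrl, mut, q):
        lay = GenomeLayout([("chr1", 200_000)])
        calls = call_switches(
            lay,
            np.array([ctrl]),
            np.array([mut]),
            d=np.array([abs(mut - ctrl)]),
            p=np.array([q]),
            q=np.array([q]),
            masked=np.array([False]),
            q_cutoff=0.01,
        )
        return calls.iloc[0]

    @pytest.mark.parametrize(
        "ctrl,mut,q,expected",
        [
            (0.5, -0.4, 0.005, "EtoL"),
            (0.5, -0.4, 0.2, "EtoE"),  # not significant: endpoint sign of control
            (-0.6, 0.3, 0.004, "LtoE"),
            (0.5, 0.9, 0.2, "EtoE"),
            (-0.5, -0.9, 0.2, "LtoL"),
            (0.5, 1.5, 0.005, "EtoE"),  # significant early -> earlier keeps endpoint class
            (-0.5, -1.5, 0.005, "LtoL"),
        ],
    )
    def test_classification_rules(self, ctrl, mut, q, expected):
        row = self.call_one(ctrl, mut, q)
        assert row["class"] == expected
        assert row["significant"] == (q <= 0.01)

    def test_masked_segment_class(self):
        lay = GenomeLayout([("chr1", 200_000)])
        calls = call_switches(
            lay, np.array([np.nan]), np.array([np.nan]), np.array([np.nan]),
            np.array([np.nan]), np.array([np.nan]), np.array([True]),
        )
        assert calls.iloc[0]["class"] == "masked"

    def test_switch_sign_invariant(self, rng):
        lay = GenomeLayout([("chr1", 10_000_000)])
        n = lay.n_segments
        ctrl = rng.normal(0, 1, n)
        mut = ctrl + rng.normal(0, 1, n)
        q = rng.uniform(1e-4, 1, n)
        calls = call_switches(lay, ctrl, mut, np.abs(mut - ctrl), q, q, np.zeros(n, bool))
        etol = calls[calls["class"] == "EtoL"]
        ltoe = calls[calls["class"] == "LtoE"]
        assert (etol["delta"] < 0).all() and (etol["ctrl_mean"] > 0).all()
        assert (ltoe["delta"] > 0).all() and (ltoe["ctrl_mean"] < 0).all()


class TestMergeToDomains:
    def make_calls(self, classes, sig, qs, chrom="chr1"):
        n = len(classes)
        return pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "start": np.arange(n) * 200_000,
                "end": (np.arange(n) + 1) * 200_000,
                "ctrl_mean": 0.5, "mut_mean": -0.5, "delta": -1.0, "d": 1.0,
                "p": qs, "q": qs, "class": classes, "significant": sig,
            }
        )

    def test_adjacent_same_class_merged(self):
        calls = self.make_calls(["EtoL"] * 3, [True] * 3, [0.005, 0.001, 0.009])
        dom = merge_to_domains(calls)
        assert len(dom) == 1
        row = dom.iloc[0]
        assert row["end"] - row["start"] == 600_000
        assert row["q"] == 0.001
        assert row["score"] == 999
        assert row["n_segments"] == 3

    def test_gap_breaks_domain(self):
        calls = self.make_calls(["EtoL", "EtoE", "EtoL"], [True, False, True], [0.005] * 3)
        dom = merge_to_domains(calls, classes=["EtoL"])
        assert len(dom) == 2

    def test_empty_input(self):
        assert merge_to_domains(pd.DataFrame(columns=["chrom", "start", "end", "class", "q", "significant"])).empty

    def test_chromosome_boundary_never_merged(self):
        a = self.make_calls(["EtoL"], [True], [0.005], chrom="chr1")
        b = self.make_calls(["EtoL"], [True], [0.005], chrom="chr2")
        dom = merge_to_domains(pd.concat([a, b], ignore_index=True))
        assert len(dom) == 2


def hypergeom_tail_oracle(k, universe, na, nb):
    """P(overlap >= k) by exact enumeration of the hypergeometric pmf."""
    total = 0.0
    for i in range(k, min(na, nb) + 1):
        total += (
            math.comb(na, i) * math.comb(universe - na, nb - i) / math.comb(universe, nb)
        )
    return total


class TestOverlapTest:
    def test_matches_exact_enumeration(self):
        a = set(range(10))
        b = set(range(5, 15))
        k, expected, p = overlap_test(a, b, 100)
        assert k == 5
        assert expected == pytest.approx(1.0)
        assert p == pytest.approx(hypergeom_tail_oracle(5, 100, 10, 10), rel=1e-12)

    @pytest.mark.parametrize("universe,na,nb,k", [(30, 8, 12, 4), (20, 5, 5, 0), (25, 10, 3, 3)])
    def test_enumeration_grid(self, universe, na, nb, k):
        a = set(range(na))
        b = set(range(na - k, na - k + nb))
        kk, _, p = overlap_test(a, b, universe)
        assert kk == k
        assert p == pytest.approx(hypergeom_tail_oracle(k, universe, na, nb), rel=1e-12)

    def test_certain_overlap_gives_p_one(self):
        a = set(range(100))
        b = set(range(40, 60))
        k, _, p = overlap_test(a, b, 100)
        assert k == 20 and p == pytest.approx(1.0)

    def test_no_overlap_small_sets_p_near_one(self):
        k, _, p = overlap_test({1, 2}, {500, 600}, 10_000)
        assert k == 0 and p > 0.99

    def test_set_exceeding_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_test(set(range(50)), {1}, 10)


def test_small_scale_planted_switch_detection(rng):
    """End-to-end smoke: strong planted switches are found with correct labels."""
    import replikit as rk

    layout = GenomeLayout([("chr1", 60_000_000)])
    truth_a = rk.simulate_rt_landscape(layout, seed=rng)
    truth_b, sw = rk.plant_switches(truth_a, 15, 1.5, seed=rng)

    def segs(truth):
        return [
            rk.average_into_segments(rk.profile_pipeline(e, l, smooth=False))
            for e, l in rk.simulate_counts(truth, 20, 0.3, 2, seed=rng)
        ]

    # at this small scale the empirical-p floor 1/(1+|pool|) keeps q above
    # 0.01; the lower-confidence cutoff is the appropriate one here
    calls = switch_analysis(segs(truth_a), segs(truth_b), q_cutoff=0.05)
    planted = dict(zip(sw.segment_ids.tolist(), sw.directions.tolist()))
    hits = [i for i in planted if calls["q"][i] <= 0.05]
    assert len(hits) >= 0.8 * len(planted)
    assert all(calls["class"][i] == planted[i] for i in hits)
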