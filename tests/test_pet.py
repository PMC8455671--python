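"""Lesion evaluability, scan QC, Consist/PERCIST classification, burden, kappa."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import REF, consist_oracle, make_meta, make_pair
from dynamark.pet import (
    Lesion,
    ReferenceUptake,
    Scan,
    ScanPair,
    check_lesion_evaluability,
    classify_consist,
    classify_percist,
    cohen_kappa,
    disease_burden,
    lesion_delta_pct,
    qc_scan_pair,
    select_percist_targets,
)


def lesion(suvmax, **kw):
    defaults = dict(lesion_id="L1", organ="liver")
    defaults.update(kw)
    return Lesion(suvmax=suvmax, **defaults)


class TestEvaluability:
    @pytest.mark.parametrize(
        "suvmax, expected",
        [(4.0, True), (3.9, True), (3.8999, False)],  # liver threshold 3.9, inclusive
    )
    def test_liver_branch_inclusive(self, suvmax, expected):
        assert check_lesion_evaluability(lesion(suvmax), REF) is expected

    @pytest.mark.parametrize(
        "suvmax, expected",
        [(3.8, False), (3.81, True)],  # blood-pool threshold 2*(1.5+0.4)=3.8, strict
    )
    def test_bloodpool_branch_strict(self, suvmax, expected):
        ref = ReferenceUptake(
            bloodpool_suvmean=1.5, bloodpool_suvsd=0.2, liver_abnormal=True
        )
        assert check_lesion_evaluability(lesion(suvmax), ref) is expected

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="liver reference"):
            check_lesion_evaluability(lesion(5.0), ReferenceUptake())
        with pytest.raises(ValueError, match="blood-pool"):
            check_lesion_evaluability(lesion(5.0), ReferenceUptake(liver_abnormal=True))


class TestScanPairQC:
    def test_compliant_pair_passes(self):
        assert qc_scan_pair(make_pair([-30.0])) == []

    @pytest.mark.parametrize(
        "activities, flagged", [((300.0, 370.0), False), ((300.0, 380.0), True)]
    )
    def test_activity_difference_rule(self, activities, flagged):
        pair = make_pair([-30.0])
        pair = ScanPair(
            "PX",
            Scan(make_meta(activity=activities[0]), REF, pair.baseline.lesions),
            Scan(make_meta("d14", activity=activities[1], days=14), REF, pair.followup.lesions),
        )
        codes = [f.code for f in qc_scan_pair(pair)]
        assert ("activity_diff_gt_25pct" in codes) is flagged

    def test_uptake_time_violations_flag_twice(self):
        pair = make_pair([-30.0])
        pair = ScanPair(
            "PX",
            Scan(make_meta(uptake=60.0), REF, pair.baseline.lesions),
            Scan(make_meta("d14", uptake=72.0, days=14), REF, pair.followup.lesions),
        )
        codes = [f.code for f in qc_scan_pair(pair)]
        assert codes.count("uptake_time_out_of_window") == 1
        assert "uptake_time_diff_gt_10min" in codes

    def test_scanner_scheduling_and_glucose_rules(self):
        pair = make_pair([-30.0])
        pair = ScanPair(
            "PX",
            Scan(make_meta(scanner="A", days=-8, glucose=205.0), REF, pair.baseline.lesions),
            Scan(make_meta("d14", scanner="B", days=14), REF, pair.followup.lesions),
        )
        codes = {f.code for f in qc_scan_pair(pair)}
        assert {"scanner_mismatch", "baseline_gt_7d_before_start", "glucose_ge_200"} <= codes


class TestLesionDelta:
    @pytest.mark.parametrize(
        "base, fu, expected", [(10, 6.9, -31.0), (10, 10, 0.0), (4, 5, 25.0)]
    )
    def test_signed_percent_change(self, base, fu, expected):
        assert lesion_delta_pct(base, fu) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            lesion_delta_pct(0.0, 5.0)


class TestConsist:
    def test_uniform_response_is_class1(self):
        res = classify_consist(make_pair([-30.0, -40.0]), cutoff_pct=25)
        assert res.consist_class == 1 and res.responder

    def test_majority_load_mixed_response_is_class2(self):
        res = classify_consist(make_pair([-30.0, -10.0], matvs=[80.0, 20.0]), cutoff_pct=25)
        assert res.consist_class == 2 and not res.responder

    def test_minority_load_is_class3_and_half_share_ties_down(self):
        res = classify_consist(make_pair([-30.0, -10.0], matvs=[20.0, 80.0]), cutoff_pct=25)
        assert res.consist_class == 3
        res = classify_consist(make_pair([-30.0, -10.0], matvs=[50.0, 50.0]), cutoff_pct=25)
        assert res.consist_class == 3  # share exactly 0.5 is not a majority

    def test_new_lesion_forces_class4(self):
        res = classify_consist(make_pair([-30.0, -10.0], new_lesion=True), cutoff_pct=25)
        assert res.consist_class == 4 and res.new_lesion

    def test_suvmax_increase_forces_class4(self):
        assert classify_consist(make_pair([-30.0, 5.0]), cutoff_pct=25).consist_class == 4

    def test_exact_cutoff_delta_is_nonresponding(self):
        # "more than 25%" is strict: a -25.0% lesion does not respond
        assert classify_consist(make_pair([-25.0]), cutoff_pct=25).consist_class == 4

    def test_cutoff_changes_class(self):
        pair = make_pair([-20.0, -18.0])
        assert classify_consist(pair, cutoff_pct=15).consist_class == 1
        assert classify_consist(pair, cutoff_pct=25).consist_class == 4

    def test_missing_matv_falls_back_to_suvmax_weights(self):
        pair = make_pair([-30.0, -10.0], matvs=[80.0, None])
        res = classify_consist(pair, cutoff_pct=25, load_weight="matv")
        assert res.load_weight_used == "baseline_suvmax"
        # equal baseline SUVmax -> share 0.5 -> class 3
        assert res.consist_class == 3

    def test_zero_weights_fall_back_to_counts(self):
        pair = make_pair([-30.0, -28.0, -10.0], matvs=[0.0, 0.0, 0.0])
        res = classify_consist(pair, cutoff_pct=25)
        assert res.load_weight_used == "unweighted"
        assert res.consist_class == 2  # 2 of 3 lesions respond

    def test_no_matched_lesion_rejected(self):
        pair = make_pair([], new_lesion=True)
        with pytest.raises(ValueError, match="no matched"):
            classify_consist(pair, cutoff_pct=25)

    @given(
        deltas=st.lists(st.floats(-90.0, 90.0), min_size=1, max_size=4),
        scale=st.floats(0.1, 10.0),
        seed=st.integers(0, 10**6),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_invariant_under_reordering_and_rescaling(self, deltas, scale, seed):
        pair = make_pair(deltas)
        res = classify_consist(pair, cutoff_pct=25)

        order = np.random.default_rng(seed).permutation(len(deltas))
        shuffled = ScanPair(
            "PX",
            Scan(pair.baseline.meta, REF, tuple(pair.baseline.lesions[i] for i in order)),
            Scan(pair.followup.meta, REF, tuple(pair.followup.lesions[i] for i in order)),
        )
        assert classify_consist(shuffled, cutoff_pct=25).consist_class == res.consist_class

        def rescale(scan):
            # uniform positive rescaling of SUVmax at both timepoints; drop
            # evaluability gating since absolute uptake is deliberately moved
            return Scan(
                scan.meta,
                REF,
                tuple(
                    Lesion(l.lesion_id, l.organ, l.suvmax * scale, matv_cm3=l.matv_cm3)
                    for l in scan.lesions
                ),
            )

        rescaled = ScanPair("PX", rescale(pair.baseline), rescale(pair.followup))
        assert (
            classify_consist(rescaled, cutoff_pct=25, require_evaluable=False).consist_class
            == classify_consist(pair, cutoff_pct=25, require_evaluable=False).consist_class
        )

    @given(
        deltas=st.lists(st.floats(-90.0, 50.0), min_size=1, max_size=4),
        c_low=st.floats(5.0, 20.0),
        c_high=st.floats(20.001, 60.0),
        new_lesion=st.booleans(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_cutoff_monotonicity(self, deltas, c_low, c_high, new_lesion):
        # class 1 at a high cut-off implies class 1 at any lower cut-off
        pair = make_pair(deltas, new_lesion=new_lesion)
        if classify_consist(pair, cutoff_pct=c_high).responder:
            assert classify_consist(pair, cutoff_pct=c_low).responder

    def test_matches_rule_enumeration_oracle(self):
        grid = [-40.0, -30.0, -25.0, -20.0, -16.0, -15.0, -10.0, 0.0, 8.0]
        weights = [3.0, 1.0, 2.0]
        for n in (1, 2, 3):
            for deltas in itertools.product(grid, repeat=n):
                for new_lesion in (False, True):
                    for cutoff in (15.0, 25.0):
                        pair = make_pair(list(deltas), matvs=weights[:n], new_lesion=new_lesion)
                        got = classify_consist(pair, cutoff_pct=cutoff).consist_class
                        want = consist_oracle(deltas, weights[:n], new_lesion, cutoff)
                        assert got == want, (deltas, new_lesion, cutoff)


def percist_lesion(lid, organ, suvpeak, diameter=2.0):
    return Lesion(lid, organ, suvmax=suvpeak + 1.0, suvpeak=suvpeak, diameter_cm=diameter)


class TestPercistSelection:
    def test_keeps_two_hottest_per_organ(self):
        lesions = [percist_lesion(f"L{i}", "liver", p) for i, p in enumerate([8.0, 6.0, 5.0])]
        assert select_percist_targets(lesions, REF) == ["L0", "L1"]

    def test_caps_at_ten_targets_overall(self):
        organs = ["liver", "lung", "bone", "node", "other"]
        lesions = [
            percist_lesion(f"L{i:02d}", organs[i % 5], 12.0 - 0.5 * i) for i in range(12)
        ]
        got = select_percist_targets(lesions, REF)
        assert len(got) == 10
        assert got == [f"L{i:02d}" for i in range(10)]  # the ten hottest

    def test_small_or_cold_lesions_excluded(self):
        lesions = [
            percist_lesion("Lsmall", "lung", 9.0, diameter=1.4),
            percist_lesion("Lcold", "lung", 2.0),  # below uptake threshold 3.9
            percist_lesion("Lok", "lung", 9.0),
        ]
        assert select_percist_targets(lesions, REF) == ["Lok"]

    def test_no_candidates_is_empty(self):
        assert select_percist_targets([percist_lesion("L1", "lung", 9.0, diameter=1.0)], REF) == []

    @given(
        peaks=st.lists(st.floats(4.0, 20.0), min_size=1, max_size=20),
        seed=st.integers(0, 10**6),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_limits_and_permutation_determinism(self, peaks, seed):
        organs = ["liver", "lung", "bone", "node", "other"]
        lesions = [
            percist_lesion(f"L{i:02d}", organs[i % 3], round(p, 2)) for i, p in enumerate(peaks)
        ]
        got = select_percist_targets(lesions, REF)
        assert len(got) <= 10
        per_organ = {l.lesion_id: l.organ for l in lesions}
        for organ in organs:
            assert sum(per_organ[lid] == organ for lid in got) <= 2
        order = np.random.default_rng(seed).permutation(len(lesions))
        assert select_percist_targets([lesions[i] for i in order], REF) == got


class TestPercistClassification:
    def _pair(self, base_peak, fu_peak):
        base = Lesion("L1", "liver", base_peak + 1, suvpeak=base_peak, diameter_cm=2.0)
        fu = Lesion("L1", "liver", fu_peak + 1, suvpeak=fu_peak, diameter_cm=2.0)
        return ScanPair(
            "PX",
            Scan(make_meta(), REF, (base,)),
            Scan(make_meta("d14", days=14), REF, (fu,)),
        )

    @pytest.mark.parametrize(
        "fu_peak, status", [(6.9, "MR"), (7.0, "MNR"), (12.0, "MNR")]
    )
    def test_thirty_percent_rule_is_strict(self, fu_peak, status):
        res = classify_percist(self._pair(10.0, fu_peak), ["L1"])
        assert res.status == status

    def test_missing_followup_peak_is_inevaluable(self):
        base = Lesion("L1", "liver", 11.0, suvpeak=10.0, diameter_cm=2.0)
        fu = Lesion("L1", "liver", 7.0, suvpeak=None)
        pair = ScanPair(
            "PX", Scan(make_meta(), REF, (base,)), Scan(make_meta("d14", days=14), REF, (fu,))
        )
        res = classify_percist(pair, ["L1"])
        assert res.status is None and math.isnan(res.hottest_delta_pct)

    def test_empty_target_list_rejected(self):
        with pytest.raises(ValueError):
            classify_percist(self._pair(10.0, 6.0), [])


class TestDiseaseBurden:
    def test_totals_and_dichotomies(self):
        lesions = [lesion(6.0, lesion_id="L1", matv_cm3=60.0), lesion(6.0, lesion_id="L2", matv_cm3=50.0)]
        b = disease_burden(lesions)
        assert b.matv_total_cm3 == pytest.approx(110.0) and b.matv_gt_100cm3

    @pytest.mark.parametrize("n, flagged", [(7, False), (8, True)])
    def test_lesion_count_dichotomy(self, n, flagged):
        lesions = [lesion(6.0, lesion_id=f"L{i}", matv_cm3=1.0) for i in range(n)]
        assert disease_burden(lesions).gt_7_lesions is flagged

    def test_empty_and_missing_matv(self):
        b = disease_burden([])
        assert b.matv_total_cm3 == 0.0 and b.n_lesions == 0
        b = disease_burden([lesion(6.0, lesion_id="L1"), lesion(6.0, lesion_id="L2", matv_cm3=5.0)])
        assert b.matv_total_cm3 == pytest.approx(5.0) and b.matv_incomplete

    def test_reference_gates_the_count(self):
        lesions = [lesion(6.0, lesion_id="L1"), lesion(2.0, lesion_id="L2")]
        assert disease_burden(lesions, REF).n_lesions == 1


class TestCohenKappa:
    def test_identical_nonconstant_raters_score_one(self):
        assert cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_independent_table_scores_zero(self):
        a = [0] * 50 + [1] * 50
        b = ([0] * 25 + [1] * 25) * 2
        assert cohen_kappa(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_table(self):
        # 2x2 table {20, 5, 5, 20}: po = 0.8, pe = 0.5, kappa = 0.6
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 5 + [1] * 20
        assert cohen_kappa(a, b) == pytest.approx(0.6)

    def test_degenerate_and_invalid_inputs(self):
        assert math.isnan(cohen_kappa([1, 1, 1], [1, 1, 1]))
        with pytest.raises(ValueError):
            cohen_kappa([0, 1], [0, 1, 1])
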