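"""Skip detection, misfire detection and MU reconciliation."""

import copy
from dataclasses import replace

import numpy as np
import pytest

from beamletqa import (
    MatchKey,
    SynthConfig,
    compare_fraction,
    find_misfires,
    find_skipped,
    generate_plan,
    index_events,
    mu_per_firing_position,
    reconcile_mu,
    simulate_delivery,
)
from beamletqa.compare import key_of

from conftest import MU_CONST, make_event, make_sequence


def _plan_10():
    """Ten nonzero events plus two zero-MU ones, across two couch positions."""
    events = []
    for c in range(2):
        for f in range(5):
            events.append(make_event(len(events), couch_index=c, firing_index=f))
    events.append(make_event(len(events), couch_index=1, firing_index=5, mu=0.0))
    events.append(make_event(len(events), couch_index=1, firing_index=6, mu=0.0))
    return make_sequence(events)


def _as_delivery(plan, drop_keys=(), fraction=1):
    events, i = [], 0
    out = copy.deepcopy(plan)
    for e in plan.events:
        if key_of(e) in set(drop_keys):
            continue
        events.append(replace(e, event_index=len(events)))
    out.events = events
    out.fraction = fraction
    return out


class TestIndexEvents:
    def test_zero_mu_events_discarded(self):
        assert len(index_events(_plan_10())) == 10

    def test_empty_sequence(self):
        assert index_events(make_sequence([])) == {}

    def test_duplicate_nonzero_key_is_integrity_error(self):
        seq = make_sequence([make_event(0), make_event(1)])
        with pytest.raises(ValueError, match="duplicate"):
            index_events(seq)

    def test_zero_mu_duplicate_key_tolerated(self):
        seq = make_sequence([make_event(0, mu=0.0), make_event(1)])
        assert len(index_events(seq)) == 1


class TestFindSkipped:
    def test_identical_delivery_has_no_skips(self):
        plan = _plan_10()
        assert find_skipped(plan, _as_delivery(plan)) == []

    def test_removed_events_are_returned_in_plan_order(self):
        plan = _plan_10()
        keys = [MatchKey(0, 0, 3), MatchKey(1, 0, 1)]
        skipped = find_skipped(plan, _as_delivery(plan, drop_keys=keys))
        assert [key_of(e) for e in skipped] == keys

    def test_patient_mismatch_rejected(self):
        plan = _plan_10()
        delivery = _as_delivery(plan)
        delivery.patient_id = "OTHER"
        with pytest.raises(ValueError, match="patient"):
            find_skipped(plan, delivery)

    def test_plan_must_be_fraction_zero(self):
        plan = _plan_10()
        delivery = _as_delivery(plan)
        with pytest.raises(ValueError, match="fraction 0"):
            find_skipped(delivery, delivery)


class TestFindMisfires:
    def test_subset_delivery_has_no_misfires(self):
        plan = _plan_10()
        delivery = _as_delivery(plan, drop_keys=[MatchKey(0, 0, 0)])
        assert find_misfires(plan, delivery) == []

    def test_unplanned_event_detected(self):
        plan = _plan_10()
        delivery = _as_delivery(plan)
        delivery.events.append(
            make_event(len(delivery.events), couch_index=1, rotation_index=7, firing_index=0)
        )
        [(event, reason)] = find_misfires(plan, delivery)
        assert reason == "unplanned"
        assert key_of(event) == MatchKey(1, 7, 0)

    def test_flipped_leaf_detected_as_mask_mismatch(self):
        plan = _plan_10()
        delivery = _as_delivery(plan)
        e = delivery.events[3]
        e.leaf_mask = "1" + e.leaf_mask[1:]
        [(event, reason)] = find_misfires(plan, delivery)
        assert reason == "mask-mismatch"
        assert key_of(event) == key_of(e)

    def test_anomalous_mu_detected(self):
        plan = _plan_10()
        delivery = _as_delivery(plan)
        delivery.events[2].mu = 0.5
        [(event, reason)] = find_misfires(plan, delivery)
        assert reason == "mu-anomaly"


class TestReconcileMu:
    def test_identical_delivery_reconciles_to_zero(self):
        plan = _plan_10()
        report = reconcile_mu(plan, _as_delivery(plan))
        assert report.mu_reduction == 0
        assert report.percent_skipped == 0
        assert report.n_plan_events == 10

    def test_one_skip_of_ten(self):
        plan = _plan_10()
        report = reconcile_mu(plan, _as_delivery(plan, drop_keys=[MatchKey(0, 0, 0)]))
        assert report.mu_reduction == pytest.approx(MU_CONST, rel=1e-12)
        assert report.percent_skipped == pytest.approx(10.0)
        assert report.plan_mu_total == pytest.approx(10 * MU_CONST)

    def test_representative_fraction_arithmetic(self):
        # 22 skips of 11 726 planned positions prints as 0.19%
        assert round(100 * 22 / 11726, 2) == 0.19

    def test_empty_plan_rejected(self):
        plan = make_sequence([make_event(0, mu=0.0)])
        with pytest.raises(ValueError, match="no nonzero-MU"):
            reconcile_mu(plan, _as_delivery(plan))


class TestCompareFraction:
    def test_identity_comparison_is_clean(self):
        plan = _plan_10()
        result = compare_fraction(plan, _as_delivery(plan))
        assert result.skipped == []
        assert result.misfires == []
        assert result.leaf_discrepancies == []
        assert result.mu_report.percent_reduction == 0

    def test_skips_and_misfire_reported_simultaneously(self):
        plan = _plan_10()
        delivery = _as_delivery(plan, drop_keys=[MatchKey(0, 0, 1), MatchKey(1, 0, 4)])
        delivery.events.append(
            make_event(len(delivery.events), couch_index=1, rotation_index=9, firing_index=0)
        )
        result = compare_fraction(plan, delivery)
        assert result.mu_report.n_skipped == 2
        assert len(result.misfires) == 1

    def test_json_report_shape(self):
        plan = _plan_10()
        doc = compare_fraction(plan, _as_delivery(plan, drop_keys=[MatchKey(0, 0, 2)])).to_json_dict()
        assert doc["n_skipped"] == 1
        assert doc["skipped_keys"] == [[0, 0, 2]]
        assert set(doc["mu"]) == {"plan", "delivered", "reduction", "percent"}

    @pytest.mark.parametrize("seed", range(20))
    def test_simulator_ground_truth_recovered(self, seed, small_config):
        p = [0.0, 0.0019, 0.01, 0.15][seed % 4]
        plan = generate_plan(small_config, patient_index=seed % 2)
        delivery, truth = simulate_delivery(
            plan, p, 0.0, np.random.default_rng(1000 + seed), fraction=1
        )
        result = compare_fraction(plan, delivery)
        assert [key_of(e) for e in result.skipped] == truth.skipped_keys
        assert result.misfires == []

    def test_injected_misfires_recovered(self, small_config):
        plan = generate_plan(small_config, 0)
        delivery, truth = simulate_delivery(
            plan, 0.0, 0.01, np.random.default_rng(7), fraction=1
        )
        result = compare_fraction(plan, delivery)
        assert truth.misfire_keys  # the draw injects at least one
        assert sorted(key_of(e) for e, _ in result.misfires) == sorted(truth.misfire_keys)
        assert all(reason == "mask-mismatch" for _, reason in result.misfires)


class TestConstantMuIdentities:
    @pytest.mark.parametrize("seed", range(10))
    def test_reduction_proportional_to_skips(self, seed, small_config):
        plan = generate_plan(small_config, 0)
        delivery, truth = simulate_delivery(
            plan, 0.02, 0.0, np.random.default_rng(seed), fraction=1
        )
        report = compare_fraction(plan, delivery).mu_report
        expected = len(truth.skipped_keys) * mu_per_firing_position(plan.spec)
        assert report.mu_reduction == pytest.approx(expected, rel=1e-9)
        assert report.percent_reduction == pytest.approx(report.percent_skipped, rel=1e-9)

    def test_one_extra_skip_adds_exactly_one_quantum(self):
        plan = _plan_10()
        r1 = reconcile_mu(plan, _as_delivery(plan, drop_keys=[MatchKey(0, 0, 0)]))
        r2 = reconcile_mu(
            plan, _as_delivery(plan, drop_keys=[MatchKey(0, 0, 0), MatchKey(1, 0, 2)])
        )
        assert r2.mu_reduction - r1.mu_reduction == pytest.approx(MU_CONST, rel=1e-12)
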