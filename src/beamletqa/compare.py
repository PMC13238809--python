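"""Plan-vs-delivery comparison: skipped firing positions, misfires, MU.

The machine occasionally withholds the beam pulse at a planned firing
position to mitigate a transient hardware fault (arcing, low air pressure,
late MLC configuration); such positions simply do not appear in the daily
delivery log.  A planned nonzero-MU firing position that is missing from
the delivery is a *skipped firing position*.  The converse anomalies —
an unplanned delivered pulse, a delivered pulse with the wrong leaf mask,
or a delivered MU that is not the machine constant — are *misfires* and
are genuinely alarming: a healthy machine produces none.

Matching is by the exact integer key (couch_index, rotation_index,
firing_index); the machine fires on fixed grids, so index matching is
unambiguous (structural grid conformance is the job of
:func:`~beamletqa.beamlet_io.validate_sequence`).  Zero-MU firing events
are discarded before any comparison: they carry no dose and are not part
of the plan-vs-delivery ledger.

Because every delivered pulse carries the same MU quantum, the MU deficit
of a fraction equals the skip count times the machine constant, and the
percent MU reduction equals the percent of positions skipped — exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

from .beamlet_io import MU_TOL, BeamletSequence, FiringEvent
from .machine_model import MachineSpec, mu_per_firing_position

__all__ = [
    "MatchKey",
    "MUReport",
    "ComparisonResult",
    "index_events",
    "find_skipped",
    "find_misfires",
    "reconcile_mu",
    "compare_fraction",
]


class MatchKey(NamedTuple):
    """Integer identity of a firing position within one plan or fraction."""

    couch_index: int
    rotation_index: int
    firing_index: int


def key_of(event: FiringEvent) -> MatchKey:
    return MatchKey(event.couch_index, event.rotation_index, event.firing_index)


@dataclass
class MUReport:
    """MU reconciliation for one fraction against its plan."""

    plan_mu_total: float
    delivered_mu_total: float
    mu_reduction: float
    percent_reduction: float
    n_plan_events: int
    n_skipped: int
    percent_skipped: float


@dataclass
class ComparisonResult:
    """Full plan-vs-delivery comparison for one treatment fraction."""

    patient_id: str
    fraction: int
    skipped: list[FiringEvent]
    misfires: list[tuple[FiringEvent, str]]
    leaf_discrepancies: list[tuple[MatchKey, str, str]]
    mu_report: MUReport

    def to_json_dict(self) -> dict:
        """Serializable report (percentages 2 d.p., MU 1 d.p. at this
        presentation boundary only; stored values stay unrounded)."""
        return {
            "patient_id": self.patient_id,
            "fraction": self.fraction,
            "n_plan_events": self.mu_report.n_plan_events,
            "n_skipped": self.mu_report.n_skipped,
            "skipped_keys": [list(key_of(e)) for e in self.skipped],
            "misfires": [
                {"key": list(key_of(e)), "reason": reason} for e, reason in self.misfires
            ],
            "mu": {
                "plan": round(self.mu_report.plan_mu_total, 1),
                "delivered": round(self.mu_report.delivered_mu_total, 1),
                "reduction": round(self.mu_report.mu_reduction, 1),
                "percent": round(self.mu_report.percent_reduction, 2),
            },
        }


def index_events(seq: BeamletSequence) -> dict[MatchKey, FiringEvent]:
    """Index the nonzero-MU events of a sequence by their match key.

    Zero-MU firing positions are discarded — they never participate in
    matching, skip counts or MU totals.

    Raises
    ------
    ValueError
        If two nonzero-MU events share a key (corrupt sequence).
    """
    index: dict[MatchKey, FiringEvent] = {}
    for e in seq.events:
        if e.mu <= 0:
            continue
        key = key_of(e)
        if key in index:
            raise ValueError(f"duplicate nonzero-MU key {key} in sequence")
        index[key] = e
    return index


def _check_comparable(plan: BeamletSequence, delivery: BeamletSequence) -> None:
    if plan.fraction != 0:
        raise ValueError(f"plan sequence must have fraction 0, got {plan.fraction}")
    if plan.patient_id != delivery.patient_id:
        raise ValueError(
            f"patient mismatch: plan {plan.patient_id!r} vs delivery {delivery.patient_id!r}"
        )
    if plan.spec != delivery.spec:
        raise ValueError("plan and delivery use different machine specs")


def find_skipped(plan: BeamletSequence, delivery: BeamletSequence) -> list[FiringEvent]:
    """Planned nonzero-MU events absent from the delivery, in plan order."""
    _check_comparable(plan, delivery)
    delivered = index_events(delivery)
    return [e for e in plan.events if e.mu > 0 and key_of(e) not in delivered]


def find_misfires(
    plan: BeamletSequence, delivery: BeamletSequence
) -> list[tuple[FiringEvent, str]]:
    """Delivered anomalies: unplanned keys, wrong leaf masks, anomalous MU.

    Returns (delivered event, reason) pairs in delivery order, with reasons
    "unplanned", "mask-mismatch", "mu-anomaly"; an event may appear once
    per reason.
    """
    _check_comparable(plan, delivery)
    plan_index = index_events(plan)
    mu_const = mu_per_firing_position(plan.spec)
    out: list[tuple[FiringEvent, str]] = []
    for e in delivery.events:
        if e.mu <= 0:
            continue
        planned = plan_index.get(key_of(e))
        if planned is None:
            out.append((e, "unplanned"))
            continue
        if e.leaf_mask != planned.leaf_mask:
            out.append((e, "mask-mismatch"))
        if abs(e.mu - mu_const) > MU_TOL:
            out.append((e, "mu-anomaly"))
    return out


def reconcile_mu(
    plan: BeamletSequence,
    delivery: BeamletSequence,
    spec: Optional[MachineSpec] = None,
) -> MUReport:
    """Reconcile delivered MU against the plan via the machine constant.

    Both totals are counted events times the MU quantum; only delivered
    events with a plan counterpart contribute to the delivered total.

    Raises
    ------
    ValueError
        If the plan has no nonzero-MU events.
    """
    _check_comparable(plan, delivery)
    spec = spec or plan.spec
    mu_const = mu_per_firing_position(spec)

    plan_index = index_events(plan)
    n_plan = len(plan_index)
    if n_plan == 0:
        raise ValueError("plan contains no nonzero-MU firing events")
    delivered_index = index_events(delivery)
    n_matched = sum(1 for k in delivered_index if k in plan_index)
    n_skipped = n_plan - sum(1 for k in plan_index if k in delivered_index)

    plan_total = n_plan * mu_const
    delivered_total = n_matched * mu_const
    reduction = plan_total - delivered_total
    return MUReport(
        plan_mu_total=plan_total,
        delivered_mu_total=delivered_total,
        mu_reduction=reduction,
        percent_reduction=100.0 * reduction / plan_total,
        n_plan_events=n_plan,
        n_skipped=n_skipped,
        percent_skipped=100.0 * n_skipped / n_plan,
    )


def compare_fraction(
    plan: BeamletSequence,
    delivery: BeamletSequence,
    spec: Optional[MachineSpec] = None,
) -> ComparisonResult:
    """Bundle skip detection, misfire detection and MU reconciliation.

    Deterministic for fixed inputs.
    """
    skipped = find_skipped(plan, delivery)
    misfires = find_misfires(plan, delivery)
    plan_index = index_events(plan)
    discrepancies = [
        (key_of(e), plan_index[key_of(e)].leaf_mask, e.leaf_mask)
        for e, reason in misfires
        if reason == "mask-mismatch"
    ]
    mu_report = reconcile_mu(plan, delivery, spec)
    return ComparisonResult(
        patient_id=plan.patient_id,
        fraction=delivery.fraction,
        skipped=skipped,
        misfires=misfires,
        leaf_discrepancies=discrepancies,
        mu_report=mu_report,
    )
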