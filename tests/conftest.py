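"""Shared fixtures and sequence-building helpers for the test suite."""

from __future__ import annotations

import pytest

from beamletqa import (
    BeamletSequence,
    FiringEvent,
    SynthConfig,
    default_spec,
    generate_plan,
    mu_per_firing_position,
)

SPEC = default_spec()
MU_CONST = mu_per_firing_position(SPEC)


def make_event(
    event_index: int,
    couch_index: int = 0,
    rotation_index: int = 0,
    firing_index: int = 0,
    mu: float = MU_CONST,
    leaf_mask: str | None = None,
    couch_mm: float | None = None,
    gantry_deg: float | None = None,
) -> FiringEvent:
    """Hand-build a grid-conformant firing event with sensible defaults."""
    if leaf_mask is None:
        leaf_mask = "0" * 28 + "1" * 8 + "0" * 28
    if couch_mm is None:
        couch_mm = couch_index * SPEC.couch_step_mm
    if gantry_deg is None:
        gantry_deg = (firing_index * SPEC.sector_deg) % 360.0
    return FiringEvent(
        event_index=event_index,
        couch_index=couch_index,
        couch_mm=couch_mm,
        rotation_index=rotation_index,
        firing_index=firing_index,
        gantry_deg=gantry_deg,
        mu=mu,
        leaf_mask=leaf_mask,
    )


def make_sequence(
    events: list[FiringEvent],
    fraction: int = 0,
    patient_id: str = "T000",
) -> BeamletSequence:
    return BeamletSequence(
        patient_id=patient_id,
        fraction=fraction,
        spec=SPEC,
        events=events,
        plan_mu=sum(e.mu for e in events),
    )


def assert_sequences_equal(a: BeamletSequence, b: BeamletSequence) -> None:
    """Field-for-field equality: masks/integers bit-exact, numerics within
    the BLSQ dialect's write precision."""
    assert a.patient_id == b.patient_id
    assert a.fraction == b.fraction
    assert a.spec == b.spec
    assert abs(a.plan_mu - b.plan_mu) <= 1e-9 * max(1.0, abs(a.plan_mu))
    assert len(a.events) == len(b.events)
    for ea, eb in zip(a.events, b.events):
        assert (ea.event_index, ea.couch_index, ea.rotation_index, ea.firing_index) == (
            eb.event_index, eb.couch_index, eb.rotation_index, eb.firing_index
        )
        assert ea.leaf_mask == eb.leaf_mask
        assert abs(ea.couch_mm - eb.couch_mm) <= 5e-7
        assert abs(ea.gantry_deg - eb.gantry_deg) <= 5e-7
        assert abs(ea.mu - eb.mu) <= 1e-6


@pytest.fixture(scope="session")
def spec():
    return SPEC


@pytest.fixture(scope="session")
def small_config():
    """A fast-to-generate cohort configuration for structural tests."""
    return SynthConfig(
        n_patients=2,
        ptv_length_mm_range=(43.0, 60.0),
        couch_margin_steps=1,
        rotations_per_couch_range=(2, 3),
        fractions_range=(3, 4),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_plan(small_config):
    return generate_plan(small_config, 0)
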