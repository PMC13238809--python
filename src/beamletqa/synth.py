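"""Synthetic plan generator and delivery simulator with fault injection.

The vendor's delivery logs are proprietary, so this module emulates their
content: one-pass plans in which the couch steps through a planning-target
length at 2.1 mm increments, several full gantry rotations are delivered
at each couch position, and every firing position carries either zero MU
or the single machine MU quantum with a binary leaf aperture.

Delivery faults are modelled as the machine exhibits them:

* **Skips** — each nonzero-MU planned firing position is independently
  omitted with probability ``skip_prob``.  Transient hardware faults
  (arcing, compressed-air pressure dips, late MLC configuration) strike
  essentially at random with respect to the plan, and observed skip rates
  show no strong correlation with modulation, so independent Bernoulli
  skipping is the model; bursts/correlated faults are out of scope.
* **Misfires** — with probability ``misfire_prob`` a retained event has
  one uniformly chosen leaf flipped.  Real machines should produce none;
  injection exists to exercise the detector.

Every simulated fraction returns its ground truth (the exact skipped and
misfired keys), making the simulator the oracle for the whole comparison
pipeline.  All randomness derives from ``SynthConfig.seed`` through
per-patient / per-fraction substreams, so any single plan or fraction is
reproducible in isolation.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .beamlet_io import BeamletSequence, FiringEvent, write_sequence
from .compare import MatchKey, key_of
from .machine_model import MachineSpec, default_spec, mu_per_firing_position

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_plan",
    "simulate_delivery",
    "generate_cohort",
    "write_cohort",
]

APERTURE_MODELS = ("random-contiguous", "sweep", "static")


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition knobs for the simulator.

    Defaults emulate the clinical cohort the toolkit targets: target
    lengths of 4.3-20.0 cm, a couch travel margin, 5-9 full rotations per
    couch position, ~30% zero-MU firing positions, a per-position skip
    probability of 0.19%, no misfires, and 5-33 fractions per patient.
    """

    n_patients: int = 10
    ptv_length_mm_range: tuple[float, float] = (43.0, 200.0)
    couch_margin_steps: int = 3
    rotations_per_couch_range: tuple[int, int] = (5, 9)
    aperture_model: str = "random-contiguous"
    open_fraction_range: tuple[float, float] = (0.2, 0.6)
    zero_mu_fraction: float = 0.3
    skip_prob: float = 0.0019
    misfire_prob: float = 0.0
    fractions_range: tuple[int, int] = (5, 33)
    seed: int = 0
    spec: MachineSpec = field(default_factory=default_spec)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name in ("ptv_length_mm_range", "rotations_per_couch_range",
                     "open_fraction_range", "fractions_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered (min <= max), got {(lo, hi)}")
        if self.ptv_length_mm_range[0] <= 0 or self.rotations_per_couch_range[0] < 1:
            raise ValueError("degenerate ptv_length_mm_range or rotations_per_couch_range")
        if self.couch_margin_steps < 0:
            raise ValueError("couch_margin_steps must be non-negative")
        if self.aperture_model not in APERTURE_MODELS:
            raise ValueError(f"aperture_model must be one of {APERTURE_MODELS}")
        if not (0.0 <= self.open_fraction_range[0] and self.open_fraction_range[1] <= 1.0):
            raise ValueError("open_fraction_range must lie in [0, 1]")
        for name in ("zero_mu_fraction", "skip_prob", "misfire_prob"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1), got {p}")


@dataclass
class GroundTruth:
    """Exact fault record for one simulated fraction (the oracle)."""

    skipped_keys: list[MatchKey] = field(default_factory=list)
    misfire_keys: list[MatchKey] = field(default_factory=list)


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for a (seed, patient[, fraction]) substream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def _run_mask(n_leaves: int, start: int, length: int) -> str:
    return "0" * start + "1" * length + "0" * (n_leaves - start - length)


def generate_plan(
    config: SynthConfig,
    patient_index: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> BeamletSequence:
    """Generate one synthetic one-pass treatment plan (fraction 0).

    Target length is drawn uniformly from ``ptv_length_mm_range``; the
    couch visits ``ceil(L / couch_step_mm) + 2 * couch_margin_steps``
    positions; each couch position receives a uniformly drawn number of
    full rotations of ``fp_per_rotation`` events.  MU is the machine
    quantum with probability ``1 - zero_mu_fraction``, else 0.  Apertures
    are a single contiguous open leaf run per the configured model.

    Deterministic given (config, patient_index); generated plans satisfy
    every structural invariant checked by
    :func:`~beamletqa.beamlet_io.validate_sequence`.
    """
    spec = config.spec
    rng = rng if rng is not None else _substream(config.seed, patient_index)
    mu_const = mu_per_firing_position(spec)
    sector = spec.sector_deg
    n_leaves = spec.n_leaves

    length_mm = rng.uniform(*config.ptv_length_mm_range)
    n_couch = math.ceil(length_mm / spec.couch_step_mm) + 2 * config.couch_margin_steps

    lo_f, hi_f = config.open_fraction_range
    run_len = max(1, round(rng.uniform(lo_f, hi_f) * n_leaves))
    run_start = int(rng.integers(0, n_leaves - run_len + 1))

    events: list[FiringEvent] = []
    lo_rot, hi_rot = config.rotations_per_couch_range
    fire_counter = 0
    for c in range(n_couch):
        n_rot = int(rng.integers(lo_rot, hi_rot + 1))
        couch_mm = c * spec.couch_step_mm
        for r in range(n_rot):
            for f in range(spec.fp_per_rotation):
                if config.aperture_model == "random-contiguous":
                    ln = max(1, round(rng.uniform(lo_f, hi_f) * n_leaves))
                    st = int(rng.integers(0, n_leaves - ln + 1))
                    mask = _run_mask(n_leaves, st, ln)
                elif config.aperture_model == "sweep":
                    st = (run_start + fire_counter) % (n_leaves - run_len + 1)
                    mask = _run_mask(n_leaves, st, run_len)
                else:  # static
                    mask = _run_mask(n_leaves, run_start, run_len)
                mu = mu_const if rng.random() >= config.zero_mu_fraction else 0.0
                events.append(
                    FiringEvent(
                        event_index=len(events),
                        couch_index=c,
                        couch_mm=couch_mm,
                        rotation_index=r,
                        firing_index=f,
                        gantry_deg=(f * sector) % 360.0,
                        mu=mu,
                        leaf_mask=mask,
                    )
                )
                fire_counter += 1

    plan_mu = sum(e.mu for e in events)
    return BeamletSequence(
        patient_id=f"SYN{patient_index:03d}",
        fraction=0,
        spec=spec,
        events=events,
        plan_mu=plan_mu,
    )


def simulate_delivery(
    plan: BeamletSequence,
    skip_prob: float,
    misfire_prob: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    fraction: int = 1,
) -> tuple[BeamletSequence, GroundTruth]:
    """Simulate one delivered fraction of ``plan`` with fault injection.

    Each nonzero-MU planned event is independently dropped with
    probability ``skip_prob``; each retained nonzero-MU event has one
    uniformly chosen leaf flipped with probability ``misfire_prob``.
    Zero-MU events pass through unchanged.  Event indices are renumbered
    consecutively so the output is a valid sequence.

    Returns the delivery and its exact ground truth.
    """
    for name, p in (("skip_prob", skip_prob), ("misfire_prob", misfire_prob)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    rng = rng if rng is not None else np.random.default_rng()

    truth = GroundTruth()
    events: list[FiringEvent] = []
    for e in plan.events:
        if e.mu > 0 and rng.random() < skip_prob:
            truth.skipped_keys.append(key_of(e))
            continue
        new = replace(e, event_index=len(events))
        if e.mu > 0 and misfire_prob > 0 and rng.random() < misfire_prob:
            leaf = int(rng.integers(0, plan.spec.n_leaves))
            bit = "0" if e.leaf_mask[leaf] == "1" else "1"
            new.leaf_mask = e.leaf_mask[:leaf] + bit + e.leaf_mask[leaf + 1 :]
            truth.misfire_keys.append(key_of(e))
        events.append(new)

    delivery = BeamletSequence(
        patient_id=plan.patient_id,
        fraction=fraction,
        spec=plan.spec,
        events=events,
        plan_mu=plan.plan_mu,
    )
    return delivery, truth


def generate_cohort(
    config: SynthConfig,
) -> list[tuple[BeamletSequence, list[tuple[BeamletSequence, GroundTruth]]]]:
    """Generate a full cohort: per patient, a plan and simulated fractions.

    Fraction counts are drawn uniformly from ``config.fractions_range``.
    Randomness is split into per-patient and per-(patient, fraction)
    substreams keyed off ``config.seed``, so any item regenerates
    identically in isolation.
    """
    cohort = []
    for p in range(config.n_patients):
        plan = generate_plan(config, p)
        n_frac = int(
            _substream(config.seed, p, 0).integers(
                config.fractions_range[0], config.fractions_range[1] + 1
            )
        )
        fractions = []
        for k in range(1, n_frac + 1):
            rng = _substream(config.seed, p, k)
            fractions.append(
                simulate_delivery(plan, config.skip_prob, config.misfire_prob, rng, fraction=k)
            )
        cohort.append((plan, fractions))
    return cohort


def write_cohort(
    cohort: list[tuple[BeamletSequence, list[tuple[BeamletSequence, GroundTruth]]]],
    root: Union[str, os.PathLike],
) -> None:
    """Write a cohort as ``<root>/<patient_id>/plan.blsq`` plus per-fraction
    ``fx<k>.blsq`` files and ground-truth JSON sidecars."""
    for plan, fractions in cohort:
        pdir = os.path.join(root, plan.patient_id)
        os.makedirs(pdir, exist_ok=True)
        write_sequence(plan, os.path.join(pdir, "plan.blsq"))
        for delivery, truth in fractions:
            k = delivery.fraction
            write_sequence(delivery, os.path.join(pdir, f"fx{k}.blsq"))
            with open(os.path.join(pdir, f"fx{k}.truth.json"), "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "skipped_keys": [list(key) for key in truth.skipped_keys],
                        "misfire_keys": [list(key) for key in truth.misfire_keys],
                    },
                    fh,
                )
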