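"""Leaf-modulation metrics and plan/delivery aggregation heatmap matrices.

Two families of summaries:

* **Transition rates** — how aggressively a plan modulates the aperture.
  Between consecutive firing positions within one couch segment, each leaf
  either holds or toggles its open/closed state; the number of toggles is
  the Hamming distance between consecutive masks.  The *average* rate is
  total toggles divided by beam-on time; the *maximum* rate is the peak of
  a sliding-window sum (default window: one full rotation, i.e. one second
  at 60 RPM and 50 firing positions per rotation).  Zero-MU events still
  occupy machine time and the leaves still move through them, so they
  contribute masks and dwell time here — unlike in the open-count
  aggregates below, where only dose-carrying events count.

* **Aggregation matrices** — heatmap-ready open-leaf counts marginalised
  over couch position and over gantry firing index, plus a beam-on count
  per (couch, firing) cell.  Element-wise plan-minus-delivery differences
  of these matrices localise skipped firing positions in space and angle;
  for skip-only deliveries every difference entry is a non-negative
  integer and the (couch x gantry) difference sums to the skip count.

Intervals never span couch shifts: the beam is off while the couch steps,
so each couch segment is an independent modulation stream.  Gantry
aggregation is by firing index (bin-exact), not by raw angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Optional, Union
import os

import numpy as np
import pandas as pd

from .beamlet_io import BeamletSequence
from .machine_model import MachineSpec, firing_frequency

__all__ = [
    "TransitionProfile",
    "AggregateSet",
    "transition_profile",
    "aggregate_open_counts",
    "difference_maps",
    "write_aggregate_csv",
]


@dataclass
class TransitionProfile:
    """Leaf transition statistics for one sequence.

    ``per_interval_changes`` holds the Hamming distances between
    consecutive masks within each couch segment, concatenated in sequence
    order; rates are leaves/second; ``beam_on_seconds`` is the total event
    count over the firing frequency.
    """

    per_interval_changes: np.ndarray
    max_rate: float
    avg_rate: float
    beam_on_seconds: float


@dataclass
class AggregateSet:
    """The three aggregation matrices (integer counts).

    leaf_by_couch : (n_leaves, n_couch) — times each leaf is open at each
    couch position, summed over gantry angles.
    leaf_by_gantry : (n_leaves, fp_per_rotation) — times each leaf is open
    at each firing index, summed over couch positions.
    couch_by_gantry : (n_couch, fp_per_rotation) — times the beam is on at
    each (couch, firing) cell.
    """

    leaf_by_couch: np.ndarray
    leaf_by_gantry: np.ndarray
    couch_by_gantry: np.ndarray


def transition_profile(
    seq: BeamletSequence,
    spec: Optional[MachineSpec] = None,
    window_intervals: Optional[int] = None,
) -> TransitionProfile:
    """Compute per-interval leaf changes and max/average transition rates.

    ``window_intervals`` sets the sliding-window length for the maximum
    rate, in inter-event intervals; default is one rotation
    (``fp_per_rotation`` intervals — a 1-second window at the default
    machine).  ``window_intervals=1`` gives the instantaneous peak.  A
    couch segment shorter than the window contributes its total change
    count against the full window duration.

    A sequence with fewer than two events in every segment yields empty
    changes and zero rates.
    """
    spec = spec or seq.spec
    if window_intervals is None:
        window_intervals = spec.fp_per_rotation
    if window_intervals < 1:
        raise ValueError("window_intervals must be a positive integer")
    freq = firing_frequency(spec)

    masks = seq.mask_matrix()
    segment_ids = [e.couch_index for e in seq.events]
    changes_parts: list[np.ndarray] = []
    max_rate = 0.0
    window_seconds = window_intervals / freq

    start = 0
    for _, grp in groupby(segment_ids):
        n = sum(1 for _ in grp)
        seg = masks[start : start + n]
        start += n
        if n < 2:
            continue
        d = (seg[1:] != seg[:-1]).sum(axis=1).astype(np.int64)
        changes_parts.append(d)
        if d.size >= window_intervals:
            kernel = np.ones(window_intervals, dtype=np.int64)
            peak = int(np.convolve(d, kernel, mode="valid").max())
        else:
            peak = int(d.sum())
        max_rate = max(max_rate, peak / window_seconds)

    if changes_parts:
        changes = np.concatenate(changes_parts)
    else:
        changes = np.zeros(0, dtype=np.int64)
    beam_on_seconds = len(seq.events) / freq
    avg_rate = float(changes.sum() / beam_on_seconds) if beam_on_seconds > 0 else 0.0
    return TransitionProfile(
        per_interval_changes=changes,
        max_rate=float(max_rate),
        avg_rate=avg_rate,
        beam_on_seconds=beam_on_seconds,
    )


def aggregate_open_counts(
    seq: BeamletSequence, n_couch: Optional[int] = None
) -> AggregateSet:
    """Accumulate open-leaf and beam-on counts over nonzero-MU events.

    ``n_couch`` fixes the couch dimension (needed to difference a plan
    against a delivery whose trailing couch positions were all skipped);
    default is ``max couch_index + 1``.
    """
    spec = seq.spec
    nonzero = seq.nonzero_events()
    if n_couch is None:
        n_couch = max((e.couch_index for e in nonzero), default=-1) + 1
    leaf_by_couch = np.zeros((spec.n_leaves, n_couch), dtype=np.int64)
    leaf_by_gantry = np.zeros((spec.n_leaves, spec.fp_per_rotation), dtype=np.int64)
    couch_by_gantry = np.zeros((n_couch, spec.fp_per_rotation), dtype=np.int64)
    for e in nonzero:
        if e.couch_index >= n_couch:
            raise ValueError(f"couch_index {e.couch_index} >= n_couch {n_couch}")
        bits = e.mask_bits()
        leaf_by_couch[:, e.couch_index] += bits
        leaf_by_gantry[:, e.firing_index] += bits
        couch_by_gantry[e.couch_index, e.firing_index] += 1
    return AggregateSet(leaf_by_couch, leaf_by_gantry, couch_by_gantry)


def difference_maps(plan_agg: AggregateSet, deliv_agg: AggregateSet) -> AggregateSet:
    """Element-wise plan-minus-delivery differences of the three matrices.

    Raises
    ------
    ValueError
        On any shape mismatch.
    """
    pairs = (
        (plan_agg.leaf_by_couch, deliv_agg.leaf_by_couch),
        (plan_agg.leaf_by_gantry, deliv_agg.leaf_by_gantry),
        (plan_agg.couch_by_gantry, deliv_agg.couch_by_gantry),
    )
    for p, d in pairs:
        if p.shape != d.shape:
            raise ValueError(f"aggregate shape mismatch: {p.shape} vs {d.shape}")
    return AggregateSet(*(p - d for p, d in pairs))


def write_aggregate_csv(
    agg: AggregateSet, out_dir: Union[str, os.PathLike], prefix: str = ""
) -> list[str]:
    """Export the three matrices as labelled CSV files for heatmap plotting.

    Rows/columns are labelled by leaf index, couch index and firing index.
    Returns the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, matrix, row_label, col_label in (
        ("leaf_by_couch", agg.leaf_by_couch, "leaf", "couch"),
        ("leaf_by_gantry", agg.leaf_by_gantry, "leaf", "firing"),
        ("couch_by_gantry", agg.couch_by_gantry, "couch", "firing"),
    ):
        df = pd.DataFrame(
            matrix,
            index=pd.Index(range(matrix.shape[0]), name=row_label),
            columns=[f"{col_label}{j}" for j in range(matrix.shape[1])],
        )
        path = os.path.join(out_dir, f"{prefix}{name}.csv")
        df.to_csv(path)
        written.append(path)
    return written
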