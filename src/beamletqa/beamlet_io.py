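"""The BLSQ beamlet-sequence file dialect: validated read/write and checks.

A beamlet sequence is the ordered list of beam firing events for one
treatment plan (fraction 0) or one delivered fraction.  Each event records
the couch position, rotation and firing indices, gantry angle, delivered MU
and the full binary leaf mask.  The vendor's native log layout is
proprietary; BLSQ is an open, human-diffable CSV dialect carrying the same
content::

    #BLSQ v1
    #patient_id=<text>
    #fraction=<int>            (0 = plan)
    #plan_mu=<float>
    #n_leaves=64
    #fp_per_rotation=50
    #gantry_rpm=60.0
    #couch_step_mm=2.1
    #nominal_dose_rate=1000.0
    event_index,couch_index,couch_mm,rotation_index,firing_index,gantry_deg,mu,leaf_mask
    0,0,0.000000,0,0,0.000000,0.333333333,00000...111...000

Header lines start with ``#`` and are ``key=value``; exactly one column
header line follows; each data row is one firing event, with the leaf mask
written as exactly ``n_leaves`` characters from {0,1}, leaf 0 first (leaf 0
is the first leaf on the machine's negative lateral side).  Encoding is
UTF-8 with ``\\n`` line endings and ``.`` decimal separators.

Zero-MU firing events are legal and retained in files — the machine's logs
contain them and the leaves still move through them; downstream analysis
discards them, not the reader.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import numpy as np

from .machine_model import MachineSpec, mu_per_firing_position

__all__ = [
    "FiringEvent",
    "BeamletSequence",
    "ValidationReport",
    "BlsqFormatError",
    "read_sequence",
    "write_sequence",
    "validate_sequence",
]

MU_TOL = 1e-6  # MU must be 0 or the machine constant within this absolute tolerance

_COLUMNS = (
    "event_index,couch_index,couch_mm,rotation_index,firing_index,gantry_deg,mu,leaf_mask"
)

# MachineSpec fields that belong in a BLSQ header (all of them).
_SPEC_KEYS = (
    "n_leaves",
    "fp_per_rotation",
    "gantry_rpm",
    "couch_step_mm",
    "nominal_dose_rate",
    "leaf_width_mm",
    "jaw_width_cm",
    "field_width_cm",
)


class BlsqFormatError(ValueError):
    """Raised when a file does not conform to the BLSQ dialect."""


@dataclass
class FiringEvent:
    """One beam firing: where the machine was and what it delivered.

    ``leaf_mask`` is a string of '0'/'1' characters, one per leaf, '1' =
    open; use :meth:`mask_bits` for a boolean array view.
    """

    event_index: int
    couch_index: int
    couch_mm: float
    rotation_index: int
    firing_index: int
    gantry_deg: float
    mu: float
    leaf_mask: str

    def mask_bits(self) -> np.ndarray:
        """Leaf mask as a boolean numpy array (True = leaf open)."""
        return np.frombuffer(self.leaf_mask.encode("ascii"), dtype=np.uint8) != ord("0")

    @property
    def open_count(self) -> int:
        """Number of open leaves at this firing."""
        return self.leaf_mask.count("1")


@dataclass
class BeamletSequence:
    """Ordered firing events for one plan (fraction 0) or delivered fraction."""

    patient_id: str
    fraction: int
    spec: MachineSpec
    events: list[FiringEvent] = field(default_factory=list)
    plan_mu: float = 0.0

    def __len__(self) -> int:
        return len(self.events)

    def nonzero_events(self) -> list[FiringEvent]:
        """Events with nonzero MU — the ones that enter every analysis."""
        return [e for e in self.events if e.mu > 0]

    def mask_matrix(self) -> np.ndarray:
        """All leaf masks stacked as an (n_events, n_leaves) boolean matrix."""
        if not self.events:
            return np.zeros((0, self.spec.n_leaves), dtype=bool)
        buf = "".join(e.leaf_mask for e in self.events).encode("ascii")
        arr = np.frombuffer(buf, dtype=np.uint8) != ord("0")
        return arr.reshape(len(self.events), self.spec.n_leaves)


@dataclass
class ValidationReport:
    """Outcome of structural validation: ``ok`` iff no error-severity issue."""

    issues: list[tuple[str, Optional[int], str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.issues)

    def errors(self) -> list[tuple[str, Optional[int], str]]:
        return [i for i in self.issues if i[0] == "error"]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_sequence(path: Union[str, os.PathLike]) -> BeamletSequence:
    """Parse a BLSQ file into a :class:`BeamletSequence`.

    Every data row becomes exactly one :class:`FiringEvent`, in file order.

    Raises
    ------
    BlsqFormatError
        Missing/garbled header (named by line number), wrong column count,
        wrong mask length, or non-numeric fields (named by row).
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.read().split("\n")

    it: Iterator[tuple[int, str]] = iter(enumerate(lines, start=1))
    try:
        lineno, first = next(it)
    except StopIteration:
        raise BlsqFormatError(f"{path}: empty file") from None
    if first.strip() != "#BLSQ v1":
        raise BlsqFormatError(f"{path}:1: expected '#BLSQ v1' magic, got {first!r}")

    header: dict[str, str] = {}
    columns_line = None
    for lineno, line in it:
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise BlsqFormatError(f"{path}:{lineno}: header line without '=': {line!r}")
            key, _, value = body.partition("=")
            header[key.strip()] = value.strip()
        else:
            columns_line = (lineno, line)
            break
    if columns_line is None or columns_line[1].strip() != _COLUMNS:
        got = None if columns_line is None else columns_line[1]
        raise BlsqFormatError(f"{path}: missing or wrong column header line, got {got!r}")

    for key in ("patient_id", "fraction"):
        if key not in header:
            raise BlsqFormatError(f"{path}: header missing required key '{key}'")
    try:
        spec = MachineSpec.from_mapping(header)
        fraction = int(header["fraction"])
        plan_mu = float(header.get("plan_mu", "0"))
    except (ValueError, TypeError) as exc:
        raise BlsqFormatError(f"{path}: bad header value: {exc}") from exc

    events: list[FiringEvent] = []
    for lineno, line in it:
        if line == "":
            continue  # trailing newline
        parts = line.split(",")
        if len(parts) != 8:
            raise BlsqFormatError(
                f"{path}:{lineno}: expected 8 comma-separated fields, got {len(parts)}"
            )
        mask = parts[7]
        if len(mask) != spec.n_leaves or set(mask) - {"0", "1"}:
            raise BlsqFormatError(
                f"{path}:{lineno}: leaf_mask must be {spec.n_leaves} characters of 0/1"
            )
        try:
            ev = FiringEvent(
                event_index=int(parts[0]),
                couch_index=int(parts[1]),
                couch_mm=float(parts[2]),
                rotation_index=int(parts[3]),
                firing_index=int(parts[4]),
                gantry_deg=float(parts[5]),
                mu=float(parts[6]),
                leaf_mask=mask,
            )
        except ValueError as exc:
            raise BlsqFormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
        events.append(ev)

    return BeamletSequence(
        patient_id=header["patient_id"],
        fraction=fraction,
        spec=spec,
        events=events,
        plan_mu=plan_mu,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_sequence(seq: BeamletSequence, path: Union[str, os.PathLike]) -> None:
    """Write ``seq`` as a BLSQ v1 file that :func:`read_sequence` reproduces.

    couch_mm and gantry_deg are rendered to 6 decimals, mu to 9, enough to
    round-trip within the dialect's stated precision.
    """
    lines = ["#BLSQ v1", f"#patient_id={seq.patient_id}", f"#fraction={seq.fraction}",
             f"#plan_mu={seq.plan_mu!r}"]
    spec_map = seq.spec.to_mapping()
    lines.extend(f"#{key}={spec_map[key]}" for key in _SPEC_KEYS)
    lines.append(_COLUMNS)
    for e in seq.events:
        lines.append(
            f"{e.event_index},{e.couch_index},{e.couch_mm:.6f},{e.rotation_index},"
            f"{e.firing_index},{e.gantry_deg:.6f},{e.mu:.9f},{e.leaf_mask}"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

def validate_sequence(
    seq: BeamletSequence,
    couch_tol_mm: float = 0.1,
    gantry_tol_deg: float = 0.5,
) -> ValidationReport:
    """Check a sequence against the machine's delivery constraints.

    Errors: decreasing couch position (one-pass rule); couch position off
    the 2.1 mm grid anchored at the sequence's first couch position; gantry
    angle off the firing-position grid (anchored per rotation at that
    rotation's first observed event); MU neither 0 nor the machine constant;
    duplicate or out-of-order (couch, rotation, firing) keys; wrong mask
    length.  Warnings: zero-MU events (legal, informational).

    Problems are reported, never raised.
    """
    report = ValidationReport()
    spec = seq.spec
    mu_const = mu_per_firing_position(spec)
    sector = spec.sector_deg

    seen_keys: set[tuple[int, int, int]] = set()
    rotation_start: dict[tuple[int, int], float] = {}
    prev_couch_mm: Optional[float] = None
    prev_key: Optional[tuple[int, int, int]] = None
    first_couch: Optional[tuple[int, float]] = None  # (couch_index, couch_mm)

    for e in seq.events:
        i = e.event_index
        if len(e.leaf_mask) != spec.n_leaves:
            report.issues.append(
                ("error", i, f"leaf_mask length {len(e.leaf_mask)} != n_leaves {spec.n_leaves}")
            )

        # one-pass couch movement
        if prev_couch_mm is not None and e.couch_mm < prev_couch_mm - 1e-9:
            report.issues.append(
                ("error", i, f"couch_mm decreased from {prev_couch_mm} to {e.couch_mm}")
            )
        prev_couch_mm = e.couch_mm

        # couch grid relative to the first couch position
        if first_couch is None:
            first_couch = (e.couch_index, e.couch_mm)
        expected_mm = first_couch[1] + (e.couch_index - first_couch[0]) * spec.couch_step_mm
        if abs(e.couch_mm - expected_mm) > couch_tol_mm:
            report.issues.append(
                ("error", i,
                 f"couch_mm {e.couch_mm} off the {spec.couch_step_mm} mm grid "
                 f"(expected {expected_mm:.3f} for couch_index {e.couch_index})")
            )

        # gantry grid, anchored per (couch, rotation) at its first event
        rot = (e.couch_index, e.rotation_index)
        if rot not in rotation_start:
            rotation_start[rot] = (e.gantry_deg - e.firing_index * sector) % 360.0
        expected_deg = (rotation_start[rot] + e.firing_index * sector) % 360.0
        delta = abs((e.gantry_deg - expected_deg + 180.0) % 360.0 - 180.0)
        if delta > gantry_tol_deg:
            report.issues.append(
                ("error", i,
                 f"gantry_deg {e.gantry_deg} off the {sector:.1f} deg grid by {delta:.2f} deg")
            )

        # MU quantisation
        if e.mu == 0.0:
            report.issues.append(("warning", i, "zero-MU firing event"))
        elif abs(e.mu - mu_const) > MU_TOL:
            report.issues.append(
                ("error", i, f"mu {e.mu} is neither 0 nor the machine constant {mu_const:.9f}")
            )

        # key uniqueness and ordering
        key = (e.couch_index, e.rotation_index, e.firing_index)
        if key in seen_keys:
            report.issues.append(("error", i, f"duplicate key {key}"))
        seen_keys.add(key)
        if prev_key is not None and key[0] == prev_key[0] and key[1:] <= prev_key[1:]:
            report.issues.append(
                ("error", i, f"(rotation, firing) not increasing within couch segment: {key}")
            )
        prev_key = key

    return report
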