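"""Machine constants and geometric conventions for a ring-gantry binary-MLC linac.

The machine modelled here delivers radiation while the gantry spins
continuously (60 RPM by default) and pulses the beam at a fixed number of
evenly spaced *firing positions* per rotation (50 by default, i.e. one
aperture update every 7.2 degrees).  A binary multi-leaf collimator (64
leaves, 6.25 mm projected width) shapes each pulse: every leaf is either
fully open or fully closed, with no intermediate positions.  The treatment
couch steps incrementally (2.1 mm) between beam-on segments, always in one
direction (one-pass plans).

Because the gantry speed and firing grid are fixed, the machine delivers a
single constant monitor-unit (MU) quantum at every non-skipped firing
position: ``nominal_dose_rate / (gantry_rpm * fp_per_rotation)``.  That one
constant underpins the whole toolkit — skipped-position counts and MU
deficits are exactly proportional.

Angle convention: IEC-style degrees in [0, 360), 0 deg at the vertical top,
increasing in the machine's rotation direction.  Each rotation carries an
explicit start angle in the log files rather than assuming a fixed zero
reference.  Angles are always degrees, couch positions always millimetres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "MachineSpec",
    "default_spec",
    "firing_frequency",
    "mu_per_firing_position",
    "gantry_angle_of",
]


@dataclass(frozen=True)
class MachineSpec:
    """Immutable bundle of machine constants.

    Parameters
    ----------
    n_leaves:
        Number of binary MLC leaves (count).
    fp_per_rotation:
        Firing positions per gantry rotation; the rotation is divided into
        ``360 / fp_per_rotation`` degree sectors.
    gantry_rpm:
        Gantry rotation speed in rotations per minute.
    couch_step_mm:
        Couch increment between beam-on segments, millimetres.
    nominal_dose_rate:
        Beam output in MU per minute.
    leaf_width_mm:
        Projected leaf width at isocenter, millimetres.
    jaw_width_cm:
        Superior-inferior jaw opening, centimetres.
    field_width_cm:
        Maximum lateral field width, centimetres.
    """

    n_leaves: int = 64
    fp_per_rotation: int = 50
    gantry_rpm: float = 60.0
    couch_step_mm: float = 2.1
    nominal_dose_rate: float = 1000.0
    leaf_width_mm: float = 6.25
    jaw_width_cm: float = 2.0
    field_width_cm: float = 40.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"MachineSpec.{f.name} must be strictly positive, got {value!r}")
        if int(self.n_leaves) != self.n_leaves or int(self.fp_per_rotation) != self.fp_per_rotation:
            raise ValueError("n_leaves and fp_per_rotation must be integers")

    @property
    def sector_deg(self) -> float:
        """Angular spacing between consecutive firing positions, degrees."""
        return 360.0 / self.fp_per_rotation

    # -- flat key=value serialization (file headers and config files) ------

    def to_mapping(self) -> dict[str, str]:
        """Render every field as a flat ``key=value`` string mapping."""
        return {f.name: repr(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "MachineSpec":
        """Build a spec from ``key=value`` pairs; missing keys take defaults."""
        kwargs: dict[str, float] = {}
        field_names = {f.name for f in dataclasses.fields(cls)}
        for key, raw in mapping.items():
            if key in field_names:
                value = float(raw)
                if key in ("n_leaves", "fp_per_rotation"):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def default_spec() -> MachineSpec:
    """Return the study machine: 64 leaves, 50 firing positions per rotation,
    60 RPM, 2.1 mm couch steps, 1000 MU/min, 40 x 2 cm jaw setting."""
    return MachineSpec()


def firing_frequency(spec: MachineSpec) -> float:
    """Aperture updates per second: ``gantry_rpm / 60 * fp_per_rotation``."""
    return spec.gantry_rpm / 60.0 * spec.fp_per_rotation


def mu_per_firing_position(spec: MachineSpec) -> float:
    """The constant MU quantum delivered at every non-skipped firing position.

    ``nominal_dose_rate / (gantry_rpm * fp_per_rotation)``; a machine-level
    constant shared by all plans and deliveries.
    """
    return spec.nominal_dose_rate / (spec.gantry_rpm * spec.fp_per_rotation)


def gantry_angle_of(firing_index: int, start_angle: float, spec: MachineSpec) -> float:
    """Gantry angle (degrees in [0, 360)) of a firing position.

    ``(start_angle + firing_index * 360/fp_per_rotation) mod 360``.

    Raises
    ------
    ValueError
        If ``firing_index`` is outside ``[0, fp_per_rotation)``.
    """
    if not 0 <= firing_index < spec.fp_per_rotation:
        raise ValueError(
            f"firing_index {firing_index} out of range [0, {spec.fp_per_rotation})"
        )
    return (start_angle + firing_index * spec.sector_deg) % 360.0
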