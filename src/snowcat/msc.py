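"""Marine Snow Catcher (MSC) fraction accounting.

The MSC is a large (~100 L) closing water sampler that is left standing on
deck after recovery so that particles partition by settling velocity:
fast-sinking particles collect on a small bottom plate (~243 mL), slow-sinking
material in a 7 L base compartment, and the non-sinking fraction (free-living
cells plus suspended particles) remains in the upper volume.  Quantities
measured on the concentrated plate sample therefore have to be (i) corrected
for any handling dilution, (ii) stripped of the ambient non-sinking signal
carried over in the plate seawater, and (iii) re-expressed per litre of the
water column actually sampled by the catcher.

This module also provides a lumped-capacitance model of on-deck warming of
the sampler during the settling period, used to bound the thermal artefact of
deck incubation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "FRACTION_TAGS",
    "MscGeometry",
    "FractionMeasurement",
    "ThermalParams",
    "undilute",
    "deconvolve_fast_sinking",
    "concentration_factor",
    "estimate_msc_warming",
]

#: Sample provenance tags: Niskin bottle water, the MSC top (both non-sinking)
#: and the fast-sinking particle plate.
FRACTION_TAGS = ("niskin", "nonsink_top", "fast_plate")


@dataclass(frozen=True)
class MscGeometry:
    """Dimensions and working volumes of a Marine Snow Catcher.

    Volumes in litres, lengths in metres.  ``v_plate < v_base < v_total``
    must hold: the plate tray sits inside the base compartment which sits
    inside the full sampler.
    """

    v_total: float = 100.0
    v_base: float = 7.0
    v_plate: float = 0.243
    settle_time_h: float = 2.0
    height_m: float = 1.5
    radius_m: float = 0.3
    wall_thickness_m: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "v_total",
            "v_base",
            "v_plate",
            "settle_time_h",
            "height_m",
            "radius_m",
            "wall_thickness_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"MscGeometry.{name} must be positive")
        if not (self.v_plate < self.v_base < self.v_total):
            raise ValueError(
                "MSC volumes must satisfy v_plate < v_base < v_total, got "
                f"{self.v_plate}, {self.v_base}, {self.v_total}"
            )

    @property
    def wall_area_m2(self) -> float:
        """Full cylinder area (lateral surface plus both end caps)."""
        r, h = self.radius_m, self.height_m
        return 2.0 * math.pi * r * h + 2.0 * math.pi * r * r


@dataclass(frozen=True)
class FractionMeasurement:
    """A per-unit-volume quantity measured on one MSC fraction.

    ``value`` is a concentration-like quantity (e.g. pmol Leu L-1 h-1 or
    cells L-1) in the units named by ``units``.  ``dilution`` >= 1 records any
    handling dilution of the measured sample (value is the *measured*,
    i.e. diluted, quantity).
    """

    fraction: str
    value: float
    units: str = ""
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.fraction not in FRACTION_TAGS:
            raise ValueError(
                f"unknown fraction tag {self.fraction!r}; expected one of {FRACTION_TAGS}"
            )
        if self.value < 0:
            raise ValueError("measurement value must be >= 0")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass(frozen=True)
class ThermalParams:
    """Parameters of the on-deck warming model.

    ``t_initial_c`` is the in-situ water temperature at closing depth,
    ``t_ambient_c`` the deck air temperature.  ``k_wall`` is the thermal
    conductivity of the sampler wall (W m-1 K-1; 0.10 is typical for the
    polypropylene body).
    """

    t_initial_c: float
    t_ambient_c: float
    c_water: float = 4186.0
    mass_water_kg: float = 100.0
    k_wall: float = 0.10

    def __post_init__(self) -> None:
        if self.c_water <= 0 or self.mass_water_kg <= 0 or self.k_wall < 0:
            raise ValueError("c_water and mass_water_kg must be > 0, k_wall >= 0")


def undilute(m: FractionMeasurement) -> FractionMeasurement:
    """Undo a handling dilution: multiply the value by the dilution factor.

    Returns a new measurement with ``dilution`` reset to 1; units unchanged.
    """
    if m.dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    return replace(m, value=m.value * m.dilution, dilution=1.0)


def deconvolve_fast_sinking(
    plate: FractionMeasurement,
    nonsink: FractionMeasurement,
    geometry: MscGeometry = MscGeometry(),
) -> float:
    """Per-litre fast-sinking quantity from plate and ambient measurements.

    The plate slurry contains fast-sinking particles *plus* the ambient
    seawater (non-sinking material) that filled the tray.  The fast-sinking
    signal is the plate concentration in excess of the ambient concentration,
    scaled from the plate volume to the full catcher volume::

        Q_fast = max(0, plate - nonsink) * v_plate / v_total

    The result is expressed per litre of MSC-sampled seawater, in the same
    units as the inputs.  A negative excess (plate below ambient) has no
    physical meaning for a sinking flux and is clamped to zero with a warning.
    """
    if plate.fraction != "fast_plate":
        raise ValueError("plate measurement must carry the 'fast_plate' tag")
    if nonsink.fraction not in ("niskin", "nonsink_top"):
        raise ValueError("ambient measurement must be 'niskin' or 'nonsink_top'")
    if plate.units != nonsink.units:
        raise ValueError(
            f"unit mismatch: plate in {plate.units!r}, ambient in {nonsink.units!r}"
        )
    if plate.dilution != 1.0 or nonsink.dilution != 1.0:
        raise ValueError("undilute() both measurements before deconvolution")
    excess = plate.value - nonsink.value
    if excess < 0:
        warnings.warn(
            "plate value below ambient; clamping fast-sinking signal to 0",
            stacklevel=2,
        )
        excess = 0.0
    return excess * geometry.v_plate / geometry.v_total


def concentration_factor(plate_cells: float, nonsink_cells: float) -> float:
    """Ratio of plate to ambient cell concentration (dimensionless).

    Quantifies how strongly settling concentrates particle-attached cells in
    the plate relative to the surrounding water.
    """
    if nonsink_cells <= 0:
        raise ValueError("ambient cell concentration must be > 0")
    if plate_cells < 0:
        raise ValueError("plate cell concentration must be >= 0")
    return plate_cells / nonsink_cells


def estimate_msc_warming(
    p: ThermalParams,
    geometry: MscGeometry = MscGeometry(),
    duration_h: float | None = None,
) -> float:
    """Water temperature (deg C) after ``duration_h`` hours on deck.

    Lumped-capacitance Newton cooling with a conduction-limited wall (film
    resistances neglected) over the full cylinder area A::

        U = k_wall / wall_thickness
        T(t) = T_amb - (T_amb - T_0) * exp(-U * A * t / (m * c))

    The temperature approaches the deck temperature monotonically; perfect
    insulation (k_wall = 0) returns the initial temperature for any duration.
    Defaults to the geometry's settling time when ``duration_h`` is omitted.
    """
    if duration_h is None:
        duration_h = geometry.settle_time_h
    if duration_h < 0:
        raise ValueError("duration must be >= 0")
    u = p.k_wall / geometry.wall_thickness_m
    rate = u * geometry.wall_area_m2 / (p.mass_water_kg * p.c_water)
    return p.t_ambient_c - (p.t_ambient_c - p.t_initial_c) * math.exp(
        -rate * duration_h * 3600.0
    )
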