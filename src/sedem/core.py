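"""Core SeDeM parameter computation and radius conversion.

The SeDeM expert system characterizes a powder by twelve parameters
grouped into five incidence factors (dimensions, compressibility,
flowability, lubrication/stability and dosage/lubrication).  Each
parameter value ``v``, measured in its physical unit, is mapped onto a
common 0-10 "radius" scale by a fixed linear conversion; 5 is the
minimum acceptable radius.  This module owns the parameter registry,
the conversions (and their inverses), and the derivation of the twelve
parameters from raw replicate measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping

from .measurements import (
    CohesionMeasurement,
    DensityMeasurement,
    FlowTimeMeasurement,
    MoistureMeasurement,
    ReplicateMeasurements,
    ReposeMeasurement,
)

__all__ = [
    "PARAMETER_ORDER",
    "PARAMETER_LABELS",
    "INCIDENCE_GROUPS",
    "RADIUS_DIRECTION",
    "DEFAULT_ICD_DIVISOR",
    "NON_FLOWING_LIMIT_S",
    "ParameterSet",
    "RadiusProfile",
    "densities",
    "derived_ratios",
    "angle_of_repose",
    "cohesion_index",
    "flow_time",
    "to_radius",
    "invert_radius",
    "build_profile",
    "parameters_from_replicate",
]

#: Canonical parameter order; every radius vector, table and diagram uses it.
PARAMETER_ORDER = (
    "Da", "Dc", "Ie", "IC", "Icd", "IH", "alpha", "t", "HR", "H", "Pf", "Itheta",
)

#: Display symbols for reports and diagram axes.
PARAMETER_LABELS = {
    "Da": "Da", "Dc": "Dc", "Ie": "Ie", "IC": "IC", "Icd": "Icd", "IH": "IH",
    "alpha": "α", "t": "t″", "HR": "%HR", "H": "%H", "Pf": "%Pf",
    "Itheta": "Iθ",
}

#: The five incidence factors and their member parameters.
INCIDENCE_GROUPS = {
    "dimensions": ("Da", "Dc"),
    "compressibility": ("Ie", "IC", "Icd"),
    "flowability": ("IH", "alpha", "t"),
    "lubricity_stability": ("HR", "H"),
    "lubricity_dosage": ("Pf", "Itheta"),
}

#: Sign of d(radius)/d(value): +1 for parameters whose radius grows with the
#: value, -1 for reversed scales (worse as the raw value increases).
RADIUS_DIRECTION = {
    "Da": +1, "Dc": +1, "Ie": +1, "IC": +1, "Icd": +1,
    "IH": -1, "alpha": -1, "t": -1, "HR": -1, "H": -1, "Pf": -1,
    "Itheta": +1,
}

#: Hardness (N) per radius unit for the cohesion index.  The 0-200 N limit
#: maps onto the 0-10 radius scale with a divisor of 20.
DEFAULT_ICD_DIVISOR = 20.0

#: A flow time at or beyond this many seconds per 100 g scores radius 0,
#: the same as a powder that does not flow at all.
NON_FLOWING_LIMIT_S = 20.0


@dataclass(frozen=True)
class ParameterSet:
    """The twelve SeDeM parameter values in physical units.

    ``flow_time`` is ``None`` for a powder that does not flow through the
    funnel at all (the non-flowing sentinel).
    """

    Da: float          # bulk density, g/mL
    Dc: float          # tapped density (2500 strokes), g/mL
    Ie: float          # inter-particle porosity, dimensionless
    IC: float          # Carr compressibility index, %
    Icd: float         # cohesion index (mean tablet hardness), N
    IH: float          # Hausner ratio, dimensionless
    alpha: float       # angle of repose, degrees
    flow_time: float | None  # s per 100 g, None = non-flowing
    HR: float          # loss on drying, %
    H: float           # hygroscopicity (24 h at 76 % RH), %
    Pf: float          # particles < 50 um, %
    Itheta: float      # relative homogeneity index, dimensionless

    def __post_init__(self) -> None:
        for pid in PARAMETER_ORDER:
            v = self[pid]
            if v is not None and not math.isfinite(v):
                raise ValueError(f"parameter {pid!r} is not finite: {v!r}")
        if self.Da > self.Dc:
            warnings.warn(
                f"bulk density Da={self.Da:g} exceeds tapped density "
                f"Dc={self.Dc:g}; check the settling measurements",
                stacklevel=3,
            )

    def __getitem__(self, pid: str) -> float | None:
        if pid == "t":
            return self.flow_time
        if pid not in PARAMETER_ORDER:
            raise KeyError(pid)
        return getattr(self, pid)

    def as_dict(self) -> dict[str, float | None]:
        return {pid: self[pid] for pid in PARAMETER_ORDER}


@dataclass(frozen=True)
class RadiusProfile:
    """Twelve radii in canonical order, each on the 0-10 scale."""

    radii: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.radii) != len(PARAMETER_ORDER):
            raise ValueError(
                f"expected {len(PARAMETER_ORDER)} radii, got {len(self.radii)}"
            )
        for pid, r in zip(PARAMETER_ORDER, self.radii):
            if not (0.0 <= r <= 10.0):
                raise ValueError(f"radius {pid}={r!r} outside [0, 10]")
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))

    @classmethod
    def from_dict(cls, radii: Mapping[str, float]) -> "RadiusProfile":
        return cls(tuple(radii[pid] for pid in PARAMETER_ORDER))

    def __getitem__(self, pid: str) -> float:
        return self.radii[PARAMETER_ORDER.index(pid)]

    def __iter__(self) -> Iterator[float]:
        return iter(self.radii)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARAMETER_ORDER, self.radii))

    def mean(self) -> float:
        return sum(self.radii) / len(self.radii)


# ---------------------------------------------------------------------------
# Parameter computation from raw measurements
# ---------------------------------------------------------------------------

def densities(m: DensityMeasurement) -> tuple[float, float]:
    """Bulk and tapped density, Da = P/Va and Dc = P/Vc, in g/mL."""
    if m.poured_volume_ml <= 0 or m.tapped_volume_ml <= 0:
        raise ValueError("settling volumes must be positive")
    return m.sample_mass_g / m.poured_volume_ml, m.sample_mass_g / m.tapped_volume_ml


def derived_ratios(Da: float, Dc: float) -> tuple[float, float, float]:
    """Inter-particle porosity, Carr index (%) and Hausner ratio from the
    bulk/tapped density pair:

        Ie = (Dc - Da) / (Dc * Da)
        IC = 100 * (Dc - Da) / Dc
        IH = Dc / Da
    """
    if Da <= 0 or Dc <= 0:
        raise ValueError("densities must be positive")
    Ie = (Dc - Da) / (Dc * Da)
    IC = 100.0 * (Dc - Da) / Dc
    IH = Dc / Da
    return Ie, IC, IH


def angle_of_repose(m: ReposeMeasurement) -> float:
    """Angle of the powder cone in degrees, tan(α) = h / mean(r)."""
    r = sum(m.base_radii_mm) / len(m.base_radii_mm)
    if r <= 0:
        raise ValueError("mean base radius must be positive")
    return math.degrees(math.atan(m.cone_height_mm / r))


def cohesion_index(m: CohesionMeasurement) -> float:
    """Mean tablet hardness in N; 0 for a powder that cannot be compressed."""
    if not m.compressible:
        return 0.0
    if not m.hardness_n:
        raise ValueError("compressible powder requires at least one hardness value")
    return sum(m.hardness_n) / len(m.hardness_n)


def flow_time(m: FlowTimeMeasurement) -> float | None:
    """Seconds per 100 g, or None for a non-flowing powder."""
    return m.seconds_per_100g


# ---------------------------------------------------------------------------
# Radius conversion
# ---------------------------------------------------------------------------

def _conversion(pid: str, icd_divisor: float):
    # value -> unclamped radius, one entry per canonical parameter
    table = {
        "Da": lambda v: 10.0 * v,
        "Dc": lambda v: 10.0 * v,
        "Ie": lambda v: 10.0 * v / 1.2,
        "IC": lambda v: v / 5.0,
        "Icd": lambda v: v / icd_divisor,
        "IH": lambda v: 5.0 * (3.0 - v),
        "alpha": lambda v: 10.0 - v / 5.0,
        "t": lambda v: 10.0 - v / 2.0,
        "HR": lambda v: 10.0 - v,
        "H": lambda v: 10.0 - v / 2.0,
        "Pf": lambda v: 10.0 - v / 5.0,
        "Itheta": lambda v: 500.0 * v,
    }
    return table[pid]


def to_radius(
    pid: str,
    v: float | None,
    *,
    icd_divisor: float = DEFAULT_ICD_DIVISOR,
    warn_out_of_limits: bool = True,
) -> float:
    """Convert a parameter value in physical units to its 0-10 radius.

    Values outside the tabulated limits clamp to the nearest end of the
    scale (with a warning); the non-flowing sentinel (``v is None`` for
    the flow-time parameter) scores 0.
    """
    if pid not in PARAMETER_ORDER:
        raise KeyError(f"unknown SeDeM parameter: {pid!r}")
    if v is None:
        if pid == "t":
            return 0.0
        raise TypeError(f"parameter {pid!r} has no value")
    r = _conversion(pid, icd_divisor)(float(v))
    if r < 0.0 or r > 10.0:
        if warn_out_of_limits:
            warnings.warn(
                f"{pid} value {v:g} outside the conversion limits; "
                f"radius clamped to [0, 10]",
                stacklevel=2,
            )
        r = min(10.0, max(0.0, r))
    return r


def invert_radius(
    pid: str, r: float, *, icd_divisor: float = DEFAULT_ICD_DIVISOR
) -> float | None:
    """Back-convert a radius to the parameter value that produces it.

    Exact inverse of :func:`to_radius` on the interior of the scale; a
    flow-time radius of 0 maps back to the non-flowing sentinel ``None``
    (a 20 s flow time gives the same radius, but every non-flowing
    determination is reported as radius 0, so that is the faithful
    pre-image).
    """
    if not (0.0 <= r <= 10.0):
        raise ValueError(f"radius {r!r} outside [0, 10]")
    inverses = {
        "Da": lambda x: x / 10.0,
        "Dc": lambda x: x / 10.0,
        "Ie": lambda x: 1.2 * x / 10.0,
        "IC": lambda x: 5.0 * x,
        "Icd": lambda x: icd_divisor * x,
        "IH": lambda x: 3.0 - x / 5.0,
        "alpha": lambda x: 5.0 * (10.0 - x),
        "t": lambda x: None if x == 0.0 else 2.0 * (10.0 - x),
        "HR": lambda x: 10.0 - x,
        "H": lambda x: 2.0 * (10.0 - x),
        "Pf": lambda x: 5.0 * (10.0 - x),
        "Itheta": lambda x: x / 500.0,
    }
    if pid not in inverses:
        raise KeyError(f"unknown SeDeM parameter: {pid!r}")
    return inverses[pid](float(r))


def build_profile(
    p: ParameterSet, *, icd_divisor: float = DEFAULT_ICD_DIVISOR
) -> RadiusProfile:
    """Convert a complete parameter set into its 12-radius profile."""
    return RadiusProfile(
        tuple(
            to_radius(pid, p[pid], icd_divisor=icd_divisor)
            for pid in PARAMETER_ORDER
        )
    )


def parameters_from_replicate(
    rep: ReplicateMeasurements, *, top_diameter_um: float | None = None
) -> ParameterSet:
    """Derive the twelve parameters from one replicate's raw measurements."""
    # local import: granulometry depends on measurement types, not on core
    from . import granulometry

    Da, Dc = densities(rep.density)
    Ie, IC, IH = derived_ratios(Da, Dc)
    table = granulometry.fraction_table(rep.sieve, top_diameter_um=top_diameter_um)
    return ParameterSet(
        Da=Da,
        Dc=Dc,
        Ie=Ie,
        IC=IC,
        Icd=cohesion_index(rep.cohesion),
        IH=IH,
        alpha=angle_of_repose(rep.repose),
        flow_time=flow_time(rep.flow),
        HR=rep.moisture.loss_on_drying_pct,
        H=rep.moisture.hygroscopicity_pct,
        Pf=granulometry.percent_fines(rep.sieve),
        Itheta=granulometry.homogeneity_index(table),
    )
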