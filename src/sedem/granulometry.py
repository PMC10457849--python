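"""Particle-size analysis: sieve fractions, homogeneity index, PSD quantiles.

Two size descriptors feed the SeDeM profile: the percentage of fines
(%Pf, particles below 50 um) and the relative homogeneity index Iθ,
computed from the mass fractions retained on a descending sieve stack.
Independently of the sieve test, laser-diffraction cumulative curves
yield the D10/D50/D90 quantiles and the breadth ratio F' = D90/D10 used
to compare particle-size distributions between suppliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurements import PSDCurve, SieveAnalysis

__all__ = [
    "Fraction",
    "FractionTable",
    "PSDQuantiles",
    "fraction_table",
    "percent_fines",
    "homogeneity_index",
    "psd_quantiles",
]

#: Assumed mean diameter of the pan fraction (< 50 um), the midpoint of
#: the (0, 50) um interval.
PAN_DIAMETER_UM = 25.0


@dataclass(frozen=True)
class Fraction:
    """One granulometric fraction: size interval, mean diameter, percent."""

    lower_um: float
    upper_um: float | None   # None for the open-ended top fraction
    diameter_um: float       # mean particle diameter assigned to the fraction
    percent: float


@dataclass(frozen=True)
class FractionTable:
    """Sieve fractions in stack order (coarse to fine) with the majority
    fraction marked."""

    fractions: tuple[Fraction, ...]
    majority_index: int

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("a fraction table needs at least one fraction")
        if not 0 <= self.majority_index < len(self.fractions):
            raise ValueError("majority_index out of range")
        fmax = max(f.percent for f in self.fractions)
        if self.fractions[self.majority_index].percent != fmax:
            raise ValueError("majority_index must point at the largest fraction")

    @property
    def majority(self) -> Fraction:
        return self.fractions[self.majority_index]


@dataclass(frozen=True)
class PSDQuantiles:
    """Volume-weighted size quantiles (um) and breadth ratio F' = D90/D10."""

    D10: float
    D50: float
    D90: float
    Fprime: float

    def __post_init__(self) -> None:
        if not (0 < self.D10 <= self.D50 <= self.D90):
            raise ValueError("quantiles must satisfy 0 < D10 <= D50 <= D90")


def fraction_table(
    s: SieveAnalysis, *, top_diameter_um: float | None = None
) -> FractionTable:
    """Build the granulometric fraction table from a sieve analysis.

    One fraction per inter-sieve interval plus the open top fraction and
    the pan.  Mean diameters are arithmetic midpoints of the bounding
    apertures; the pan uses the midpoint of (0, 50) um and the top
    fraction uses the largest aperture itself, unless a nominal upper
    bound ``top_diameter_um`` is supplied (then the midpoint of
    (aperture, bound)).  Percentages are renormalized to the recovered
    mass, and empty fractions are dropped.  Ties for the majority
    fraction resolve to the smallest diameter.
    """
    apertures = s.apertures_um
    raw: list[Fraction] = []
    # top fraction: everything above the coarsest sieve
    top_d = (apertures[0] if top_diameter_um is None
             else 0.5 * (apertures[0] + top_diameter_um))
    raw.append(Fraction(apertures[0], top_diameter_um, top_d, s.retained_pct[0]))
    for i in range(1, len(apertures)):
        lo, hi = apertures[i], apertures[i - 1]
        raw.append(Fraction(lo, hi, 0.5 * (lo + hi), s.retained_pct[i]))
    raw.append(Fraction(0.0, apertures[-1],
                        0.5 * apertures[-1], s.pan_pct))

    recovered = sum(f.percent for f in raw)
    if recovered <= 0:
        raise ValueError("sieve analysis recovered no mass")
    fractions = tuple(
        Fraction(f.lower_um, f.upper_um, f.diameter_um,
                 100.0 * f.percent / recovered)
        for f in raw if f.percent > 0
    )
    # smallest diameter wins a tie; fractions run coarse -> fine
    fmax = max(f.percent for f in fractions)
    candidates = [i for i, f in enumerate(fractions) if f.percent == fmax]
    best = min(candidates, key=lambda i: fractions[i].diameter_um)
    return FractionTable(fractions=fractions, majority_index=best)


def percent_fines(s: SieveAnalysis) -> float:
    """%Pf: particles below 50 um.

    The dedicated vibration test (``fines_direct_pct``) takes precedence
    over the pan percentage of the stack test, which underestimates fines
    that adhere to retained material.
    """
    if s.fines_direct_pct is not None:
        return s.fines_direct_pct
    return s.pan_pct


def homogeneity_index(t: FractionTable) -> float:
    """Relative homogeneity index Iθ of a fraction table.

    The percentage of the majority fraction, discounted by the other
    fractions weighted with their diameter distance (um) from it:

        Iθ = Fm / (100 + Σ_n |d_m - d_n| · F_n)        (n ≠ m)

    Iθ is bounded by Fm/100 and approaches it for a powder concentrated
    in a single fraction.
    """
    m = t.majority
    denom = 100.0 + sum(
        abs(m.diameter_um - f.diameter_um) * f.percent
        for i, f in enumerate(t.fractions) if i != t.majority_index
    )
    return m.percent / denom


def _interp_quantile(
    sizes: np.ndarray, cum: np.ndarray, q: float, interpolation: str
) -> float:
    if q < cum[0] or q > cum[-1]:
        raise ValueError(
            f"quantile {q} % outside the measured cumulative range "
            f"[{cum[0]:g}, {cum[-1]:g}] %"
        )
    j = int(np.searchsorted(cum, q, side="left"))
    if cum[j] == q:
        return float(sizes[j])
    x0, x1 = cum[j - 1], cum[j]
    w = (q - x0) / (x1 - x0)
    if interpolation == "loglinear":
        return float(10 ** (np.log10(sizes[j - 1]) * (1 - w) + np.log10(sizes[j]) * w))
    if interpolation == "linear":
        return float(sizes[j - 1] * (1 - w) + sizes[j] * w)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def psd_quantiles(c: PSDCurve, *, interpolation: str = "loglinear") -> PSDQuantiles:
    """D10, D50, D90 and F' = D90/D10 from a cumulative undersize curve.

    Quantiles are interpolated linearly in (log10 size, cumulative %) by
    default, matching the log-spaced grids of laser-diffraction
    instruments; plain linear interpolation is available.
    """
    sizes = np.asarray(c.sizes_um, dtype=float)
    cum = np.asarray(c.cumulative_volume_pct, dtype=float)
    d10, d50, d90 = (_interp_quantile(sizes, cum, q, interpolation)
                     for q in (10.0, 50.0, 90.0))
    return PSDQuantiles(D10=d10, D50=d50, D90=d90, Fprime=d90 / d10)
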