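"""SeDeM indices, incidence summaries, suitability verdict and radar diagram.

Three global indices condense a 12-radius profile:

* parametric index ``IP`` — fraction of radii at or above the acceptable
  value 5;
* parametric profile index ``IPP`` (PP) — arithmetic mean of the radii;
* good compression index ``GCI`` (IGC) — ``IPP`` scaled by the
  reliability factor ``f``, the polygon-to-circle area ratio of the
  diagram.

A powder is judged suitable for direct compression when GCI exceeds 5;
IP and IPP are reported as supporting evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import INCIDENCE_GROUPS, PARAMETER_LABELS, PARAMETER_ORDER, RadiusProfile

__all__ = [
    "DEFAULT_RELIABILITY_FACTOR",
    "IndexSet",
    "IncidenceSummary",
    "Verdict",
    "reliability_factor",
    "indices",
    "incidence_summary",
    "dc_verdict",
    "render_diagram",
    "batch_report",
]

#: Reliability factor used for the standard 12-parameter diagram.  The
#: exact dodecagon/circle area ratio is 3/π ≈ 0.95493; the value 0.952
#: is the rounded constant in established SeDeM practice and reproduces
#: published GCI = IPP x f arithmetic bit-for-bit, so it is the default.
DEFAULT_RELIABILITY_FACTOR = 0.952


@dataclass(frozen=True)
class IndexSet:
    """Global profile indices: IP, IPP, the reliability factor and GCI."""

    IP: float
    IPP: float
    f: float
    GCI: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.IP <= 1.0):
            raise ValueError("IP must lie in [0, 1]")
        if not (0.0 <= self.IPP <= 10.0):
            raise ValueError("IPP must lie in [0, 10]")
        if not (0.0 < self.f <= 1.0):
            raise ValueError("f must lie in (0, 1]")
        if not math.isclose(self.GCI, self.IPP * self.f, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("GCI must equal IPP * f")


@dataclass(frozen=True)
class IncidenceSummary:
    """Mean radius per incidence factor."""

    dimensions: float
    compressibility: float
    flowability: float
    lubricity_stability: float
    lubricity_dosage: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INCIDENCE_GROUPS}


@dataclass(frozen=True)
class Verdict:
    """Direct-compression suitability classification."""

    suitable: bool
    failed_criteria: tuple[str, ...]
    ipp_acceptable: bool   # IPP >= 5, supporting flag
    ip_acceptable: bool    # IP >= 0.5, supporting flag

    @property
    def label(self) -> str:
        return "suitable" if self.suitable else "not_suitable"


def reliability_factor(k: int = 12, *, convention: str = "tabulated") -> float:
    """Polygon/circle area ratio for a k-axis diagram.

    ``convention="tabulated"`` returns the constant 0.952 for the
    standard 12-parameter diagram (and falls back to the exact geometric
    ratio for other k); ``convention="regular-polygon"`` always returns
    the area ratio of the regular k-gon inscribed in its circumscribed
    circle, k·sin(2π/k)/(2π), which approaches 1 as k grows.
    """
    if k < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    if convention == "tabulated" and k == 12:
        return DEFAULT_RELIABILITY_FACTOR
    if convention in ("tabulated", "regular-polygon"):
        return k * math.sin(2.0 * math.pi / k) / (2.0 * math.pi)
    raise ValueError(f"unknown reliability-factor convention {convention!r}")


def indices(p: RadiusProfile, *, f: float | None = None) -> IndexSet:
    """IP, IPP and GCI of a radius profile.

    IP counts radii >= 5 out of 12; IPP is the mean of all 12 radii; GCI
    multiplies IPP by the reliability factor (0.952 unless overridden).
    """
    if f is None:
        f = reliability_factor(len(p.radii))
    ip = sum(1 for r in p.radii if r >= 5.0) / len(p.radii)
    ipp = p.mean()
    return IndexSet(IP=ip, IPP=ipp, f=f, GCI=ipp * f)


def incidence_summary(p: RadiusProfile) -> IncidenceSummary:
    """Unweighted mean radius of each incidence factor's members."""
    values = {
        name: sum(p[pid] for pid in members) / len(members)
        for name, members in INCIDENCE_GROUPS.items()
    }
    return IncidenceSummary(**values)


def dc_verdict(ix: IndexSet, *, gci_limit: float = 5.0) -> Verdict:
    """Classify direct-compression suitability from the index set.

    GCI > 5 (strict) is decisive; IPP >= 5 and IP >= 0.5 are reported as
    supporting flags but do not gate the verdict.
    """
    failed = []
    if not ix.GCI > gci_limit:
        failed.append(f"GCI {ix.GCI:.2f} <= {gci_limit:g}")
    return Verdict(
        suitable=not failed,
        failed_criteria=tuple(failed),
        ipp_acceptable=ix.IPP >= 5.0,
        ip_acceptable=ix.IP >= 0.5,
    )


# ---------------------------------------------------------------------------
# Diagram
# ---------------------------------------------------------------------------

def render_diagram(
    profiles: RadiusProfile | Sequence[RadiusProfile],
    labels: Sequence[str] | None = None,
    out: str | Path | None = None,
    *,
    acceptability: float = 5.0,
    title: str | None = None,
):
    """Draw the 12-axis SeDeM radar diagram for 1-4 profiles.

    Axes follow the canonical parameter order, clockwise from 12
    o'clock; the radial scale runs 0-10 with the minimum-acceptability
    circle drawn at radius 5.  Overlaid profiles are distinguished by
    color and a translucent fill.  Returns the matplotlib figure; saves
    to ``out`` (format from the suffix, e.g. .svg or .png) when given.
    """
    import matplotlib.pyplot as plt

    if isinstance(profiles, RadiusProfile):
        profiles = [profiles]
    if not 1 <= len(profiles) <= 4:
        raise ValueError("render_diagram accepts 1-4 profiles")
    if labels is not None and len(labels) != len(profiles):
        raise ValueError("one label per profile")

    n = len(PARAMETER_ORDER)
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)

    circle = np.linspace(0.0, 2.0 * np.pi, 241)
    ax.plot(circle, np.full_like(circle, acceptability),
            color="0.4", lw=1.0, ls="--", zorder=1,
            gid="sedem-acceptability-circle")

    colors = ["tab:blue", "tab:red", "tab:green", "tab:orange"]
    for i, prof in enumerate(profiles):
        r = np.asarray(prof.radii, dtype=float)
        th = np.concatenate([theta, theta[:1]])
        rr = np.concatenate([r, r[:1]])
        label = labels[i] if labels else None
        ax.plot(th, rr, color=colors[i], lw=1.6, label=label,
                gid=f"sedem-profile-{i}", zorder=3)
        ax.fill(th, rr, color=colors[i], alpha=0.15, zorder=2)

    ax.set_ylim(0.0, 10.0)
    ax.set_rgrids(range(0, 11, 2), angle=90, fontsize=8)
    ax.set_thetagrids(np.degrees(theta),
                      [PARAMETER_LABELS[p] for p in PARAMETER_ORDER])
    if labels:
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=9)
    if title:
        ax.set_title(title, pad=18)
    fig.tight_layout()
    if out is not None:
        try:
            fig.savefig(out)
        except OSError:
            plt.close(fig)
            raise
    return fig


def batch_report(
    p: RadiusProfile, *, f: float | None = None, gci_limit: float = 5.0
) -> dict:
    """JSON-ready summary of one profile: radii, incidences, indices,
    verdict, with display-precision roundings alongside full precision."""
    ix = indices(p, f=f)
    inc = incidence_summary(p)
    verdict = dc_verdict(ix, gci_limit=gci_limit)
    return {
        "radii": p.as_dict(),
        "radii_rounded": {k: round(v, 2) for k, v in p.as_dict().items()},
        "incidences": inc.as_dict(),
        "incidences_rounded": {k: round(v, 2) for k, v in inc.as_dict().items()},
        "IP": ix.IP,
        "IPP": ix.IPP,
        "f": ix.f,
        "GCI": ix.GCI,
        "indices_rounded": {"IP": round(ix.IP, 2), "IPP": round(ix.IPP, 2),
                            "GCI": round(ix.GCI, 2)},
        "verdict": {
            "label": verdict.label,
            "failed_criteria": list(verdict.failed_criteria),
            "ipp_acceptable": verdict.ipp_acceptable,
            "ip_acceptable": verdict.ip_acceptable,
        },
    }
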