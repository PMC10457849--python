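"""Packaged reference tables from the published Linezolid supplier study.

Three suppliers (Glenmarck, USV, UQUIFA) were each characterized on
three pilot-scale and three industrial-scale batches, every parameter in
triplicate.  The package ships the resulting replicate-level radius
tables, the pooled descriptive statistics, the pilot-scale batch
comparison tests, the laser-diffraction quantiles and the
source-comparison incidence summary, so that the whole pipeline can be
exercised and checked against published values without external data.

Raw measurements were not published; :func:`reconstruct_raw_batch`
builds a synthetic raw-measurement record for a batch by inverting the
radius conversions, for use as reader/pipeline fixtures.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib.resources import files

import pandas as pd

from .core import PARAMETER_ORDER, RadiusProfile, invert_radius
from .indices import reliability_factor
from .measurements import (
    CohesionMeasurement,
    DensityMeasurement,
    FlowTimeMeasurement,
    MoistureMeasurement,
    RawBatchRecord,
    ReplicateMeasurements,
    ReposeMeasurement,
    SieveAnalysis,
)

__all__ = [
    "SOURCES",
    "batch_ids",
    "batch_table",
    "replicate_profiles",
    "mean_profile",
    "study_frame",
    "pooled_stats",
    "psd_quantiles_table",
    "stat_tests_pilot",
    "incidence_table",
    "reconstruct_raw_batch",
]

SOURCES = ("Glenmarck", "USV", "UQUIFA")

#: Sieve stack used throughout the study, um.
_STACK = (355.0, 212.0, 100.0, 50.0)


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    return json.loads((files("sedem") / "data" / name).read_text())


def batch_ids(source: str | None = None, scale: str | None = None) -> list[str]:
    """Batch identifiers, optionally filtered by source and/or scale."""
    out = []
    for bid, rec in _load("radius_tables.json")["batches"].items():
        if source is not None and rec["source"] != source:
            continue
        if scale is not None and rec["scale"] != scale:
            continue
        out.append(bid)
    return out


def batch_table(batch_id: str) -> dict:
    """The published table for one batch: per-replicate radii, printed
    means, and the printed IP/PP/IGC columns."""
    batches = _load("radius_tables.json")["batches"]
    if batch_id not in batches:
        raise KeyError(f"unknown batch {batch_id!r}")
    return batches[batch_id]


def replicate_profiles(batch_id: str) -> list[RadiusProfile]:
    """The three replicate radius profiles of a batch."""
    tab = batch_table(batch_id)["radii"]
    n = len(next(iter(tab.values())))
    return [
        RadiusProfile(tuple(tab[pid][i] for pid in PARAMETER_ORDER))
        for i in range(n)
    ]


def mean_profile(batch_id: str, *, printed: bool = False) -> RadiusProfile:
    """Mean radius profile of a batch.

    Computed at full precision from the replicate radii by default;
    ``printed=True`` returns the published 2-decimal mean column instead.
    """
    tab = batch_table(batch_id)
    if printed:
        return RadiusProfile.from_dict(tab["mean"])
    radii = tab["radii"]
    return RadiusProfile(
        tuple(sum(radii[pid]) / len(radii[pid]) for pid in PARAMETER_ORDER)
    )


def study_frame(
    source: str | None = None, scale: str | None = None, *, f: float | None = None
) -> pd.DataFrame:
    """Replicate-level radius table of the published study.

    Same layout as :func:`sedem.stats.study_frame`; PP and IGC are
    recomputed at full precision from the 12 replicate radii.
    """
    if f is None:
        f = reliability_factor(len(PARAMETER_ORDER))
    rows = []
    for bid in batch_ids(source, scale):
        tab = batch_table(bid)
        for i, prof in enumerate(replicate_profiles(bid)):
            row = {"source_id": tab["source"], "batch_id": bid,
                   "scale": tab["scale"], "replicate": i}
            row.update(prof.as_dict())
            row["PP"] = prof.mean()
            row["IGC"] = row["PP"] * f
            rows.append(row)
    return pd.DataFrame(rows)


def pooled_stats(scale: str = "pilot") -> dict:
    """Published pooled statistics [mean, variance, sd, CV%] per source.

    ``scale`` is "pilot", "industrial" or "pooled" (both scales, 18
    replicates)."""
    doc = _load("pooled_stats.json")
    if scale not in ("pilot", "industrial", "pooled"):
        raise KeyError(f"unknown scale {scale!r}")
    return doc[scale]


def psd_quantiles_table() -> dict:
    """Published D10/D50/D90 (um) and F' per source."""
    doc = _load("psd_quantiles.json")
    return {src: dict(zip(doc["columns"], vals))
            for src, vals in doc["sources"].items()}


def stat_tests_pilot() -> dict:
    """Published pilot-scale batch-comparison tests per source:
    [levene_p, anova_F, anova_p], None where not testable."""
    return _load("stat_tests_pilot.json")["sources"]


def incidence_table() -> dict:
    """Published incidence-factor and index summary per source and scale
    ("pilot", "industrial", "average")."""
    doc = _load("incidence_table.json")
    return {k: doc[k] for k in ("pilot", "industrial", "average")}


# ---------------------------------------------------------------------------
# Synthetic raw-measurement reconstruction
# ---------------------------------------------------------------------------

def _sieve_for_homogeneity(itheta: float) -> tuple[tuple[float, ...], float]:
    """Synthetic stack percentages reproducing a target homogeneity index.

    Places the majority mass F in the pan (mean diameter 25 um) and the
    remainder on the coarsest sieve (diameter 355 um, distance 330 um),
    so Iθ = F / (100 + 330 (100 - F)), i.e. F = 33100 Iθ / (1 + 330 Iθ).
    Valid for Iθ > 1/332 (majority must stay in the pan).
    """
    F = 33100.0 * itheta / (1.0 + 330.0 * itheta)
    if not 50.0 < F <= 100.0:
        raise ValueError(
            f"homogeneity index {itheta:g} outside the invertible range "
            "of the two-fraction reconstruction"
        )
    return (100.0 - F, 0.0, 0.0, 0.0), F


def reconstruct_raw_batch(batch_id: str) -> RawBatchRecord:
    """Synthetic raw-measurement record whose derived radii reproduce the
    published replicate radii of a batch.

    Directly measured parameters invert exactly (a 100 g settling sample
    with volumes from the density radii; cone geometry from the repose
    radius; moisture and fines percentages; a sieve stack constructed to
    match the homogeneity index).  The density-derived parameters (Ie,
    IC, IH) are recomputed from the inverted densities, so their radii
    match the published ones only to the 2-decimal printing precision.
    The record is synthetic: it is one of many raw datasets consistent
    with the published radii, not the laboratory's raw data.
    """
    tab = batch_table(batch_id)
    radii = tab["radii"]
    reps = []
    for i in range(len(radii["Da"])):
        r = {pid: radii[pid][i] for pid in PARAMETER_ORDER}
        da = invert_radius("Da", r["Da"])
        dc = invert_radius("Dc", r["Dc"])
        mass = 100.0
        density = DensityMeasurement(
            sample_mass_g=mass,
            poured_volume_ml=mass / da,
            tapped_volume_ml=mass / dc,
        )
        icd = invert_radius("Icd", r["Icd"])
        cohesion = (CohesionMeasurement(hardness_n=(icd,), lubricated=True)
                    if icd > 0 else
                    CohesionMeasurement(compressible=False))
        alpha = invert_radius("alpha", r["alpha"])
        base = 40.0
        repose = ReposeMeasurement(
            cone_height_mm=base * math.tan(math.radians(alpha)),
            base_radii_mm=(base,) * 4,
        )
        flow = FlowTimeMeasurement(seconds_per_100g=invert_radius("t", r["t"]))
        moisture = MoistureMeasurement(
            loss_on_drying_pct=invert_radius("HR", r["HR"]),
            hygroscopicity_pct=invert_radius("H", r["H"]),
        )
        retained, pan = _sieve_for_homogeneity(invert_radius("Itheta", r["Itheta"]))
        sieve = SieveAnalysis(
            retained_pct=retained, pan_pct=pan, apertures_um=_STACK,
            fines_direct_pct=invert_radius("Pf", r["Pf"]),
        )
        reps.append(ReplicateMeasurements(
            density=density, cohesion=cohesion, repose=repose,
            flow=flow, moisture=moisture, sieve=sieve,
        ))
    return RawBatchRecord(
        source_id=tab["source"], batch_id=batch_id, scale=tab["scale"],
        replicates=tuple(reps),
    )
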