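"""Raw powder-characterization measurements and batch I/O.

Domain types for the replicate-level raw data behind a SeDeM
characterization — settling volumes, tablet hardness, repose cone
geometry, funnel flow time, moisture, the 355/212/100/50 um sieve stack
and an optional laser-diffraction cumulative curve — plus readers and
writers for a documented JSON and long-format CSV schema.

Units are fixed by the schema (g, mL, mm, um, s, %) and carried in the
field names; readers reject unknown or missing fields rather than guess.
"""

from __future__ import annotations

import json
import math
from dataclasses import MISSING, dataclass, fields as dc_fields
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

__all__ = [
    "SCALES",
    "SchemaError",
    "DensityMeasurement",
    "CohesionMeasurement",
    "ReposeMeasurement",
    "FlowTimeMeasurement",
    "MoistureMeasurement",
    "SieveAnalysis",
    "PSDCurve",
    "ReplicateMeasurements",
    "RawBatchRecord",
    "read_batches",
    "write_batches",
]

SCALES = ("pilot", "industrial")

#: Allowed excess of (retained + pan) over 100 % before a sieve analysis
#: is rejected; small excess happens through weighing error.
SIEVE_MASS_TOLERANCE_PCT = 1.0


class SchemaError(ValueError):
    """A batch file does not match the documented schema."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite(values: Sequence[float], name: str) -> None:
    _require(all(math.isfinite(v) for v in values), f"{name} must be finite")


@dataclass(frozen=True)
class DensityMeasurement:
    """One settling determination: sample mass and poured/tapped volumes."""

    sample_mass_g: float
    poured_volume_ml: float
    tapped_volume_ml: float  # volume after 2500 strokes

    def __post_init__(self) -> None:
        _finite((self.sample_mass_g, self.poured_volume_ml, self.tapped_volume_ml),
                "density measurement")
        _require(self.sample_mass_g > 0, "sample_mass_g must be > 0")
        _require(0 < self.tapped_volume_ml <= self.poured_volume_ml,
                 "tapped volume must satisfy 0 < Vc <= Va")


@dataclass(frozen=True)
class CohesionMeasurement:
    """Tablet hardness values from the direct-compression cohesion test.

    ``compressible=False`` records a powder from which no tablet could be
    produced even after adding the 3.5 % standard lubricant blend; its
    cohesion index is 0 downstream.
    """

    hardness_n: tuple[float, ...] = ()
    lubricated: bool = False
    compressible: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "hardness_n", tuple(float(h) for h in self.hardness_n))
        _finite(self.hardness_n, "hardness_n")
        _require(all(h >= 0 for h in self.hardness_n), "hardness values must be >= 0")
        if not self.compressible:
            _require(not self.hardness_n,
                     "incompressible powder cannot carry hardness values")


@dataclass(frozen=True)
class ReposeMeasurement:
    """Cone height and the four measured base radii, in mm."""

    cone_height_mm: float
    base_radii_mm: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_radii_mm",
                           tuple(float(r) for r in self.base_radii_mm))
        _finite((self.cone_height_mm, *self.base_radii_mm), "repose measurement")
        _require(self.cone_height_mm >= 0, "cone height must be >= 0")
        _require(len(self.base_radii_mm) == 4, "exactly 4 base radii are required")
        _require(all(r > 0 for r in self.base_radii_mm), "base radii must be > 0")


@dataclass(frozen=True)
class FlowTimeMeasurement:
    """Funnel flow time in s per 100 g; None marks a non-flowing powder."""

    seconds_per_100g: float | None

    def __post_init__(self) -> None:
        if self.seconds_per_100g is not None:
            _finite((self.seconds_per_100g,), "flow time")
            _require(self.seconds_per_100g >= 0, "flow time must be >= 0")


@dataclass(frozen=True)
class MoistureMeasurement:
    """Loss on drying (105 °C to constant weight) and 24 h weight gain at
    76 % relative humidity, both in %."""

    loss_on_drying_pct: float
    hygroscopicity_pct: float

    def __post_init__(self) -> None:
        _finite((self.loss_on_drying_pct, self.hygroscopicity_pct), "moisture")
        _require(self.loss_on_drying_pct >= 0, "loss_on_drying_pct must be >= 0")
        _require(self.hygroscopicity_pct >= 0, "hygroscopicity_pct must be >= 0")


@dataclass(frozen=True)
class SieveAnalysis:
    """Percent retained on each sieve of a descending stack plus the pan.

    ``fines_direct_pct`` holds the dedicated < 50 um vibration test when it
    was run; it takes precedence over ``pan_pct`` for the %Pf parameter,
    because fines adhering to coarser material during the stack test bias
    the pan fraction low.
    """

    retained_pct: tuple[float, ...]
    pan_pct: float
    apertures_um: tuple[float, ...] = (355.0, 212.0, 100.0, 50.0)
    fines_direct_pct: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "retained_pct",
                           tuple(float(x) for x in self.retained_pct))
        object.__setattr__(self, "apertures_um",
                           tuple(float(x) for x in self.apertures_um))
        _finite(self.retained_pct + (self.pan_pct,), "sieve percentages")
        _require(len(self.retained_pct) == len(self.apertures_um),
                 "one retained percentage per sieve aperture")
        _require(all(b < a for a, b in zip(self.apertures_um, self.apertures_um[1:])),
                 "sieve apertures must be strictly decreasing")
        _require(all(0 <= x <= 100 for x in self.retained_pct),
                 "retained percentages must lie in [0, 100]")
        _require(0 <= self.pan_pct <= 100, "pan_pct must lie in [0, 100]")
        total = sum(self.retained_pct) + self.pan_pct
        _require(total <= 100 + SIEVE_MASS_TOLERANCE_PCT,
                 f"retained + pan = {total:.3f} % exceeds 100 % beyond tolerance")
        if self.fines_direct_pct is not None:
            _require(0 <= self.fines_direct_pct <= 100,
                     "fines_direct_pct must lie in [0, 100]")


@dataclass(frozen=True)
class PSDCurve:
    """Cumulative volume-percent undersize curve from laser diffraction."""

    sizes_um: tuple[float, ...]
    cumulative_volume_pct: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes_um", tuple(float(x) for x in self.sizes_um))
        object.__setattr__(self, "cumulative_volume_pct",
                           tuple(float(x) for x in self.cumulative_volume_pct))
        _finite(self.sizes_um + self.cumulative_volume_pct, "PSD curve")
        _require(len(self.sizes_um) == len(self.cumulative_volume_pct) >= 2,
                 "PSD curve needs matching size/cumulative arrays (n >= 2)")
        _require(all(b > a > 0 for a, b in zip(self.sizes_um, self.sizes_um[1:])),
                 "sizes must be positive and strictly increasing")
        cum = self.cumulative_volume_pct
        _require(all(b >= a for a, b in zip(cum, cum[1:])),
                 "cumulative curve must be nondecreasing")
        _require(cum[0] >= 0 and cum[-1] <= 100 + 1e-6,
                 "cumulative percentages must lie in [0, 100]")
        _require(cum[-1] >= 99.0, "cumulative curve must reach ~100 %")


@dataclass(frozen=True)
class ReplicateMeasurements:
    """All raw determinations for one replicate of one batch."""

    density: DensityMeasurement
    cohesion: CohesionMeasurement
    repose: ReposeMeasurement
    flow: FlowTimeMeasurement
    moisture: MoistureMeasurement
    sieve: SieveAnalysis
    psd: PSDCurve | None = None


@dataclass(frozen=True)
class RawBatchRecord:
    """One manufactured batch: identity, scale and replicate measurements."""

    source_id: str
    batch_id: str
    scale: str
    replicates: tuple[ReplicateMeasurements, ...]

    def __post_init__(self) -> None:
        _require(self.scale in SCALES, f"scale must be one of {SCALES}")
        _require(len(self.replicates) >= 1, "at least one replicate is required")
        object.__setattr__(self, "replicates", tuple(self.replicates))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_MEASUREMENT_TYPES: dict[str, type] = {
    "density": DensityMeasurement,
    "cohesion": CohesionMeasurement,
    "repose": ReposeMeasurement,
    "flow": FlowTimeMeasurement,
    "moisture": MoistureMeasurement,
    "sieve": SieveAnalysis,
    "psd": PSDCurve,
}

_LIST_FIELDS = {
    "hardness_n", "base_radii_mm", "retained_pct", "apertures_um",
    "sizes_um", "cumulative_volume_pct",
}
_BOOL_FIELDS = {"lubricated", "compressible"}
_OPTIONAL_FIELDS = {"seconds_per_100g", "fines_direct_pct"}


def _measurement_to_dict(m: Any) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in dc_fields(m):
        v = getattr(m, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def _measurement_from_dict(kind: str, payload: Any, where: str) -> Any:
    cls = _MEASUREMENT_TYPES[kind]
    if not isinstance(payload, dict):
        raise SchemaError(f"{where}: expected an object for {kind!r}")
    expected = {f.name for f in dc_fields(cls)}
    unknown = set(payload) - expected
    if unknown:
        raise SchemaError(f"{where}.{kind}: unknown field(s) {sorted(unknown)}")
    required = {
        f.name for f in dc_fields(cls)
        if f.default is MISSING and f.default_factory is MISSING
    }
    missing = required - set(payload)
    if missing:
        raise SchemaError(f"{where}.{kind}: missing field(s) {sorted(missing)}")
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{where}.{kind}: {exc}") from exc


def _record_to_dict(rec: RawBatchRecord) -> dict[str, Any]:
    reps = []
    for rep in rec.replicates:
        d = {kind: _measurement_to_dict(getattr(rep, kind))
             for kind in _MEASUREMENT_TYPES if getattr(rep, kind) is not None}
        reps.append(d)
    return {
        "source_id": rec.source_id,
        "batch_id": rec.batch_id,
        "scale": rec.scale,
        "replicates": reps,
    }


def _record_from_dict(doc: Any, where: str) -> RawBatchRecord:
    if not isinstance(doc, dict):
        raise SchemaError(f"{where}: expected a batch object")
    for key in ("source_id", "batch_id", "scale", "replicates"):
        if key not in doc:
            raise SchemaError(f"{where}: missing field {key!r}")
    unknown = set(doc) - {"source_id", "batch_id", "scale", "replicates"}
    if unknown:
        raise SchemaError(f"{where}: unknown field(s) {sorted(unknown)}")
    reps = []
    for i, rep_doc in enumerate(doc["replicates"]):
        rwhere = f"{where}.replicates[{i}]"
        if not isinstance(rep_doc, dict):
            raise SchemaError(f"{rwhere}: expected an object")
        unknown = set(rep_doc) - set(_MEASUREMENT_TYPES)
        if unknown:
            raise SchemaError(f"{rwhere}: unknown measurement(s) {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for kind in _MEASUREMENT_TYPES:
            if kind == "psd" and kind not in rep_doc:
                kwargs[kind] = None
                continue
            if kind not in rep_doc:
                raise SchemaError(f"{rwhere}: missing measurement {kind!r}")
            kwargs[kind] = _measurement_from_dict(kind, rep_doc[kind], rwhere)
        reps.append(ReplicateMeasurements(**kwargs))
    try:
        return RawBatchRecord(
            source_id=doc["source_id"], batch_id=doc["batch_id"],
            scale=doc["scale"], replicates=tuple(reps),
        )
    except ValueError as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def write_batches(
    records: Sequence[RawBatchRecord], path: str | Path, format: str | None = None
) -> None:
    """Write batch records to a JSON or long-format CSV file."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {"format": "sedem-batches", "version": 1,
               "batches": [_record_to_dict(r) for r in records]}
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return
    rows = []
    for rec in records:
        for ri, rep in enumerate(rec.replicates):
            for kind in _MEASUREMENT_TYPES:
                m = getattr(rep, kind)
                if m is None:
                    continue
                for fname, v in _measurement_to_dict(m).items():
                    if isinstance(v, list):
                        sval = ";".join(repr(float(x)) for x in v)
                    elif isinstance(v, bool):
                        sval = "true" if v else "false"
                    elif v is None:
                        sval = ""
                    else:
                        sval = repr(float(v))
                    rows.append((rec.source_id, rec.batch_id, rec.scale, ri,
                                 kind, fname, sval))
    frame = pd.DataFrame(rows, columns=["source_id", "batch_id", "scale",
                                        "replicate", "measurement", "field", "value"])
    frame.to_csv(path, index=False)


def _parse_csv_value(fname: str, sval: str, where: str) -> Any:
    if fname in _LIST_FIELDS:
        if sval == "":
            return []
        return [float(x) for x in sval.split(";")]
    if fname in _BOOL_FIELDS:
        if sval not in ("true", "false"):
            raise SchemaError(f"{where}.{fname}: expected true/false, got {sval!r}")
        return sval == "true"
    if sval == "":
        if fname in _OPTIONAL_FIELDS:
            return None
        raise SchemaError(f"{where}.{fname}: empty value")
    return float(sval)


def read_batches(path: str | Path, format: str | None = None) -> list[RawBatchRecord]:
    """Read batch records from a JSON or long-format CSV file.

    Every record is validated against the measurement invariants; a
    violation raises :class:`SchemaError` naming the offending record
    and field.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
        if not isinstance(doc, dict) or "batches" not in doc:
            raise SchemaError(f"{path}: missing top-level 'batches' array")
        return [
            _record_from_dict(b, f"batches[{i}]")
            for i, b in enumerate(doc["batches"])
        ]

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected_cols = ["source_id", "batch_id", "scale", "replicate",
                     "measurement", "field", "value"]
    if list(frame.columns) != expected_cols:
        raise SchemaError(f"{path}: expected columns {expected_cols}")
    records: list[RawBatchRecord] = []
    for (source, batch, scale), grp in frame.groupby(
        ["source_id", "batch_id", "scale"], sort=False
    ):
        where = f"batch {batch!r}"
        reps = []
        for ri, rep_grp in grp.groupby(grp["replicate"].astype(int), sort=True):
            rwhere = f"{where}.replicates[{ri}]"
            payloads: dict[str, dict[str, Any]] = {}
            for _, row in rep_grp.iterrows():
                kind, fname = row["measurement"], row["field"]
                if kind not in _MEASUREMENT_TYPES:
                    raise SchemaError(f"{rwhere}: unknown measurement {kind!r}")
                payloads.setdefault(kind, {})[fname] = _parse_csv_value(
                    fname, row["value"], f"{rwhere}.{kind}")
            kwargs: dict[str, Any] = {}
            for kind in _MEASUREMENT_TYPES:
                if kind not in payloads:
                    if kind == "psd":
                        kwargs[kind] = None
                        continue
                    raise SchemaError(f"{rwhere}: missing measurement {kind!r}")
                payload = payloads[kind]
                if kind == "cohesion":
                    payload.setdefault("hardness_n", [])
                kwargs[kind] = _measurement_from_dict(kind, payload, rwhere)
            reps.append(ReplicateMeasurements(**kwargs))
        try:
            records.append(RawBatchRecord(source_id=source, batch_id=batch,
                                          scale=scale, replicates=tuple(reps)))
        except ValueError as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    return records
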