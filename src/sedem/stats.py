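"""Batch-validation statistics for SeDeM radius tables.

Reproducibility of a powder manufacturing process is judged on the
replicate radii: per-parameter descriptive statistics, a variance
homogeneity check (Levene), and a one-way ANOVA across a chosen grouping
— batches within one source, pilot versus industrial scale, or source
versus source.  A grouping shows "no difference" when every testable
parameter keeps p above the significance level (0.05 by default).

Parameters whose values are identical everywhere (flow time for powders
that never flow; the cohesion index of incompressible sources) carry no
information for the tests and are reported as not testable rather than
silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PARAMETER_ORDER, build_profile, parameters_from_replicate
from .indices import reliability_factor
from .measurements import RawBatchRecord

__all__ = [
    "NotTestableError",
    "DescriptiveStats",
    "ComparisonRow",
    "ValidationReport",
    "GROUPINGS",
    "describe",
    "levene",
    "one_way_anova",
    "study_frame",
    "validation_report",
]

#: Statistic columns run on every parameter plus the two profile indices.
REPORT_COLUMNS = PARAMETER_ORDER + ("PP", "IGC")

GROUPINGS = ("batches_within_source", "pilot_vs_industrial", "source_vs_source")


class NotTestableError(ValueError):
    """The data are degenerate (identical values); the test carries no
    information."""


@dataclass(frozen=True)
class DescriptiveStats:
    """Sample mean, variance and sd (n-1 divisor) and CV%.

    ``cv_pct`` is None when the mean is zero (undefined)."""

    mean: float
    variance: float
    sd: float
    cv_pct: float | None
    n: int


@dataclass(frozen=True)
class ComparisonRow:
    parameter: str
    levene_stat: float | None
    levene_p: float | None
    anova_F: float | None
    anova_p: float | None
    verdict: str   # no_difference | difference | not_testable


@dataclass(frozen=True)
class ValidationReport:
    grouping: str
    group_ids: tuple[str, ...]
    alpha: float
    rows: tuple[ComparisonRow, ...]
    n_tested: int
    overall: str   # no_difference | difference | not_testable

    def to_json(self) -> str:
        doc = {
            "grouping": self.grouping,
            "groups": list(self.group_ids),
            "alpha": self.alpha,
            "n_tested": self.n_tested,
            "overall": self.overall,
            "rows": [
                {
                    "parameter": r.parameter,
                    "levene_stat": r.levene_stat,
                    "levene_p": r.levene_p,
                    "anova_F": r.anova_F,
                    "anova_p": r.anova_p,
                    "verdict": r.verdict,
                }
                for r in self.rows
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [
            f"# Validation report — grouping: {self.grouping}",
            "",
            f"Groups compared: {', '.join(self.group_ids)}  ",
            f"Significance level: α = {self.alpha:g}; "
            f"{self.n_tested} parameters tested (no multiplicity correction).",
            "",
            "| Parameter | Levene p | ANOVA F | ANOVA p | Verdict |",
            "|---|---|---|---|---|",
        ]
        for r in self.rows:
            if r.verdict == "not_testable":
                lines.append(f"| {r.parameter} | NA | NA | NA | not testable |")
            else:
                lines.append(
                    f"| {r.parameter} | {r.levene_p:.4f} | {r.anova_F:.2f} "
                    f"| {r.anova_p:.4f} | {r.verdict.replace('_', ' ')} |"
                )
        lines += ["", f"**Overall: {self.overall.replace('_', ' ')}**", ""]
        return "\n".join(lines)


def describe(values: Sequence[float]) -> DescriptiveStats:
    """Descriptive statistics with the n-1 divisor."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("describe needs at least 2 values")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    sd = float(np.sqrt(var))
    cv = None if mean == 0.0 else 100.0 * sd / abs(mean)
    return DescriptiveStats(mean=mean, variance=var, sd=sd, cv_pct=cv, n=x.size)


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    allv = np.concatenate(gs)
    if np.all(allv == allv[0]):
        raise NotTestableError("all values identical; nothing to test")
    return gs


def levene(
    groups: Sequence[Sequence[float]], *, center: str = "median"
) -> tuple[float, float]:
    """Levene variance-homogeneity test across groups.

    The default median centering (Brown–Forsythe) matches the variance
    check used by common stats packages for these data; classical
    mean-centered Levene is available with ``center="mean"``.
    """
    gs = _check_groups(groups)
    if center not in ("median", "mean"):
        raise ValueError(f"unknown Levene center {center!r}")
    stat, p = sps.levene(*gs, center=center)
    return float(stat), float(p)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F with df (k-1, N-k) and its p-value."""
    gs = _check_groups(groups)
    if all(np.all(g == g[0]) for g in gs):
        raise NotTestableError("zero within-group variance; F undefined")
    # identical groups give F = 0, p = 1 naturally
    F, p = sps.f_oneway(*gs)
    return float(F), float(p)


# ---------------------------------------------------------------------------
# Study frame and validation report
# ---------------------------------------------------------------------------

def study_frame(
    records: Sequence[RawBatchRecord],
    *,
    icd_divisor: float = 20.0,
    f: float | None = None,
) -> pd.DataFrame:
    """Replicate-level radius table for a set of batches.

    One row per replicate with identity columns (source_id, batch_id,
    scale, replicate) and one column per parameter radius, plus the
    per-replicate profile mean PP and good-compression index IGC.
    """
    if f is None:
        f = reliability_factor(len(PARAMETER_ORDER))
    rows = []
    for rec in records:
        for ri, rep in enumerate(rec.replicates):
            profile = build_profile(parameters_from_replicate(rep),
                                    icd_divisor=icd_divisor)
            row = {"source_id": rec.source_id, "batch_id": rec.batch_id,
                   "scale": rec.scale, "replicate": ri}
            row.update(profile.as_dict())
            row["PP"] = profile.mean()
            row["IGC"] = row["PP"] * f
            rows.append(row)
    return pd.DataFrame(rows)


_GROUP_COLUMN = {
    "batches_within_source": "batch_id",
    "pilot_vs_industrial": "scale",
    "source_vs_source": "source_id",
}


def validation_report(
    frame: pd.DataFrame | Sequence[RawBatchRecord],
    grouping: str,
    *,
    alpha: float = 0.05,
    levene_center: str = "median",
    columns: Sequence[str] = REPORT_COLUMNS,
) -> ValidationReport:
    """Run the per-parameter Levene + ANOVA comparison for a grouping.

    ``frame`` is a replicate radius table from :func:`study_frame` (raw
    batch records are converted automatically).  Groupings:

    * ``batches_within_source`` — replicates grouped by batch; the frame
      must hold a single source (batch reproducibility);
    * ``pilot_vs_industrial`` — replicates pooled by scale for a single
      source (scale transposition);
    * ``source_vs_source`` — replicates pooled by source across scales
      (supplier comparison).
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    if not isinstance(frame, pd.DataFrame):
        frame = study_frame(frame)
    col = _GROUP_COLUMN[grouping]
    if grouping in ("batches_within_source", "pilot_vs_industrial"):
        sources = frame["source_id"].unique()
        if len(sources) != 1:
            raise ValueError(
                f"grouping {grouping!r} expects a single source, got {list(sources)}"
            )
    group_ids = tuple(str(g) for g in pd.unique(frame[col]))
    if len(group_ids) < 2:
        raise ValueError(f"grouping {grouping!r} needs >= 2 groups, "
                         f"got {list(group_ids)}")
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"frame lacks parameter column(s) {missing}")

    rows = []
    for param in columns:
        groups = [frame.loc[frame[col] == g, param].to_numpy() for g in group_ids]
        try:
            lstat, lp = levene(groups, center=levene_center)
            F, p = one_way_anova(groups)
        except NotTestableError:
            rows.append(ComparisonRow(param, None, None, None, None, "not_testable"))
            continue
        verdict = "no_difference" if p > alpha else "difference"
        rows.append(ComparisonRow(param, lstat, lp, F, p, verdict))

    testable = [r for r in rows if r.verdict != "not_testable"]
    if not testable:
        overall = "not_testable"
    elif all(r.verdict == "no_difference" for r in testable):
        overall = "no_difference"
    else:
        overall = "difference"
    return ValidationReport(
        grouping=grouping, group_ids=group_ids, alpha=alpha,
        rows=tuple(rows), n_tested=len(testable), overall=overall,
    )
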