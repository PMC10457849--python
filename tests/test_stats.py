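"""Descriptive statistics, Levene, one-way ANOVA, validation reports."""

import json

import numpy as np
import pandas as pd
import pytest

import sedem
from sedem import (
    NotTestableError,
    describe,
    fixtures,
    levene,
    one_way_anova,
    validation_report,
)
from sedem.stats import study_frame


def _batch_groups(frame, param):
    return [frame.loc[frame.batch_id == b, param].to_numpy()
            for b in frame.batch_id.unique()]


def test_describe_reproduces_published_pooled_row(pilot_frames):
    d = describe(pilot_frames["Glenmarck"]["Da"])
    assert round(d.mean, 4) == 4.1767
    assert round(d.variance, 4) == 0.0038
    assert round(d.sd, 4) == 0.0616
    assert round(d.cv_pct, 4) == 1.4759
    assert d.n == 9


def test_describe_trivial_cases():
    d = describe([1, 1, 1])
    assert (d.mean, d.variance, d.sd, d.cv_pct) == (1.0, 0.0, 0.0, 0.0)
    d = describe([2, 4])
    assert d.mean == 3.0 and d.variance == 2.0
    assert d.sd == pytest.approx(np.sqrt(2))
    assert d.cv_pct == pytest.approx(47.1405, abs=1e-4)


def test_describe_zero_mean_flags_cv():
    assert describe([-1.0, 1.0]).cv_pct is None


def test_describe_needs_two_values():
    with pytest.raises(ValueError):
        describe([1.0])


def test_describe_matches_two_pass_oracle():
    rng = np.random.default_rng(99)
    for _ in range(20):
        x = rng.normal(5, 2, size=rng.integers(2, 40))
        d = describe(x)
        n = len(x)
        mean = sum(x) / n
        var = sum((v - mean) ** 2 for v in x) / (n - 1)
        assert d.mean == pytest.approx(mean, abs=1e-12)
        assert d.variance == pytest.approx(var, abs=1e-12)


def test_levene_reproduces_published_variance_checks(pilot_frames):
    """Median-centred Levene reproduces the published variance-check
    p-values for the Glenmarck pilot batches to 4 decimals."""
    frame = pilot_frames["Glenmarck"]
    for param, want in [("IC", 0.6607), ("Da", 0.5787), ("Dc", 0.9796)]:
        _, p = levene(_batch_groups(frame, param))
        assert round(p, 4) == want, param


def test_levene_symmetric_spreads():
    _, p = levene([[0.0, 1.0, 2.0], [5.0, 6.0, 7.0]])
    assert p > 0.99


def test_levene_detects_tenfold_spread():
    rng = np.random.default_rng(7)
    a = rng.normal(0, 1, 50)
    b = rng.normal(0, 10, 50)
    _, p = levene([a, b])
    assert p < 0.01


def test_levene_center_config():
    frame = sedem.fixtures.study_frame("Glenmarck", "pilot")
    groups = _batch_groups(frame, "IC")
    _, p_med = levene(groups, center="median")
    _, p_mean = levene(groups, center="mean")
    assert p_med != p_mean
    with pytest.raises(ValueError):
        levene(groups, center="trimmed")


def test_anova_reproduces_published_cells(pilot_frames):
    frame = pilot_frames["Glenmarck"]
    F, p = one_way_anova(_batch_groups(frame, "IC"))
    assert round(F, 2) == 3.02
    assert round(p, 4) == 0.1236
    _, p = one_way_anova(_batch_groups(frame, "Da"))
    assert round(p, 4) == 0.9934


def test_anova_identical_groups():
    F, p = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert F == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_degenerate_data_not_testable():
    with pytest.raises(NotTestableError):
        one_way_anova([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(NotTestableError):
        levene([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(NotTestableError):
        one_way_anova([[1.0, 1.0], [2.0, 2.0]])  # zero within-group variance


def test_anova_affine_invariance():
    """F is unchanged by any affine rescaling — statistics on radii equal
    statistics on raw values for linear conversions."""
    rng = np.random.default_rng(21)
    groups = [rng.normal(m, 1, 6) for m in (0.0, 0.4, 0.9)]
    F0, _ = one_way_anova(groups)
    F1, _ = one_way_anova([10.0 * g for g in groups])          # e.g. density
    F2, _ = one_way_anova([10.0 - g / 5.0 for g in groups])    # reversed scale
    assert F1 == pytest.approx(F0, rel=1e-9)
    assert F2 == pytest.approx(F0, rel=1e-9)


def test_anova_type_one_error_calibrated():
    """Under H0 (equal means, normal noise) the 3x3 ANOVA rejects at
    alpha = 0.05 in 5 % +- 1.5 % of 1000 seeded repetitions."""
    from scipy.stats import f_oneway
    rng = np.random.default_rng(12345)
    x = rng.normal(0.0, 1.0, size=(1000, 3, 3))
    _, p = f_oneway(x[:, 0, :], x[:, 1, :], x[:, 2, :], axis=1)
    rate = float((p < 0.05).mean())
    assert 0.035 <= rate <= 0.065


# ---------------------------------------------------------------------------
# Validation reports
# ---------------------------------------------------------------------------

def test_batch_reproducibility_of_published_pilot_sources(pilot_frames):
    """Every published source shows no significant batch-to-batch
    difference at the pilot scale (p > 0.05 on every testable row)."""
    for src, frame in pilot_frames.items():
        report = validation_report(frame, "batches_within_source")
        assert report.overall == "no_difference", src


def test_not_testable_rows_mirror_published_footnotes(pilot_frames):
    rows = {r.parameter: r.verdict
            for r in validation_report(pilot_frames["USV"],
                                       "batches_within_source").rows}
    assert rows["t"] == "not_testable"       # no source flows
    assert rows["Icd"] == "not_testable"     # USV is incompressible
    assert rows["Da"] != "not_testable"


def test_source_comparison_flags_differences():
    frame = pd.concat([fixtures.study_frame("Glenmarck"),
                       fixtures.study_frame("UQUIFA")], ignore_index=True)
    report = validation_report(frame, "source_vs_source")
    verdicts = {r.parameter: r.verdict for r in report.rows}
    for pid in ("Da", "Dc", "IC", "IH", "Pf", "Itheta", "PP", "IGC"):
        assert verdicts[pid] == "difference", pid
    assert report.overall == "difference"


def test_scale_transposition_of_published_sources():
    for src in fixtures.SOURCES:
        report = validation_report(fixtures.study_frame(src),
                                   "pilot_vs_industrial")
        assert report.grouping == "pilot_vs_industrial"
        assert {r.parameter for r in report.rows} >= set(sedem.PARAMETER_ORDER)


def test_self_comparison_shows_no_difference(pilot_frames):
    a = pilot_frames["Glenmarck"].copy()
    b = a.copy()
    b["source_id"] = "Glenmarck-copy"
    report = validation_report(pd.concat([a, b], ignore_index=True),
                               "source_vs_source")
    assert report.overall == "no_difference"
    for r in report.rows:
        if r.verdict != "not_testable":
            assert r.anova_p == pytest.approx(1.0)


def test_grouping_preconditions(pilot_frames):
    both = pd.concat(pilot_frames.values(), ignore_index=True)
    with pytest.raises(ValueError, match="single source"):
        validation_report(both, "batches_within_source")
    with pytest.raises(ValueError, match=">= 2 groups"):
        validation_report(pilot_frames["Glenmarck"], "pilot_vs_industrial")
    with pytest.raises(ValueError, match="grouping"):
        validation_report(both, "by_moon_phase")


def test_report_serialization(pilot_frames):
    report = validation_report(pilot_frames["Glenmarck"],
                               "batches_within_source")
    doc = json.loads(report.to_json())
    assert doc["overall"] == "no_difference"
    assert len(doc["rows"]) == 14  # 12 parameters + PP + IGC
    md = report.to_markdown()
    assert "| Da |" in md and "not testable" in md


def test_study_frame_from_raw_records():
    recs = [fixtures.reconstruct_raw_batch(b) for b in ("GL-1", "GL-2", "GL-3")]
    frame = study_frame(recs)
    assert len(frame) == 9
    printed = fixtures.study_frame("Glenmarck", "pilot")
    # directly inverted parameters agree exactly with the printed radii
    for pid in ("Da", "Dc", "Icd", "alpha", "HR", "H", "Pf", "Itheta"):
        assert np.allclose(frame[pid], printed[pid], atol=1e-9), pid
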