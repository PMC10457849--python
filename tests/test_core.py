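"""Parameter computation and radius conversion."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import sedem
from sedem import (
    PARAMETER_ORDER,
    CohesionMeasurement,
    DensityMeasurement,
    ParameterSet,
    ReposeMeasurement,
    angle_of_repose,
    build_profile,
    cohesion_index,
    densities,
    derived_ratios,
    invert_radius,
    to_radius,
)
from sedem.core import RADIUS_DIRECTION

finite = st.floats(allow_nan=False, allow_infinity=False, width=32)


@pytest.mark.parametrize(
    "mass,va,vc,da,dc",
    [
        (100.0, 239.2, 185.2, 0.418, 0.540),
        (50.0, 50.0, 50.0, 1.0, 1.0),
        (100.0, 400.0, 250.0, 0.25, 0.40),
    ],
)
def test_densities(mass, va, vc, da, dc):
    m = DensityMeasurement(sample_mass_g=mass, poured_volume_ml=va,
                           tapped_volume_ml=vc)
    got = densities(m)
    assert got[0] == pytest.approx(da, abs=5e-4)
    assert got[1] == pytest.approx(dc, abs=5e-4)
    assert got[0] <= got[1]


def test_density_invariants_rejected():
    with pytest.raises(ValueError):
        DensityMeasurement(sample_mass_g=0, poured_volume_ml=1, tapped_volume_ml=1)
    with pytest.raises(ValueError):
        DensityMeasurement(sample_mass_g=10, poured_volume_ml=100,
                           tapped_volume_ml=120)  # tapped > poured


@pytest.mark.parametrize(
    "da,dc,ie,ic,ih",
    [
        (0.418, 0.540, 0.5405, 22.59, 1.2919),
        (0.7, 0.7, 0.0, 0.0, 1.0),
        (0.25, 0.40, 1.5, 37.5, 1.6),
    ],
)
def test_derived_ratios(da, dc, ie, ic, ih):
    got = derived_ratios(da, dc)
    assert got[0] == pytest.approx(ie, abs=5e-4)
    assert got[1] == pytest.approx(ic, abs=5e-3)
    assert got[2] == pytest.approx(ih, abs=5e-5)


def test_derived_ratio_radii_match_published_means():
    # bulk/tapped densities back-converted from published mean radii
    ie, ic, ih = derived_ratios(0.418, 0.540)
    assert to_radius("Ie", ie) == pytest.approx(4.51, abs=0.01)
    assert to_radius("IC", ic) == pytest.approx(4.52, abs=0.01)
    assert to_radius("IH", ih) == pytest.approx(8.54, abs=0.01)


@given(da=st.floats(0.05, 1.0), dc=st.floats(0.05, 1.0))
@settings(derandomize=True, max_examples=100)
def test_ratio_internal_consistency(da, dc):
    """Carr index and Hausner ratio are algebraically linked:
    IH = 1/(1 - IC/100)."""
    _, ic, ih = derived_ratios(da, dc)
    assert ih == pytest.approx(1.0 / (1.0 - ic / 100.0), rel=1e-9)


@pytest.mark.parametrize(
    "h,radii,alpha,radius",
    [
        (40.0, (40.0,) * 4, 45.0, 1.0),
        (0.0, (40.0,) * 4, 0.0, 10.0),
        (35.4, (40.0,) * 4, 41.51, 1.70),
    ],
)
def test_angle_of_repose(h, radii, alpha, radius):
    m = ReposeMeasurement(cone_height_mm=h, base_radii_mm=radii)
    a = angle_of_repose(m)
    assert a == pytest.approx(alpha, abs=5e-3)
    assert to_radius("alpha", a) == pytest.approx(radius, abs=5e-3)


def test_repose_invariants():
    with pytest.raises(ValueError):
        ReposeMeasurement(cone_height_mm=10, base_radii_mm=(0.0, 40, 40, 40))
    with pytest.raises(TypeError):
        ReposeMeasurement(cone_height_mm=10)  # radii are mandatory


@pytest.mark.parametrize(
    "m,icd,radius",
    [
        (CohesionMeasurement(compressible=False), 0.0, 0.0),
        (CohesionMeasurement(hardness_n=(37.1,)), 37.1, 1.855),
        (CohesionMeasurement(hardness_n=(30, 40, 41)), 37.0, 1.85),
    ],
)
def test_cohesion_index(m, icd, radius):
    got = cohesion_index(m)
    assert got == pytest.approx(icd, abs=1e-9)
    assert to_radius("Icd", got) == pytest.approx(radius, abs=1e-9)


@pytest.mark.parametrize(
    "pid,v,r",
    [
        ("Da", 0.418, 4.18),
        ("IH", 3.0, 0.0),
        ("IH", 1.0, 10.0),
        ("Itheta", 0.019, 9.5),
        ("t", None, 0.0),
        ("t", 20.0, 0.0),
        ("HR", 0.0, 10.0),
        ("Pf", 50.0, 0.0),
        ("H", 20.0, 0.0),
        ("Ie", 1.2, 10.0),
        ("IC", 50.0, 10.0),
        ("Icd", 200.0, 10.0),
    ],
)
def test_to_radius_examples(pid, v, r):
    assert to_radius(pid, v) == pytest.approx(r, abs=1e-9)


def test_to_radius_clamps_with_warning():
    with pytest.warns(UserWarning, match="clamped"):
        assert to_radius("Itheta", 0.05) == 10.0
    with pytest.warns(UserWarning, match="clamped"):
        assert to_radius("HR", 15.0) == 0.0
    with pytest.warns(UserWarning, match="clamped"):
        assert to_radius("t", 25.0) == 0.0


def test_to_radius_unknown_parameter():
    with pytest.raises(KeyError):
        to_radius("XX", 1.0)


@given(v=finite)
@settings(derandomize=True, max_examples=200)
def test_radius_always_in_bounds(v):
    """Any finite input clamps into [0, 10] for every parameter."""
    import warnings
    for pid in PARAMETER_ORDER:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = to_radius(pid, float(v))
        assert 0.0 <= r <= 10.0


@pytest.mark.parametrize("pid", PARAMETER_ORDER)
def test_radius_monotone_in_value(pid):
    """Each conversion is monotone with the direction of its limit scale."""
    import numpy as np
    import warnings
    lo, hi = {
        "Da": (0, 1), "Dc": (0, 1), "Ie": (0, 1.2), "IC": (0, 50),
        "Icd": (0, 200), "IH": (1, 3), "alpha": (0, 50), "t": (0, 20),
        "HR": (0, 10), "H": (0, 20), "Pf": (0, 50), "Itheta": (0, 0.02),
    }[pid]
    grid = np.linspace(lo, hi, 41)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        radii = [to_radius(pid, v) for v in grid]
    diffs = np.diff(radii) * RADIUS_DIRECTION[pid]
    assert (diffs >= -1e-12).all()


@pytest.mark.parametrize("pid", [p for p in PARAMETER_ORDER if p != "t"])
def test_invert_radius_round_trip(pid):
    import numpy as np
    for r in np.linspace(0.0, 10.0, 21):
        v = invert_radius(pid, float(r))
        assert to_radius(pid, v) == pytest.approx(r, abs=1e-9)


def test_invert_flow_radius():
    assert invert_radius("t", 0.0) is None
    assert to_radius("t", invert_radius("t", 4.0)) == pytest.approx(4.0)


def _parameter_set_from_radii(radii):
    values = {pid: invert_radius(pid, r) for pid, r in
              zip(PARAMETER_ORDER, radii)}
    values["flow_time"] = values.pop("t")
    return ParameterSet(**values)


def test_build_profile_reproduces_published_batch_means():
    """Back-converted mean parameters of the first published Glenmarck
    batch round-trip into the published radii (derived parameters to the
    printing precision of the density radii)."""
    printed = (4.18, 5.40, 4.51, 4.52, 1.85, 8.54, 1.68, 0.00,
               9.79, 9.99, 7.57, 4.18)
    p = _parameter_set_from_radii(printed)
    profile = build_profile(p)
    for pid, want in zip(PARAMETER_ORDER, printed):
        assert profile[pid] == pytest.approx(want, abs=0.011), pid


def test_build_profile_best_limits_give_full_circle():
    p = ParameterSet(Da=1.0, Dc=1.0, Ie=1.2, IC=50.0, Icd=200.0, IH=1.0,
                     alpha=0.0, flow_time=0.0, HR=0.0, H=0.0, Pf=0.0,
                     Itheta=0.02)
    assert all(r == 10.0 for r in build_profile(p).radii)


def test_parameter_set_warns_when_bulk_exceeds_tapped():
    with pytest.warns(UserWarning, match="exceeds tapped"):
        ParameterSet(Da=0.6, Dc=0.5, Ie=0.1, IC=5, Icd=0, IH=0.9,
                     alpha=40, flow_time=None, HR=1, H=1, Pf=10, Itheta=0.01)


def test_radius_profile_validation():
    with pytest.raises(ValueError):
        sedem.RadiusProfile((1.0,) * 11)
    with pytest.raises(ValueError):
        sedem.RadiusProfile((1.0,) * 11 + (10.5,))
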