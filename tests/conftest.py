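import matplotlib
import pytest

matplotlib.use("Agg")

from sedem import builtin_archetypes, fixtures  # noqa: E402


@pytest.fixture(scope="session")
def pilot_frames():
    """Replicate radius tables of the three published sources, pilot scale."""
    return {src: fixtures.study_frame(src, "pilot") for src in fixtures.SOURCES}


@pytest.fixture(scope="session")
def archetypes():
    return {a.name: a for a in builtin_archetypes()}


@pytest.fixture(autouse=True)
def _ignore_clamp_warnings():
    """Simulated noise legitimately pushes Ie/Itheta past their limits;
    the clamp warning is expected behaviour, not a test failure."""
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*outside the conversion limits.*")
        yield
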