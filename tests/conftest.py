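import pytest

from oxynmr import (
    LineshapeParams,
    default_catalogue,
    make_timecourse,
    packaged_fixture,
    quantify_spectrum,
    render_spectrum,
)

ALL_DAYS = list(range(17))


@pytest.fixture(scope="session")
def cat():
    return default_catalogue()


@pytest.fixture(scope="session")
def anchors():
    return packaged_fixture()


@pytest.fixture(scope="session")
def timecourse(anchors):
    return make_timecourse(anchors, ALL_DAYS)


@pytest.fixture(scope="session")
def clean_spectra(cat, timecourse):
    """Noise-free synthetic spectrum for every fixture day."""
    lp = LineshapeParams()
    return {
        day: render_spectrum(timecourse.row(day), cat, lp, meta={"day": day})
        for day in ALL_DAYS
    }


@pytest.fixture(scope="session")
def clean_quants(cat, clean_spectra):
    """quantify_spectrum on every noise-free day spectrum (lod 0 to expose
    raw channel values)."""
    return {day: quantify_spectrum(sp, cat, lod=0.0) for day, sp in clean_spectra.items()}
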