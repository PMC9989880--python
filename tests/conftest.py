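import numpy as np
import pytest

from shgflux.analysis import (
    build_decay_map,
    detect_guv,
    extract_traces,
    fit_decay,
    normalize_polarization,
    polar_transform,
    segment_rois,
)
from shgflux.synthetic import (
    PRESETS,
    OpticsConfig,
    default_geometry,
    default_schedule,
    generate_movie,
)


@pytest.fixture(scope="session")
def optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def geometry(optics):
    return default_geometry(optics=optics)


@pytest.fixture(scope="session")
def dopc_movie(optics, geometry):
    """Default DOPC:DOPA movie: 30 frames, 60 s period, 64x64 px."""
    return generate_movie(PRESETS["DOPC:DOPA"], geometry, optics,
                          default_schedule(30, 60.0), seed=3)


@pytest.fixture(scope="session")
def dopc_analysis(dopc_movie, optics):
    """Full measurement chain on the session DOPC movie."""
    det = detect_guv(dopc_movie.frames[0], optics.pixel_size,
                     psf_fwhm_um=optics.psf_fwhm)
    prof = normalize_polarization(
        polar_transform(dopc_movie.frames[0], det),
        optics.polarization_angle,
    )
    rois = segment_rois(prof, 25)
    traces, whole = extract_traces(dopc_movie, det, rois)
    fits = [fit_decay(tr) for tr in traces]
    dmap = build_decay_map(fits, rois)
    return {
        "geometry": det,
        "profile": prof,
        "rois": rois,
        "traces": traces,
        "whole": whole,
        "fits": fits,
        "map": dmap,
    }
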