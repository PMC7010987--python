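"""Shared fixtures: the cord preset, schedules, and simulated image series.

The five-image raster series (control and injured) are expensive enough to
share session-wide; they use fixed seeds so every test sees the same
realization.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pvohscan import phantom, scan

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calib():
    return phantom.cord_calibration()


@pytest.fixture(scope="session")
def protocol():
    return scan.ScanProtocol()


@pytest.fixture(scope="session")
def raster_schedule(protocol):
    return scan.build_raster_schedule(protocol)


@pytest.fixture(scope="session")
def line_schedule(protocol):
    return scan.build_line_schedule(protocol)


def simulate_image_series(spec, schedule, calib, seed, n_images=5):
    """Run n successive raster scans sharing one bleach state."""
    state = phantom.new_bleach_state(spec)
    rng = np.random.default_rng(seed)
    images = []
    for k in range(n_images):
        stream, state = phantom.simulate_scan(
            spec, schedule, state, rng, start_time=k * schedule.duration_s)
        images.append(scan.assemble_image(stream, schedule, calib))
    return images


@pytest.fixture(scope="session")
def control_images(raster_schedule, calib):
    return simulate_image_series(phantom.cord_control(seed=42), raster_schedule,
                                 calib, seed=42)


@pytest.fixture(scope="session")
def injured_images(raster_schedule, calib):
    onset = raster_schedule.duration_s  # injury after the first image completes
    return simulate_image_series(phantom.cord_injured(onset, seed=42),
                                 raster_schedule, calib, seed=43)
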