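import numpy as np
import pytest

import pupilshift as ps


@pytest.fixture(scope="session")
def geometry():
    """1920x1080 px, 53.1x29.1 cm display at 93 cm."""
    return ps.ScreenGeometry()


@pytest.fixture(scope="session")
def calib_grid():
    return ps.CALIBRATION_GRID


@pytest.fixture(scope="session")
def valid_grid():
    return ps.VALIDATION_GRID


@pytest.fixture(scope="session")
def field():
    """A moderate artifact field: 0.4 deg/mm, typical of real setups."""
    return ps.make_field(101, eye="left", magnitude=0.4)


@pytest.fixture(scope="session")
def plr_sim(field, calib_grid):
    """One simulated calibration PLR phase with default (low) noise."""
    return ps.simulate_plr_phase(field, calib_grid, seed=202)


@pytest.fixture(scope="session")
def benchmark_model(calib_grid):
    """Model fitted on the benchmark configuration (noise 0.1 deg,
    field 0.4 deg/mm, pupil 2-6 mm)."""
    f = ps.make_field(11, eye="left", magnitude=0.4, noise_sd=0.1)
    cs, cep, _ = ps.simulate_plr_phase(f, calib_grid, seed=21)
    model = ps.fit_psa_model(cs, calib_grid, cep)
    return f, model


def constant_stream(n=1000, pupil=4.0, rate_hz=1000.0, eye="left"):
    t = np.arange(n) * (1000.0 / rate_hz)
    return ps.SampleStream(eye, rate_hz, t, np.zeros(n), np.zeros(n),
                           np.full(n, float(pupil)))
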