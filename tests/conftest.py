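import numpy as np
import pytest

from brainmre import AcquisitionSpec, MediumSpec

# Table-style group media: chronic-progressive MS patients and healthy controls
CONTROL_MEDIUM = MediumSpec(mu=3278.0, alpha=0.2934)
PATIENT_MEDIUM = MediumSpec(mu=2607.0, alpha=0.2756)


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    """Default acquisition: 128x128 @ 1.5 mm, 64 samples over 80 ms."""
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def control_medium() -> MediumSpec:
    return CONTROL_MEDIUM


@pytest.fixture(scope="session")
def patient_medium() -> MediumSpec:
    return PATIENT_MEDIUM


def make_plane_wave_series(
    k_cycles: float,
    frequency: float,
    acq: AcquisitionSpec,
    amplitude: float = 50e-6,
    mask: np.ndarray | None = None,
):
    """Undamped plane shear wave along +x, built directly from the analytic form."""
    from brainmre import WaveFieldSeries

    nr, nc = acq.grid_shape
    x = np.arange(nr)[:, None] * acq.pixel_spacing
    t = np.arange(acq.n_timesteps) * (acq.period / acq.n_timesteps)
    spatial = amplitude * np.exp(-1j * 2 * np.pi * k_cycles * x) * np.ones((1, nc))
    u = np.real(spatial[:, :, None] * np.exp(1j * 2 * np.pi * frequency * t)[None, None, :])
    if mask is None:
        mask = np.ones((nr, nc), dtype=bool)
    return WaveFieldSeries(
        data=u, mask=mask, spacing=acq.pixel_spacing, period=acq.period,
        frequencies=(frequency,),
    )
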