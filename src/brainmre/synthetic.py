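"""Synthetic shear-wave image series and cohort tables.

Stands in for patient data so the full pipeline is testable: wave-image
series are built as superpositions of attenuating plane shear waves in a
homogeneous springpot medium at the four drive frequencies (25, 37.5, 50,
62.5 Hz), with additive white Gaussian displacement noise and an optional
low-spatial-frequency compression-wave contaminant; cohort tables are
independent Gaussian draws per variable from per-group means/SDs.

The default acquisition geometry mirrors a clinical cerebral MRE
protocol: 128x128 matrix over a 192 mm field of view (1.5 mm in-plane
spacing), 64 time samples over one 80 ms vibration period, so the drive
frequencies are harmonics 2, 3, 4 and 5 of the 12.5 Hz base frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from brainmre.springpot import DEFAULT_ETA, springpot_wavenumber

#: Drive frequencies of the multifrequency vibration, Hz.
DEFAULT_FREQUENCIES = (25.0, 37.5, 50.0, 62.5)

#: Default plane-wave propagation directions (unit 2-vectors, row/col):
#: eight evenly spaced azimuths.  Waves enter the ROI from all around, as
#: skull vibrations launch shear waves along the whole head circumference;
#: with strong viscoelastic damping this keeps the displacement SNR
#: workable everywhere in the parenchyma mask.
_SQ = math.sqrt(0.5)
DEFAULT_DIRECTIONS = (
    (1.0, 0.0),
    (_SQ, _SQ),
    (0.0, 1.0),
    (-_SQ, _SQ),
    (-1.0, 0.0),
    (-_SQ, -_SQ),
    (0.0, -1.0),
    (_SQ, -_SQ),
)


@dataclass(frozen=True)
class MediumSpec:
    """Homogeneous springpot medium.

    mu: shear elasticity, Pa; alpha: powerlaw exponent; eta: viscosity,
    Pa.s; rho: density, kg/m^3 (brain tissue: 1000).
    """

    mu: float
    alpha: float
    eta: float = DEFAULT_ETA
    rho: float = 1000.0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(
                f"alpha must lie in [0, 1] (unphysical dispersion otherwise), got {self.alpha}"
            )
        if not self.eta > 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging geometry and temporal sampling of the wave acquisition."""

    grid_shape: tuple[int, int] = (128, 128)
    pixel_spacing: float = 0.0015  # m (192 mm FoV / 128)
    n_timesteps: int = 64
    period: float = 0.08  # s
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    vibration_amplitude: float = 50e-6  # m, in-brain displacement scale

    def __post_init__(self) -> None:
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if not self.vibration_amplitude > 0:
            raise ValueError("vibration_amplitude must be positive")
        if len(self.frequencies) == 0:
            raise ValueError("at least one drive frequency required")
        for f in self.frequencies:
            h = f * self.period
            if abs(h - round(h)) > 1e-9:
                raise ValueError(
                    f"frequency {f} Hz is not a harmonic of 1/period = {1.0 / self.period} Hz"
                )
        max_harmonic = max(int(round(f * self.period)) for f in self.frequencies)
        if self.n_timesteps < 2 * max_harmonic + 1:
            raise ValueError(
                f"n_timesteps={self.n_timesteps} cannot resolve harmonic {max_harmonic}"
            )

    def harmonic_index(self, frequency: float) -> int:
        """Integer harmonic index of a drive frequency (frequency * period)."""
        h = frequency * self.period
        if abs(h - round(h)) > 1e-9:
            raise ValueError(f"{frequency} Hz is not a harmonic of 1/period")
        return int(round(h))


@dataclass
class WaveFieldSeries:
    """Time-resolved scalar displacement field u(x, y, t) with a parenchyma mask.

    data: (rows, cols, time) real array, displacement in m; mask: 2D bool
    (parenchyma = True); spacing: isotropic in-plane pixel spacing, m;
    period: duration of the sampled vibration cycle, s.
    """

    data: np.ndarray
    mask: np.ndarray
    spacing: float
    period: float
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be (rows, cols, time)")
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must match the spatial grid")
        if not self.mask.any():
            raise ValueError("mask must contain at least one parenchyma pixel")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("displacement data must be finite inside the mask")
        if not self.spacing > 0 or not self.period > 0:
            raise ValueError("spacing and period must be positive")

    @property
    def n_timesteps(self) -> int:
        return self.data.shape[2]


def elliptical_mask(grid_shape: tuple[int, int], coverage: float = 0.6) -> np.ndarray:
    """Centered elliptical parenchyma-ROI mask covering ~``coverage`` of the grid.

    Emulates a brain mask that excludes the air outside the head but keeps
    CSF and ventricles inside.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    nr, nc = grid_shape
    # ellipse area pi*a*b = coverage * nr * nc with a/b = nr/nc
    scale = math.sqrt(coverage / math.pi)
    a, b = scale * nr, scale * nc
    r = np.arange(nr)[:, None] - (nr - 1) / 2.0
    c = np.arange(nc)[None, :] - (nc - 1) / 2.0
    return (r / a) ** 2 + (c / b) ** 2 <= 1.0


def simulate_wavefield(
    medium: MediumSpec,
    acq: AcquisitionSpec,
    directions: Sequence[Sequence[float]] = DEFAULT_DIRECTIONS,
    noise_sd: float | None = None,
    seed: int = 0,
    mask: np.ndarray | None = None,
    compression_amplitude_fraction: float = 0.2,
    compression_spatial_frequency: float = 0.05,
) -> WaveFieldSeries:
    """Simulate a time-resolved shear-wave image series in a springpot medium.

    The field is the real part of a superposition of attenuating plane
    waves, one per (frequency, direction) pair::

        u(r, t) = Re sum_f sum_d A exp(i (omega_f t - k*(omega_f) (d . r)))

    where the complex wavenumber obeys ``k*(omega) = omega sqrt(rho/G*)``
    with ``G*`` the springpot modulus of ``medium`` and the root chosen so
    the amplitude decays along each propagation direction.  White Gaussian
    noise of standard deviation ``noise_sd`` (default 2% of the vibration
    amplitude) is added to every space-time sample.

    ``compression_amplitude_fraction`` > 0 adds a slowly varying
    compression-wave contaminant: an undamped plane wave at each drive
    frequency with isotropic spatial frequency
    ``compression_spatial_frequency`` (cycles/m).  The default 0.05
    cycles/m matches the order of a physical compressional wave at these
    frequencies (speed ~1.5 km/s, wavelength tens of meters — far below
    every bandpass lower threshold), exercising the k-space filter stage.

    Reproducible for a fixed ``seed``.
    """
    dirs = np.asarray(directions, dtype=float)
    if dirs.size == 0:
        raise ValueError("directions must be non-empty")
    if dirs.ndim != 2 or dirs.shape[1] != 2:
        raise ValueError("directions must be a list of 2-vectors")
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero direction vector is not allowed")
    dirs = dirs / norms[:, None]
    if noise_sd is None:
        noise_sd = 0.02 * acq.vibration_amplitude
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if compression_amplitude_fraction < 0:
        raise ValueError("compression_amplitude_fraction must be non-negative")

    nr, nc = acq.grid_shape
    if mask is None:
        mask = elliptical_mask(acq.grid_shape)
    mask = np.asarray(mask, dtype=bool)

    rows = np.arange(nr, dtype=float)[:, None] * acq.pixel_spacing
    cols = np.arange(nc, dtype=float)[None, :] * acq.pixel_spacing
    t = np.arange(acq.n_timesteps, dtype=float) * (acq.period / acq.n_timesteps)

    amp = acq.vibration_amplitude
    u = np.zeros((nr, nc, acq.n_timesteps), dtype=float)
    for f in acq.frequencies:
        omega = 2.0 * math.pi * f
        k = springpot_wavenumber(medium.mu, medium.alpha, medium.eta, medium.rho, omega)
        spatial = np.zeros((nr, nc), dtype=complex)
        for d in dirs:
            # distance travelled from the wave's entry edge (>= 0), so the
            # amplitude is A there and decays along the propagation direction
            xi = d[0] * rows + d[1] * cols
            xi = xi - xi.min()
            spatial += amp * np.exp(-1j * k * xi)
        if compression_amplitude_fraction > 0:
            # undamped long-wavelength contaminant along the first direction
            k_comp = 2.0 * math.pi * compression_spatial_frequency
            xi = dirs[0][0] * rows + dirs[0][1] * cols
            spatial += compression_amplitude_fraction * amp * np.exp(-1j * k_comp * xi)
        phases = np.exp(1j * omega * t)
        u += np.real(spatial[:, :, None] * phases[None, None, :])

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        u = u + rng.normal(0.0, noise_sd, size=u.shape)

    return WaveFieldSeries(
        data=u,
        mask=mask,
        spacing=acq.pixel_spacing,
        period=acq.period,
        frequencies=tuple(acq.frequencies),
    )


# --- cohort simulation -------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Per-group Gaussian parameters (mean, SD) for each cohort variable."""

    n: int
    mu_kpa: tuple[float, float]
    alpha: tuple[float, float]
    volume_dm3: tuple[float, float]
    bpf: tuple[float, float]
    age: tuple[float, float]
    edss: tuple[float, float]
    duration_y: tuple[float, float] = (0.0, 0.0)
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2 (group statistics undefined)")
        for name in ("mu_kpa", "alpha", "volume_dm3", "bpf", "age", "edss", "duration_y"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: SD must be non-negative, got {sd}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")


#: Chronic-progressive MS patient group, means (SDs) as published for the
#: study cohort: n = 23 (17 secondary + 6 primary progressive).
PATIENT_GROUP = GroupParams(
    n=23,
    mu_kpa=(2.607, 0.482),
    alpha=(0.2756, 0.0108),
    volume_dm3=(1.513, 0.178),
    bpf=(0.9610, 0.012),
    age=(51.7, 8.0),
    edss=(5.5, 1.4),
    duration_y=(16.0, 8.0),
    female_fraction=13.0 / 23.0,
)

#: Age/gender-matched healthy control group, n = 38.
CONTROL_GROUP = GroupParams(
    n=38,
    mu_kpa=(3.278, 0.314),
    alpha=(0.2934, 0.0086),
    volume_dm3=(1.636, 0.068),
    bpf=(0.9775, 0.008),
    age=(48.0, 9.7),
    edss=(0.0, 0.0),
    duration_y=(0.0, 0.0),
    female_fraction=22.0 / 38.0,
)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-simulation specification: per-group parameters plus a seed."""

    patients: GroupParams = PATIENT_GROUP
    controls: GroupParams = CONTROL_GROUP
    seed: int = 0


def _draw_group(rng: np.random.Generator, params: GroupParams, label: str, start_id: int) -> pd.DataFrame:
    n = params.n
    records = {
        "subject_id": [f"{label[:1].upper()}{start_id + i:03d}" for i in range(n)],
        "group": [label] * n,
        "sex": np.where(rng.random(n) < params.female_fraction, "F", "M"),
        "age": rng.normal(*params.age, size=n),
        "edss": np.clip(rng.normal(*params.edss, size=n), 0.0, 10.0),
        "duration_y": np.clip(rng.normal(*params.duration_y, size=n), 0.0, None),
        "volume_dm3": rng.normal(*params.volume_dm3, size=n),
        "bpf": np.clip(rng.normal(*params.bpf, size=n), 1e-6, 1.0),
        "mu_kpa": rng.normal(*params.mu_kpa, size=n),
        "alpha": rng.normal(*params.alpha, size=n),
    }
    return pd.DataFrame(records)


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort table from per-group Gaussian parameters.

    Each variable is drawn independently per subject from
    Gaussian(mean, SD) of its group; EDSS and BPF are clipped to their
    valid ranges.  Deterministic for a fixed ``spec.seed``.  Column schema
    matches the cohort CSV written by the pipeline: subject_id, group,
    sex, age, edss, duration_y, volume_dm3, bpf, mu_kpa, alpha.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed)
    patients = _draw_group(rng, spec.patients, "patient", 0)
    controls = _draw_group(rng, spec.controls, "control", 0)
    return pd.concat([patients, controls], ignore_index=True)
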