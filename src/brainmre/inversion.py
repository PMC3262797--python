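"""2D algebraic Helmholtz inversion of filtered complex wave images.

For a time-harmonic shear wave in a locally homogeneous, isotropic
medium the displacement obeys the Helmholtz equation
``rho omega^2 U + G* Laplacian(U) = 0``, so the complex shear modulus can
be recovered pointwise as::

    G*(x, y, omega) = -rho omega^2 U / Laplacian(U)

with the Laplacian discretized by the 5-point central-difference stencil.
Pixels where |Laplacian(U)| is small relative to its in-mask median are
excluded (the algebraic division is singular there), the mask is eroded
to suppress boundary stencil artifacts, and the surviving complex values
are averaged over the parenchyma ROI — one dispersion sample per drive
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.ndimage import binary_erosion

if TYPE_CHECKING:  # pragma: no cover
    from brainmre.wave_processing import ComplexWaveField


@dataclass(frozen=True)
class InversionConfig:
    """Parameters of the algebraic inversion.

    rho: tissue density, kg/m^3 (brain: 1000, i.e. 1 kg/dm^3);
    laplacian_tolerance: pixels with |Laplacian U| below this fraction of
    the in-mask median are flagged invalid; mask_erosion: pixels of
    binary erosion applied to the mask before inversion.
    """

    rho: float = 1000.0
    laplacian_tolerance: float = 1e-3
    mask_erosion: int = 1

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.laplacian_tolerance < 0:
            raise ValueError("laplacian_tolerance must be non-negative")
        if self.mask_erosion < 0:
            raise ValueError("mask_erosion must be non-negative")


@dataclass
class ComplexModulusMap:
    """Per-pixel complex shear modulus G*(x, y, omega) with validity flags."""

    data: np.ndarray
    frequency: float
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape != self.valid.shape:
            raise ValueError("data and valid must share a shape")
        if not np.isfinite(self.data[self.valid]).all():
            raise ValueError("modulus must be finite wherever valid")


@dataclass(frozen=True)
class DispersionSample:
    """ROI-averaged complex shear modulus at one drive frequency."""

    frequency: float
    g_star: complex
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("a dispersion sample needs at least one pixel")


def laplacian_2d(field: "ComplexWaveField") -> np.ndarray:
    """Central-difference 5-point Laplacian with physical pixel spacing.

    Returns Laplacian(U) on the interior; the one-pixel boundary ring is
    set to NaN (the stencil does not extend there).  The stencil is exact
    for polynomials up to cubic order; for a plane wave
    exp(-i 2 pi k . r) its eigenvalue is
    ``sum_i (2 cos(2 pi k_i h) - 2) / h^2``, a second-order-accurate
    approximation of ``-(2 pi |k|)^2``.
    """
    u = field.data
    if u.shape[0] < 3 or u.shape[1] < 3:
        raise ValueError("grid must be at least 3x3 for the 5-point stencil")
    h2 = field.spacing**2
    lap = np.full_like(u, np.nan, dtype=complex)
    lap[1:-1, 1:-1] = (
        u[2:, 1:-1] + u[:-2, 1:-1] + u[1:-1, 2:] + u[1:-1, :-2] - 4.0 * u[1:-1, 1:-1]
    ) / h2
    return lap


def stencil_error_bound(wavelength: float, spacing: float) -> float:
    """Relative error of the 5-point stencil on a plane wave of given wavelength.

    For an axis-aligned plane wave the discrete eigenvalue is
    ``(2 cos(kh) - 2)/h^2`` versus the exact ``-k^2``; the relative
    discrepancy ``1 - (2 - 2 cos(kh)) / (kh)^2 ~ (kh)^2 / 12`` bounds the
    bias of the recovered modulus (the recovered G* is scaled by the
    inverse of this factor).
    """
    kh = 2.0 * np.pi * spacing / wavelength
    return float(abs(1.0 - (2.0 - 2.0 * np.cos(kh)) / kh**2))


class InversionError(RuntimeError):
    """Raised when no pixel survives the numerical admissibility guards."""


def helmholtz_invert(
    field: "ComplexWaveField", config: InversionConfig | None = None
) -> ComplexModulusMap:
    """Recover G* = -rho omega^2 U / Laplacian(U) per pixel.

    The mask is eroded by ``config.mask_erosion`` pixels; within the
    eroded mask, pixels with ``|Laplacian U|`` below
    ``laplacian_tolerance * median(|Laplacian U|)`` are flagged invalid
    (division guard).  Raises :class:`InversionError` with diagnostics if
    no pixel is admissible.
    """
    if config is None:
        config = InversionConfig()
    lap = laplacian_2d(field)
    mask = field.mask.copy()
    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False
    if config.mask_erosion > 0:
        mask = binary_erosion(mask, iterations=config.mask_erosion)
    if not mask.any():
        raise InversionError("mask empty after boundary removal and erosion")

    abs_lap = np.abs(lap)
    median_lap = float(np.median(abs_lap[mask]))
    if median_lap == 0.0:
        raise InversionError(
            f"Laplacian vanishes over the mask at {field.frequency} Hz "
            "(field is harmonic-free, e.g. a linear ramp)"
        )
    valid = mask & (abs_lap > config.laplacian_tolerance * median_lap)
    if not valid.any():
        below = float(np.mean(abs_lap[mask] <= config.laplacian_tolerance * median_lap))
        raise InversionError(
            f"no admissible pixel at {field.frequency} Hz: "
            f"{below:.1%} of masked pixels below the Laplacian tolerance"
        )

    omega = field.angular_frequency
    g = np.zeros_like(field.data, dtype=complex)
    g[valid] = -config.rho * omega**2 * field.data[valid] / lap[valid]
    return ComplexModulusMap(data=g, frequency=field.frequency, valid=valid)


def roi_average(
    maps: Sequence[ComplexModulusMap], mask: np.ndarray | None = None
) -> list[DispersionSample]:
    """Average complex G* over valid pixels (optionally further masked).

    Returns one :class:`DispersionSample` per modulus map (one per drive
    frequency); maps at the same frequency (e.g. multiple slices) are
    pooled into a single sample weighted by valid-pixel count.
    """
    by_freq: dict[float, tuple[complex, int]] = {}
    order: list[float] = []
    for m in maps:
        sel = m.valid if mask is None else (m.valid & np.asarray(mask, dtype=bool))
        n = int(sel.sum())
        if n == 0:
            raise ValueError(
                f"no valid pixel within the ROI at {m.frequency} Hz"
            )
        total = complex(m.data[sel].sum())
        if m.frequency in by_freq:
            prev_total, prev_n = by_freq[m.frequency]
            by_freq[m.frequency] = (prev_total + total, prev_n + n)
        else:
            by_freq[m.frequency] = (total, n)
            order.append(m.frequency)
    return [
        DispersionSample(frequency=f, g_star=by_freq[f][0] / by_freq[f][1], n_pixels=by_freq[f][1])
        for f in order
    ]
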