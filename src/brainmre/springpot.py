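"""Springpot (fractional-element) model of the complex shear modulus.

The springpot interpolates between a spring (``alpha = 0``) and a dashpot
(``alpha = 1``)::

    G*(omega) = kappa * (i omega)**alpha,   kappa = mu**(1 - alpha) * eta**alpha

``mu`` (Pa) quantifies the strength of the tissue's mechanical network,
``alpha`` its topology, and ``eta`` (Pa.s) is a viscosity constant fixed
a priori (3.7 Pa.s for human brain) so that fitted shear moduli are
comparable across studies.  Fitting the two free parameters (mu, alpha)
to the ROI-averaged modulus at the drive frequencies is the per-subject
endpoint of the multifrequency MRE pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import least_squares

if TYPE_CHECKING:  # pragma: no cover
    from brainmre.inversion import DispersionSample

#: Viscosity convention constant for human brain parenchyma, Pa.s.
DEFAULT_ETA = 3.7

#: Fixed multi-start grid for the deterministic least-squares fit.
_FIT_STARTS_MU_PA = (1000.0, 3000.0, 10000.0)
_FIT_STARTS_ALPHA = (0.1, 0.3, 0.6)


@dataclass(frozen=True)
class SpringpotFit:
    """Result of a two-parameter springpot dispersion fit.

    Attributes
    ----------
    mu : float
        Shear elasticity, Pa.
    alpha : float
        Powerlaw exponent, dimensionless, in (0, 1).
    kappa : float
        Derived fractional-element constant ``mu**(1-alpha) * eta**alpha``.
    eta : float
        The fixed viscosity constant used, Pa.s.
    residual : float
        Sum of squared complex misfits at the optimum, Pa^2.
    n_freqs : int
        Number of dispersion samples fitted.
    """

    mu: float
    alpha: float
    kappa: float
    eta: float
    residual: float
    n_freqs: int

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        expected = self.mu ** (1.0 - self.alpha) * self.eta**self.alpha
        if not math.isclose(self.kappa, expected, rel_tol=1e-12):
            raise ValueError("kappa inconsistent with (mu, alpha, eta)")
        if self.n_freqs < 2:
            raise ValueError("a springpot fit needs at least 2 frequencies")


def springpot_gstar(
    mu: float, alpha: float, eta: float, omega: float | np.ndarray
) -> complex | np.ndarray:
    """Evaluate the springpot complex shear modulus at angular frequency omega.

    Returns ``kappa * omega**alpha * exp(i alpha pi / 2)`` (principal branch
    of ``i**alpha``), with ``kappa = mu**(1-alpha) * eta**alpha``.

    Parameters
    ----------
    mu : float
        Shear elasticity, Pa; must be positive.
    alpha : float
        Powerlaw exponent in [0, 1].  ``alpha = 0`` gives a pure spring
        (``G* = mu``), ``alpha = 1`` a pure dashpot (``G* = i omega eta``).
    eta : float
        Viscosity constant, Pa.s; must be positive.
    omega : float or ndarray
        Angular frequency, rad/s; must be positive.
    """
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if not eta > 0:
        raise ValueError(f"eta must be positive, got {eta}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    kappa = mu ** (1.0 - alpha) * eta**alpha
    phase = complex(math.cos(alpha * math.pi / 2.0), math.sin(alpha * math.pi / 2.0))
    out = kappa * omega**alpha * phase
    return complex(out) if out.ndim == 0 else out


def springpot_wavenumber(
    mu: float, alpha: float, eta: float, rho: float, omega: float
) -> complex:
    """Complex shear wavenumber ``k*(omega) = omega * sqrt(rho / G*(omega))``.

    The square root is taken on the principal branch and the sign of the
    imaginary part is enforced negative, so that a plane wave
    ``exp(i(omega t - k* x))`` decays along its propagation direction
    (physical attenuating wave).

    Returns k* in rad/m; ``2*pi / Re(k*)`` is the shear wavelength and
    ``1 / |Im(k*)|`` the amplitude 1/e decay length.
    """
    if not rho > 0:
        raise ValueError(f"rho must be positive, got {rho}")
    gstar = springpot_gstar(mu, alpha, eta, omega)
    k = omega * np.sqrt(rho / gstar)
    if k.imag > 0:
        k = np.conj(k)
    return complex(k)


def _residuals(params: np.ndarray, omegas: np.ndarray, g: np.ndarray, eta: float) -> np.ndarray:
    mu, alpha = params
    model = springpot_gstar(mu, alpha, eta, omegas)
    diff = model - g
    return np.concatenate([diff.real, diff.imag])


def fit_springpot(
    samples: Sequence[DispersionSample], eta: float = DEFAULT_ETA
) -> SpringpotFit:
    """Fit (mu, alpha) to ROI-averaged modulus samples by least squares.

    Minimizes the sum of squared complex misfits
    ``sum_f |G*_f - springpot(mu, alpha, eta, 2 pi f)|**2`` jointly over
    the real and imaginary parts, with bounds ``mu > 0`` and
    ``0 < alpha < 1``.  The optimizer is deterministic: bounded
    trust-region least squares launched from a fixed 3x3 grid of starts
    (mu in {1, 3, 10} kPa, alpha in {0.1, 0.3, 0.6}); the lowest residual
    wins, ties broken toward the smallest alpha.

    Parameters
    ----------
    samples : sequence of DispersionSample
        One complex modulus per drive frequency; at least two distinct
        frequencies required.
    eta : float
        Fixed viscosity convention constant, Pa.s (default 3.7, the human
        brain value); never fitted.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 dispersion samples to fit")
    freqs = np.array([s.frequency for s in samples], dtype=float)
    if len(np.unique(freqs)) != len(freqs):
        raise ValueError("dispersion sample frequencies must be distinct")
    g = np.array([s.g_star for s in samples], dtype=complex)
    omegas = 2.0 * math.pi * freqs

    bounds = ([1e-12, 1e-9], [np.inf, 1.0 - 1e-9])
    best: tuple[float, float, float] | None = None  # (residual, alpha, mu)
    any_success = False
    for mu0 in _FIT_STARTS_MU_PA:
        for alpha0 in _FIT_STARTS_ALPHA:
            sol = least_squares(
                _residuals,
                x0=[mu0, alpha0],
                bounds=bounds,
                args=(omegas, g, eta),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if not sol.success:
                continue
            any_success = True
            resid = float(np.sum(sol.fun**2))
            mu_hat, alpha_hat = float(sol.x[0]), float(sol.x[1])
            key = (resid, alpha_hat, mu_hat)
            # strictly better residual, or tie (within fp noise) with smaller alpha
            if best is None or resid < best[0] * (1.0 - 1e-12) or (
                abs(resid - best[0]) <= 1e-12 * max(1.0, best[0]) and alpha_hat < best[1]
            ):
                best = key
    if not any_success or best is None:
        raise RuntimeError(
            "springpot fit did not converge from any start; "
            f"frequencies={freqs.tolist()}, |g|={np.abs(g).tolist()}"
        )
    resid, alpha_hat, mu_hat = best
    kappa = mu_hat ** (1.0 - alpha_hat) * eta**alpha_hat
    return SpringpotFit(
        mu=mu_hat,
        alpha=alpha_hat,
        kappa=kappa,
        eta=eta,
        residual=resid,
        n_freqs=len(samples),
    )


# --- classical comparison models (not used by the headline pipeline) ---


def voigt_gstar(mu: float, eta: float, omega: float | np.ndarray):
    """Kelvin-Voigt model: spring and dashpot in parallel, G* = mu + i omega eta."""
    omega = np.asarray(omega, dtype=float)
    return mu + 1j * omega * eta


def maxwell_gstar(mu: float, eta: float, omega: float | np.ndarray):
    """Maxwell model: spring and dashpot in series."""
    omega = np.asarray(omega, dtype=float)
    return 1j * omega * eta * mu / (mu + 1j * omega * eta)


def zener_gstar(mu1: float, mu2: float, eta: float, omega: float | np.ndarray):
    """Three-parameter Zener (standard linear solid) model.

    A Maxwell arm (mu1, eta) in parallel with a spring mu2.  Provided for
    comparison only; the pipeline's endpoint is the two-parameter
    springpot, which avoids the Zener model's second shear modulus.
    """
    omega = np.asarray(omega, dtype=float)
    return maxwell_gstar(mu1, eta, omega) + mu2
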