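"""Dipolar auto- and cross-relaxation rates for a like-spin (1H-1H) pair.

Rates follow the Solomon / rotating-frame expressions for two identical
spin-1/2 nuclei relaxed by their mutual dipolar interaction under isotropic
rotational diffusion.  The spectral density convention used throughout is

    J(omega) = tau_c / (1 + (omega * tau_c)**2)        [seconds]

i.e. J(0) = tau_c, with *all* numerical prefactors carried by the rate
expressions, not by J.  With the dipolar coupling constant

    d = (mu0 / 4 pi) * gamma_H**2 * hbar / r**3        [rad/s]

and q = d**2 / 10, the rates are

    sigma    = q * (6 J(2 w0) - J(0))            longitudinal (z-z) cross
    mu       = q * (2 J(0) + 3 J(w0))            transverse (x-x, y-y) cross
    rho1_dip = q * (J(0) + 3 J(w0) + 6 J(2 w0))  dipolar contribution to R1
    rho2_dip = q/2 * (5 J(0) + 9 J(w0) + 6 J(2 w0))  dipolar contribution to R2

These reproduce the textbook limits: sigma/rho1 -> 1/2 in extreme narrowing
(positive NOE), sigma -> -q J(0) < 0 and mu -> +2 q J(0) in the slow-tumbling
(spin-diffusion) limit relevant to nucleic-acid duplexes, where |mu| > |sigma|.

Distances are accepted in Angstrom and frequencies in Hz at the interface;
everything is converted to SI / angular units internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# CODATA physical constants (6 significant figures)
GAMMA_H = 2.67522e8  # 1H gyromagnetic ratio, rad s^-1 T^-1
HBAR = 1.05457e-34  # reduced Planck constant, J s
MU0_OVER_4PI = 1.00000e-7  # magnetic constant / 4 pi, T m A^-1

ANGSTROM = 1e-10  # m

__all__ = [
    "TumblingModel",
    "RelaxationRates",
    "spectral_density",
    "dipolar_coupling_constant",
    "dipolar_rates",
]


@dataclass(frozen=True)
class TumblingModel:
    """Isotropic rotational diffusion of the molecule carrying the spin pair.

    Parameters
    ----------
    tau_c : float
        Rotational correlation time in seconds (e.g. 5.1e-9 for a 14-mer
        DNA duplex at 298 K).
    larmor_frequency : float
        1H Larmor frequency in Hz.  Default corresponds to a 600 MHz
        (14.1 T) spectrometer.
    """

    tau_c: float
    larmor_frequency: float = 600.16e6

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau_c) and self.tau_c > 0):
            raise ValueError(f"tau_c must be positive and finite, got {self.tau_c}")
        if not (np.isfinite(self.larmor_frequency) and self.larmor_frequency > 0):
            raise ValueError(
                f"larmor_frequency must be positive and finite, got {self.larmor_frequency}"
            )

    @property
    def omega0(self) -> float:
        """Larmor angular frequency, rad/s."""
        return 2.0 * math.pi * self.larmor_frequency


@dataclass(frozen=True)
class RelaxationRates:
    """Dipolar relaxation rates for one 1H-1H pair at a fixed distance.

    sigma couples z magnetisation between the two spins, mu couples the
    transverse (x-x / y-y) components; rho1_dip / rho2_dip are the dipolar
    contributions to the auto-relaxation rates R1 / R2.  All rates in s^-1.
    ``d`` is the dipolar coupling constant in rad/s and ``j_values`` holds
    J(0), J(w0), J(2 w0) in seconds.
    """

    sigma: float
    mu: float
    rho1_dip: float
    rho2_dip: float
    d: float
    j_values: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def scaled(self, sigma_scale: float = 1.0, mu_scale: float = 1.0) -> "RelaxationRates":
        """Return a copy with cross-relaxation rates scaled (for artifact
        dissection: zeroing sigma and/or mu)."""
        return RelaxationRates(
            sigma=self.sigma * sigma_scale,
            mu=self.mu * mu_scale,
            rho1_dip=self.rho1_dip,
            rho2_dip=self.rho2_dip,
            d=self.d,
            j_values=self.j_values,
        )


def spectral_density(omega: float | np.ndarray, tumbling: TumblingModel) -> float | np.ndarray:
    """Lorentzian spectral density J(omega) = tau_c / (1 + (omega tau_c)^2).

    Parameters
    ----------
    omega : float or array
        Angular frequency in rad/s, must be non-negative and finite.
    tumbling : TumblingModel

    Returns
    -------
    J(omega) in seconds; strictly decreasing in omega, J(0) = tau_c.
    """
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("omega must be finite")
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    tc = tumbling.tau_c
    out = tc / (1.0 + (omega * tc) ** 2)
    return float(out) if out.ndim == 0 else out


def dipolar_coupling_constant(r_angstrom: float) -> float:
    """Dipolar coupling constant d = (mu0/4pi) gamma_H^2 hbar / r^3 in rad/s."""
    if not (np.isfinite(r_angstrom) and r_angstrom > 0):
        raise ValueError(f"distance must be positive and finite, got {r_angstrom}")
    r = r_angstrom * ANGSTROM
    return MU0_OVER_4PI * GAMMA_H**2 * HBAR / r**3


def dipolar_rates(r_angstrom: float, tumbling: TumblingModel) -> RelaxationRates:
    """Compute sigma, mu, rho1_dip, rho2_dip for a 1H-1H pair at distance r.

    All rates scale exactly as r^-6.  At slow tumbling (omega0 * tau_c >> 1)
    sigma is negative (spin diffusion) while mu is positive with |mu| > |sigma|.

    Parameters
    ----------
    r_angstrom : float
        Interproton distance in Angstrom, > 0.
    tumbling : TumblingModel

    Returns
    -------
    RelaxationRates
    """
    d = dipolar_coupling_constant(r_angstrom)
    q = d * d / 10.0
    w0 = tumbling.omega0
    j0 = spectral_density(0.0, tumbling)
    j1 = spectral_density(w0, tumbling)
    j2 = spectral_density(2.0 * w0, tumbling)
    sigma = q * (6.0 * j2 - j0)
    mu = q * (2.0 * j0 + 3.0 * j1)
    rho1 = q * (j0 + 3.0 * j1 + 6.0 * j2)
    rho2 = 0.5 * q * (5.0 * j0 + 9.0 * j1 + 6.0 * j2)
    return RelaxationRates(
        sigma=sigma, mu=mu, rho1_dip=rho1, rho2_dip=rho2, d=d, j_values=(j0, j1, j2)
    )
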