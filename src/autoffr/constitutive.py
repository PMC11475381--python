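"""Blood properties and the vessel wall constitutive (tube) law.

Everything internal is CGS: pressure dyn/cm^2, flow cm^3/s, length cm.
User-facing pressures are mmHg (1 mmHg = 1333.22 dyn/cm^2).

The wall is a non-linear elastic (optionally visco-elastic) tube:

    P - Pext - P0 = (2 rho c0^2 / b) [ (A/A0)^(b/2) - 1 ] + Gamma/A0^(3/2) dA/dt

with reference wave speed

    c0(r0) = sqrt( (2 / 3 rho) (k1 exp(k2 r0) + k3) )

so small vessels are stiffer (k2 < 0).  With the collapse pressure unset,
the exponent b defaults to 2 (square-root tube law); otherwise
b = 2 rho c0^2 / (P0 - Pcollapse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MMHG = 1333.22  # dyn/cm^2 per mmHg


@dataclass
class BloodProperties:
    """Density (g/cm^3) and dynamic viscosity (Poise) of blood."""

    rho: float = 1.06
    mu: float = 0.04

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu < 0:
            raise ValueError("rho must be > 0 and mu >= 0")


@dataclass
class WallLaw:
    """Constants of the wall law (CGS).

    ``k1``, ``k3`` in g/(cm s^2), ``k2`` in 1/cm.  ``P0`` is the reference
    pressure at which the imaged area equals A0 (default: mean arterial
    pressure for 80/120 mmHg, since CCTA is acquired near mean pressure);
    ``Pext`` the external tissue pressure.  ``Gamma`` (g/cm^4/s) adds a
    visco-elastic term (0 = purely elastic).
    """

    k1: float = 2.0e7
    k2: float = -22.53
    k3: float = 8.65e5
    P0: float = (2 * 80.0 + 120.0) / 3.0 * MMHG
    Pext: float = 0.0
    b: float = 2.0
    Gamma: float = 0.0
    Pcollapse: float | None = None

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be > 0")


def wave_speed(r0, blood: BloodProperties, wall: WallLaw):
    """Reference pulse wave speed c0(r0) in cm/s (scalar or array)."""
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise ValueError("r0 must be > 0")
    radicand = (2.0 / (3.0 * blood.rho)) * (wall.k1 * np.exp(wall.k2 * r0) + wall.k3)
    if np.any(radicand <= 0):
        raise ValueError("invalid wall constants: non-positive wave-speed radicand")
    c0 = np.sqrt(radicand)
    return float(c0) if c0.ndim == 0 else c0


def exponent_b(c0, blood: BloodProperties, wall: WallLaw):
    """Tube-law exponent: from Pcollapse when given, else the default b."""
    if wall.Pcollapse is None:
        return np.full_like(np.asarray(c0, dtype=float), wall.b) if np.ndim(c0) else wall.b
    b = 2.0 * blood.rho * np.asarray(c0, dtype=float) ** 2 / (wall.P0 - wall.Pcollapse)
    if np.any(b <= 0):
        raise ValueError("Pcollapse must be below P0 (b must be > 0)")
    return float(b) if b.ndim == 0 else b


def tube_law(A, A0, wall: WallLaw, blood: BloodProperties, c0=None, dA_dt=0.0):
    """Transmural pressure of the tube law (dyn/cm^2).

    ``c0`` defaults to the wave speed of the radius implied by A0.
    """
    A = np.asarray(A, dtype=float)
    A0 = np.asarray(A0, dtype=float)
    if np.any(A <= 0):
        raise ValueError("cross-sectional area must be > 0")
    if np.any(A0 <= 0):
        raise ValueError("reference area must be > 0")
    if c0 is None:
        c0 = wave_speed(np.sqrt(A0 / np.pi), blood, wall)
    b = exponent_b(c0, blood, wall)
    elastic = (2.0 * blood.rho * np.asarray(c0) ** 2 / b) * ((A / A0) ** (b / 2.0) - 1.0)
    visco = wall.Gamma / A0**1.5 * dA_dt
    P = wall.Pext + wall.P0 + elastic + visco
    return float(P) if P.ndim == 0 else P


def elastic_dPdA(A, A0, c0, wall: WallLaw, blood: BloodProperties):
    """d(elastic pressure)/dA, used in Jacobian assembly."""
    b = exponent_b(c0, blood, wall)
    return blood.rho * np.asarray(c0) ** 2 * (np.asarray(A) / A0) ** (b / 2.0 - 1.0) / A0
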