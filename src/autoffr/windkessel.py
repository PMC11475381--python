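"""Coronary outflow boundary conditions: perfusion targets and Windkessel beds.

Total coronary resistance per side is MAP / mean inflow.  It is shared
among the terminal vessels of the 1D tree by a Murray-type power law
(flow fraction proportional to terminal radius^2.27), and each terminal is
closed by a three-resistor / two-capacitor bed:

    1D end --R1--(C1)--R2--(C2, referenced to scaled ventricular
    pressure PLV)--R3--> venous pressure Pven

R1 is the characteristic impedance rho*c0/A0_end; the remaining bed
resistance splits 0.79/0.21 between the arterial and venous side of the
micro-circulation.  The C2-PLV coupling produces the systolic throttling
of coronary flow (intramyocardial compression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import MMHG, BloodProperties, WallLaw, wave_speed
from .mesh import Mesh1D
from .waveforms import PeriodicWaveform, scaled_plv

MURRAY_POWER = 2.27
DEFAULT_TOTAL_COMPLIANCE = 6.0e-5  # cm^5/dyn per coronary side
DEFAULT_C1_FRACTION = 0.2


@dataclass
class PerfusionTargets:
    """Idealised perfusion pressures (mmHg) and per-side mean inflows (cm^3/s)."""

    diastolic: float = 80.0
    systolic: float = 120.0
    q_left: float = 2.0
    q_right: float = 1.0

    @property
    def map_mmhg(self) -> float:
        return (2.0 * self.diastolic + self.systolic) / 3.0

    @property
    def map_cgs(self) -> float:
        return self.map_mmhg * MMHG

    def q_mean(self, side: str) -> float:
        if side == "left":
            return self.q_left
        if side == "right":
            return self.q_right
        raise ValueError("side must be 'left' or 'right'")


def total_resistance(targets: PerfusionTargets, side: str) -> float:
    """Total coronary resistance of one side, MAP/Qcor, in dyn s/cm^5."""
    q = targets.q_mean(side)
    if q <= 0:
        raise ValueError("mean coronary inflow must be > 0")
    return targets.map_cgs / q


class BedResistanceError(ValueError):
    """Characteristic impedance exceeds the terminal's total bed resistance."""


@dataclass
class WindkesselBed:
    """0D micro-circulation bed attached to one terminal vessel."""

    vessel_id: int
    R1: float
    R2: float
    R3: float
    C1: float
    C2: float
    Pven: float = 5.0 * MMHG
    plv: PeriodicWaveform | None = None
    A0_end: float = 0.0
    flow_fraction: float = 1.0
    # discrete state of the two compliance nodes (dyn/cm^2)
    Pc1: float = 0.0
    Pc2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.R1, self.R2, self.R3) <= 0:
            raise ValueError("all bed resistances must be > 0")

    @property
    def RTf(self) -> float:
        return self.R1 + self.R2 + self.R3

    def plv_at(self, t: float) -> float:
        return 0.0 if self.plv is None else float(self.plv(t))

    def initialise_steady(self, q: float) -> None:
        """Set compliance-node pressures consistent with steady flow q."""
        self.Pc2 = self.Pven + q * self.R3
        self.Pc1 = self.Pc2 + q * self.R2

    def step(self, q_in: float, dt: float, t: float) -> float:
        """Backward-Euler update of the bed state for one time step.

        Returns the coupling pressure seen by the 1D domain,
        ``P_in = q_in * R1 + Pc1``.  With constant inflow the state relaxes
        to ``P_in = Pven + q_in * (R1 + R2 + R3)``.
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        dplv = (self.plv_at(t) - self.plv_at(t - dt)) / dt
        # implicit 2x2 linear system in (Pc1, Pc2)
        a11 = self.C1 / dt + 1.0 / self.R2
        a12 = -1.0 / self.R2
        b1 = self.C1 / dt * self.Pc1 + q_in
        a21 = -1.0 / self.R2
        a22 = self.C2 / dt + 1.0 / self.R2 + 1.0 / self.R3
        b2 = self.C2 / dt * self.Pc2 + self.Pven / self.R3 + self.C2 * dplv
        det = a11 * a22 - a12 * a21
        pc1 = (b1 * a22 - a12 * b2) / det
        pc2 = (a11 * b2 - a21 * b1) / det
        self.Pc1, self.Pc2 = float(pc1), float(pc2)
        return q_in * self.R1 + self.Pc1


def distribute_terminals(
    mesh: Mesh1D,
    Rcor: float,
    blood: BloodProperties,
    wall: WallLaw,
    power: float = MURRAY_POWER,
    total_compliance: float = DEFAULT_TOTAL_COMPLIANCE,
    c1_fraction: float = DEFAULT_C1_FRACTION,
    plv: PeriodicWaveform | None = None,
    pven: float = 5.0 * MMHG,
) -> list[WindkesselBed]:
    """Build one Windkessel bed per terminal vessel of a 1D mesh.

    Flow fractions follow the Murray-law variant f_i = r_i^p / sum r_j^p on
    terminal end radii; each terminal's total resistance is RTf_i = Rcor/f_i
    and the bed compliance is distributed proportionally to f_i.
    """
    terminals = mesh.terminals()
    if not terminals:
        raise ValueError("mesh has no terminal vessel")
    r_end = np.array([v.r0[-1] for v in terminals])
    f = r_end**power
    f = f / f.sum()
    beds = []
    for v, fi, r in zip(terminals, f, r_end):
        rtf = Rcor / fi
        c0 = wave_speed(r, blood, wall)
        a0 = np.pi * r**2
        r1 = blood.rho * c0 / a0
        if rtf <= r1:
            raise BedResistanceError(
                f"characteristic impedance exceeds bed resistance at vessel "
                f"{v.vessel_id} (R1={r1:.3e}, RTf={rtf:.3e}): unphysical "
                f"geometry/flow combination"
            )
        r2 = 0.79 * (rtf - r1)
        r3 = 0.21 * (rtf - r1)
        ci = total_compliance * fi
        beds.append(
            WindkesselBed(
                vessel_id=v.vessel_id,
                R1=r1,
                R2=r2,
                R3=r3,
                C1=c1_fraction * ci,
                C2=(1.0 - c1_fraction) * ci,
                Pven=pven,
                plv=plv,
                A0_end=float(a0),
                flow_fraction=float(fi),
            )
        )
    return beds
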