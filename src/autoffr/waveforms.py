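"""Periodic boundary-condition waveforms: coronary inflow and ventricular pressure.

The solver takes inflow and ventricular-pressure waveforms as sampled
(t, value) tables, interpolated linearly and periodically.  Shipped default
shapes are representative, not patient-calibrated: left-coronary inflow is
diastolic-dominant (myocardial compression throttles systolic flow), the
right side is more uniform over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import MMHG

DEFAULT_PERIOD = 0.8  # s (75 bpm)
DEFAULT_Q_LEFT = 2.0  # cm^3/s mean left-coronary inflow (hyperaemic-range)
DEFAULT_Q_RIGHT = 1.0  # cm^3/s mean right-coronary inflow


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump of unit height, support ``width`` around ``center``."""
    u = (t - center) / (width / 2.0)
    return np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)


@dataclass
class PeriodicWaveform:
    """A sampled periodic signal with linear interpolation."""

    t: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.t) != len(self.values) or len(self.t) < 2:
            raise ValueError("need matching t/value samples (>= 2)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")
        if abs(self.values[0] - self.values[-1]) > 1e-9 * (1 + np.abs(self.values).max()):
            raise ValueError("waveform must be periodic: value(0) != value(T)")

    def __call__(self, t) -> np.ndarray | float:
        tm = np.mod(t, self.period)
        out = np.interp(tm, self.t, self.values)
        return float(out) if np.ndim(t) == 0 else out

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.values, self.t) / (self.t[-1] - self.t[0]))


@dataclass
class InflowWaveform(PeriodicWaveform):
    """Volumetric inflow (cm^3/s) prescribed at a coronary ostium."""

    side: str = "left"

    @classmethod
    def from_samples(cls, t, q, period: float, side: str) -> "InflowWaveform":
        return cls(np.asarray(t, float), np.asarray(q, float), period, side=side)

    @classmethod
    def default(
        cls, side: str, q_mean: float | None = None, period: float = DEFAULT_PERIOD, n: int = 201
    ) -> "InflowWaveform":
        """Representative coronary inflow with prescribed cycle-mean flow."""
        t = np.linspace(0.0, period, n)
        if side == "left":
            q_mean = DEFAULT_Q_LEFT if q_mean is None else q_mean
            shape = 0.15 + 0.25 * _bump(t, 0.18 * period, 0.25 * period)
            shape += 1.0 * _bump(t, 0.65 * period, 0.55 * period)
        elif side == "right":
            q_mean = DEFAULT_Q_RIGHT if q_mean is None else q_mean
            shape = 0.6 + 0.5 * _bump(t, 0.30 * period, 0.50 * period)
            shape += 0.3 * _bump(t, 0.70 * period, 0.40 * period)
        else:
            raise ValueError("side must be 'left' or 'right'")
        shape *= q_mean / np.trapezoid(shape, t) * period
        return cls(t, shape, period, side=side)

    @classmethod
    def constant(cls, q: float, period: float = DEFAULT_PERIOD, side: str = "left") -> "InflowWaveform":
        t = np.array([0.0, period])
        return cls(t, np.array([q, q]), period, side=side)


def ventricular_pressure(
    period: float = DEFAULT_PERIOD,
    p_max_mmhg: float = 120.0,
    systole_fraction: float = 0.35,
    n: int = 201,
) -> PeriodicWaveform:
    """Idealised ventricular pressure pulse (dyn/cm^2): sin^2 systolic bump."""
    t = np.linspace(0.0, period, n)
    ts = systole_fraction * period
    p = np.where(t < ts, np.sin(np.pi * t / np.maximum(ts, 1e-12)) ** 2, 0.0)
    return PeriodicWaveform(t, p * p_max_mmhg * MMHG, period)


def scaled_plv(side: str, period: float = DEFAULT_PERIOD, scale: float | None = None) -> PeriodicWaveform:
    """Ventricular pressure scaled for a coronary side (default 0.5 L / 0.2 R).

    The scaling mimics the stronger intramyocardial compression of the left
    ventricle; it is uncalibrated and exposed in config.
    """
    if scale is None:
        scale = 0.5 if side == "left" else 0.2
    base = ventricular_pressure(period)
    return PeriodicWaveform(base.t, base.values * scale, period)
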