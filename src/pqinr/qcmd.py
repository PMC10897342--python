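"""Quartz crystal microbalance with dissipation (QCM-D) utilities.

The Sauerbrey relation converts a rigid-film resonant frequency shift
into an adsorbed areal mass,

    delta_m = -C * delta_f / n,      C = sqrt(rho_q * mu_q) / (2 * f0^2),

with the overtone-normalised frequency shift delta_f / n.  The sign
convention here is "frequency decrease -> positive adsorbed mass", and
the mass sensitivity C for a standard 5 MHz AT-cut crystal is
~17.7 ng cm^-2 Hz^-1.  Viscoelastic films violate the rigid-film
assumption; high-dissipation steps should be read qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["QuartzCrystal", "QCMDTrace", "sauerbrey_mass",
           "mass_sensitivity", "step_change"]

_KG_M2_TO_NG_CM2 = 1.0e8  # 1 kg/m^2 = 1e12 ng / 1e4 cm^2


@dataclass(frozen=True)
class QuartzCrystal:
    """AT-cut quartz resonator constants (SI units)."""

    f0: float = 5.0e6            # fundamental resonant frequency, Hz
    rho_q: float = 2648.0        # quartz density, kg m^-3
    mu_q: float = 2.947e10       # quartz shear modulus, kg m^-1 s^-2
    area: float = 1.0e-4         # piezoelectrically excited area, m^2

    def __post_init__(self) -> None:
        if min(self.f0, self.rho_q, self.mu_q, self.area) <= 0:
            raise ValueError("all crystal constants must be > 0")


def mass_sensitivity(crystal: QuartzCrystal) -> float:
    """Sauerbrey constant C in ng cm^-2 per Hz of normalised shift."""
    c_si = np.sqrt(crystal.rho_q * crystal.mu_q) / (2.0 * crystal.f0**2)
    return c_si * _KG_M2_TO_NG_CM2


def sauerbrey_mass(delta_f: float, crystal: QuartzCrystal = QuartzCrystal(),
                   harmonic: int = 1) -> float:
    """Adsorbed areal mass (ng cm^-2) from a frequency shift at one overtone.

    ``delta_f`` is the raw shift at the given odd harmonic; it is
    normalised by the harmonic number before conversion.  A frequency
    decrease (negative ``delta_f``) gives a positive mass.
    """
    if harmonic % 2 != 1 or harmonic < 1:
        raise ValueError(f"harmonic must be a positive odd integer, got {harmonic}")
    return -mass_sensitivity(crystal) * delta_f / harmonic


@dataclass
class QCMDTrace:
    """Time series of frequency and dissipation shifts per harmonic."""

    time: np.ndarray
    delta_f: Mapping[int, np.ndarray]
    delta_d: Mapping[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for n in self.delta_f:
            if n % 2 != 1:
                raise ValueError(f"harmonics must be odd, got {n}")
        self.delta_f = {n: np.asarray(v, dtype=float)
                        for n, v in self.delta_f.items()}
        if self.delta_d is not None:
            self.delta_d = {n: np.asarray(v, dtype=float)
                            for n, v in self.delta_d.items()}


def _window_median(time: np.ndarray, values: np.ndarray,
                   window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (time >= lo) & (time <= hi)
    if not np.any(mask):
        raise ValueError(f"window {window} contains no samples")
    return float(np.median(values[mask]))


def step_change(trace: QCMDTrace, window_pre: tuple[float, float],
                window_post: tuple[float, float]) -> dict[int, dict[str, float]]:
    """Frequency/dissipation step between two time windows, per harmonic.

    Uses windowed medians (robust to transient spikes).  Windows must
    not overlap.  Returns ``{harmonic: {"delta_f": ..., "delta_d": ...}}``
    (``delta_d`` only when dissipation data are present).
    """
    if window_pre[1] > window_post[0] and window_post[1] > window_pre[0]:
        raise ValueError("pre and post windows must not overlap")
    out: dict[int, dict[str, float]] = {}
    for n, f in trace.delta_f.items():
        step = (_window_median(trace.time, f, window_post)
                - _window_median(trace.time, f, window_pre))
        out[n] = {"delta_f": step}
        if trace.delta_d is not None and n in trace.delta_d:
            d = trace.delta_d[n]
            out[n]["delta_d"] = (_window_median(trace.time, d, window_post)
                                 - _window_median(trace.time, d, window_pre))
    return out
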