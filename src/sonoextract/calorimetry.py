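"""Calorimetric estimation of effective ultrasonic power and power density.

With the vessel unthermostated and no sample present, acoustic energy
dissipates into the solvent as heat, so the initial temperature rise obeys
P = m * cp * dT/dt.  The heating rate dT/dt is the ordinary least-squares
slope of temperature against time over the analysis window (default the
first 5 min at 1 Hz logging), which is robust to sensor noise where a
two-point difference is not.  Dividing the power by the extraction volume
gives the acoustic power density in W/L, the quantity that actually
characterises a sonicated process independent of probe geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalorimetryTrace",
    "PowerResult",
    "estimate_power",
    "power_density",
    "replicate_summary",
    "WATER_CP",
    "WATER_DENSITY",
]

#: Specific heat of water, J/(kg degC) — the solvent in aqueous extraction.
WATER_CP = 4186.0
#: Density of water near room temperature, kg/L, for mass-from-volume defaults.
WATER_DENSITY = 0.998


@dataclass(frozen=True)
class CalorimetryTrace:
    """Sampled (time, temperature) pairs from one sonication run."""

    times: tuple[float, ...]
    temperatures: tuple[float, ...]
    probe_id: str = ""

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        temp = tuple(float(x) for x in self.temperatures)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", temp)
        if len(t) != len(temp):
            raise ValueError("times and temperatures must have equal length")
        if len(t) < 2:
            raise ValueError("trace needs at least two samples")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")

    @staticmethod
    def average(traces: Sequence["CalorimetryTrace"]) -> "CalorimetryTrace":
        """Pointwise mean of synchronised traces (e.g. two thermocouples)."""
        if not traces:
            raise ValueError("no traces to average")
        t0 = np.asarray(traces[0].times)
        for tr in traces[1:]:
            if not np.array_equal(np.asarray(tr.times), t0):
                raise ValueError("traces must share identical time stamps")
        mean_T = np.mean([tr.temperatures for tr in traces], axis=0)
        return CalorimetryTrace(tuple(t0), tuple(mean_T), probe_id="averaged")


@dataclass(frozen=True)
class PowerResult:
    """Effective ultrasonic power estimate from one calorimetry trace."""

    power: float            # W
    power_density: float    # W/L (nan if volume not supplied)
    slope: float            # K/s
    slope_stderr: float     # K/s
    power_stderr: float     # W
    mass: float             # kg
    cp: float               # J/(kg degC)
    volume: float | None    # L
    heating: bool           # False flags a cooling (negative-slope) trace


def estimate_power(
    trace: CalorimetryTrace,
    mass: float | None = None,
    cp: float = WATER_CP,
    window: tuple[float, float] = (0.0, 300.0),
    volume: float | None = None,
) -> PowerResult:
    """Estimate P = m * cp * dT/dt from the initial temperature rise.

    Parameters
    ----------
    trace : CalorimetryTrace
        Logged solvent temperatures, degC, at times in seconds.
    mass : float, optional
        Solvent mass in kg. Defaults to ``volume`` x 0.998 kg/L (water);
        one of mass or volume must be given.
    cp : float
        Specific heat, J/(kg degC); water by default.
    window : (float, float)
        Regression window in seconds, default the first 300 s.
    volume : float, optional
        Extraction volume in L; enables the power-density field.
    """
    if mass is None:
        if volume is None:
            raise ValueError("supply mass, or volume to infer the water mass")
        mass = volume * WATER_DENSITY
    if not mass > 0:
        raise ValueError(f"mass must be > 0 kg, got {mass}")
    if not cp > 0:
        raise ValueError(f"cp must be > 0, got {cp}")
    t = np.asarray(trace.times)
    T = np.asarray(trace.temperatures)
    keep = (t >= window[0]) & (t <= window[1])
    if keep.sum() < 3:
        raise ValueError(
            f"regression window {window} contains {int(keep.sum())} samples; "
            "need at least 3"
        )
    if np.ptp(T[keep]) == 0.0:  # constant trace: zero power, zero slope
        slope, stderr = 0.0, 0.0
    else:
        fit = stats.linregress(t[keep], T[keep])
        slope, stderr = float(fit.slope), float(fit.stderr)
    power = mass * cp * slope
    return PowerResult(
        power=power,
        power_density=power / volume if volume else float("nan"),
        slope=slope,
        slope_stderr=stderr,
        power_stderr=mass * cp * stderr,
        mass=mass,
        cp=cp,
        volume=volume,
        heating=slope >= 0.0,
    )


def power_density(power: float, volume: float) -> float:
    """Acoustic power density (W/L) = power / extraction volume."""
    if not volume > 0:
        raise ValueError(f"volume must be > 0 L, got {volume}")
    return power / volume


def replicate_summary(results: Sequence[PowerResult]) -> tuple[float, float]:
    """Mean and sample standard deviation of power density across replicates."""
    if len(results) < 2:
        raise ValueError("need >= 2 replicate measurements to summarise")
    dens = np.array([r.power_density for r in results])
    if np.any(np.isnan(dens)):
        raise ValueError("all replicates need a volume for power density")
    return float(dens.mean()), float(dens.std(ddof=1))
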