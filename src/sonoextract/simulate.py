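"""Synthetic extraction datasets and calorimetry traces.

The generator mirrors the standard study design: triplicate yield curves at
5, 15 and 25 degC sampled at 1, 2, 3, 4, 5, 6, 8, 10 and 30 min, with
homoscedastic additive Gaussian noise on the yield scale (symmetric scatter
is what replicate error bars on extraction curves show; nothing supports a
multiplicative model).  Negative draws are truncated at zero and counted —
at the default noise level truncation touches well under 1% of points.
The mean function is exactly :func:`sonoextract.kinetics.predict_curve`, so
generate -> fit round-trips are exact at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .calorimetry import CalorimetryTrace
from .equilibrium import EquilibriumLine
from .kinetics import (
    ExtractionCurve,
    KineticsDataset,
    WeibullArrheniusParams,
    predict_curve,
)
from .reference import SAMPLE_TIMES_S, STUDY_TEMPERATURES_C

__all__ = [
    "SyntheticDesign",
    "GeneratedDataset",
    "generate_extraction_dataset",
    "generate_calorimetry_trace",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Design of a simulated extraction experiment.

    Defaults reproduce the standard study conditions: 3 temperatures x
    9 sampling times x 3 replicates, noise_sd = 2 yield-points (a stand-in
    for unpublished replicate scatter; configurable).
    ``equilibrium`` is either an :class:`EquilibriumLine` or a mapping
    temperature (degC) -> Y_eq (%).
    """

    true_params: WeibullArrheniusParams
    equilibrium: EquilibriumLine | Mapping[float, float]
    temperatures_C: tuple[float, ...] = STUDY_TEMPERATURES_C
    sample_times_s: tuple[float, ...] = SAMPLE_TIMES_S
    replicates: int = 3
    noise_sd: float = 2.0
    seed: int = 0
    condition: str = "SIM"
    response: str = "SIM"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if len(set(self.temperatures_C)) < 2:
            raise ValueError("need >= 2 distinct temperatures")

    def y_eq(self, temperature_C: float) -> float:
        if isinstance(self.equilibrium, EquilibriumLine):
            return self.equilibrium.predict(temperature_C)
        return float(self.equilibrium[temperature_C])


@dataclass(frozen=True)
class GeneratedDataset:
    """A simulated dataset plus the ground truth that produced it."""

    dataset: KineticsDataset
    design: SyntheticDesign
    n_truncated: int = 0

    @property
    def true_params(self) -> WeibullArrheniusParams:
        return self.design.true_params


def generate_extraction_dataset(design: SyntheticDesign) -> GeneratedDataset:
    """Draw one replicated, noisy dataset from the forward model.

    Yields are the Weibull-Arrhenius mean plus i.i.d. N(0, noise_sd),
    truncated at zero; replicate observations share a sampling time within
    each curve.  Each curve's equilibrium yield is set to the design's true
    asymptote, matching the convention that Y_eq enters the fit as a fixed
    known quantity.  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    curves = []
    n_trunc = 0
    for T in design.temperatures_C:
        y_eq = design.y_eq(T)
        mean = predict_curve(design.true_params, y_eq, design.sample_times_s, T)
        times, yields = [], []
        for t, mu in zip(design.sample_times_s, mean):
            draws = mu + design.noise_sd * rng.standard_normal(design.replicates)
            n_trunc += int(np.sum(draws < 0))
            draws = np.maximum(draws, 0.0)
            times.extend([t] * design.replicates)
            yields.extend(draws.tolist())
        curves.append(
            ExtractionCurve(
                condition=design.condition,
                temperature_C=T,
                response=design.response,
                times=tuple(times),
                yields=tuple(yields),
                equilibrium_yield=y_eq,
            )
        )
    return GeneratedDataset(KineticsDataset(tuple(curves)), design, n_trunc)


def generate_calorimetry_trace(
    power: float,
    mass: float,
    cp: float,
    duration_s: float = 300.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    start_temperature_C: float = 20.0,
) -> CalorimetryTrace:
    """Linear-ramp trace T(t) = T0 + (P/(m*cp))*t + N(0, noise_sd), 1 Hz.

    Inverts the calorimetric power balance P = m*cp*dT/dt, so estimating
    the power back from a noiseless trace is an identity.
    """
    if mass <= 0 or cp <= 0:
        raise ValueError("mass and cp must be positive")
    if power < 0:
        raise ValueError(f"power must be >= 0 W, got {power}")
    if duration_s < 2:
        raise ValueError("trace must cover at least 2 s at 1 Hz sampling")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + 1.0)
    slope = power / (mass * cp)
    T = start_temperature_C + slope * t
    if noise_sd > 0:
        T = T + noise_sd * rng.standard_normal(t.size)
    return CalorimetryTrace(tuple(t), tuple(T), probe_id="synthetic")
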