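"""Weibull-Arrhenius forward model for solid-liquid extraction kinetics.

The extraction yield Y(t) (percent of the maximum extractable content) at
temperature T follows a Weibull (stretched-exponential) law

    Y(t) = Y_eq * (1 - exp(-(t / alpha(T))**beta))

where ``alpha`` is the characteristic extraction time (s; smaller alpha =
faster extraction), ``beta`` the dimensionless shape index (beta = 1 gives
first-order kinetics, beta < 1 a rate that decays over time) and ``Y_eq``
the equilibrium yield, taken as the terminal (30 min) observation.

The temperature dependence of the time scale is of Arrhenius type,

    alpha(T) = alpha0 * exp(+Ea / (R*T)),

so that the *rate* 1/alpha obeys the standard Arrhenius law
1/alpha = (1/alpha0) * exp(-Ea/(R*T)): heating shortens the characteristic
time when the activation energy Ea > 0.  alpha is evaluated in log space to
avoid overflow for large Ea or low T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "WeibullArrheniusParams",
    "ExtractionCurve",
    "KineticsDataset",
    "alpha_at_temperature",
    "weibull_yield",
    "predict_curve",
    "celsius_to_kelvin",
]

#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.314


def celsius_to_kelvin(temperature_C: float) -> float:
    """Convert Celsius to Kelvin (user interfaces are in Celsius)."""
    return float(temperature_C) + 273.15


@dataclass(frozen=True)
class WeibullArrheniusParams:
    """Kinetic parameters of the Weibull-Arrhenius extraction model.

    Parameters
    ----------
    alpha0 : float
        Pre-exponential time scale, seconds. Must be positive. Typical
        identified values span 1e-10 to 1e-1 s.
    Ea : float
        Arrhenius activation energy, J/mol, >= 0. The energy barrier a
        biocompound must cross to leave the solid matrix.
    beta : float
        Dimensionless Weibull shape, > 0.
    """

    alpha0: float
    Ea: float
    beta: float
    R: float = field(default=GAS_CONSTANT, repr=False)

    def __post_init__(self) -> None:
        if not self.alpha0 > 0:
            raise ValueError(f"alpha0 must be > 0, got {self.alpha0}")
        if self.Ea < 0:
            raise ValueError(f"Ea must be >= 0 J/mol, got {self.Ea}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.R != GAS_CONSTANT:
            raise ValueError("R is a physical constant and cannot be changed")

    def alpha(self, temperature_K: float) -> float:
        """Characteristic time alpha(T) in seconds at ``temperature_K``."""
        return alpha_at_temperature(self, temperature_K)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha0, self.Ea, self.beta], dtype=float)


def alpha_at_temperature(
    params: WeibullArrheniusParams, temperature_K: float
) -> float:
    """Evaluate the Arrhenius time scale alpha(T) = alpha0*exp(+Ea/(R*T)).

    Computed as exp(log(alpha0) + Ea/(R*T)) so extreme Ea/(R*T) ratios do
    not overflow intermediate terms. Strictly decreasing in T for Ea > 0.

    Raises
    ------
    ValueError
        If ``temperature_K`` is not positive (absolute temperature).
    """
    T = float(temperature_K)
    if not T > 0:
        raise ValueError(f"absolute temperature must be > 0 K, got {T}")
    log_alpha = np.log(params.alpha0) + params.Ea / (params.R * T)
    return float(np.exp(log_alpha))


def weibull_yield(
    t: float | np.ndarray,
    alpha: float,
    beta: float,
    y_eq: float,
) -> float | np.ndarray:
    """Weibull extraction yield Y(t) = y_eq*(1 - exp(-(t/alpha)**beta)).

    Vectorised over ``t``. Y(0) = 0 (the extract starts solute-free), Y is
    non-decreasing in t and approaches ``y_eq`` from below.

    Raises
    ------
    ValueError
        On negative times or non-positive alpha, beta or y_eq.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("times must be non-negative")
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if not y_eq > 0:
        raise ValueError(f"equilibrium yield must be > 0, got {y_eq}")
    # (t/alpha)**beta via exp(beta*log(t/alpha)); t = 0 handled explicitly.
    with np.errstate(divide="ignore"):
        log_ratio = np.log(t_arr) - np.log(alpha)
    exponent = np.where(t_arr > 0, np.exp(beta * log_ratio), 0.0)
    out = y_eq * (-np.expm1(-exponent))
    return out if isinstance(t, np.ndarray) else float(out)


def predict_curve(
    params: WeibullArrheniusParams,
    y_eq: float,
    times: Sequence[float] | np.ndarray,
    temperature_C: float,
) -> np.ndarray:
    """Predicted yields at ``times`` (s) for a run at ``temperature_C``."""
    alpha = alpha_at_temperature(params, celsius_to_kelvin(temperature_C))
    return np.asarray(
        weibull_yield(np.asarray(times, dtype=float), alpha, params.beta, y_eq)
    )


@dataclass(frozen=True)
class ExtractionCurve:
    """One extraction time-series: a condition x temperature x response run.

    ``times`` are seconds (sorted ascending, >= 0; ties mark replicate
    observations at one sampling time); ``yields`` are percent of the maximum
    extractable content; ``equilibrium_yield`` is the yield at the terminal
    sampling point, used as the model asymptote.
    """

    condition: str
    temperature_C: float
    response: str
    times: tuple[float, ...]
    yields: tuple[float, ...]
    equilibrium_yield: float

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        yields = tuple(float(y) for y in self.yields)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "yields", yields)
        if len(times) != len(yields):
            raise ValueError(
                f"times ({len(times)}) and yields ({len(yields)}) "
                "must have equal length"
            )
        if len(times) == 0:
            raise ValueError("curve must contain at least one observation")
        if times[0] < 0:
            raise ValueError("times must be non-negative")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("times must be sorted in ascending order")
        if not self.equilibrium_yield > 0:
            raise ValueError(
                f"equilibrium_yield must be > 0, got {self.equilibrium_yield}"
            )

    @property
    def temperature_K(self) -> float:
        return celsius_to_kelvin(self.temperature_C)

    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def yields_array(self) -> np.ndarray:
        return np.asarray(self.yields, dtype=float)


@dataclass(frozen=True)
class KineticsDataset:
    """ExtractionCurves sharing one condition and response across temperatures.

    The simultaneous fit pools every (time, yield) observation of every curve
    into one least-squares objective, so all temperatures jointly identify
    (alpha0, Ea, beta).
    """

    curves: tuple[ExtractionCurve, ...]

    def __post_init__(self) -> None:
        curves = tuple(self.curves)
        object.__setattr__(self, "curves", curves)
        if len(curves) == 0:
            raise ValueError("dataset must contain at least one curve")
        conditions = {c.condition for c in curves}
        responses = {c.response for c in curves}
        if len(conditions) > 1:
            raise ValueError(f"curves mix conditions: {sorted(conditions)}")
        if len(responses) > 1:
            raise ValueError(f"curves mix responses: {sorted(responses)}")
        temps = [c.temperature_C for c in curves]
        if len(set(temps)) != len(temps):
            raise ValueError(f"temperatures must be distinct, got {temps}")

    @property
    def condition(self) -> str:
        return self.curves[0].condition

    @property
    def response(self) -> str:
        return self.curves[0].response

    @property
    def temperatures_C(self) -> tuple[float, ...]:
        return tuple(c.temperature_C for c in self.curves)

    @property
    def n_obs(self) -> int:
        return sum(len(c.times) for c in self.curves)

    def __iter__(self) -> Iterable[ExtractionCurve]:
        return iter(self.curves)

    def reordered(self, order: Sequence[int]) -> "KineticsDataset":
        """Dataset with curves permuted (fit results must be invariant)."""
        return KineticsDataset(tuple(self.curves[i] for i in order))

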