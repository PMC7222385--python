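"""Extraction yields and their equilibrium temperature dependence.

Concentrations are expressed as yields Y = 100 * C / C_max, percent of the
content of the starting material (C_max), so that curves for different
responses (total polyphenols in mg GAE, flavonoids in mg catechin,
antioxidant activity in mg Trolox, all per 100 g dry matter) become
comparable.  The equilibrium yield Y_eq is the observation at the terminal
sampling point (30 min), and its temperature dependence over the studied
range is summarised by an ordinary least-squares line
Y_eq = slope * T(degC) + intercept with a t-test on the slope deciding
whether a temperature dependence is supported at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConcentrationRecord",
    "EquilibriumLine",
    "extraction_yield",
    "equilibrium_yield",
    "fit_equilibrium_line",
]


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measured extract concentration with its reference maximum.

    ``concentration`` and ``c_max`` share response-specific units
    (e.g. mg GAE / 100 g dm); ``c_max`` is the content of the starting
    byproduct before extraction.
    """

    response: str
    concentration: float
    c_max: float
    time_s: float
    temperature_C: float
    condition: str

    def __post_init__(self) -> None:
        if not self.c_max > 0:
            raise ValueError(f"c_max must be > 0, got {self.c_max}")
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class EquilibriumLine:
    """OLS line Y_eq = slope * T(degC) + intercept with its diagnostics."""

    slope: float            # percent / degC
    intercept: float        # percent
    r_squared: float
    temperature_dependent: bool
    slope_pvalue: float = float("nan")

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")

    def predict(self, temperature_C: float) -> float:
        return self.slope * temperature_C + self.intercept


def extraction_yield(record: ConcentrationRecord) -> float:
    """Yield (%) = 100 * C / C_max.

    Values above 100% (measurement noise near exhaustion) are retained and
    flagged with a warning, never clipped — the fitter must see data as-is.
    """
    y = 100.0 * record.concentration / record.c_max
    if y > 100.0:
        warnings.warn(
            f"yield {y:.2f}% exceeds 100% for {record.response} at "
            f"t={record.time_s}s; kept as-is",
            RuntimeWarning,
            stacklevel=2,
        )
    return y


def equilibrium_yield(
    times: Sequence[float], yields: Sequence[float], terminal_time: float | None = None
) -> float:
    """Yield at the terminal sampling time; replicate values are averaged.

    ``terminal_time`` defaults to the last observed time. The equilibrium
    concentration is by convention the experimental value at the end of the
    run (30 min in the standard design), not an extrapolated asymptote.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(yields, dtype=float)
    if t.size == 0 or t.size != y.size:
        raise ValueError("times and yields must be equal-length and non-empty")
    if terminal_time is None:
        terminal_time = float(t.max())
    at_terminal = np.isclose(t, terminal_time)
    if not at_terminal.any():
        raise ValueError(
            f"no observation at the terminal time {terminal_time} s"
        )
    return float(y[at_terminal].mean())


def fit_equilibrium_line(
    temperatures_C: Sequence[float],
    y_eq: Sequence[float],
    alpha: float = 0.05,
) -> EquilibriumLine:
    """OLS fit of equilibrium yield against temperature.

    ``temperature_dependent`` is False when the slope's two-sided t-test
    p-value exceeds ``alpha`` — a documented criterion replacing visual
    judgement of whether Y_eq varies over the studied range.
    """
    T = np.asarray(temperatures_C, dtype=float)
    y = np.asarray(y_eq, dtype=float)
    if np.unique(T).size < 2:
        raise ValueError("need >= 2 distinct temperatures")
    if T.size < 3:
        raise ValueError("need >= 3 points for a slope significance test")
    fit = stats.linregress(T, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # flat response: the zero-slope line is exact
        return EquilibriumLine(0.0, float(y.mean()), 1.0, False, 1.0)
    r2 = float(fit.rvalue**2)
    significant = bool(fit.pvalue < alpha)
    return EquilibriumLine(
        float(fit.slope), float(fit.intercept), r2, significant, float(fit.pvalue)
    )
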