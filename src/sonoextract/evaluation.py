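"""Model-adequacy statistics and derived kinetic summaries.

The adequacy of a fitted extraction model is judged by the mean relative
error

    MRE (%) = 100/n * sum_i |Y_i_exp - Y_i_cal| / Y_i_exp,

computed over all observed (experimental) vs calculated yield pairs with
Y_exp > 0 (the zero-time point, where the extract is still solute-free, is
excluded upstream).  This module also derives the comparative summaries an
extraction study reports: percentage reductions of the activation energy
under sonication and of the characteristic time alpha across the combined
temperature/power range.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .kinetics import WeibullArrheniusParams, alpha_at_temperature, celsius_to_kelvin

__all__ = [
    "MreReport",
    "mean_relative_error",
    "summarize_mre",
    "ea_reduction",
    "alpha_reduction_range",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (report display convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def mean_relative_error(
    y_exp: Sequence[float], y_cal: Sequence[float]
) -> float:
    """MRE (%) between experimental and calculated yields.

    Raises
    ------
    ValueError
        If lengths differ or any experimental yield is <= 0 (exclude the
        zero-time observation before calling).
    """
    ye = np.asarray(y_exp, dtype=float)
    yc = np.asarray(y_cal, dtype=float)
    if ye.size == 0 or ye.shape != yc.shape:
        raise ValueError("y_exp and y_cal must be equal-length and non-empty")
    if np.any(ye <= 0):
        raise ValueError(
            "experimental yields must be > 0; exclude zero-time points "
            "before computing the MRE"
        )
    return float(100.0 / ye.size * np.sum(np.abs(ye - yc) / ye))


def summarize_mre(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of a set of MREs, percent.

    A singleton gets sd = 0.0 (undefined with one value; reported as zero
    so downstream tables stay numeric). Use :func:`round_half_up` for the
    one-decimal display convention; raw values are returned here.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one MRE value")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd


def ea_reduction(ea_reference: float, ea_alternative: float) -> float:
    """Percent decrease of activation energy relative to a reference process.

    100 * (Ea_ref - Ea_alt) / Ea_ref; positive when the alternative
    (e.g. sonicated) process has the lower energy barrier.
    """
    if not ea_reference > 0:
        raise ValueError(f"reference Ea must be > 0, got {ea_reference}")
    return 100.0 * (ea_reference - ea_alternative) / ea_reference


def alpha_reduction_range(
    params_by_condition: Mapping[str, WeibullArrheniusParams],
    reference_condition: str = "CE",
    test_condition: str = "UAE2",
    temperature_low_C: float = 5.0,
    temperature_high_C: float = 25.0,
) -> float:
    """Percent decrease of alpha across the combined temperature/power sweep.

    Compares the characteristic time of the reference process at the low
    temperature with that of the test process at the high temperature:
    100 * (1 - alpha_test(T_high) / alpha_ref(T_low)).
    """
    for cond in (reference_condition, test_condition):
        if cond not in params_by_condition:
            raise ValueError(f"missing fitted parameters for condition {cond!r}")
    a_ref = alpha_at_temperature(
        params_by_condition[reference_condition],
        celsius_to_kelvin(temperature_low_C),
    )
    a_test = alpha_at_temperature(
        params_by_condition[test_condition],
        celsius_to_kelvin(temperature_high_C),
    )
    return 100.0 * (1.0 - a_test / a_ref)


@dataclass(frozen=True)
class MreReport:
    """MRE summary across conditions and responses.

    ``per_cell`` maps (condition, response) -> MRE; the marginal maps and
    the overall mean +/- sample sd are derived from it.
    """

    per_cell: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_cell.values()):
            raise ValueError("MRE values must be non-negative")

    @property
    def per_condition(self) -> dict[str, float]:
        return self._marginal(0)

    @property
    def per_response(self) -> dict[str, float]:
        return self._marginal(1)

    def _marginal(self, axis: int) -> dict[str, float]:
        out: dict[str, list[float]] = {}
        for key, v in self.per_cell.items():
            out.setdefault(key[axis], []).append(v)
        return {k: float(np.mean(vs)) for k, vs in out.items()}

    @property
    def overall(self) -> tuple[float, float]:
        return summarize_mre(list(self.per_cell.values()))
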