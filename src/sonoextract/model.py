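"""Simultaneous nonlinear least-squares identification of (alpha0, Ea, beta).

All observations of a :class:`~sonoextract.kinetics.KineticsDataset` — every
temperature, every sampling time — enter one unweighted sum-of-squares
objective; the per-curve equilibrium yields are held fixed at their supplied
values.  The optimiser works on the internal coordinates
(log10 alpha0, Ea, log beta): alpha0 spans ten orders of magnitude across
typical extraction systems, so a log scale is required for conditioning.

Uncertainties follow the classical nonlinear-regression recipe: with J the
Jacobian of the residual vector at the optimum, sigma2 = RSS/dof and
Cov = sigma2 * (J'J)^-1 on the internal scale; standard errors and
t-based confidence intervals are mapped to the natural (alpha0, Ea, beta)
scale by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .kinetics import (
    GAS_CONSTANT,
    KineticsDataset,
    WeibullArrheniusParams,
    alpha_at_temperature,
    celsius_to_kelvin,
    weibull_yield,
)

__all__ = [
    "FitConfig",
    "WeibullArrheniusModel",
    "WeibullArrheniusResults",
    "fit_weibull_arrhenius",
    "t_confidence_intervals",
]

_LN10 = np.log(10.0)

# Internal parameter order: (log10 alpha0, Ea [J/mol], log beta).
_DEFAULT_BOUNDS = (
    (-14.0, 2.0),        # log10 alpha0
    (0.0, 2.0e5),        # Ea, J/mol
    (np.log(1e-3), np.log(3.0)),  # log beta; identified betas go down to 0.009
)


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings for :class:`WeibullArrheniusModel`.

    ``init`` is an optional (alpha0, Ea, beta) start on the natural scale;
    by default starts come from per-temperature linearised Weibull fits
    followed by an Arrhenius regression, with a multistart grid fallback.
    ``use_replicate_means`` controls whether replicate observations at one
    time point are averaged before fitting (default) or pooled as-is.
    """

    init: tuple[float, float, float] | None = None
    bounds: tuple[tuple[float, float], ...] = _DEFAULT_BOUNDS
    max_iterations: int = 500
    tolerance: float = 1e-10
    multistart_grid: int = 5
    seed: int = 0
    use_replicate_means: bool = True

    def __post_init__(self) -> None:
        if self.init is not None:
            theta = _to_internal(np.asarray(self.init, dtype=float))
            for v, (lo, hi) in zip(theta, self.bounds):
                if not lo <= v <= hi:
                    raise ValueError(
                        f"init {self.init} outside bounds on the internal scale"
                    )


def _to_internal(natural: np.ndarray) -> np.ndarray:
    alpha0, ea, beta = natural
    return np.array([np.log10(alpha0), ea, np.log(beta)])


def _to_natural(theta: np.ndarray) -> np.ndarray:
    return np.array([10.0 ** theta[0], theta[1], np.exp(theta[2])])


def _natural_jacobian_diag(theta: np.ndarray) -> np.ndarray:
    """d(natural)/d(internal), diagonal (the map is coordinate-wise)."""
    return np.array([10.0 ** theta[0] * _LN10, 1.0, np.exp(theta[2])])


def t_confidence_intervals(
    estimates: np.ndarray,
    standard_errors: np.ndarray,
    dof: int,
    level: float = 0.95,
) -> np.ndarray:
    """t-based intervals estimate +/- t_{(1+level)/2, dof} * SE, shape (p, 2).

    The same quantile rule `coefCI`-style nonlinear-regression software
    applies; used for both the kinetic fit and any linear model pushed
    through the machinery.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if dof < 1:
        raise ValueError(f"need dof >= 1 for t intervals, got {dof}")
    tq = stats.t.ppf(0.5 + level / 2.0, dof)
    half = tq * np.asarray(standard_errors, dtype=float)
    est = np.asarray(estimates, dtype=float)
    return np.column_stack([est - half, est + half])


class WeibullArrheniusModel:
    """Weibull-Arrhenius extraction model bound to a kinetics dataset.

    Parameters
    ----------
    dataset : KineticsDataset
        Extraction curves for one condition/response at >= 2 temperatures,
        each with its equilibrium yield set.
    config : FitConfig, optional
        Optimiser settings.

    Examples
    --------
    >>> model = WeibullArrheniusModel(dataset)
    >>> res = model.fit()
    >>> res.params.Ea
    """

    def __init__(self, dataset: KineticsDataset, config: FitConfig | None = None):
        self.dataset = dataset
        self.config = config or FitConfig()
        if len(dataset.curves) < 2:
            raise ValueError(
                "simultaneous identification needs curves at >= 2 temperatures"
            )
        times, yields, temps, y_eqs = [], [], [], []
        for curve in dataset.curves:
            t = curve.times_array()
            y = curve.yields_array()
            if self.config.use_replicate_means:
                t, y = _replicate_means(t, y)
            times.append(t)
            yields.append(y)
            temps.append(np.full(t.shape, celsius_to_kelvin(curve.temperature_C)))
            y_eqs.append(np.full(t.shape, curve.equilibrium_yield))
        self._t = np.concatenate(times)
        self._y = np.concatenate(yields)
        self._T = np.concatenate(temps)
        self._yeq = np.concatenate(y_eqs)
        if self._t.size < 4:
            raise ValueError(
                f"need >= 4 observations to identify 3 parameters with "
                f"dof >= 1, got {self._t.size}"
            )

    @classmethod
    def from_dataframe(cls, frame, config: FitConfig | None = None):
        """Build from a long-format DataFrame.

        Requires columns ``condition, response, temperature_C, time_s,
        yield_pct``; equilibrium yields are the mean yield at each curve's
        terminal time.
        """
        from .io import dataset_from_frame  # local import avoids a cycle

        return cls(dataset_from_frame(frame), config=config)

    # ---- objective -----------------------------------------------------

    def _mean_from_theta(self, theta: np.ndarray) -> np.ndarray:
        log_alpha = theta[0] * _LN10 + theta[1] / (GAS_CONSTANT * self._T)
        beta = np.exp(theta[2])
        with np.errstate(divide="ignore"):
            log_ratio = np.log(self._t) - log_alpha
        exponent = np.where(self._t > 0, np.exp(beta * log_ratio), 0.0)
        return self._yeq * (-np.expm1(-exponent))

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self._y - self._mean_from_theta(theta)

    # ---- initialisation ------------------------------------------------

    def _linearized_start(self) -> np.ndarray | None:
        """Per-curve log-log Weibull fits, then Arrhenius regression.

        For each curve, -ln(1 - Y/Y_eq) = (t/alpha)**beta, so regressing
        ln(-ln(1 - Y/Y_eq)) on ln t gives beta (slope) and alpha
        (from the intercept). ln alpha against 1/T then yields ln alpha0
        (intercept) and Ea/R (slope).
        """
        ln_alphas, inv_T, betas = [], [], []
        for curve in self.dataset.curves:
            t = curve.times_array()
            y = curve.yields_array()
            frac = y / curve.equilibrium_yield
            keep = (t > 0) & (frac > 1e-6) & (frac < 1.0 - 1e-6)
            if keep.sum() < 2:
                continue
            z = np.log(-np.log1p(-frac[keep]))
            slope, intercept = np.polyfit(np.log(t[keep]), z, 1)
            if slope <= 0:
                continue
            betas.append(slope)
            ln_alphas.append(-intercept / slope)
            inv_T.append(1.0 / celsius_to_kelvin(curve.temperature_C))
        if len(ln_alphas) < 2:
            return None
        ea_over_R, ln_alpha0 = np.polyfit(inv_T, ln_alphas, 1)
        theta = np.array(
            [
                ln_alpha0 / _LN10,
                max(ea_over_R, 0.0) * GAS_CONSTANT,
                np.log(np.mean(betas)),
            ]
        )
        lo = np.array([b[0] for b in self.config.bounds])
        hi = np.array([b[1] for b in self.config.bounds])
        return np.clip(theta, lo, hi)

    def _multistart_grid(self) -> list[np.ndarray]:
        n = self.config.multistart_grid
        axes = [
            np.linspace(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), n)
            for lo, hi in self.config.bounds
        ]
        grid = [np.array(p) for p in np.stack(np.meshgrid(*axes), -1).reshape(-1, 3)]
        rng = np.random.default_rng(self.config.seed)
        rng.shuffle(grid)
        return grid

    # ---- fitting -------------------------------------------------------

    def fit(self) -> "WeibullArrheniusResults":
        """Minimise the pooled sum of squared yield residuals.

        Tries the data-driven start first, then multistart grid points until
        a converged solution is found; the best (lowest-RSS) solution wins.
        """
        cfg = self.config
        lo = np.array([b[0] for b in cfg.bounds])
        hi = np.array([b[1] for b in cfg.bounds])
        if np.any(lo > hi):
            raise ValueError("each bound needs low <= high")
        # equal bounds pin a parameter; widen infinitesimally for the solver
        pinned = lo == hi
        hi = np.where(pinned, hi + np.maximum(np.abs(hi) * 1e-12, 1e-12), hi)

        starts: list[np.ndarray] = []
        if cfg.init is not None:
            starts.append(_to_internal(np.asarray(cfg.init, dtype=float)))
        else:
            lin = self._linearized_start()
            if lin is not None:
                starts.append(lin)
        grid = self._multistart_grid()

        best = None
        n_tried = 0
        for theta0 in starts + grid:
            n_tried += 1
            try:
                sol = optimize.least_squares(
                    self._residuals,
                    np.clip(theta0, lo, hi),
                    bounds=(lo, hi),
                    method="trf",
                    ftol=cfg.tolerance,
                    xtol=1e-12,
                    gtol=1e-12,
                    max_nfev=cfg.max_iterations * 4,
                )
            except Exception:  # singular steps on absurd grid corners
                continue
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
            # the data-driven start plus a handful of grid starts suffice;
            # stop early once a converged optimum has been reproduced
            if best is not None and best.success and n_tried >= len(starts) + 8:
                break
        if best is None:
            raise RuntimeError("all optimisation starts failed")
        return self._results_from_solution(best)

    def _results_from_solution(self, sol) -> "WeibullArrheniusResults":
        theta = sol.x
        resid = self._residuals(theta)
        rss = float(resid @ resid)
        n_obs = resid.size
        dof = n_obs - 3
        J = sol.jac  # Jacobian of residuals wrt internal theta
        sigma2 = rss / dof if dof > 0 else np.nan
        JtJ = J.T @ J
        rank_deficient = False
        try:
            cov_internal = sigma2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            rank_deficient = True
            cov_internal = sigma2 * np.linalg.pinv(JtJ)
            warnings.warn(
                "J'J is singular: parameters are not jointly identified; "
                "confidence intervals use a pseudo-inverse and may be wide",
                RuntimeWarning,
                stacklevel=3,
            )
        if np.linalg.cond(JtJ) > 1e12 and not rank_deficient:
            rank_deficient = True
            warnings.warn(
                "J'J is near-singular (condition number > 1e12); "
                "confidence intervals may be unreliable",
                RuntimeWarning,
                stacklevel=3,
            )
        natural = _to_natural(theta)
        params = WeibullArrheniusParams(*natural)
        return WeibullArrheniusResults(
            model=self,
            params=params,
            theta_internal=theta,
            cov_internal=cov_internal,
            ssr=rss,
            nobs=n_obs,
            df_resid=dof,
            converged=bool(sol.success),
            n_iterations=int(sol.nfev),
            rank_deficient=rank_deficient,
        )


@dataclass(frozen=True)
class WeibullArrheniusResults:
    """Fit results: point estimates, covariance, intervals, diagnostics.

    Covariance is kept on the internal (log10 alpha0, Ea, log beta) scale;
    ``bse`` and ``conf_int`` map to the natural scale via the delta method.
    """

    model: WeibullArrheniusModel
    params: WeibullArrheniusParams
    theta_internal: np.ndarray
    cov_internal: np.ndarray
    ssr: float
    nobs: int
    df_resid: int
    converged: bool
    n_iterations: int
    rank_deficient: bool = False

    param_names = ("alpha0", "Ea", "beta")

    @property
    def bse_internal(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_internal), 0.0, None))

    @property
    def bse(self) -> np.ndarray:
        """Delta-method standard errors on the natural (alpha0, Ea, beta) scale."""
        return self.bse_internal * np.abs(_natural_jacobian_diag(self.theta_internal))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Per-parameter (low, high) on the natural scale, shape (3, 2).

        t-intervals are formed on the internal (log10 alpha0, Ea, log beta)
        scale and their endpoints mapped through the monotone parameter
        transform.  For the log-scale parameters this respects the skew of
        their sampling distribution; a symmetric natural-scale interval for
        alpha0 (which ranges over orders of magnitude) undercovers badly.
        """
        if not self.converged:
            warnings.warn(
                "confidence intervals from a non-converged fit",
                RuntimeWarning,
                stacklevel=2,
            )
        internal = t_confidence_intervals(
            self.theta_internal, self.bse_internal, self.df_resid, level
        )
        return np.column_stack(
            [_to_natural(internal[:, 0]), _to_natural(internal[:, 1])]
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model._mean_from_theta(self.theta_internal)

    @property
    def resid(self) -> np.ndarray:
        return self.model._y - self.fittedvalues

    def predict(self, times: Sequence[float], temperature_C: float,
                y_eq: float | None = None) -> np.ndarray:
        """Predicted yields at new times/temperature.

        ``y_eq`` defaults to the equilibrium yield of the fitted curve at
        that temperature (must then match one of the dataset temperatures).
        """
        if y_eq is None:
            matches = [
                c.equilibrium_yield
                for c in self.model.dataset.curves
                if np.isclose(c.temperature_C, temperature_C)
            ]
            if not matches:
                raise ValueError(
                    f"no fitted curve at {temperature_C} degC; pass y_eq explicitly"
                )
            y_eq = matches[0]
        alpha = alpha_at_temperature(self.params, celsius_to_kelvin(temperature_C))
        return np.asarray(
            weibull_yield(np.asarray(times, float), alpha, self.params.beta, y_eq)
        )

    def mre(self) -> float:
        """Mean relative error (%) of the fit, excluding t = 0 observations."""
        from .evaluation import mean_relative_error

        keep = self.model._t > 0
        return mean_relative_error(self.model._y[keep], self.fittedvalues[keep])

    def summary(self, level: float = 0.95) -> str:
        """Human-readable parameter table in the style of regression summaries."""
        ci = self.conf_int(level)
        ds = self.model.dataset
        lines = [
            "Weibull-Arrhenius extraction kinetics",
            "=" * 66,
            f"condition: {ds.condition:<10} response: {ds.response}",
            f"temperatures (degC): {', '.join(f'{t:g}' for t in ds.temperatures_C)}",
            f"n_obs: {self.nobs}   dof: {self.df_resid}   RSS: {self.ssr:.4g}   "
            f"converged: {self.converged}",
            f"MRE of fit: {self.mre():.2f} %",
            "-" * 66,
            f"{'param':<8}{'estimate':>12}{'std err':>12}"
            f"{f'[{level:.0%} CI':>16}{']':>14}",
        ]
        est = [self.params.alpha0, self.params.Ea, self.params.beta]
        for name, e, se, (lo, hi) in zip(self.param_names, est, self.bse, ci):
            lines.append(f"{name:<8}{e:>12.4g}{se:>12.3g}{lo:>16.4g}{hi:>14.4g}")
        lines.append("=" * 66)
        lines.append("alpha(T) = alpha0*exp(+Ea/(R*T)); alpha0 [s], Ea [J/mol]")
        return "\n".join(lines)


def _replicate_means(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average replicate yields sharing one sampling time."""
    ut = np.unique(t)
    if ut.size == t.size:
        return t, y
    ym = np.array([y[t == v].mean() for v in ut])
    return ut, ym


def fit_weibull_arrhenius(
    dataset: KineticsDataset, config: FitConfig | None = None
) -> WeibullArrheniusResults:
    """Functional entry point: build the model and fit it."""
    return WeibullArrheniusModel(dataset, config=config).fit()
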