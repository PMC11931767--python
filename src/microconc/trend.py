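"""Log-linear trend in repeat probability.

The probability that a case occurs at a repeat location is modelled as
``P(repeat = 1) = exp(b0 + b1 * year)`` — a Bernoulli outcome with a log
link (log-binomial regression), so ``exp(b1)`` is the relative risk per
year, not an odds ratio.  Log-binomial likelihoods are famously fragile
near the ``p = 1`` boundary; when the primary fit fails to converge the
model refits as a Poisson working model with robust (sandwich) standard
errors, the standard fallback for risk-ratio estimation.

The interface follows the statsmodels convention: build a
:class:`RepeatTrendModel` from data, call :meth:`~RepeatTrendModel.fit`,
and read estimates off the returned :class:`RepeatTrendResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cases import CaseSeries

__all__ = [
    "RepeatTrendModel",
    "RepeatTrendResults",
    "DerivedQuantities",
    "DegenerateOutcomeError",
    "InsufficientVariationError",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateOutcomeError(ValueError):
    """All outcomes identical; the trend is not estimable."""


class InsufficientVariationError(ValueError):
    """Fewer than two distinct year values."""


@dataclass(frozen=True)
class DerivedQuantities:
    """Presentation-scale summaries of a fitted per-year relative risk.

    ``annual_pct_change`` is ``100 * (rr - 1)``;
    ``aggregate_relative_reduction`` is ``100 * (1 - rr**span)`` over the
    stated span; the absolute percentage-point reduction applies that
    relative change to a baseline concentration, and ``events_shifted``
    scales it by the mean annual event count.
    """

    annual_pct_change: float
    aggregate_relative_reduction: float
    absolute_pp_reduction: float | None
    events_shifted: float | None
    span_years: float


class RepeatTrendModel:
    """Log-binomial model of the repeat indicator on study year.

    Parameters
    ----------
    repeat : array of {0, 1}
        Per-case repeat indicator.
    year : array of float
        Per-case year value (integer calendar year by default; may be
        fractional).  Centered at its minimum internally for numerical
        stability; the slope is unaffected.
    """

    def __init__(self, repeat, year):
        self.repeat = np.asarray(repeat, dtype=float)
        self.year = np.asarray(year, dtype=float)
        if self.repeat.shape != self.year.shape:
            raise ValueError("repeat and year must have the same length")
        if not np.isin(self.repeat, (0.0, 1.0)).all():
            raise ValueError("repeat must be binary")
        self.n_cases = len(self.repeat)

    @classmethod
    def from_case_series(
        cls, series: CaseSeries, year_coding: str = "integer"
    ) -> "RepeatTrendModel":
        """Build the model from an assigned series with repeat computed.

        ``year_coding='integer'`` uses the calendar year;
        ``'fractional'`` adds the within-year fraction of the date
        (day-of-year / 365.25).
        """
        if not series.has_repeat:
            raise ValueError("repeat indicators must be computed first")
        dates = series.data["date"]
        if year_coding == "integer":
            year = dates.dt.year.to_numpy(dtype=float)
        elif year_coding == "fractional":
            year = (
                dates.dt.year + (dates.dt.dayofyear - 0.5) / 365.25
            ).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown year_coding {year_coding!r}")
        return cls(series.data["repeat"].to_numpy(dtype=float), year)

    # ------------------------------------------------------------------
    def _aggregate(self):
        """Collapse to unique year values with success/failure counts."""
        x, inverse = np.unique(self.year, return_inverse=True)
        succ = np.bincount(inverse, weights=self.repeat)
        tot = np.bincount(inverse).astype(float)
        return x, succ, tot

    def fit(self, method: str = "auto") -> "RepeatTrendResults":
        """Fit and return results.

        ``method`` is ``'auto'`` (log-binomial with Poisson-robust
        fallback), ``'log_binomial'`` or ``'poisson_robust'``.
        """
        total = self.repeat.sum()
        if total == 0 or total == self.n_cases:
            raise DegenerateOutcomeError(
                "all repeat indicators identical "
                f"({int(self.repeat[0])}); trend not estimable"
            )
        x, succ, tot = self._aggregate()
        if len(x) < 2:
            raise InsufficientVariationError(
                "at least two distinct year values are required"
            )
        x0 = x.min()
        if method in ("auto", "log_binomial"):
            res = self._fit_log_binomial(x - x0, succ, tot)
            if res is not None:
                return self._wrap(res, "log_binomial", True)
            if method == "log_binomial":
                raise RuntimeError("log-binomial fit failed to converge")
        res = self._fit_poisson_robust(x0)
        return self._wrap(res, "poisson_robust", True)

    def _fit_log_binomial(self, xc, succ, tot):
        endog = np.column_stack([succ, tot - succ])
        exog = sm.add_constant(xc)
        # start from an OLS line through the empirical log-proportions
        p_hat = np.clip(succ / tot, 1e-6, 1 - 1e-6)
        beta = np.polyfit(xc, np.log(p_hat), 1)
        start = np.array([min(beta[1], -1e-6), beta[0]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    endog, exog, family=sm.families.Binomial(sm.families.links.Log())
                )
                res = model.fit(start_params=start, maxiter=200, tol=1e-10)
        except (ValueError, np.linalg.LinAlgError):
            return None
        if not res.converged or not np.all(np.isfinite(res.bse)):
            return None
        if np.any(res.fittedvalues > 1.0 + 1e-12):
            return None
        return res

    def _fit_poisson_robust(self, x0):
        # modified Poisson on individual-level data with sandwich errors
        exog = sm.add_constant(self.year - x0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(self.repeat, exog, family=sm.families.Poisson())
            return model.fit(cov_type="HC1", maxiter=200)

    def _wrap(self, res, family_used, converged):
        log_rr = float(res.params[1])
        se = float(res.bse[1])
        return RepeatTrendResults(
            model=self,
            log_rr=log_rr,
            se_log_rr=se,
            p_value=float(res.pvalues[1]),
            family_used=family_used,
            converged=converged,
            n_cases=self.n_cases,
            _sm_results=res,
        )


@dataclass
class RepeatTrendResults:
    """Fitted per-year relative risk with uncertainty."""

    model: RepeatTrendModel
    log_rr: float
    se_log_rr: float
    p_value: float
    family_used: str
    converged: bool
    n_cases: int
    _sm_results: object = None

    @property
    def rr_per_year(self) -> float:
        return float(np.exp(self.log_rr))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = np.exp(self.log_rr - _Z95 * self.se_log_rr)
        hi = np.exp(self.log_rr + _Z95 * self.se_log_rr)
        return (float(lo), float(hi))

    def derive_quantities(
        self,
        span_years: float,
        baseline_concentration: float | None = None,
        mean_annual_events: float | None = None,
    ) -> DerivedQuantities:
        """Translate the fitted RR into presentation-scale summaries."""
        if span_years < 0:
            raise ValueError("span_years must be non-negative")
        rr = self.rr_per_year
        annual = 100.0 * (rr - 1.0)
        aggregate = 100.0 * (1.0 - rr**span_years)
        absolute = (
            baseline_concentration * aggregate
            if baseline_concentration is not None
            else None
        )
        shifted = (
            absolute / 100.0 * mean_annual_events
            if absolute is not None and mean_annual_events is not None
            else None
        )
        return DerivedQuantities(
            annual_pct_change=annual,
            aggregate_relative_reduction=aggregate,
            absolute_pp_reduction=absolute,
            events_shifted=shifted,
            span_years=span_years,
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "rr_per_year": self.rr_per_year,
            "log_rr": self.log_rr,
            "se_log_rr": self.se_log_rr,
            "ci95_low": lo,
            "ci95_high": hi,
            "p_value": self.p_value,
            "family_used": self.family_used,
            "converged": self.converged,
            "n_cases": self.n_cases,
        }

    def summary(self) -> str:
        lo, hi = self.ci95
        lines = [
            "Repeat-location trend (log-binomial / relative-risk scale)",
            "=" * 58,
            f"n cases:            {self.n_cases}",
            f"family:             {self.family_used}",
            f"RR per year:        {self.rr_per_year:.3f}",
            f"95% CI:             ({lo:.3f}, {hi:.3f})",
            f"p (Wald, 2-sided):  {self.p_value:.3g}",
            f"annual change:      {100 * (self.rr_per_year - 1):+.1f}% per year",
        ]
        return "\n".join(lines)
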