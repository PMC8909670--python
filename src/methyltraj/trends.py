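"""Competitive fitting of functional forms of age and Gompertz-style timescales.

Five candidate trends (plus a plain linear form) are fitted to (age, value)
pairs: quadratic, logarithmic, and square-root forms by closed-form linear
least squares on transformed regressors; the saturating exponential
``a (1 - exp(-b x))`` and the sum-of-two-exponentials
``a (1 + c - exp(-b x) - c exp(-d x))`` by multi-start nonlinear least
squares seeded from a rate grid, exploiting that the amplitude parameters
are linear given the rates.  Fits are compared by the Gaussian
maximum-likelihood AIC that counts the error variance as a parameter.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Rate grid for the multi-start nonlinear fits.
RATE_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 2.0)

#: Floor applied to age for the logarithmic form only (log is undefined at 0).
LOG_AGE_FLOOR = 0.1

FIVE_FORMS = ("quadratic", "logarithmic", "square_root",
              "exponential", "double_exponential")


class FitError(ValueError):
    pass


def _eval_quadratic(c, x):
    return c[0] + c[1] * x + c[2] * x ** 2


def _eval_logarithmic(c, x):
    return c[0] + c[1] * np.log(np.maximum(x, LOG_AGE_FLOOR))


def _eval_square_root(c, x):
    return c[0] + c[1] * np.sqrt(x)


def _safe_exp(z):
    # clamp the exponent so optimizer excursions to extreme rates cannot overflow
    return np.exp(np.clip(z, -745.0, 709.0))


def _eval_exponential(c, x):
    return c[0] * (1.0 - _safe_exp(-c[1] * x))


def _eval_double_exponential(c, x):
    a, b, cc, d = c
    return a * (1.0 + cc - _safe_exp(-b * x) - cc * _safe_exp(-d * x))


def _eval_linear(c, x):
    return c[0] + c[1] * x


@dataclasses.dataclass(frozen=True)
class TrendForm:
    name: str
    n_coefficients: int
    evaluate: Callable[[Sequence[float], np.ndarray], np.ndarray]


FORMS: Dict[str, TrendForm] = {
    "quadratic": TrendForm("quadratic", 3, _eval_quadratic),
    "logarithmic": TrendForm("logarithmic", 2, _eval_logarithmic),
    "square_root": TrendForm("square_root", 2, _eval_square_root),
    "exponential": TrendForm("exponential", 2, _eval_exponential),
    "double_exponential": TrendForm("double_exponential", 4, _eval_double_exponential),
    "linear": TrendForm("linear", 2, _eval_linear),
}


@dataclasses.dataclass
class TrendFit:
    form: TrendForm
    coefficients: Tuple[float, ...]
    rss: float
    rmse: float
    r_squared: float
    aic: float
    n: int
    converged: bool = True


@dataclasses.dataclass
class GompertzReference:
    """Published mortality-hazard parameters ``mu(x) = alpha * exp(beta x)``.

    ``alpha`` is carried for completeness and never fitted here.
    """

    beta: float
    alpha: Optional[float] = None
    source_doubling_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise FitError("beta must be > 0")


def aic_from_rss(rss: float, n: int, n_coefficients: int) -> float:
    """Gaussian ML AIC: ``n ln(2 pi rss/n) + n + 2 (n_coefficients + 1)``.

    The error variance counts as a parameter.  A perfect fit (rss = 0) has
    an unbounded likelihood; negative infinity is returned as the marker.
    """
    if rss < 0:
        raise FitError("rss must be >= 0")
    if rss == 0.0:
        return -math.inf
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (n_coefficients + 1)


def aic(fit: TrendFit) -> float:
    return aic_from_rss(fit.rss, fit.n, fit.form.n_coefficients)


def _metrics(form: TrendForm, coeffs, x, y, converged=True) -> TrendFit:
    resid = y - form.evaluate(coeffs, x)
    rss = float(resid @ resid)
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    constant = np.ptp(y) == 0.0
    r2 = 0.0 if constant else 1.0 - rss / tss
    return TrendFit(form=form, coefficients=tuple(float(c) for c in coeffs),
                    rss=rss, rmse=math.sqrt(rss / n), r_squared=r2,
                    aic=aic_from_rss(rss, n, form.n_coefficients),
                    n=n, converged=converged)


def _linear_fit(form: TrendForm, design: np.ndarray, x, y) -> TrendFit:
    coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise FitError(f"singular design matrix for form {form.name!r}")
    return _metrics(form, coeffs, x, y)


def _amplitudes_given_rates(x, y, rates) -> Tuple[np.ndarray, float]:
    """Least-squares amplitudes for y = sum_k u_k (1 - exp(-rate_k x))."""
    g = np.column_stack([1.0 - np.exp(-r * x) for r in rates])
    coeffs, _, rank, _ = np.linalg.lstsq(g, y, rcond=None)
    if rank < g.shape[1]:
        return None, np.inf
    resid = y - g @ coeffs
    return coeffs, float(resid @ resid)


def _refine(x, y, fun, p0) -> Tuple[np.ndarray, float, bool]:
    res = optimize.least_squares(lambda p: fun(p, x) - y, p0, method="lm",
                                 max_nfev=2000)
    return res.x, float(2.0 * res.cost), bool(res.success)


def _fit_exponential(x, y, grid) -> TrendFit:
    candidates = []
    for b in grid:
        coeffs, rss = _amplitudes_given_rates(x, y, (b,))
        if coeffs is not None:
            candidates.append((rss, (coeffs[0], b)))
    if not candidates:
        raise FitError("no admissible exponential start")
    candidates.sort(key=lambda t: t[0])
    best_rss, best_p, ok = np.inf, None, False
    for rss0, p0 in candidates[:3]:
        p, rss, success = _refine(x, y, _eval_exponential, np.asarray(p0))
        if rss < best_rss:
            best_rss, best_p, ok = rss, p, success
    return _metrics(FORMS["exponential"], best_p, x, y, converged=ok)


def _order_double_exponential(p) -> Tuple[float, float, float, float]:
    """Resolve the (b, d) label-swap symmetry: report with b <= d.

    Swapping the two exponentials maps (a, b, c, d) -> (a c, d, 1/c, b),
    which leaves the fitted values unchanged.
    """
    a, b, c, d = (float(v) for v in p)
    if b > d and c != 0.0:
        a, b, c, d = a * c, d, 1.0 / c, b
    return a, b, c, d


def _fit_double_exponential(x, y, grid) -> TrendFit:
    candidates = []
    for b, d in itertools.combinations(grid, 2):
        coeffs, rss = _amplitudes_given_rates(x, y, (b, d))
        if coeffs is None:
            continue
        u, v = coeffs
        if abs(u) < 1e-12:
            continue
        candidates.append((rss, (u, b, v / u, d)))
    if not candidates:
        raise FitError("no admissible double-exponential start")
    candidates.sort(key=lambda t: t[0])
    best_rss, best_p, ok = np.inf, None, False
    for rss0, p0 in candidates[:5]:
        p, rss, success = _refine(x, y, _eval_double_exponential, np.asarray(p0))
        if rss < best_rss:
            best_rss, best_p, ok = rss, p, success
    coeffs = _order_double_exponential(best_p)
    return _metrics(FORMS["double_exponential"], coeffs, x, y, converged=ok)


def fit_trend(x, y, form: str, multi_start: Sequence[float] = RATE_GRID) -> TrendFit:
    """Fit one functional form of age by least squares.

    Polynomial-type forms are solved in closed form; exponential forms run
    damped nonlinear least squares from every admissible point of the rate
    grid and keep the minimum-RSS solution.  ``converged=False`` flags a fit
    where no refinement reported success (the best candidate is still
    returned).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if form not in FORMS:
        raise FitError(f"unknown form {form!r}")
    spec = FORMS[form]
    if len(x) <= spec.n_coefficients:
        raise FitError("need more points than coefficients")
    if (x < 0).any():
        raise FitError("ages must be >= 0")
    if form == "quadratic":
        return _linear_fit(spec, np.column_stack([np.ones_like(x), x, x ** 2]), x, y)
    if form == "logarithmic":
        lx = np.log(np.maximum(x, LOG_AGE_FLOOR))
        return _linear_fit(spec, np.column_stack([np.ones_like(x), lx]), x, y)
    if form == "square_root":
        return _linear_fit(spec, np.column_stack([np.ones_like(x), np.sqrt(x)]), x, y)
    if form == "linear":
        return _linear_fit(spec, np.column_stack([np.ones_like(x), x]), x, y)
    if form == "exponential":
        return _fit_exponential(x, y, multi_start)
    return _fit_double_exponential(x, y, multi_start)


def compare_forms(x, y, forms: Sequence[str] = FIVE_FORMS,
                  multi_start: Sequence[float] = RATE_GRID) -> pd.DataFrame:
    """Fit the candidate forms and rank them by AIC (ascending).

    Per-form failures are recorded in the table, never fatal.  The winner is
    flagged in the ``best`` column.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= 5:
        raise FitError("need more than 5 points")
    rows = []
    for name in forms:
        try:
            fit = fit_trend(x, y, name, multi_start)
            rows.append({"form": name,
                         "coefficients": ",".join(f"{c:.10g}" for c in fit.coefficients),
                         "aic": fit.aic, "rmse": fit.rmse,
                         "r_squared": fit.r_squared, "converged": fit.converged,
                         "error": ""})
        except (FitError, np.linalg.LinAlgError) as exc:
            logger.warning("fit of %s failed: %s", name, exc)
            rows.append({"form": name, "coefficients": "", "aic": math.inf,
                         "rmse": math.nan, "r_squared": math.nan,
                         "converged": False, "error": str(exc)})
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["best"] = [i == 0 for i in range(len(table))]
    return table


def doubling_time(beta: float) -> float:
    """Years for an exponential process at rate ``beta``/year to double."""
    if beta <= 0:
        raise FitError("beta must be > 0")
    return math.log(2.0) / beta


def pearson_with_p(a, b) -> Tuple[float, float]:
    """Pearson r with the two-sided p from the t-transform (n - 2 df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(a) != len(b):
        raise FitError("need two equal-length vectors with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise FitError("inputs must be non-constant")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def format_p(p: float, floor: float = 1e-300) -> str:
    """Human-readable p value; below the representable range prints '< 1e-300'."""
    return f"< {floor:g}" if p < floor else f"{p:.3g}"
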