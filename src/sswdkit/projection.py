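"""ARIMA projection of pre-epidemic abundance and deviation flagging.

The pre-epidemic annual abundance scores (eight points, 2006-2013 in
the motivating study) are fitted with low-order ARIMA(p, d, q) models.
Candidate orders are kept deliberately small (p + q <= 2, d in {0, 1})
because eight observations cannot support more; model selection
minimises the small-sample-corrected AICc, with ties broken by the ML
residual variance and then by parsimony.  The selected model forecasts
the epidemic years, and an observed abundance falling strictly outside
the 95% prediction interval is flagged as a biologically meaningful
deviation (below / above); a value exactly on a bound counts as within.

The intercept-only model ARIMA(0, 0, 0)+c has a closed-form maximum
likelihood fit (mean, variance with divisor n) and its forecasts at any
horizon equal the pre-period mean — the behaviour the projection is
meant to reproduce for stable series.  Other orders are fitted by
Gaussian maximum likelihood (statsmodels state-space ARIMA, which picks
starting values before the ML optimisation).

AICc convention: AICc = AIC + 2k(k+1)/(n-k-1) with k counting the AR
and MA coefficients, the intercept when present, and the innovation
variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

_Z95 = 1.959964  # normal quantile for two-sided 95%
_ROOT_TOL = 1e-6


@dataclass(frozen=True)
class ArimaSpec:
    p: int
    d: int
    q: int
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be non-negative")
        if self.d > 1:
            raise ValueError("differencing order limited to d <= 1")

    def __str__(self) -> str:
        c = "+c" if self.include_intercept else ""
        return f"ARIMA({self.p},{self.d},{self.q}){c}"


@dataclass
class ArimaFit:
    """One fitted candidate model.

    ``sigma2`` is the ML innovation-variance estimate; ``aicc`` uses
    the module's documented parameter count.  ``admissible`` is False
    when any AR/MA root lies on or inside the unit circle, or the
    optimiser failed, or the fit is degenerate.
    """

    spec: ArimaSpec
    ar_coefs: np.ndarray
    ma_coefs: np.ndarray
    intercept: float
    sigma2: float
    loglik: float
    aicc: float
    residuals: np.ndarray
    converged: bool
    admissible: bool
    n_params: int
    n_obs: int
    series: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False
    _res: object = field(repr=False, default=None, compare=False)


@dataclass
class Projection:
    """h-step forecast with symmetric Gaussian prediction intervals."""

    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    se: np.ndarray
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.point) and np.all(self.point <= self.upper)):
            raise ValueError("interval must bracket the point forecast")


class ModelSelectionError(RuntimeError):
    """No admissible candidate model; carries per-spec diagnostics."""

    def __init__(self, diagnostics: dict):
        self.diagnostics = diagnostics
        super().__init__(f"no admissible ARIMA fit; diagnostics: {diagnostics}")


def aicc(loglik: float, k: int, n: int) -> float:
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _poly_roots_outside(coefs: np.ndarray, sign: float) -> bool:
    """Check roots of 1 + sign * (c1 z + c2 z^2 + ...) lie outside the unit circle."""
    if len(coefs) == 0:
        return True
    poly = np.r_[1.0, sign * np.asarray(coefs, dtype=float)]  # ascending powers
    roots = np.roots(poly[::-1])
    if len(roots) == 0:
        return True
    return bool(np.min(np.abs(roots)) > 1.0 + _ROOT_TOL)


def fit_arima(series: Sequence[float], spec: ArimaSpec) -> ArimaFit:
    """Fit one ARIMA(p,d,q) candidate by Gaussian maximum likelihood."""
    y = np.asarray(series, dtype=float)
    n = len(y)
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if n < spec.p + spec.q + spec.d + 2:
        raise ValueError(
            f"series of length {n} too short for {spec}")

    k = spec.p + spec.q + int(spec.include_intercept) + 1  # + sigma2

    if spec.p == 0 and spec.q == 0 and spec.d == 0:
        # closed-form ML: mean and variance with divisor n
        mu = float(np.mean(y)) if spec.include_intercept else 0.0
        resid = y - mu
        sigma2 = float(np.mean(resid**2))
        if sigma2 > 0:
            loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        else:
            loglik = math.inf  # degenerate: perfect fit
        return ArimaFit(
            spec=spec, ar_coefs=np.array([]), ma_coefs=np.array([]),
            intercept=mu, sigma2=sigma2, loglik=loglik,
            aicc=aicc(loglik, k, n) if np.isfinite(loglik) else -math.inf,
            residuals=resid, converged=True, admissible=True,
            n_params=k, n_obs=n, series=y,
            degenerate=not sigma2 > 0,
        )

    # degenerate input: constant series cannot identify AR/MA terms
    if np.ptp(y if spec.d == 0 else np.diff(y)) == 0:
        return ArimaFit(
            spec=spec, ar_coefs=np.full(spec.p, np.nan),
            ma_coefs=np.full(spec.q, np.nan), intercept=float(np.mean(y)),
            sigma2=math.nan, loglik=-math.inf, aicc=math.inf,
            residuals=np.full(n, np.nan), converged=False, admissible=False,
            n_params=k, n_obs=n, series=y, degenerate=True,
        )

    from statsmodels.tsa.arima.model import ARIMA as _SmARIMA

    trend = "n"
    if spec.include_intercept:
        trend = "c" if spec.d == 0 else "t"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = _SmARIMA(y, order=(spec.p, spec.d, spec.q), trend=trend)
            res = model.fit()
        converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    except Exception:
        return ArimaFit(
            spec=spec, ar_coefs=np.full(spec.p, np.nan),
            ma_coefs=np.full(spec.q, np.nan), intercept=math.nan,
            sigma2=math.nan, loglik=-math.inf, aicc=math.inf,
            residuals=np.full(n, np.nan), converged=False, admissible=False,
            n_params=k, n_obs=n, series=y,
        )

    ar = np.asarray(res.arparams, dtype=float) if spec.p else np.array([])
    ma = np.asarray(res.maparams, dtype=float) if spec.q else np.array([])
    params = res.params
    intercept = 0.0
    if spec.include_intercept:
        intercept = float(params[0])
    sigma2 = float(params[-1])
    loglik = float(res.llf)
    admissible = (
        converged
        and np.all(np.isfinite(np.r_[ar, ma, sigma2, loglik]))
        and _poly_roots_outside(ar, -1.0)
        and _poly_roots_outside(ma, +1.0)
    )
    return ArimaFit(
        spec=spec, ar_coefs=ar, ma_coefs=ma, intercept=intercept,
        sigma2=sigma2, loglik=loglik, aicc=aicc(loglik, k, n),
        residuals=np.asarray(res.resid, dtype=float),
        converged=converged, admissible=bool(admissible),
        n_params=k, n_obs=n, series=y, _res=res,
    )


def default_grid(max_order: int = 2, d_values: Iterable[int] = (0, 1)) -> list[ArimaSpec]:
    """All candidates with p + q <= max_order, intercept always included."""
    grid = []
    for d in d_values:
        for p in range(max_order + 1):
            for q in range(max_order + 1 - p):
                grid.append(ArimaSpec(p, d, q, include_intercept=True))
    return grid


def select_model(
    series: Sequence[float],
    grid: Iterable[ArimaSpec] | None = None,
) -> ArimaFit:
    """Fit all candidates and select by AICc, then sigma2, then parsimony.

    Non-convergent or inadmissible fits are excluded.  A constant
    series selects the intercept-only model (exact fit).  Raises
    :class:`ModelSelectionError` with per-spec diagnostics when no
    candidate is admissible.
    """
    grid = list(grid) if grid is not None else default_grid()
    y = np.asarray(series, dtype=float)
    if np.ptp(y) == 0:
        spec = ArimaSpec(0, 0, 0, include_intercept=True)
        if spec in grid or not grid:
            return fit_arima(y, spec)

    fits, diagnostics = [], {}
    for spec in grid:
        try:
            fit = fit_arima(y, spec)
        except ValueError as exc:
            diagnostics[str(spec)] = f"error: {exc}"
            continue
        if fit.admissible and np.isfinite(fit.aicc):
            fits.append(fit)
        else:
            reason = "degenerate" if fit.degenerate else (
                "non-convergent" if not fit.converged else "inadmissible roots")
            diagnostics[str(spec)] = reason
    if not fits:
        raise ModelSelectionError(diagnostics)

    tol = 1e-6
    best_aicc = min(f.aicc for f in fits)
    pool = [f for f in fits if f.aicc <= best_aicc + tol]
    best_s2 = min(f.sigma2 for f in pool)
    pool = [f for f in pool if f.sigma2 <= best_s2 + tol]
    return min(pool, key=lambda f: (f.n_params, str(f.spec)))


def residual_diagnostics(fit: ArimaFit) -> dict:
    """Residual autocorrelation and normality report (no pass/fail).

    ACF at lags 1..min(5, n-2) with +-1.96/sqrt(n) reference bands and
    a Shapiro-Wilk statistic; degenerate (constant) residuals are
    reported as such with no ACF.
    """
    r = np.asarray(fit.residuals, dtype=float)
    r = r[np.isfinite(r)]
    n = len(r)
    report: dict = {"n": n, "degenerate": False}
    if n < 3 or np.ptp(r) == 0:
        report["degenerate"] = True
        report["acf"] = {}
        return report
    nlags = min(5, n - 2)
    c = r - r.mean()
    denom = float(np.sum(c**2))
    acf = {lag: float(np.sum(c[lag:] * c[:-lag]) / denom) for lag in range(1, nlags + 1)}
    report["acf"] = acf
    report["acf_band"] = 1.96 / math.sqrt(n)
    w, p = sps.shapiro(r)
    report["shapiro_stat"] = float(w)
    report["shapiro_p"] = float(p)
    return report


def forecast(fit: ArimaFit, h: int = 2, level: float = 0.95) -> Projection:
    """h-step-ahead forecast with Gaussian prediction intervals.

    For the intercept-only model every forecast equals the pre-period
    ML mean with standard error sqrt(sigma2); other models use the
    fitted state-space forecast-error variances.
    """
    if h < 1:
        raise ValueError("horizon must be >= 1")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    if fit._res is None:
        if not (fit.spec.p == 0 and fit.spec.q == 0 and fit.spec.d == 0):
            raise ValueError("cannot forecast a failed fit")
        point = np.full(h, fit.intercept)
        se = np.full(h, math.sqrt(max(fit.sigma2, 0.0)))
    else:
        pred = fit._res.get_forecast(steps=h)
        point = np.asarray(pred.predicted_mean, dtype=float)
        se = np.asarray(pred.se_mean, dtype=float)
    return Projection(point=point, lower=point - z * se,
                      upper=point + z * se, se=se, level=level)


def flag_deviation(projection: Projection, observed: Sequence[float]) -> list[str]:
    """Classify each observed epidemic-year value against the interval.

    Strictly below the lower bound -> "below", strictly above the upper
    bound -> "above", otherwise (including exact ties with a bound)
    -> "within".
    """
    obs = np.asarray(observed, dtype=float)
    if len(obs) > len(projection.point):
        raise ValueError("more observations than forecast steps")
    flags = []
    for o, lo, hi in zip(obs, projection.lower, projection.upper):
        if o < lo:
            flags.append("below")
        elif o > hi:
            flags.append("above")
        else:
            flags.append("within")
    return flags


def project_series(
    series: Sequence[float],
    observed: Sequence[float],
    grid: Iterable[ArimaSpec] | None = None,
    level: float = 0.95,
) -> tuple[ArimaFit, Projection, list[str]]:
    """Select, forecast len(observed) steps and flag, in one call."""
    fit = select_model(series, grid)
    proj = forecast(fit, h=len(observed), level=level)
    return fit, proj, flag_deviation(proj, observed)
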