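"""Sigmoidal kinetics of marker time series and lag-phase classification.

Marker trajectories are fit with the four-parameter logistic

    y(t) = y0 + (ymax - y0) / (1 + exp(-k (t - t50)))

and the lag time is the conventional tangent construction: the intersection
of the maximum-slope tangent with the initial plateau, lag = t50 - 2/k,
floored at zero.  Aggregation without a detectable lag (immediate change) is
amorphous-like; a distinct lag marks amyloid-like nucleation-elongation
kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .exceptions import DomainError, InsufficientDataError, UndefinedLagError
from .markers import MarkerSeries

DEFAULT_LAG_THRESHOLD_H = 2.0  # the smallest gap in the default sampling grid
K_BOUNDS = (1e-4, 10.0)  # h^-1


def logistic4(t: np.ndarray, y0: float, ymax: float, k: float, t50: float) -> np.ndarray:
    return y0 + (ymax - y0) * expit(k * (t - t50))


@dataclass
class SigmoidFit:
    """A fitted four-parameter logistic; ``lag = max(t50 - 2/k, 0)``."""

    y0: float
    ymax: float
    k: float  # h^-1, > 0 when converged
    t50: float  # h
    r_squared: float
    converged: bool
    direction: str = "none"  # increase | decrease | none
    residual_rms: float = float("nan")

    @property
    def lag(self) -> float:
        return max(self.t50 - 2.0 / self.k, 0.0)


def fit_sigmoid(series: MarkerSeries) -> SigmoidFit:
    """Weighted logistic fit with a multi-start over the observed time grid.

    Flat series (variance indistinguishable from the noise floor) return
    ``converged=False`` with direction "none" rather than a spurious fit.
    """
    mask = np.isfinite(series.values)
    t = series.times[mask]
    y = series.values[mask]
    if t.size < 5:
        raise InsufficientDataError("sigmoid fit needs >= 5 non-missing points")
    if t[-1] - t[0] < 10.0:
        raise InsufficientDataError("sigmoid fit needs a time span of >= 10 h")

    scale = max(float(np.max(np.abs(y))), 1e-12)
    if float(np.std(y)) < 1e-9 * scale:
        return SigmoidFit(float(y[0]), float(y[0]), K_BOUNDS[0], float(t[0]),
                          0.0, False, "none", 0.0)

    sig = series.uncertainties[mask]
    w = np.ones_like(y)
    if np.all(np.isfinite(sig)) and np.all(sig > 0):
        w = 1.0 / sig

    span = t[-1] - t[0]
    # plateaus bounded near the data range: keeps the optimizer off the
    # degenerate huge-amplitude/tiny-slope ridge of the logistic surface
    y_span = float(np.max(y) - np.min(y))
    y_lo = float(np.min(y)) - 2.0 * y_span
    y_hi = float(np.max(y)) + 2.0 * y_span
    lb = [y_lo, y_lo, K_BOUNDS[0], t[0] - span]
    ub = [y_hi, y_hi, K_BOUNDS[1], t[-1] + span]

    def residual(p):
        return w * (logistic4(t, *p) - y)

    best = None
    for t50_0 in t:
        for k0 in (0.05, 0.5):
            x0 = np.clip([y[0], y[-1], k0, t50_0], lb, ub)
            res = least_squares(residual, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000)
            if best is None or res.cost < best.cost:
                best = res

    y0, ymax, k, t50 = (float(v) for v in best.x)
    pred = logistic4(t, y0, ymax, k, t50)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rms = float(np.sqrt(ss_res / t.size))

    amplitude = abs(ymax - y0)
    significant = amplitude > max(3.0 * rms, 1e-9 * scale)
    converged = bool(best.success) and significant
    direction = "none"
    if converged:
        direction = "increase" if ymax > y0 else "decrease"
    return SigmoidFit(y0, ymax, k, t50, r2, converged, direction, rms)


def lag_time(fit: SigmoidFit) -> float:
    """Tangent-construction lag time in hours, floored at zero."""
    if not fit.converged:
        raise UndefinedLagError("lag time is undefined for a non-converged fit")
    return fit.lag


def classify_kinetics(
    fits: list[SigmoidFit], lag_threshold: float = DEFAULT_LAG_THRESHOLD_H
) -> str:
    """amorphous_like (no lag), amyloid_like (distinct lag) or indeterminate.

    The median lag across converged fits is compared with ``lag_threshold``
    (default 2 h, the sampling resolution of the early time grid: a shorter
    lag is not distinguishable from an immediate change).
    """
    if not fits:
        raise DomainError("classify_kinetics needs at least one fit")
    converged = [f for f in fits if f.converged]
    if not converged:
        return "indeterminate"
    median_lag = float(np.median([f.lag for f in converged]))
    if median_lag > lag_threshold:
        return "amyloid_like"
    return "amorphous_like"
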