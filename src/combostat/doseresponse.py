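"""Two-parameter Hill concentration-response curves.

The Loewe additivity analysis needs, for each single drug, a monotone
concentration-response curve and its inverse.  The classical two-parameter
Hill model is used,

    R(c) = 1 / (1 + (c / c50)**H),

with fixed asymptotes R(0) = 1 and R(inf) = 0; ``c50`` is the concentration
of half-maximal survival and ``H`` the Hill slope.  Both parameters are
estimated jointly by least squares on the per-concentration replicate
means.  Start values come from an exact two-point solution of the Hill
equation; a small multi-start guards against local minima.

A curve is declared ``computable = False`` when the data are essentially
flat (fitted dynamic range below a threshold), when the fitted c50 lands
absurdly far outside the tested ladder, or when the optimizer fails.  Any
Loewe quantity built on a non-computable curve is reported as NA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

_CLAMP = 1e-6  # used only in the closed-form start values, never the objective


@dataclass
class DoseResponseCurve:
    """Fitted Hill parameters for one drug.

    ``dynamic_range`` is the fitted response span over the tested ladder,
    R(c_min) - R(c_max); a near-zero span means the data carry no
    concentration-response information and the curve is unusable.
    """

    c50: Optional[float]
    H: Optional[float]
    fit_sse: float = np.nan
    computable: bool = True
    dynamic_range: float = np.nan

    def __post_init__(self) -> None:
        if self.computable:
            if self.c50 is None or self.H is None or self.c50 <= 0 or self.H <= 0:
                raise ValueError("computable curve requires c50 > 0 and H > 0")


def _hill(c, c50: float, H: float):
    c = np.asarray(c, dtype=float)
    out = np.ones_like(c)
    pos = c > 0
    # exp/log form avoids overflow for extreme slopes
    t = np.exp(np.clip(H * np.log(c[pos] / c50), -700.0, 700.0))
    out[pos] = 1.0 / (1.0 + t)
    if np.ndim(c) == 0:
        return float(out)
    return out


def hill_response(c, curve: DoseResponseCurve):
    """Survival R(c) predicted by the curve; R(0) = 1."""
    if not curve.computable:
        raise ValueError("curve is not computable")
    if np.any(np.asarray(c) < 0):
        raise ValueError("concentration must be non-negative")
    return _hill(c, curve.c50, curve.H)


def hill_inverse(s, curve: DoseResponseCurve):
    """Concentration at survival level s: c = c50 * ((1-s)/s)**(1/H).

    Defined for 0 < s < 1 only; outside that range the Hill curve (and
    hence the Loewe isobole construction) has no inverse.
    """
    if not curve.computable:
        raise ValueError("curve is not computable")
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr <= 0) or np.any(s_arr >= 1):
        raise ValueError("survival level must lie strictly between 0 and 1")
    out = curve.c50 * np.exp(np.log((1.0 - s_arr) / s_arr) / curve.H)
    if np.ndim(s) == 0:
        return float(out)
    return out


def _two_point_start(concs: np.ndarray, resp: np.ndarray) -> tuple[float, float]:
    """Closed-form Hill parameters through two data points.

    Prefers the pair bracketing s = 0.5 (the responses nearest the midpoint
    from above and below); falls back to the two most separated responses.
    Responses are clamped away from {0, 1} for the logs.
    """
    s = np.clip(resp, _CLAMP, 1.0 - _CLAMP)
    above = np.flatnonzero(s >= 0.5)
    below = np.flatnonzero(s < 0.5)
    if len(above) and len(below):
        i1 = above[np.argmin(s[above] - 0.5)]
        i2 = below[np.argmin(0.5 - s[below])]
    else:
        i1 = int(np.argmax(s))
        i2 = int(np.argmin(s))
    c1, c2, s1, s2 = concs[i1], concs[i2], s[i1], s[i2]
    H0 = np.nan
    if c1 != c2 and s1 != s2:
        H0 = np.log((1.0 / s1 - 1.0) / (1.0 / s2 - 1.0)) / np.log(c1 / c2)
    if not np.isfinite(H0) or H0 <= 0:
        H0 = 1.0
    c50_0 = c1 * (1.0 / s1 - 1.0) ** (-1.0 / H0)
    if not np.isfinite(c50_0) or c50_0 <= 0:
        c50_0 = float(np.exp(np.mean(np.log(concs))))
    return float(c50_0), float(H0)


def fit_hill(
    concs: Sequence[float],
    responses: Sequence[float],
    include_zero_anchor: bool = True,
    multistart: int = 3,
    flat_range_min: float = 0.1,
) -> DoseResponseCurve:
    """Least-squares fit of the two-parameter Hill model.

    Parameters are optimized on a log scale (positivity built in), starting
    from the two-point closed form plus deterministic perturbed starts.
    ``include_zero_anchor`` appends an untreated point (c = 0, s = 1); with
    the asymptotes fixed at 1 and 0 this point is reproduced exactly by any
    parameter value, so it only documents the normalization and never
    steers the fit.
    """
    concs = np.asarray(concs, dtype=float)
    responses = np.asarray(responses, dtype=float)
    ok = np.isfinite(concs) & np.isfinite(responses) & (concs >= 0)
    concs, responses = concs[ok], responses[ok]
    if include_zero_anchor and not np.any(concs == 0):
        concs = np.concatenate([[0.0], concs])
        responses = np.concatenate([[1.0], responses])
    pos = concs > 0
    if np.sum(pos) < 2 or len(np.unique(concs[pos])) < 2:
        return DoseResponseCurve(None, None, computable=False, dynamic_range=0.0)

    obs_range = float(np.max(responses[pos]) - np.min(responses[pos]))
    if obs_range < flat_range_min:
        logger.info("flat concentration-response (range %.3g); curve not computable", obs_range)
        return DoseResponseCurve(None, None, computable=False, dynamic_range=obs_range)

    c50_0, H0 = _two_point_start(concs[pos], responses[pos])

    def resid(theta):
        return _hill(concs, np.exp(theta[0]), np.exp(theta[1])) - responses

    factors = [(1.0, 1.0), (3.0, 0.5), (1.0 / 3.0, 2.0), (10.0, 1.0), (0.1, 1.0)]
    best = None
    for fc, fh in factors[: max(1, multistart)]:
        theta0 = np.log([c50_0 * fc, H0 * fh])
        try:
            sol = least_squares(resid, theta0, method="lm", max_nfev=2000)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        logger.warning("Hill fit failed from all start values")
        return DoseResponseCurve(None, None, computable=False, dynamic_range=obs_range)

    sse, theta = best
    c50, H = float(np.exp(theta[0])), float(np.exp(theta[1]))
    cmin, cmax = float(np.min(concs[pos])), float(np.max(concs[pos]))
    dyn = float(_hill(cmin, c50, H) - _hill(cmax, c50, H))
    if dyn < flat_range_min or not (cmin / 100.0 <= c50 <= cmax * 100.0):
        logger.info(
            "Hill fit degenerate (dynamic range %.3g, c50 %.3g); curve not computable",
            dyn,
            c50,
        )
        return DoseResponseCurve(None, None, fit_sse=sse, computable=False, dynamic_range=dyn)
    return DoseResponseCurve(c50=c50, H=H, fit_sse=sse, computable=True, dynamic_range=dyn)
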