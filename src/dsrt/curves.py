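"""Four-parameter logistic dose-response fitting (bottom fixed at 0).

The response model is

    y(x) = d / (1 + 10 ** (s * (c - x)))

with ``x`` the log10 concentration, ``d`` the top asymptote (percent),
``c`` the log10 EC50 and ``s`` a positive Hill slope.  Responses are
percent inhibition (viability channels) or percent toxicity, so the
bottom asymptote is fixed at 0 and the curve is non-decreasing in dose.

Fitting is bounded nonlinear least squares with a deterministic
multi-start grid; there is no randomness anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponsePoints",
    "DoseResponseFit",
    "fit_logistic",
    "predict_response",
    "logistic",
]

#: Responses below this ceiling are treated as inactive (no optimization).
ACTIVITY_FLOOR = 10.0

#: Pre-fit clipping window for normalized responses (percent).
CLIP_LO, CLIP_HI = -20.0, 120.0

_SLOPE_BOUNDS = (0.1, 10.0)
_SLOPE_STARTS = (0.5, 1.0, 2.0)
_N_POLISH = 4  # starts polished by the optimizer, best-first
_LN10 = np.log(10.0)


def logistic(x, top, log_ec50, slope):
    """Evaluate ``top / (1 + 10 ** (slope * (log_ec50 - x)))``."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # overflow -> inf -> response 0
        return top / (1.0 + 10.0 ** (slope * (log_ec50 - x)))


@dataclass(frozen=True)
class DoseResponsePoints:
    """Aggregated dose-response observations for one curve.

    Parameters
    ----------
    x
        log10 concentrations, strictly increasing after replicate
        aggregation.
    y
        Percent responses, same length as ``x``.
    readout
        Channel label carried through to the fit record.
    """

    x: tuple
    y: tuple
    readout: str = ""

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.size != y.size:
            raise ValueError(f"x and y lengths differ: {x.size} != {y.size}")
        if x.size < 2:
            raise ValueError("need at least 2 dose-response points")
        object.__setattr__(self, "x", tuple(x))
        object.__setattr__(self, "y", tuple(y))

    @classmethod
    def from_replicates(cls, x, y, readout=""):
        """Average replicate y values at identical x, sort by x."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ux = np.unique(x)
        uy = np.array([y[x == v].mean() for v in ux])
        return cls(x=tuple(ux), y=tuple(uy), readout=readout)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted logistic parameters and diagnostics.

    ``top`` is the maximum asymptote ``d`` in [0, 100], ``log_ec50``
    the midpoint ``c`` (log10 nM) and ``slope`` the positive Hill
    coefficient ``s``.  The bottom asymptote is fixed at 0.
    """

    top: float
    log_ec50: float
    slope: float
    rss: float
    converged: bool
    n_points: int
    degenerate: str = "none"  # none | flat_zero | flat_max | non_converged
    readout: str = ""
    bottom: float = field(default=0.0, init=False)

    @property
    def ec50(self) -> float:
        """EC50 on the linear concentration scale (nM)."""
        return 10.0 ** self.log_ec50


def predict_response(fit: DoseResponseFit, x):
    """Predicted percent response of a fit at log10 concentration ``x``.

    Degenerate flat fits predict their constant level everywhere.
    """
    if fit.degenerate == "non_converged":
        raise ValueError("cannot predict from a non-converged fit")
    if fit.degenerate in ("flat_zero", "flat_max"):
        return np.broadcast_to(fit.top, np.shape(x)).copy() if np.ndim(x) else fit.top
    return logistic(x, fit.top, fit.log_ec50, fit.slope)


def _flat_fit(level, y, n, degenerate, readout):
    level = float(np.clip(level, 0.0, 100.0))
    rss = float(np.sum((np.asarray(y, dtype=float) - level) ** 2))
    return DoseResponseFit(
        top=level,
        log_ec50=float("nan"),
        slope=1.0,
        rss=rss,
        converged=True,
        n_points=n,
        degenerate=degenerate,
        readout=readout,
    )


def fit_logistic(points: DoseResponsePoints) -> DoseResponseFit:
    """Fit the bounded logistic model to one set of dose-response points.

    Responses are clipped to [-20, 120] before fitting.  Curves whose
    maximum observed response does not exceed the 10% activity floor are
    returned as flat-zero fits without optimization; fewer than 3
    distinct doses yields a flat fit at the mean response.  Otherwise a
    bounded trust-region least-squares fit is run from every point of a
    fixed (c, s) start grid (c over the tested doses, s in {0.5, 1, 2})
    and the solution with the lowest residual sum of squares wins; exact
    RSS ties break toward the smallest slope, then the smallest c.
    """
    x = np.asarray(points.x, dtype=float)
    y = np.clip(np.asarray(points.y, dtype=float), CLIP_LO, CLIP_HI)
    if np.all(np.isnan(y)):
        raise ValueError("all responses missing")
    keep = ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = x.size

    if np.max(y) <= ACTIVITY_FLOOR:
        return _flat_fit(0.0, y, n, "flat_zero", points.readout)
    if np.unique(x).size < 3:
        return _flat_fit(float(np.mean(y)), y, n, "flat_max", points.readout)

    lo = np.array([0.0, x.min() - 1.0, _SLOPE_BOUNDS[0]])
    hi = np.array([100.0, x.max() + 1.0, _SLOPE_BOUNDS[1]])

    def resid(theta):
        return logistic(x, *theta) - y

    def jac(theta):
        d, c, s = theta
        u = 10.0 ** (s * (c - x))
        g = 1.0 / (1.0 + u)
        w = d * u * g * g * _LN10
        return np.column_stack([g, -w * s, -w * (c - x)])

    # rank the fixed (c, s) start grid by its initial objective, using the
    # conditionally optimal top for each start, then polish the best starts
    starts = []
    for c0 in x:
        for s0 in _SLOPE_STARTS:
            g = 1.0 / (1.0 + 10.0 ** (s0 * (c0 - x)))
            denom = float(g @ g)
            d0 = float(np.clip((g @ y) / denom if denom > 0 else 100.0,
                               1.0, 100.0))
            rss0 = float(np.sum((d0 * g - y) ** 2))
            starts.append((rss0, float(c0), s0, d0))
    starts.sort(key=lambda s: (s[0], s[2], s[1]))

    best = None
    for rss0, c0, s0, d0 in starts[:_N_POLISH]:
        theta0 = np.clip(np.array([d0, c0, s0]), lo, hi)
        sol = least_squares(
            resid, theta0, jac=jac, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        rss = float(np.sum(sol.fun ** 2))
        # tie-break: rss, then slope, then c — reproducible fits
        key = (round(rss, 9), round(float(sol.x[2]), 9), round(float(sol.x[1]), 9))
        if best is None or key < best[0]:
            best = (key, sol, rss)
        if rss < 1e-14:  # numerically exact; further starts cannot improve
            break

    _, sol, rss = best
    top, c, s = (float(v) for v in sol.x)
    return DoseResponseFit(
        top=top,
        log_ec50=c,
        slope=s,
        rss=rss,
        converged=bool(sol.success),
        n_points=n,
        degenerate="none" if sol.success else "non_converged",
        readout=points.readout,
    )
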