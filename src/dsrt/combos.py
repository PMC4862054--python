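"""Bliss-independence and ZIP delta scoring of 8x8 dose-combination
matrices.

Conventions: rows of the response matrix index drug A doses, columns
drug B doses, both with dose 0 first, so row 0 / column 0 hold the
monotherapies.  Scores are reported in percentage points with positive
values meaning synergy and negative antagonism, for both models.
Observed responses are clipped to [0, 100] before any fraction math.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import (DoseResponsePoints, fit_logistic, logistic,
                     predict_response)
from scipy.optimize import least_squares

__all__ = [
    "CombinationMatrix",
    "SynergyResult",
    "bliss_expected",
    "bliss_matrix",
    "zip_delta",
    "score_combination",
    "read_combination_table",
    "write_combination_table",
]


@dataclass(frozen=True)
class CombinationMatrix:
    """8x8 percent-effect grid for one readout.

    ``drugA_doses`` / ``drugB_doses`` are 8 concentrations (nM) each
    with 0 first; ``response[i, j]`` is the percent effect at dose i of
    drug A combined with dose j of drug B.
    """

    drugA_doses: tuple
    drugB_doses: tuple
    response: np.ndarray
    readout: str = ""
    drugA_id: str = ""
    drugB_id: str = ""

    def __post_init__(self):
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", resp)
        for name in ("drugA_doses", "drugB_doses"):
            doses = tuple(float(v) for v in getattr(self, name))
            if len(doses) != resp.shape[0 if name == "drugA_doses" else 1]:
                raise ValueError(f"{name} length does not match response shape")
            if doses[0] != 0.0:
                raise ValueError(f"{name} must start with the zero dose")
            if any(d <= 0.0 for d in doses[1:]):
                raise ValueError(f"{name} nonzero doses must be positive")
            object.__setattr__(self, name, doses)
        if resp.ndim != 2 or np.isnan(resp).any():
            raise ValueError("response must be a complete 2-D matrix")

    @property
    def inner_shape(self):
        return self.response.shape[0] - 1, self.response.shape[1] - 1

    def transpose(self) -> "CombinationMatrix":
        """Swap the two drugs."""
        return CombinationMatrix(
            drugA_doses=self.drugB_doses, drugB_doses=self.drugA_doses,
            response=self.response.T.copy(), readout=self.readout,
            drugA_id=self.drugB_id, drugB_id=self.drugA_id)


@dataclass
class SynergyResult:
    readout: str
    bliss: np.ndarray
    bliss_mean: float
    zip_delta_matrix: np.ndarray | None = None
    zip_mean_delta: float | None = None
    zip_fallback_slices: list = field(default_factory=list)


def bliss_expected(fa, fb):
    """Bliss-independent expected effect fraction: fa + fb - fa*fb."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if np.any((fa < 0) | (fa > 1) | (fb < 0) | (fb > 1)):
        raise ValueError("effect fractions must lie in [0, 1]")
    return fa + fb - fa * fb


def _fractions(m: CombinationMatrix) -> np.ndarray:
    return np.clip(m.response, 0.0, 100.0) / 100.0


def bliss_matrix(m: CombinationMatrix):
    """Excess over Bliss independence for every inner cell.

    Each inner cell (i>=1, j>=1) scores
    ``100 * (f_obs[i, j] - bliss_expected(f_mono_A[i], f_mono_B[j]))``.

    Returns ``(matrix, mean)`` with the inner (n-1)x(n-1) score matrix
    and its unweighted mean.
    """
    f = _fractions(m)
    fa = f[1:, 0][:, None]  # drug A monotherapy (column 0)
    fb = f[0, 1:][None, :]  # drug B monotherapy (row 0)
    excess = 100.0 * (f[1:, 1:] - bliss_expected(fa, fb))
    return excess, float(excess.mean())


def _conditional_fit(x, y, bottom):
    """Least-squares logistic with fixed bottom, top bounded by 100.

    Model: y = b + (d - b) / (1 + 10**(s (c - x))).  Returns predicted
    values at ``x`` or None when optimization fails.
    """
    x = np.asarray(x, dtype=float)
    y = np.clip(np.asarray(y, dtype=float), 0.0, 100.0)
    lo = np.array([bottom, x.min() - 1.0, 0.1])
    hi = np.array([100.0, x.max() + 1.0, 10.0])
    if bottom >= 100.0:
        return np.full_like(x, 100.0)

    def resid(theta):
        d, c, s = theta
        return bottom + (d - bottom) / (1.0 + 10.0 ** (s * (c - x))) - y

    d0 = float(np.clip(y.max(), bottom + 1e-6, 100.0))
    best = None
    for c0 in np.quantile(x, [0.25, 0.5, 0.75]):
        for s0 in (0.5, 1.0, 2.0):
            theta0 = np.clip(np.array([d0, c0, s0]), lo, hi)
            try:
                sol = least_squares(resid, theta0, bounds=(lo, hi),
                                    method="trf", xtol=1e-10, ftol=1e-10)
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        return None
    d, c, s = best[1]
    return bottom + (d - bottom) / (1.0 + 10.0 ** (s * (c - x)))


def _mono_effects(m: CombinationMatrix):
    """Fit monotherapy curves from row 0 / column 0.

    Returns fitted percent effects at the nonzero doses of each drug.
    """
    xa = np.log10(np.asarray(m.drugA_doses[1:]))
    xb = np.log10(np.asarray(m.drugB_doses[1:]))
    ya = np.clip(m.response[1:, 0], 0.0, 100.0)
    yb = np.clip(m.response[0, 1:], 0.0, 100.0)
    fit_a = fit_logistic(DoseResponsePoints(tuple(xa), tuple(ya)))
    fit_b = fit_logistic(DoseResponsePoints(tuple(xb), tuple(yb)))
    ea = np.asarray(predict_response(fit_a, xa), dtype=float)
    eb = np.asarray(predict_response(fit_b, xb), dtype=float)
    return xa, xb, ea, eb


def zip_delta(m: CombinationMatrix):
    """ZIP delta: curve-smoothed combination effect minus the Bliss
    expectation of the fitted monotherapy effects.

    For each fixed drug B dose j, the responses along drug A are re-fit
    with a logistic whose bottom is pinned at drug B's fitted
    monotherapy effect at j (top bounded by 100); symmetrically along
    drug B.  The smoothed combination effect in each inner cell is the
    mean of the two directional fits; delta subtracts the Bliss
    expectation of the fitted monotherapy effects.  Slices whose
    conditional fit fails fall back to the observed values and are
    listed in the returned fallback log.

    Returns ``(delta_matrix, mean_delta, fallback_slices)``.
    """
    xa, xb, ea, eb = _mono_effects(m)
    obs = np.clip(m.response, 0.0, 100.0)
    n_a, n_b = m.inner_shape
    fallbacks = []

    along_a = np.empty((n_a, n_b))  # fits varying drug A, fixed B dose j
    for j in range(n_b):
        pred = _conditional_fit(xa, obs[1:, j + 1], bottom=float(eb[j]))
        if pred is None:
            fallbacks.append(("B", j + 1))
            pred = obs[1:, j + 1]
        along_a[:, j] = pred
    along_b = np.empty((n_a, n_b))  # fits varying drug B, fixed A dose i
    for i in range(n_a):
        pred = _conditional_fit(xb, obs[i + 1, 1:], bottom=float(ea[i]))
        if pred is None:
            fallbacks.append(("A", i + 1))
            pred = obs[i + 1, 1:]
        along_b[i, :] = pred

    smoothed = (along_a + along_b) / 2.0
    fa = np.clip(ea, 0.0, 100.0)[:, None] / 100.0
    fb = np.clip(eb, 0.0, 100.0)[None, :] / 100.0
    delta = smoothed - 100.0 * bliss_expected(fa, fb)
    return delta, float(delta.mean()), fallbacks


def score_combination(matrices, model: str = "both") -> dict:
    """Score one or more readout matrices with Bliss and/or ZIP.

    ``matrices`` is a mapping readout -> :class:`CombinationMatrix` (or
    a single matrix).  Returns a mapping readout ->
    :class:`SynergyResult`; both models are computed independently per
    readout so synergy in one readout and antagonism in another are
    visible side by side.
    """
    if isinstance(matrices, CombinationMatrix):
        matrices = {matrices.readout or "default": matrices}
    if not matrices:
        raise ValueError("at least one readout matrix is required")
    if model not in ("bliss", "zip", "both"):
        raise ValueError(f"unknown model {model!r}")
    results = {}
    for readout, m in matrices.items():
        excess, mean = bliss_matrix(m)
        result = SynergyResult(readout=readout, bliss=excess, bliss_mean=mean)
        if model in ("zip", "both"):
            delta, mean_delta, fallbacks = zip_delta(m)
            result.zip_delta_matrix = delta
            result.zip_mean_delta = mean_delta
            result.zip_fallback_slices = fallbacks
        results[readout] = result
    return results


def write_combination_table(matrices, path) -> None:
    """Write matrices as long-format TSV (drugA_conc, drugB_conc,
    readout, response)."""
    rows = []
    items = (matrices.items() if isinstance(matrices, dict)
             else [(m.readout, m) for m in matrices])
    for readout, m in items:
        for i, da in enumerate(m.drugA_doses):
            for j, db in enumerate(m.drugB_doses):
                rows.append((da, db, readout, m.response[i, j]))
    pd.DataFrame(rows, columns=["drugA_conc", "drugB_conc", "readout",
                                "response"]).to_csv(path, sep="\t", index=False)


def read_combination_table(path) -> dict:
    """Read a long-format combination TSV into per-readout matrices."""
    df = pd.read_csv(path, sep="\t")
    need = {"drugA_conc", "drugB_conc", "readout", "response"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    out = {}
    for readout, grp in df.groupby("readout"):
        da = np.sort(grp["drugA_conc"].unique())
        db = np.sort(grp["drugB_conc"].unique())
        wide = grp.pivot_table(index="drugA_conc", columns="drugB_conc",
                               values="response").loc[da, db]
        out[readout] = CombinationMatrix(
            drugA_doses=tuple(da), drugB_doses=tuple(db),
            response=wide.to_numpy(), readout=str(readout))
    return out
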