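"""Drug sensitivity scores (DSS), selective DSS, anchored deltas and
cytotoxic/cytostatic response classification.

DSS is a normalized area under the fitted dose-response curve above an
activity threshold ``t``, integrated in log10-concentration space over
the tested range [x1, x2] only.  With the logistic curve
``y(x) = d / (1 + 10**(s (c - x)))`` the area has the closed form

    I = (d / (s ln 10)) * [ln(1 + 10**(s (x - c)))]  from x1' to x2

where x1' is the dose at which the curve crosses the threshold
(clamped to x1), and

    DSS1 = 100 * (I - t (x2 - x1')) / ((100 - t) (x2 - x1))

clipped to [0, 100].  An independent numerical-integration oracle is
provided so the closed form can be cross-checked at run time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .curves import DoseResponseFit, DoseResponsePoints, fit_logistic, predict_response

__all__ = [
    "DssConfig",
    "DssRecord",
    "ControlPanel",
    "dss1",
    "dss",
    "closed_form_vs_numeric",
    "sdss",
    "classify_response",
    "anchored_delta_dss",
    "score_screen",
    "build_control_panel",
]

log = logging.getLogger(__name__)

#: Default classification thresholds in DSS units.
T_VIAB_DEFAULT = 10.0
T_TOX_DEFAULT = 5.0


@dataclass(frozen=True)
class DssConfig:
    """Parameters of the DSS integral.

    ``t`` is the activity threshold in percent, ``x1``/``x2`` the log10
    bounds of the tested concentration range, ``variant`` the score
    flavour (only DSS1 is implemented; see :func:`dss`).
    """

    t: float = 10.0
    x1: float = 0.0
    x2: float = 4.0
    variant: str = "DSS1"

    def __post_init__(self):
        if not 0.0 < self.t < 100.0:
            raise ValueError(f"threshold t must be in (0, 100), got {self.t}")
        if self.x2 <= self.x1:
            raise ValueError(f"x2 must exceed x1 ({self.x1} >= {self.x2})")
        if self.variant not in ("DSS1", "DSS2", "DSS3"):
            raise ValueError(f"unknown DSS variant {self.variant!r}")


@dataclass(frozen=True)
class DssRecord:
    cell_line: str
    compound_id: str
    readout: str
    dss: float
    ec50: float
    top: float
    sdss: float = float("nan")
    class_label: str = ""


def _threshold_crossing(fit: DoseResponseFit, t: float) -> float:
    """Log10 dose where the fitted curve reaches the threshold ``t``."""
    # y(x) = t  =>  x = c - (1/s) log10(d/t - 1)
    return fit.log_ec50 - math.log10(fit.top / t - 1.0) / fit.slope


def dss1(fit: DoseResponseFit, cfg: DssConfig) -> float:
    """DSS1 for a fitted curve, in [0, 100].

    Returns 0 when the top asymptote does not exceed the activity
    threshold.  Degenerate flat fits are scored as constant responses.
    """
    d, t, x1, x2 = fit.top, cfg.t, cfg.x1, cfg.x2
    if d <= t:
        return 0.0
    if fit.degenerate in ("flat_zero", "flat_max"):
        # constant response d over the whole range
        score = 100.0 * (d - t) / (100.0 - t)
        return float(np.clip(score, 0.0, 100.0))
    s, c = fit.slope, fit.log_ec50
    x1p = max(x1, _threshold_crossing(fit, t))
    if x1p >= x2:
        return 0.0
    ln10 = math.log(10.0)

    def antideriv(x):
        # numerically safe log(1 + 10**(s (x - c)))
        return np.logaddexp(0.0, s * (x - c) * ln10) * d / (s * ln10)

    integral = antideriv(x2) - antideriv(x1p)
    score = 100.0 * (integral - t * (x2 - x1p)) / ((100.0 - t) * (x2 - x1))
    return float(np.clip(score, 0.0, 100.0))


def dss(fit: DoseResponseFit, cfg: DssConfig) -> float:
    """Dispatch on ``cfg.variant``; only DSS1 is currently defined."""
    if cfg.variant != "DSS1":
        raise NotImplementedError(
            f"{cfg.variant} normalization is not transcribed; use DSS1"
        )
    return dss1(fit, cfg)


def closed_form_vs_numeric(fit: DoseResponseFit, cfg: DssConfig) -> float:
    """|closed-form area - adaptive numerical integral| (oracle check).

    Integrates :func:`~dsrt.curves.predict_response` over [x1', x2] with
    adaptive quadrature and compares against the closed-form area used
    inside :func:`dss1`.  Both are zero when ``top <= t``.
    """
    d, t = fit.top, cfg.t
    if d <= t:
        return 0.0
    x1p = max(cfg.x1, _threshold_crossing(fit, t))
    if x1p >= cfg.x2:
        return 0.0
    numeric, _ = quad(lambda x: predict_response(fit, x), x1p, cfg.x2,
                      epsabs=1e-10, epsrel=1e-10, limit=200)
    s, c = fit.slope, fit.log_ec50
    ln10 = math.log(10.0)
    closed = (np.logaddexp(0.0, s * (cfg.x2 - c) * ln10)
              - np.logaddexp(0.0, s * (x1p - c) * ln10)) * d / (s * ln10)
    return float(abs(closed - numeric))


@dataclass
class ControlPanel:
    """Reference-panel mean DSS per (compound, readout) for sDSS.

    ``means`` maps ``(compound_id, readout)`` to the panel-average DSS;
    ``panel_sizes`` records how many cell lines contributed.
    """

    means: dict = field(default_factory=dict)
    panel_sizes: dict = field(default_factory=dict)
    description: str = ""

    def mean(self, compound_id: str, readout: str) -> float:
        return self.means[(compound_id, readout)]


def build_control_panel(records, description: str = "") -> ControlPanel:
    """Average DSS over a reference screen to build an sDSS panel.

    ``records`` is a DataFrame with columns cell_line, compound_id,
    readout, dss (as produced by :func:`score_screen`).
    """
    df = pd.DataFrame(records)
    grouped = df.groupby(["compound_id", "readout"])["dss"]
    means = grouped.mean().to_dict()
    sizes = grouped.size().to_dict()
    return ControlPanel(means=means, panel_sizes=sizes, description=description)


def sdss(dss_value: float, panel: ControlPanel, compound_id: str, readout: str) -> float:
    """Selective DSS: DSS minus the panel mean for the same compound.

    Missing panel entries yield NaN (logged) so downstream steps can
    exclude them.
    """
    try:
        return float(dss_value - panel.mean(compound_id, readout))
    except KeyError:
        log.warning("no control-panel entry for (%s, %s); sDSS undefined",
                    compound_id, readout)
        return float("nan")


def classify_response(dss_viab: float, dss_tox: float,
                      t_viab: float = T_VIAB_DEFAULT,
                      t_tox: float = T_TOX_DEFAULT) -> str:
    """Joint label over the viability and toxicity readouts.

    cytotoxic if the toxicity DSS reaches ``t_tox``; cytostatic if only
    the viability DSS reaches ``t_viab``; inactive otherwise.
    """
    if dss_tox >= t_tox:
        return "cytotoxic"
    if dss_viab >= t_viab:
        return "cytostatic"
    return "inactive"


def anchored_delta_dss(dss_with_anchor: float, dss_alone: float,
                       flag_threshold: float = 10.0):
    """Library-compound DSS shift caused by a fixed-dose anchor drug.

    Returns ``(delta, flag)`` where flag is "potentiation" when the
    anchored score exceeds the single-agent score by more than the
    threshold, "antagonism" for the opposite, else None.
    """
    delta = float(dss_with_anchor - dss_alone)
    if delta > flag_threshold:
        return delta, "potentiation"
    if delta < -flag_threshold:
        return delta, "antagonism"
    return delta, None


def score_screen(normalized: pd.DataFrame, cfg: DssConfig | None = None,
                 panel: ControlPanel | None = None,
                 viab_readout: str = "viab_lum", tox_readout: str = "tox_fluor",
                 t_viab: float = T_VIAB_DEFAULT,
                 t_tox: float = T_TOX_DEFAULT) -> pd.DataFrame:
    """Fit curves and score every cell line x compound x readout.

    Parameters
    ----------
    normalized
        Long table from :func:`dsrt.plates.normalize_screen` with
        columns cell_line, compound_id, conc, readout, value (sample
        wells only are used).
    cfg
        DSS configuration.  When None, x1/x2 are derived per compound
        from its tested concentration range (t = 10).
    panel
        Optional control panel; adds an sdss column.

    Returns
    -------
    DataFrame with one row per (cell_line, compound_id, readout) and
    columns dss, sdss, ec50, top, class_label (label repeated on both
    readout rows of a pair).
    """
    samples = normalized[normalized["role"] == "sample"]
    rows = []
    for (cell, comp, readout), grp in samples.groupby(
            ["cell_line", "compound_id", "readout"], sort=True):
        x = np.log10(grp["conc"].to_numpy(dtype=float))
        y = grp["value"].to_numpy(dtype=float)
        points = DoseResponsePoints.from_replicates(x, y, readout=readout)
        fit = fit_logistic(points)
        local_cfg = cfg or DssConfig(x1=float(np.min(x)), x2=float(np.max(x)))
        value = dss(fit, local_cfg)
        rows.append({
            "cell_line": cell, "compound_id": comp, "readout": readout,
            "dss": value, "ec50": fit.ec50, "top": fit.top,
        })
    out = pd.DataFrame(rows)
    if panel is not None:
        out["sdss"] = [
            sdss(r.dss, panel, r.compound_id, r.readout)
            for r in out.itertuples()
        ]
    # joint classification over the chosen viability/toxicity pair
    labels = {}
    pivot = out.pivot_table(index=["cell_line", "compound_id"],
                            columns="readout", values="dss")
    for key, row in pivot.iterrows():
        dv = row.get(viab_readout, float("nan"))
        dt = row.get(tox_readout, float("nan"))
        if np.isnan(dv) or np.isnan(dt):
            labels[key] = ""
        else:
            labels[key] = classify_response(dv, dt, t_viab=t_viab, t_tox=t_tox)
    out["class_label"] = [
        labels.get((r.cell_line, r.compound_id), "") for r in out.itertuples()
    ]
    return out
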