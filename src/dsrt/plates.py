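"""Plate-level normalization and quality control.

Raw per-well signals are normalized per plate and per readout against
the plate's own negative (DMSO) and positive (kill) control wells to
percent inhibition (viability channels) or percent toxicity (toxicity
channel).  Plate quality is summarized with the Z'-factor.

Values are deliberately NOT clipped here; clipping policy belongs to
downstream curve fitting and scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "READOUTS",
    "VIABILITY_READOUTS",
    "TOXICITY_READOUTS",
    "ROLES",
    "SCREEN_COLUMNS",
    "PlateQC",
    "read_screen_table",
    "write_screen_table",
    "percent_inhibition",
    "percent_toxicity",
    "z_prime",
    "qc_flag",
    "normalize_screen",
]

log = logging.getLogger(__name__)

VIABILITY_READOUTS = ("viab_fluor", "viab_lum")
TOXICITY_READOUTS = ("tox_fluor",)
READOUTS = VIABILITY_READOUTS + TOXICITY_READOUTS
ROLES = ("sample", "neg", "pos")

SCREEN_COLUMNS = [
    "plate_id", "well", "role", "cell_line", "compound_id", "conc",
    "readout", "signal",
]


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    readout: str
    z_prime: float
    n_neg: int
    n_pos: int
    flag: str  # pass | warn | fail


class ScreenTableError(ValueError):
    """Malformed screen table (schema or row-level problems)."""


def read_screen_table(path) -> pd.DataFrame:
    """Read and validate a long-format screen TSV.

    The file must carry the columns plate_id, well, role, cell_line,
    compound_id, conc, readout, signal (tab-separated; compound_id and
    conc empty for control wells).  Malformed rows are reported with
    their 1-based line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenTableError(f"{path}: missing columns {missing}")
    df = df[SCREEN_COLUMNS]
    # line number of each data row in the file (header is line 1)
    lines = df.index + 2

    problems = []
    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        vals = sorted(df.loc[bad_role, "role"].astype(str).unique())
        problems.append(f"unknown role values {vals} "
                        f"(lines {list(lines[bad_role])})")
    bad_readout = ~df["readout"].isin(READOUTS)
    if bad_readout.any():
        vals = sorted(df.loc[bad_readout, "readout"].astype(str).unique())
        problems.append(f"unknown readout values {vals} "
                        f"(lines {list(lines[bad_readout])})")
    is_sample = df["role"] == "sample"
    no_compound = df["compound_id"].isna() | (df["compound_id"] == "")
    bad_sample = is_sample & (no_compound | df["conc"].isna())
    if bad_sample.any():
        problems.append("sample wells missing compound_id/conc at lines "
                        f"{list(lines[bad_sample])}")
    bad_ctrl = ~is_sample & ~bad_role & ~no_compound
    if bad_ctrl.any():
        problems.append("control wells carry compound_id at lines "
                        f"{list(lines[bad_ctrl])}")
    bad_signal = df["signal"].isna() | (pd.to_numeric(df["signal"], errors="coerce") < 0)
    if bad_signal.any():
        problems.append(f"bad signal values at lines {list(lines[bad_signal])}")
    if problems:
        raise ScreenTableError(f"{path}: " + "; ".join(problems))

    df["conc"] = pd.to_numeric(df["conc"], errors="coerce")
    df["signal"] = pd.to_numeric(df["signal"]).astype(float)
    df["compound_id"] = df["compound_id"].fillna("")
    return df


def write_screen_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def percent_inhibition(signal, mu_neg: float, mu_pos: float):
    """Percent inhibition of a viability signal.

    ``100 * (mu_neg - signal) / (mu_neg - mu_pos)``: 0 at the negative
    (DMSO) control mean, 100 at the positive (kill) control mean.
    """
    if mu_neg == mu_pos:
        raise ValueError("degenerate controls: mu_neg == mu_pos")
    return 100.0 * (mu_neg - np.asarray(signal, dtype=float)) / (mu_neg - mu_pos)


def percent_toxicity(signal, mu_neg: float, mu_pos: float):
    """Percent toxicity of a cytotoxicity signal.

    The toxicity channel increases with effect, so the positive control
    carries the highest signal: ``100 * (signal - mu_neg) / (mu_pos - mu_neg)``.
    """
    if mu_neg == mu_pos:
        raise ValueError("degenerate controls: mu_neg == mu_pos")
    return 100.0 * (np.asarray(signal, dtype=float) - mu_neg) / (mu_pos - mu_neg)


def z_prime(neg_values, pos_values) -> float:
    """Z'-factor: ``1 - 3 (sd_pos + sd_neg) / |mu_pos - mu_neg|``.

    Sample standard deviations (ddof=1).  Identical control means give
    -inf so the plate fails QC rather than raising.
    """
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("need at least 2 wells per control group")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0.0:
        return float("-inf")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep)


def qc_flag(z: float, pass_at: float = 0.5, warn_at: float = 0.0) -> str:
    """pass >= 0.5 > warn >= 0 > fail (standard screening convention)."""
    if z >= pass_at:
        return "pass"
    if z >= warn_at:
        return "warn"
    return "fail"


def normalize_screen(wells: pd.DataFrame, robust: bool = False):
    """Normalize a raw screen table and compute per-plate QC.

    Each (plate, readout) group is normalized against its own control
    means (medians when ``robust``).  Viability channels map to percent
    inhibition, the toxicity channel to percent toxicity.  Plates
    lacking either control group for a readout are excluded and logged.

    Returns
    -------
    normalized : DataFrame
        Input columns plus a ``value`` column (percent scale).
    qc : DataFrame
        One row per plate x readout with z_prime, control counts, flag.
    """
    center = np.median if robust else np.mean
    out_parts, qc_rows = [], []
    for (plate, readout), grp in wells.groupby(["plate_id", "readout"], sort=True):
        neg = grp.loc[grp["role"] == "neg", "signal"].to_numpy(dtype=float)
        pos = grp.loc[grp["role"] == "pos", "signal"].to_numpy(dtype=float)
        if neg.size == 0 or pos.size == 0:
            log.error("plate %s readout %s: missing control group "
                      "(n_neg=%d, n_pos=%d); plate excluded",
                      plate, readout, neg.size, pos.size)
            continue
        mu_neg, mu_pos = float(center(neg)), float(center(pos))
        norm = percent_toxicity if readout in TOXICITY_READOUTS else percent_inhibition
        part = grp.copy()
        part["value"] = norm(part["signal"].to_numpy(dtype=float), mu_neg, mu_pos)
        out_parts.append(part)
        z = z_prime(neg, pos) if (neg.size >= 2 and pos.size >= 2) else float("-inf")
        qc_rows.append(PlateQC(plate_id=plate, readout=readout, z_prime=z,
                               n_neg=int(neg.size), n_pos=int(pos.size),
                               flag=qc_flag(z)))
    normalized = (pd.concat(out_parts, ignore_index=True)
                  if out_parts else pd.DataFrame(columns=[*wells.columns, "value"]))
    qc = pd.DataFrame([vars(q) for q in qc_rows],
                      columns=["plate_id", "readout", "z_prime", "n_neg",
                               "n_pos", "flag"])
    return normalized, qc
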