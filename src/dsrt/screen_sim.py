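"""Synthetic dual-readout screen generator with known ground truth.

Emulates a 384-well drug sensitivity and resistance testing (DSRT)
design: compound libraries at 5 ten-fold dilutions spanning a
10,000-fold range, negative (DMSO) and positive (kill) control wells on
every plate, correlated-but-distinct viability and cytotoxicity
readouts, compound-class response archetypes (broadly cytostatic
classes, classes cytotoxic only in a planted subset of cell lines,
inactives), 8x8 combination matrices with planted interactions, and
marker tables with planted responder-group differences.

Everything is driven by :class:`numpy.random.Generator` seeded from the
caller; identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .combos import CombinationMatrix
from .curves import logistic
from .plates import SCREEN_COLUMNS, TOXICITY_READOUTS

__all__ = [
    "CompoundSpec",
    "TrueResponseModel",
    "NoiseModel",
    "SyntheticTruth",
    "ClassConfig",
    "CLASS_CONFIG",
    "DEFAULT_CLASS_MIX",
    "NEG_MEAN",
    "POS_MEAN",
    "make_library",
    "make_truth",
    "simulate_plate",
    "simulate_screen",
    "simulate_combination_matrix",
    "simulate_marker_table",
]

#: Raw-signal anchors for viability channels (reversed for toxicity).
NEG_MEAN = 10_000.0
POS_MEAN = 200.0

#: Control wells per 384-well plate.
N_NEG_WELLS = 16
N_POS_WELLS = 8

_PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows x 24 columns = 384 wells
_N_COLS = 24
_SAMPLE_COLS = 22  # columns 23/24 reserved for controls
PLATE_CAPACITY = len(_PLATE_ROWS) * _SAMPLE_COLS  # 352 sample wells


@dataclass(frozen=True)
class CompoundSpec:
    """One library compound and its tested concentration grid."""

    compound_id: str
    drug_class: str
    conc_min: float  # nM
    n_conc: int = 5
    dilution_factor: float = 10.0

    def __post_init__(self):
        if self.n_conc < 2:
            raise ValueError(f"{self.compound_id}: n_conc must be >= 2")
        if self.dilution_factor <= 1.0:
            raise ValueError(f"{self.compound_id}: dilution_factor must be > 1")
        if self.conc_min <= 0.0:
            raise ValueError(f"{self.compound_id}: conc_min must be positive")

    @property
    def concentrations(self) -> np.ndarray:
        """Tested concentrations (nM), lowest first."""
        return self.conc_min * self.dilution_factor ** np.arange(self.n_conc)

    @property
    def fold_range(self) -> float:
        return self.dilution_factor ** (self.n_conc - 1)


@dataclass(frozen=True)
class TrueResponseModel:
    """Planted logistic response of one cell line to one compound.

    Viability channels share (top_viab, log_ec50_viab, slope); the
    toxicity channel uses (top_tox, log_ec50_tox, slope).
    """

    top_viab: float
    top_tox: float
    log_ec50_viab: float
    log_ec50_tox: float
    slope: float
    archetype: str  # cytotoxic | cytostatic | inactive

    # archetype consistency gates (percent)
    CYTOSTATIC_VIAB_FLOOR = 50.0
    INACTIVE_CEILING = 5.0

    def __post_init__(self):
        for name in ("top_viab", "top_tox"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.slope <= 0.0:
            raise ValueError("slope must be positive")
        if self.archetype == "cytostatic":
            if self.top_viab < self.CYTOSTATIC_VIAB_FLOOR:
                raise ValueError("cytostatic archetype requires high top_viab")
            if self.top_tox > self.INACTIVE_CEILING:
                raise ValueError("cytostatic archetype requires low top_tox")
        elif self.archetype == "inactive":
            if (self.top_viab > self.INACTIVE_CEILING
                    or self.top_tox > self.INACTIVE_CEILING):
                raise ValueError("inactive archetype requires both tops low")
        elif self.archetype != "cytotoxic":
            raise ValueError(f"unknown archetype {self.archetype!r}")

    def effect(self, readout: str, conc) -> np.ndarray:
        """True percent effect at concentration(s) ``conc`` (nM)."""
        x = np.log10(np.asarray(conc, dtype=float))
        if readout in TOXICITY_READOUTS:
            return logistic(x, self.top_tox, self.log_ec50_tox, self.slope)
        return logistic(x, self.top_viab, self.log_ec50_viab, self.slope)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise (CV) plus additive background.

    ``gradient`` optionally applies a linear column-wise plate gradient
    of the given relative amplitude (off by default).
    """

    cv_mult: float = 0.05
    sd_add: float = 0.0
    seed: int = 0
    gradient: float = 0.0

    def __post_init__(self):
        if self.cv_mult < 0.0 or self.sd_add < 0.0:
            raise ValueError("noise parameters must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, signal, rng: np.random.Generator) -> np.ndarray:
        """Apply noise to raw signals; result clipped at 0."""
        signal = np.asarray(signal, dtype=float)
        out = signal.copy()
        if self.cv_mult > 0.0:
            sigma = math.sqrt(math.log1p(self.cv_mult ** 2))
            factors = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, signal.shape))
            out = out * factors
        if self.sd_add > 0.0:
            out = out + rng.normal(0.0, self.sd_add, signal.shape)
        return np.clip(out, 0.0, None)


@dataclass
class ClassConfig:
    """Response policy of a drug class across a cell-line panel."""

    base_archetype: str  # archetype in non-sensitive lines
    toxic_fraction: float = 0.0  # fraction of lines with a cytotoxic response
    log_center_range: tuple = (1.5, 2.5)  # log10 nM of typical activity


#: Default class policies: broadly cytostatic targeted classes, classes
#: cytotoxic only in a subset of lines, and inactives.
CLASS_CONFIG = {
    "mTOR": ClassConfig("cytostatic", 0.10, (0.5, 2.0)),
    "PI3K": ClassConfig("cytostatic", 0.10, (1.0, 2.5)),
    "CDK": ClassConfig("cytostatic", 0.30, (1.5, 3.0)),
    "HSP90": ClassConfig("cytostatic", 0.30, (1.0, 2.5)),
    "antimetabolite": ClassConfig("cytostatic", 0.15, (1.5, 3.0)),
    "taxane": ClassConfig("cytostatic", 0.30, (0.5, 2.0)),
    "proteasome": ClassConfig("cytostatic", 0.60, (0.5, 2.0)),
    "topoisomerase": ClassConfig("cytotoxic", 1.0, (1.5, 3.0)),
    "kinase": ClassConfig("inactive", 0.20, (1.5, 3.0)),
    "inactive": ClassConfig("inactive", 0.0, (1.5, 3.0)),
}

DEFAULT_CLASS_MIX = {
    "mTOR": 0.08, "PI3K": 0.08, "CDK": 0.10, "HSP90": 0.06,
    "antimetabolite": 0.10, "taxane": 0.10, "proteasome": 0.08,
    "topoisomerase": 0.10, "kinase": 0.15, "inactive": 0.15,
}


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated screen.

    ``responses`` maps (cell_line, compound_id) to the planted
    :class:`TrueResponseModel`; ``sensitive_lines`` records, per drug
    class, the planted subset of lines with cytotoxic responses;
    ``combinations`` and ``markers`` collect interaction and marker
    truths as they are simulated.
    """

    responses: dict = field(default_factory=dict)
    compound_class: dict = field(default_factory=dict)
    sensitive_lines: dict = field(default_factory=dict)
    combinations: list = field(default_factory=list)
    markers: dict = field(default_factory=dict)

    def model(self, cell_line: str, compound_id: str) -> TrueResponseModel:
        try:
            return self.responses[(cell_line, compound_id)]
        except KeyError:
            raise KeyError(
                f"no truth for cell_line={cell_line!r}, "
                f"compound_id={compound_id!r}") from None

    def effect(self, cell_line, compound_id, readout, conc):
        return self.model(cell_line, compound_id).effect(readout, conc)

    def to_dict(self) -> dict:
        return {
            "responses": [
                {"cell_line": cl, "compound_id": cp, **asdict(m)}
                for (cl, cp), m in sorted(self.responses.items())
            ],
            "compound_class": dict(sorted(self.compound_class.items())),
            "sensitive_lines": {k: sorted(v)
                                for k, v in sorted(self.sensitive_lines.items())},
            "combinations": self.combinations,
            "markers": self.markers,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def make_library(n_compounds: int, class_mix: dict | None = None,
                 seed: int = 0, n_conc: int = 5,
                 dilution_factor: float = 10.0) -> list:
    """Build a reproducible compound library.

    Class counts follow ``class_mix`` proportions (largest-remainder
    rounding so they sum to ``n_compounds``); each compound's 5-dose
    ten-fold grid is centered on a class-typical activity concentration,
    spanning a 10,000-fold range at the defaults.
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    if not mix:
        raise ValueError("class_mix must not be empty")
    unknown = sorted(set(mix) - set(CLASS_CONFIG))
    if unknown:
        raise ValueError(f"unknown drug classes {unknown}")
    total = sum(mix.values())
    if any(p < 0 for p in mix.values()) or not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"class proportions must be nonnegative and sum to 1 "
                         f"(got {total})")
    classes = sorted(mix)
    exact = np.array([mix[c] * n_compounds for c in classes])
    counts = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - counts))[: n_compounds - counts.sum()]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    specs = []
    span = dilution_factor ** (n_conc - 1)
    for cls, count in zip(classes, counts):
        lo, hi = CLASS_CONFIG[cls].log_center_range
        for k in range(count):
            center = rng.uniform(lo, hi)  # log10 nM of relevant activity
            conc_min = 10.0 ** center / math.sqrt(span)
            specs.append(CompoundSpec(
                compound_id=f"{cls}_{k:03d}", drug_class=cls,
                conc_min=conc_min, n_conc=n_conc,
                dilution_factor=dilution_factor))
    return specs


def _sample_model(rng, cls_cfg: ClassConfig, archetype: str,
                  spec: CompoundSpec) -> TrueResponseModel:
    x_lo = math.log10(spec.conc_min)
    x_hi = math.log10(spec.concentrations[-1])
    mid = (x_lo + x_hi) / 2.0
    # active EC50s land inside the tested range so curves are resolvable
    ec50 = rng.uniform(mid - 0.75, mid + 0.5)
    slope = rng.uniform(0.8, 1.5)
    if archetype == "cytotoxic":
        top_viab = rng.uniform(70.0, 95.0)
        top_tox = rng.uniform(50.0, 90.0)
        ec50_tox = ec50 + rng.uniform(0.0, 0.5)  # death trails viability loss
    elif archetype == "cytostatic":
        top_viab = rng.uniform(60.0, 95.0)
        top_tox = rng.uniform(0.0, 3.0)
        ec50_tox = mid
    else:  # inactive
        top_viab = rng.uniform(0.0, 4.0)
        top_tox = rng.uniform(0.0, 3.0)
        ec50_tox = mid
    return TrueResponseModel(
        top_viab=top_viab, top_tox=top_tox,
        log_ec50_viab=ec50, log_ec50_tox=ec50_tox,
        slope=slope, archetype=archetype)


def make_truth(cell_lines, library, seed: int = 0) -> SyntheticTruth:
    """Plant a TrueResponseModel for every (cell line, compound).

    Each drug class gets a planted "sensitive" subset of cell lines
    (``toxic_fraction`` of the panel, at least one line when the
    fraction is positive) that responds cytotoxically; the remaining
    lines follow the class's base archetype.
    """
    cell_lines = list(cell_lines)
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    classes = sorted({s.drug_class for s in library})
    for cls in classes:
        cfg = CLASS_CONFIG[cls]
        k = int(round(cfg.toxic_fraction * len(cell_lines)))
        if cfg.toxic_fraction > 0.0:
            k = max(k, 1)
        chosen = rng.choice(len(cell_lines), size=k, replace=False) if k else []
        truth.sensitive_lines[cls] = tuple(sorted(cell_lines[i] for i in chosen))
    for spec in sorted(library, key=lambda s: s.compound_id):
        truth.compound_class[spec.compound_id] = spec.drug_class
        cfg = CLASS_CONFIG[spec.drug_class]
        sensitive = set(truth.sensitive_lines[spec.drug_class])
        for cell in cell_lines:
            archetype = "cytotoxic" if cell in sensitive else cfg.base_archetype
            truth.responses[(cell, spec.compound_id)] = _sample_model(
                rng, cfg, archetype, spec)
    return truth


def _well_name(row: int, col: int) -> str:
    return f"{_PLATE_ROWS[row]}{col + 1:02d}"


def _signal_from_effect(effect, readout: str) -> np.ndarray:
    """Control-anchored linear map of true percent effect to raw signal."""
    frac = np.asarray(effect, dtype=float) / 100.0
    if readout in TOXICITY_READOUTS:
        return POS_MEAN + frac * (NEG_MEAN - POS_MEAN)  # rises with effect
    return NEG_MEAN - frac * (NEG_MEAN - POS_MEAN)  # falls with effect


def simulate_plate(cell_line: str, specs, truth: SyntheticTruth,
                   noise: NoiseModel,
                   readouts=("viab_lum", "tox_fluor"),
                   plate_id: str = "P001",
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one 384-well plate of single-agent wells.

    Sample wells fill columns 1-22 column-major (5 consecutive wells per
    compound, lowest dose first); 16 negative controls sit in column 23
    and 8 positive controls in column 24.  Raw signals are the
    control-anchored map of the planted effect, then noise.
    """
    specs = list(specs)
    n_sample = sum(s.n_conc for s in specs)
    if n_sample > PLATE_CAPACITY:
        raise ValueError(f"plate {plate_id}: {n_sample} sample wells exceed "
                         f"capacity {PLATE_CAPACITY}")
    if rng is None:
        rng = noise.rng()

    rows = []
    idx = 0
    for spec in specs:
        model = truth.model(cell_line, spec.compound_id)  # raises with key
        for conc in spec.concentrations:
            r, col = idx % len(_PLATE_ROWS), idx // len(_PLATE_ROWS)
            for readout in readouts:
                eff = model.effect(readout, conc)
                rows.append((plate_id, _well_name(r, col), "sample", cell_line,
                             spec.compound_id, float(conc), readout,
                             float(_signal_from_effect(eff, readout))))
            idx += 1
    for i in range(N_NEG_WELLS):
        for readout in readouts:
            rows.append((plate_id, _well_name(i, 22), "neg", cell_line,
                         "", np.nan, readout,
                         float(_signal_from_effect(0.0, readout))))
    for i in range(N_POS_WELLS):
        for readout in readouts:
            rows.append((plate_id, _well_name(i, 23), "pos", cell_line,
                         "", np.nan, readout,
                         float(_signal_from_effect(100.0, readout))))

    df = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    if noise.gradient != 0.0:
        cols = df["well"].str[1:].astype(int) - 1
        df["signal"] *= 1.0 + noise.gradient * (cols / (_N_COLS - 1) - 0.5)
    df["signal"] = noise.apply(df["signal"].to_numpy(), rng)
    return df


def simulate_screen(cell_lines, library, truth: SyntheticTruth,
                    noise: NoiseModel,
                    readouts=("viab_lum", "tox_fluor")) -> pd.DataFrame:
    """Simulate a full multi-plate screen (all cell lines x library)."""
    rng = noise.rng()
    per_plate = PLATE_CAPACITY // max(s.n_conc for s in library)
    parts = []
    plate_no = 0
    for cell in cell_lines:
        for start in range(0, len(library), per_plate):
            plate_no += 1
            parts.append(simulate_plate(
                cell, library[start:start + per_plate], truth, noise,
                readouts=readouts, plate_id=f"P{plate_no:04d}", rng=rng))
    return pd.concat(parts, ignore_index=True)


def _combo_doses(spec: CompoundSpec, n: int = 7) -> np.ndarray:
    """n nonzero doses spanning the compound's tested fold-range."""
    step = spec.fold_range ** (1.0 / (n - 1))
    return spec.conc_min * step ** np.arange(n)


def simulate_combination_matrix(cell_line: str, drug_a: CompoundSpec,
                                drug_b: CompoundSpec, truth: SyntheticTruth,
                                interaction_delta, noise: NoiseModel,
                                mode: str = "uniform",
                                readouts=("viab_lum", "tox_fluor"),
                                rng: np.random.Generator | None = None):
    """Simulate an 8x8 dose-combination matrix per readout.

    Row/column 0 are monotherapies; inner cells are the Bliss-independent
    expectation of the two planted monotherapy effects plus the planted
    ``interaction_delta`` (percentage points; scalar or per-readout
    mapping), clipped to [0, 100], then noise on the percent scale.
    ``mode="dose-dependent"`` ramps the delta linearly with both dose
    indices instead of applying it uniformly.

    Returns ``(matrices, truth_record)`` with one
    :class:`~dsrt.combos.CombinationMatrix` per readout.
    """
    if mode not in ("uniform", "dose-dependent"):
        raise ValueError(f"unknown mode {mode!r}")
    deltas = (dict(interaction_delta) if isinstance(interaction_delta, dict)
              else {r: float(interaction_delta) for r in readouts})
    for r, d in deltas.items():
        if abs(d) > 100.0:
            raise ValueError(f"|interaction_delta| > 100 for readout {r}")
    if rng is None:
        rng = noise.rng()

    doses_a = np.concatenate([[0.0], _combo_doses(drug_a)])
    doses_b = np.concatenate([[0.0], _combo_doses(drug_b)])
    # noise scale: convert additive signal noise to percent units
    sd_pct = noise.sd_add / (NEG_MEAN - POS_MEAN) * 100.0
    pct_noise = NoiseModel(cv_mult=noise.cv_mult, sd_add=sd_pct, seed=noise.seed)

    matrices = {}
    for readout in readouts:
        delta = deltas.get(readout, 0.0)
        fa = np.zeros(8)
        fb = np.zeros(8)
        fa[1:] = truth.effect(cell_line, drug_a.compound_id, readout,
                              doses_a[1:]) / 100.0
        fb[1:] = truth.effect(cell_line, drug_b.compound_id, readout,
                              doses_b[1:]) / 100.0
        resp = np.empty((8, 8))
        for i in range(8):
            for j in range(8):
                expected = fa[i] + fb[j] - fa[i] * fb[j]
                cell_delta = 0.0
                if i >= 1 and j >= 1:
                    w = (i / 7.0) * (j / 7.0) if mode == "dose-dependent" else 1.0
                    cell_delta = delta * w
                resp[i, j] = np.clip(100.0 * expected + cell_delta, 0.0, 100.0)
        resp = pct_noise.apply(resp, rng)
        matrices[readout] = CombinationMatrix(
            drugA_doses=tuple(doses_a), drugB_doses=tuple(doses_b),
            response=resp, readout=readout,
            drugA_id=drug_a.compound_id, drugB_id=drug_b.compound_id)

    record = {"cell_line": cell_line, "drugA": drug_a.compound_id,
              "drugB": drug_b.compound_id, "mode": mode,
              "interaction_delta": deltas}
    truth.combinations.append(record)
    return matrices, record


def simulate_marker_table(group_a, group_b, n_markers: int = 70,
                          n_informative: int = 9, effect_size: float = 3.0,
                          seed: int = 0):
    """Simulate a marker x cell-line table with planted group differences.

    Marker values are standard normal; the first ``n_informative``
    markers (after a seeded shuffle of ids) get a mean shift of
    ``effect_size`` standard deviations in ``group_a``.

    Returns ``(table, truth)`` where truth lists the informative ids.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("responder groups must be disjoint")
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("each group needs at least 2 cell lines")
    if n_informative > n_markers:
        raise ValueError(f"n_informative ({n_informative}) exceeds "
                         f"n_markers ({n_markers})")
    rng = np.random.default_rng(seed)
    lines = group_a + group_b
    markers = [f"marker_{i:03d}" for i in range(n_markers)]
    values = rng.normal(0.0, 1.0, (n_markers, len(lines)))
    informative = sorted(rng.choice(n_markers, size=n_informative,
                                    replace=False).tolist())
    values[np.ix_(informative, range(len(group_a)))] += effect_size
    table = pd.DataFrame(values, index=markers, columns=lines)
    truth = {"informative": [markers[i] for i in informative],
             "effect_size": effect_size,
             "group_a": group_a, "group_b": group_b}
    return table, truth
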