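# dsrt

Analytics for dual-readout drug sensitivity and resistance testing
(DSRT) screens, where every compound is profiled simultaneously with
cell-viability and cytotoxicity readouts so cytostatic responses
(growth/metabolism inhibition without cell killing) can be separated
from genuinely cytotoxic ones.

The package covers the full analysis path:

- **`dsrt.screen_sim`** — synthetic screen generator with planted ground
  truth: 384-well plates with DMSO / kill controls, compound libraries at
  5 ten-fold dilutions (10,000-fold range), per-class response
  archetypes (broadly cytostatic classes, classes cytotoxic only in a
  planted subset of cell lines, inactives), 8×8 combination matrices
  with planted synergy/antagonism, and marker tables with planted
  responder-group differences.
- **`dsrt.plates`** — long-format plate table IO, per-plate
  normalization to percent inhibition / percent toxicity against the
  plate's own controls, Z'-factor QC.
- **`dsrt.curves`** — bounded logistic dose–response fitting
  (`y = d / (1 + 10^{s(c − x)})`, bottom fixed at 0) with a
  deterministic multi-start grid.
- **`dsrt.scoring`** — closed-form DSS (normalized area under the fitted
  curve above a 10% activity threshold over the tested log-range),
  selective DSS against a reference panel, anchored-combination ΔDSS
  with the |Δ| > 10 flagging rule, and joint cytotoxic / cytostatic /
  inactive classification from the viability + toxicity DSS pair.
- **`dsrt.combos`** — Bliss-independence excess and ZIP delta scoring of
  8×8 dose-combination matrices, per readout (positive = synergy,
  negative = antagonism, percentage points).
- **`dsrt.profiling`** — complete-linkage clustering of response
  profiles (Spearman distance for drugs, Euclidean for cell lines),
  TreeView-compatible CDT/GTR/ATR export, responder-group definition and
  per-marker Welch t-tests (optional Benjamini–Hochberg adjustment).

## CLI

All commands are under a single `dsrt` entry point:

```sh
# generate a synthetic screen + ground truth
dsrt simulate --config sim.yaml --out sim/ --seed 7

# normalize, QC, fit curves, write DSS matrices and classifications
dsrt score --screen sim/screen.tsv --out scored/

# Bliss / ZIP synergy for an 8x8 combination matrix (long TSV)
dsrt synergy --matrix combo.tsv --model both --out synergy.json

# cluster compound x cell-line profiles, export TreeView files
dsrt cluster --dss scored/dss_long.tsv --readout tox_fluor --prefix clust

# marker association between responder / non-responder groups
dsrt biomarkers --dss scored/dss_long.tsv --markers markers.tsv \
    --drug-class taxane --out markers_out.tsv

# anchored combination screen: delta-DSS vs single agents
dsrt anchored --alone alone_dss.tsv --with-anchor anchored_dss.tsv \
    --out delta.tsv
```

`sim.yaml` keys (all optional): `n_cell_lines`, `n_compounds`,
`class_mix` (class → proportion), `cv_mult`, `sd_add`, `readouts`.

## Data formats

- Screen TSV (long): `plate_id, well, role, cell_line, compound_id,
  conc, readout, signal`, with `role ∈ {sample, neg, pos}` and
  `readout ∈ {viab_fluor, viab_lum, tox_fluor}`.
- Combination TSV (long): `drugA_conc, drugB_conc, readout, response`
  (8×8 grid per readout, dose 0 rows/columns are the monotherapies).
- Marker TSV: markers × cell lines.
- Truth JSON: planted curve parameters, class sensitivity subsets,
  combination interaction terms, informative marker ids.
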