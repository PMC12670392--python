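# qsrrkit

Quantitative structure–retention relationship (QSRR) modelling of gas-
chromatographic retention indices for food-matrix metabolomics, plus the
two-group fold-change statistics used to describe metabolite changes under
thermal processing.

## The problem

In GC–MS metabolomics of complex food matrices (here: composite flours
made from coffee pulp and plantain byproducts), the retention index (RI)
— the elution position of a compound relative to bracketing *n*-alkanes,
with alkane Cn ≡ 100·n — is the primary chromatographic identifier. When
reference standards or library RIs are missing, an RI can be *predicted*
from molecular structure alone. `qsrrkit` implements the full workflow
around a conformation-independent multiple-linear-regression model for the
HP-5ms stationary phase:

```
RI = b0 + b1·Eta_betaS + b2·MDEC-22 + b3·MATS1p
```

where `Eta_betaS` is the extended-topochemical-atom sigma
valence-electron-mobility count, `MDEC-22` the molecular distance edge
between secondary carbons, and `MATS1p` the Moran autocorrelation of lag 1
weighted by atomic polarizability — all computed on the hydrogen-depleted
molecular graph. A frozen built-in calibration (`builtin("hp5ms")`, 186
training compounds, R² = 0.945, RMSEC = 73.8) ships for prediction-only
use.

The package covers, as importable modules with a thin CLI (`qsrrkit`):

* **molecules** — SMILES parsing, stereo-stripped canonicalization,
  duplicate merging with RI averaging;
* **descriptors** — the three model descriptors plus auxiliaries;
  matrix assembly, constant/missing filtering, correlation reduction;
* **dataset** — 70:30 training/test splits that pin the retention-range
  extremes into the training set;
* **ga** — genetic-algorithm variable subset selection with venetian-blinds
  RMSECV fitness, elitism, and a one-standard-error parsimony rule; a
  two-stage per-block protocol for vendor-scale pools;
* **model** — OLS calibration, standardized coefficients, cross-validation
  battery (LOO, venetian blinds, continuous blocks, Monte Carlo,
  bootstrap), Y-randomization, external Q²F3/RMSEP;
* **domain** — leverage applicability domain, warning leverage h* = 3p/n,
  Williams-plot data;
* **kovats** — van den Dool–Kratz and Kovats retention indices from alkane
  ladders;
* **foldchange** — fold changes, Welch/pooled t-tests, Benjamini–Hochberg
  FDR, and the "p < 0.05 or VIP > 1" significance classification, with a
  bundled 72-metabolite extrusion dataset;
* **synthetic** — seeded generators for molecule libraries, planted-signal
  descriptor data, chromatograms, and replicate abundance tables.

## Worked example

```python
import qsrrkit as qk

model = qk.builtin("hp5ms")
mols = {name: qk.parse_smiles(s) for name, s in {
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "glycerol": "OCC(O)CO",
}.items()}
matrix = qk.build_matrix(list(mols.values()), model.descriptor_names,
                         compound_ids=list(mols))
print(qk.predict(model, matrix.values))
```

Running `python examples/predict_retention.py` prints:

```
metabolite       Eta_betaS   MDEC-22    MATS1p  predicted RI
caffeine             10.75     0.000    -0.623          1400
glycerol              3.25     0.500    -0.200           721
nonanoic acid         5.50     9.333    -0.022          1240
lactic acid           3.25     0.000    -0.200           715
```

A predicted RI of 1400 for caffeine means the model expects it to elute
between the C14 and C15 *n*-alkanes on HP-5ms. Whether such a prediction
is trustworthy is decided by the applicability domain: a query with
leverage at or above h* = 3p/n (0.065 for the built-in model) is an
extrapolation (see `examples/applicability_domain.py`). The other example
scripts walk through variable selection plus the validation battery
(`select_and_validate.py`), retention indices from chromatograms
(`retention_from_chromatogram.py`), and the extrusion fold-change analysis
(`extrusion_fold_changes.py`), each printing the statistics it computes.

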