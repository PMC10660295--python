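# pairsyn

Order-invariant prediction of drug-combination synergy from SMILES pairs.

Finding synergistic drug combinations by exhaustive *ex vivo* screening is
slow and expensive; a regressor that maps a pair of compound structures to an
expected synergy score lets a screen be triaged *in silico* before anything
is synthesized.  `pairsyn` is such a pipeline for the **Bliss excess** score:
under Bliss independence two drugs with fractional effects $E_a, E_b$ should
combine to $E_a + E_b - E_a E_b$, and the excess
$S = E_{ab} - (E_a + E_b - E_a E_b)$ is positive for synergy, negative for
antagonism.  It is aimed at computational chemists and ML practitioners
working with combination-screen data (NCI-ALMANAC / DrugCombDB-style tables).

The pipeline:

* **Featurization** — each compound becomes an 881-bit PubChem/CACTVS-layout
  substructure fingerprint plus a 1024-bit radius-1 Morgan fingerprint; a
  pair is the concatenation of both compounds' blocks
  (`2 × (881 + 1024) = 3810` bits).
* **Per-cell-line regression** — one model per cancer cell line: a
  one-hidden-layer MLP trained with RAdam on MSE (NumPy implementation,
  bit-reproducible, warm-startable), with random-forest and
  gradient-boosting comparators behind the same contract.
* **Order invariance** — training rows are duplicated with inverted compound
  order; deployed predictions average the raw outputs over both orders, so
  `predict(A, B) == predict(B, A)` exactly.
* **Protocol** — unordered pair groups are split 90/10 into working/test,
  the working set is 10-folded (81/9/10 effective fractions), the
  best-by-validation-PCC fold supplies the final network, and the test set
  is touched exactly once.  Warm-start retraining, combined stratified
  training, and a pooled single-network probe reproduce the standard
  training-strategy studies.
* **Synthetic screens** — a bundled generator produces combination screens
  with known ground truth and an exact replicate-correlation ceiling, so the
  entire pipeline is testable without downloading any external dataset.

Performance is always the Pearson correlation (PCC) between measured and
predicted Bliss scores.  See `docs/methods.md` for the model, the generator's
assumptions, and numerical choices.

## Worked example

```python
from pairsyn import CellLineSynergyModel, MLPConfig, SyntheticScenario, generate_screen

scenario = SyntheticScenario.default(n_compounds=30, n_cell_lines=1, seed=7)
screen = generate_screen(scenario)          # 870 records: 435 pairs x 2 replicates
print(f"replicate-correlation ceiling: {scenario.replicate_correlation():.3f}")

model = CellLineSynergyModel(
    screen, cell_line="CELL_A",
    config=MLPConfig(hidden_width=256, epochs=80, batch_size=128),
)
results = model.fit(k=3, seed=1)
print(results.summary())
score = results.predict(
    "CC(=O)OC1=CC=CC=C1C(=O)O",       # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",   # caffeine
)
print(f"predicted Bliss excess (aspirin + caffeine): {score:+.4f}")
```

prints

```
replicate-correlation ceiling: 0.900
Cell-line synergy regression results
======================================================
cell line:        CELL_A
algorithm:        mlp
folds (k):        3
seed:             1
split plan hash:  b607c2427a6bbdd8
------------------------------------------------------
fold   val PCC    epoch-0 val PCC
   0   +0.576     -0.239
   1   +0.754     -0.100  <- best
   2   +0.624     +0.119
------------------------------------------------------
test PCC:         0.770 (bootstrap se 0.074, n=44)
======================================================
predicted Bliss excess (aspirin + caffeine): -0.0331
```

Reading it: each cross-validation fold trains a fresh network (the epoch-0
column shows the untrained network's validation PCC — near zero, confirming
no model reuse); fold 1 wins selection and is evaluated once on the held-out
10% test pairs, reaching PCC 0.77 against a replicate-noise ceiling of 0.90
at this reduced training budget.  The final line is an order-invariant
prediction for a new pair.

## Command line

```bash
pairsyn simulate --out screen.csv --seed 7          # synthetic screen CSV
pairsyn train   --config train.yaml --out models/   # per-cell CV + model files
pairsyn predict --mode drug-vs-drug --input1 aspirin --input2 caffeine \
                --models models/ --out pred.csv
pairsyn predict --mode bulk --input1 compounds.smi --models models/ --out pred.csv
```

Prediction modes mirror the four standard input styles (drug-vs-drug via a
bundled name→SMILES lookup, drug-vs-SMILES, SMILES-vs-SMILES, and a
FASTA-like bulk mode pairing consecutive records or an explicit pairs
manifest).  `tune` runs a hyperparameter grid against one fixed split plan;
`retrain` warm-starts existing models on a second dataset.  Every run writes
a manifest (config hash, seeds, versions) sufficient to reproduce it.

## Data format

Training data is a normalized synergy CSV with columns `cell_line`,
`smiles_a`, `smiles_b`, `bliss_score` (+ optional `source`); scores are
fractional Bliss excess values, positive = synergy.  Replicate rows of the
same (cell line, unordered pair) are mean-aggregated at the reader boundary
and invalid rows go to a rejects report, never a silent drop.
`pairsyn.data.convert_synergy_table` normalizes raw export dialects:

| dialect | cell line | SMILES A | SMILES B | score | units |
|---|---|---|---|---|---|
| `nci-almanac` | `CELLNAME` | `SMILES1` | `SMILES2` | `SCORE` | percent (÷100) |
| `drugcombdb` | `cell_line` | `drug_row_smiles` | `drug_col_smiles` | `synergy_bliss` | fraction |

so the core pipeline never branches on source conventions.

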