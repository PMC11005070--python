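# keratoscreen

Automated keratoconus screening from corneal tomography, built as a fully
testable toolkit: it computes the 19 curvature / elevation / thickness
screening indexes used by combined Placido + anterior-segment-OCT
topographers, classifies eyes into five diagnostic classes with a
from-scratch multilayer perceptron, and ships a synthetic corneal-phenotype
simulator so every stage can be exercised and validated without any device
data.

## Who this is for

Researchers and engineers working on corneal ectasia screening who need a
transparent, reproducible reference implementation of the classic
index-based screening chain — from raw elevation/pachymetry maps to a
winner-take-all diagnostic class — including the newer epithelial- and
stromal-thickness indexes that high-resolution AS-OCT devices provide.

## The model

Five diagnostic classes are used throughout, in fixed order: **Abn**
(abnormal/irregular), **Kcn** (keratoconus), **MyPO** (myopic post-op),
**Normal**, **SKcn** (keratoconus suspect).

Per eye, five maps on a shared polar grid (31 rings x 256 meridians over an
8 mm diameter by default): anterior and posterior elevation (mm, positive
toward the instrument), corneal, epithelial and stromal thickness (um, with
corneal = epithelial + stromal).

From these, 19 scalar indexes:

| Index | Meaning |
|---|---|
| SI^F, SI^B | inferior-minus-superior mean curvature of two 1.5 mm discs 3 mm from the vertex, on the 81/261 deg (OD) or 99/279 deg (OS) axis |
| CSI^F, CSI^B | central 1.5 mm disc mean curvature minus the 1.5-3 mm annulus mean |
| EI^F, EI^B | ectatic index: sum over Zernike coefficients of alpha_nm1 c_nm + alpha_nm2 c_nm^2, weights trained to separate Normal from Kcn |
| RMS^F, RMS^B | RMS deviation (um) from the best-fit aspho-toric reference (fixed Q = -0.2 anterior / -0.3 posterior, 8 mm zone) |
| SI^THK | the SI disc geometry applied to corneal thickness (negative in inferior thinning) |
| %TI, %EpiTI | max excess of the percentage thickness-increase profile over the normative 95th-percentile profile (corneal / epithelial) |
| Thk_Min | minimum corneal thickness in the 8 mm zone |
| K_Max^F, K_Max^B | maximum of the curvature map |
| DZ_Max^F, DZ_Max^B | signed maximum of the elevation-vs-reference deviation map |
| NPtsR | mean distance of seven notable points (thickness minima, curvature maxima, deviation maxima) from their barycenter |
| K_Avg^F, K_Avg^B | mean keratometric power of the two principal meridians over the central 3 mm |

Curvature is root-Gaussian keratometric power, D = 337.5 sqrt(k1 k2), so a
sphere of radius R mm reads 337.5 / R D.

The classifier is a multilayer perceptron with bipolar sigmoid activations
f(x) = 2/(1+exp(-sigma x)) - 1, inputs normalized to [-1, 1] by per-feature
percentile cutoffs, trained by full-batch backpropagation with momentum
against 1/0 one-hot targets (MSE loss); classification is winner-take-all
over the five output neurons.

Evaluation follows standard screening practice: stratified 70/30
train/test split, per-index ROC AUC (Mann-Whitney estimator) with
qualitative discrimination grades at cut points 0.5 / 0.7 / 0.8 / 0.95, a
5x5 confusion matrix with one-vs-rest accuracy/precision/recall/F1 per
class, and percentile normality ranges (p1/p5/p95/p99) per index.

## Worked example

Run a small synthetic screening study end to end (simulate a labeled
cohort, compute indexes, train EI weights / normative model / MLP on the
training partition, evaluate on the held-out test partition):

```bash
keratoscreen run-study -n 30 --seed 7 -o scratch/demo
```

prints the test-partition confusion matrix (9 test eyes per class at n=30):

```
True \ Assigned              Abn             Kcn            MyPO          Normal            SKcn
Abn                  9 (100.00%)       0 (0.00%)       0 (0.00%)       0 (0.00%)       0 (0.00%)
Kcn                    0 (0.00%)     9 (100.00%)       0 (0.00%)       0 (0.00%)       0 (0.00%)
MyPO                   0 (0.00%)       0 (0.00%)     9 (100.00%)       0 (0.00%)       0 (0.00%)
Normal                 0 (0.00%)       0 (0.00%)       0 (0.00%)     9 (100.00%)       0 (0.00%)
SKcn                   0 (0.00%)       0 (0.00%)       0 (0.00%)       0 (0.00%)     9 (100.00%)
```

and writes `indexes.csv` (19 indexes per eye), `auc.csv` (per-index AUC and
discrimination grade for Normal-vs-Kcn and Normal-vs-SKcn), `metrics.csv`
(per-class confusion metrics), the trained model `bundle.json`, and a
reproducibility `manifest.json`.  At this tiny scale the five phenotypes
separate perfectly; class overlap (and SKcn confusion) appears at realistic
cohort sizes — see the methods note.

Classify a single scan file with a saved bundle:

```bash
keratoscreen simulate -n 1 --seed 3 -o scratch/scans
keratoscreen classify scratch/demo/bundle.json scratch/scans/Kcn-0000.scan
```

which reports the assigned class, the five raw network outputs, all 19
index values, and a normal / borderline / abnormal flag per index.

The same chain is available as a library:

```python
from keratoscreen import RunConfig, run_screening_study

result = run_screening_study(RunConfig(seed=7))
print(result.confusion.to_text())
print(result.auc_table.head())
```

## Scan file format

Scans are sectioned UTF-8 text: a `[META]` header (scan id, laterality,
grid shape) followed by five CSV blocks (`[ANTERIOR_ELEVATION_MM]`,
`[POSTERIOR_ELEVATION_MM]`, `[CORNEAL_THICKNESS_UM]`,
`[EPITHELIAL_THICKNESS_UM]`, `[STROMAL_THICKNESS_UM]`), each an apex-value
line plus one row per ring.  Round trips are lossless at 9 significant
digits.  Proprietary device exports are out of scope.
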