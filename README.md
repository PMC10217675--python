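# fundusfuse

A tested, reusable implementation of a hybrid diabetic-retinopathy (DR)
grading pipeline for color fundus photographs. Images graded 0 (no DR) to 4
(proliferative DR) are preprocessed (resize, median filter, unsharp masking),
described by three feature blocks — 59-bin uniform local-binary-pattern (LBP)
texture histograms, 4096-wide FC-1 features from a 124-layer branching CNN,
and 2048-wide global-average-pool features from a ResNet50-topology backbone —
then reduced by Shannon-entropy scoring, optimized as a feature subset by the
Binary Dragonfly and Sine Cosine algorithms under a wrapper fitness, fused,
and classified by ten SVM/KNN presets with per-class metrics.

The package is aimed at researchers who want to study this family of
texture + deep fusion pipelines end to end on commodity hardware: every stage
is an importable, seeded, unit-tested function, and a bundled synthetic fundus
generator with ground-truth lesion inventories stands in for external graded
datasets.

## The core computations

**Uniform LBP (texture block).** For each interior pixel with intensity `t`
and its T = 8 circular neighbors `U_i`,

    code = Σ_i s(U_i − t) · 2^i,   s(d) = 1 if d ≥ 0 else 0.

Codes with at most two circular 0↔1 transitions (58 patterns) get their own
histogram bin; all others share a 59th bin. Histograms are normalized per
image, giving an N × 59 block for N images.

**Shannon-entropy selection.** With per-class masses
`rf_ik = o_ik / Σ_k o_ik` of (min-max normalized) feature i over t classes,

    E(r_i) = − Σ_k rf_ik · log2 rf_ik  ∈  [0, log2 t],

and features score `log2 t − E(r_i)`; selection keeps at-or-above-mean scores,
a fixed top-k, or iterates until a classifier's error rate is below 0.1.

**Wrapper subset optimization.** BDA and SCA search binary masks minimizing
`α·error + (1−α)·|mask|/D` (α = 0.99, error from seeded k-NN splits), using a
v-shaped transfer `T(x) = |x|/√(1+x²)` to binarize their continuous updates.
The deep ensemble `E = [F_GraphNet | F_ResNet]` is optimized, then fused with
the LBP block into the final classifier input.

**Evaluation.** Per class c, one-vs-rest: SEN = TP/(TP+FN), SPE = TN/(FP+TN),
PRE = TP/(TP+FP), F1 = 2·PRE·SEN/(PRE+SEN), overall ACC = trace(CM)/total, as
percentages, under stratified k-fold CV or a 70:30 holdout.

## Worked example

```python
from fundusfuse.pipeline import PipelineConfig, run_pipeline
import pandas as pd

out = run_pipeline(PipelineConfig(out_dir="runs/demo", seed=1))
print(pd.read_csv(out / "metrics.csv")[["preset", "ACC"]].head(4))
```

This generates 150 synthetic fundus images (30 per grade, 64 px), trains the
branching CNN for 30 epochs, extracts and entropy-selects the three blocks
(widths 10/32/32), optimizes the 64-column deep ensemble with BDA + SCA, fuses
to a width-74 final vector, and evaluates all presets with 5-fold CV. It
prints:

```
                preset        ACC
0           linear-svm  86.666667
1        quadratic-svm  74.666667
2    fine-gaussian-svm  54.000000
3  medium-gaussian-svm  61.333333
```

ACC is the pooled out-of-fold overall accuracy in percent; the linear SVM
exceeds the 80% calibrated floor for this separable synthetic fixture, while
presets mismatched to 74 sparse standardized columns (fine-Gaussian, coarse
k-NN) score much lower — the spread across presets is itself the interesting
output. The run directory also holds the optimizer mask with its fitness,
per-class metrics (`metrics.json`), stage timings and a config hash; re-running
with the same config and seed reproduces `metrics.csv` byte for byte.

The same stages are scriptable from a shell:

```bash
fundusfuse generate --out data --n-per-class 10 --image-size 64 --seed 0
fundusfuse extract --in data --out lbp.npz --extractor lbp
fundusfuse select --features lbp.npz --manifest data/manifest.csv --k 10 --out lbp10.npz
fundusfuse evaluate --features lbp10.npz --manifest data/manifest.csv --preset quadratic-svm
```

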