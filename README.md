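# cascadefis

Cascaded adaptive neuro-fuzzy (ANFIS) image classification for single-object
images — one fruit per 100×100 frame on a white background, in the style of
turntable capture datasets with a ~70/30 train/test split per class.

The pipeline is: **nine feature descriptors** (colour structure, region
shape, edge histogram, colour layout, GLCM texture, HOG, and pooled
SIFT/SURF-slot/ORB keypoints) → **independent per-group ICA** reduction to
9 components per group (7 groups × 9 = 63 features) → a **seven-level
cascade of 2-input Takagi–Sugeno fuzzy modules** → micro/macro/weighted
confusion-matrix evaluation with stratified k-fold cross-validation.

## The model

Each fuzzy module is a first-order Takagi–Sugeno system with `m` triangular
membership functions per input and a grid-partition rule base
(`n = m^k` rules):

```
mu(x; a,b,c) = max(min((x-a)/(b-a), (c-x)/(c-b)), 0)
w_j     = prod_i mu_{j,i}(x_i)            firing strength
wbar_j  = w_j / sum_i w_i                 normalisation
y       = sum_j wbar_j (p_j·x + r_j)      weighted linear consequents
```

Training is hybrid: an exact (ridge) least-squares solve of the consequent
coefficients per epoch, plus one finite-difference gradient step on the
premise parameters. The cascade wires these units level-wise: one module
per feature group at level 1 (each digesting its 9 features through an
internal chain of 2-input units), then one combiner per level fusing the
running scalar with the next group's output. Class labels enter through a
codec — one-vs-rest by default, scalar index regression optionally — and a
passthrough guard keeps level-wise training RMSE non-increasing.

Because real photographic corpora are external downloads, the package
ships a deterministic synthetic generator that emulates the same capture
statistics (single lobed-ellipse "fruit", white background, pose sweep,
class-controlled colour/shape/texture); the full experiment runs from one
seed on one CPU in a couple of minutes. A reader for the standard
`Training/<Class>/*.jpg` folder layout is included for real datasets.

## Worked example

```python
import numpy as np
from cascadefis import (CascadedAnfis, GroupReducer, evaluate,
                        extract_tables, generate)

ds = generate(n_classes=4, per_class=24, seed=0)          # 96 images
train_imgs, y_train = ds.subset("train")
test_imgs, y_test = ds.subset("test")

raw_train = extract_tables(train_imgs)                    # 7 group tables
raw_test = extract_tables(test_imgs)
reducer = GroupReducer(method="ICA", n_components=9, seed=0).fit(raw_train)
groups = lambda Z: [Z[:, g*9:(g+1)*9] for g in range(7)]

res = CascadedAnfis(list(y_train), groups(reducer.transform(raw_train))).fit()
pred = res.predict(groups(reducer.transform(raw_test)))
print(evaluate(list(y_test), pred).summary())
```

prints

```
Classification performance
=============================
Average Accuracy      1.0000
Overall Accuracy      1.0000
Precision (micro)     1.0000
Recall (micro)        1.0000
FScore (micro)        1.0000
Precision (macro)     1.0000
Recall (macro)        1.0000
FScore (macro)        1.0000
Precision (weighted)  1.0000
Recall (weighted)     1.0000
FScore (weighted)     1.0000
(n = 28, classes = 4)
```

— all 28 held-out frames of the 4 synthetic classes are classified
correctly (the generator's classes are hue-separable by construction, so
this is the expected outcome; `separability < 1` makes them overlap).
`res.summary()` reports the fitted cascade itself:

```
Modified cascaded-ANFIS classification results
================================================
Classes:               4
Codec strategy:        one-vs-rest
Feature groups:        7 x 9
Cascade levels:        7
MFs per input:         2
Epochs per unit:       1
```

The same pipeline is scriptable from the shell:

```bash
cascadefis simulate --classes 8 --per-class 100 --seed 7 --out data/
cascadefis extract --in data/Training --out train.csv
cascadefis extract --in data/Test --out test.csv
cascadefis reduce --in train.csv --out train_red.csv --reducer-out red.json
cascadefis reduce --in test.csv --reducer red.json --out test_red.csv
cascadefis train --in train_red.csv --out model.json
cascadefis evaluate --model model.json --in test_red.csv --report report.json
```

See `docs/methods.md` for the model details, parameter meanings, what the
synthetic generator does and does not emulate, and known limitations.

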