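# focusscore

Automated scoring of transformed foci in the **Bhas 42 cell transformation
assay (CTA)**, the OECD-guidance in-vitro assay for detecting tumor
promoters.

Bhas 42 cells (v-Ha-ras–transfected Balb/3T3) form a contact-inhibited
monolayer; exposure to a promoting carcinogen lets transformed cells grow
into colonies — *transformed foci* — scored by experts against six
morphological criteria: **basophilic** (dark Giemsa staining), **spindle**
cell shape, **multilayer** growth, **random** orientation, **invasive**
borders, and **≥ 100 cells**. Scoring by eye is slow and subjective;
`focusscore` implements the two machine classifiers used to automate it,
plus the assay-level statistics:

* **Classical branch** — each focus-candidate micrograph is binarized by
  discriminant-analysis (Otsu) thresholding of HSV **saturation**; the
  largest 8-connected foreground component is the focus region, from which
  three features are computed:

  - `MD` — median grayscale of the region (basophilic foci are dark),
  - `ED = √(4·AREA/π)` — equivalent diameter,
  - `WPD = (FRP − EFP) · (AREA − AREAmin)/(AREAmax − AREAmin)` — the excess
    of the measured region perimeter `FRP` over the equal-area-circle
    perimeter `EFP = π·ED`, weighted by min–max-normalized area
    (`AREAmin/max` taken over the training regions),

  followed by a logistic regression on `(MD, ED, WPD)`.

* **Network branch** — an 18-layer residual network (single-logit head,
  binary cross-entropy) trained from random initialization with Adam
  (initial learning rate 10⁻⁴, cosine annealing to 0, minibatch 32,
  50 epochs), with training-time augmentation: rotation ±90°, translation
  ±44 px, shear ±15°, horizontal/vertical flips at p = 0.5. The checkpoint
  with maximal validation accuracy is evaluated; the protocol is repeated
  over several seeds and reported as mean ± SD. The engine is implemented
  in numpy (im2col convolutions, batch norm, hand-written backprop) and is
  fully deterministic given the seed.

* **Evaluation & assay statistics** — stratified 70/10/20 splits (90/10 +
  external test for transfer to unseen chemicals), confusion matrix,
  accuracy, recall, ROC/AUC, multi-trial summaries, and the promotion
  decision rule: a chemical is a **promoter** when Dunnett many-to-one
  comparisons against the vehicle control are significant (α = 0.05) at two
  *consecutive* tested concentrations (one-way ANOVA is reported alongside;
  an optional gate).

* **Synthetic data** — because assay micrographs are rarely shareable, the
  package generates Giemsa-like focus images whose positive/negative
  classes encode the six criteria as generative parameters (with ground
  truth masks and a contrast dial down to label-free null data), so the
  whole pipeline is testable end to end.

## Worked example

```bash
focusscore generate --n-pos 30 --n-neg 30 --seed 7 --out-dir data --canvas 224 --mkdir
focusscore pipeline --manifest data/manifest.csv --out-dir run --branch classical --seed 7
```

prints

```
[generate] seed=7 n_pos=30 n_neg=30 out=data
[split] split=train n=42 positives=21 seed=7
[split] split=val n=6 positives=3 seed=7
[split] split=test n=12 positives=6 seed=7
[classical] test_n=12 accuracy=1.000 auc=1.000
```

i.e. a stratified 70/10/20 split of 60 labelled synthetic images, a logistic
model fitted to the (MD, ED, WPD) features of the 48 train+val images, and a
perfect test report (`run/classical_report.json` holds the confusion matrix
`TP=6, FP=0, FN=0, TN=6`, accuracy, recall, ROC points and AUC) — at full
inter-class contrast the synthetic classes are separable by design. Add
`--branch cnn --epochs 2 --input-size 64 --base-width 16` for a quick
network run (checkpoint + per-epoch history CSV land in `run/`).

The promotion rule on a plate of per-well focus counts (here a synthetic
reconstruction of a potent-promoter dose series; counts CSV has columns
`concentration,well,count`):

```bash
focusscore promotion --counts tpa_counts.csv --alternative greater
```

```
[promotion] positive=True anova_p=0.01749
[promotion] concentration=5.0 dunnett_p=0.6457 significant=False
[promotion] concentration=10.0 dunnett_p=0.0373 significant=True
[promotion] concentration=20.0 dunnett_p=0.03733 significant=True
[promotion] concentration=50.0 dunnett_p=0.009869 significant=True
PROMOTER
```

Two consecutive concentrations (10 and 20) are significantly elevated over
the control, so the chemical is called a promoter.

The same functionality is available as a library: `focusscore.synthgen`,
`segfeat`, `classical`, `cnn`, `evalstat`.

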