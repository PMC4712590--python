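# rgfbreast

Texture analysis of the spatial distribution of fibroglandular tissue (FT)
in breast CT.

In breast radiotherapy planning, the accuracy of model-based tissue
segmentation and deformable registration depends on how the dense
(fibroglandular) tissue is arranged inside the breast: scattered small
islands ("sparse") versus a centrally condensed core ("non-sparse"). This
package classifies that pattern automatically from a planning CT with a
whole-breast mask and an FT mask. It is aimed at medical-physics and image
analysis researchers working on adaptive breast radiotherapy, and ships a
phantom generator so the whole pipeline can be exercised and validated
without patient data.

## Method

1. **Reorientation.** The supine axial volume is resampled to cubic 1 mm
   voxels and rotated about the superior–inferior axis by the acute angle
   between the anterior–posterior axis and the chest-wall-normal line
   through the nipple, so coronal slices are perpendicular to the breast
   axis.
2. **Radial glandular fraction (RGF).** For a coronal slice with breast
   area A, the area-equivalent radius is R = √(A/π). RGF(r) is the fraction
   of FT pixels among breast pixels on the circle of radius r·R centred at
   the slice's centre of mass, sampled at r = 0.01, 0.02, …, 1.00. The
   breast is split into posterior, middle and anterior thirds along the
   chest-wall→nipple axis; each region's curve averages five slices centred
   on the region's middle slice.
3. **Features.** Thirteen statistics summarize each region curve: mean, SD,
   OLS slope vs r, radial position of the maximum, min, max, max−min,
   inner-50 % mean (r ≤ 0.5), outer-50 % mean, inner−outer, highest-10 %
   mean, lowest-10 % mean, highest−lowest.
4. **Statistics & classification.** Per-feature two-sided Wilcoxon rank-sum
   tests between the sparse and non-sparse groups (α = 0.05), and
   leave-one-out SVM classification (C = 1) with linear, polynomial
   (order 3), RBF (σ = 1) and sigmoid kernels, on each region's 13 features
   and on the 39-dimensional combination of all regions. Features are
   z-scored with training-fold statistics only.

The estimators compose with scikit-learn: `BreastReorienter`,
`FTSegmenter` and `RGFFeatureExtractor` are transformers,
`SparsityClassifier` is a classifier.

## Worked example

Run the full pipeline on a synthetic cohort of 15 non-sparse and 8 sparse
subjects (the study-sized design):

```bash
rgfbreast run-all --out-dir results/demo --seed 7
```

which writes `features.csv` (69 rows: 23 subjects × 3 regions),
`stats.csv` and `classification.csv`. The classification grid from that
run:

```
region_set  linear  polynomial   rbf   sigmoid
anterior     0.652       0.739  0.739    0.739
combined     0.870       0.913  0.652    0.957
middle       0.913       0.870  0.696    0.826
posterior    0.913       0.826  0.652    0.913
```

Read: with the linear kernel, 21 of the 23 held-out subjects are classified
correctly from the middle-region features alone (accuracy 0.913), and the
middle region separates the groups better than the anterior region — the
non-sparse phantoms' radial decay is strongest mid-breast, while near the
nipple both patterns concentrate FT centrally. In `stats.csv`, 9 of the 13
middle-region features differ significantly between groups while the
fibroglandular composition itself does not (p ≈ 0.83): the classifier picks
up the spatial arrangement of FT, not how much of it there is.

The same analysis from Python:

```python
from rgfbreast import generate_cohort, preprocess, loocv_accuracy
from rgfbreast.features import cohort_feature_table

cohort = generate_cohort(15, 8, seed=7)
oriented = [preprocess(vol, nipple=None) for vol, _ in cohort]
table = cohort_feature_table(oriented, [label for _, label in cohort])
print(loocv_accuracy(table, "middle", "linear").accuracy)   # 0.913
```

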