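# infarctmap

Contrast-free quantification of myocardial infarction from native T1
maps, with LGE as the in-vivo comparator, for cardiac-MR method
researchers who want a fully reproducible, ground-truthed testbed for
SD-threshold infarct analysis.

Late gadolinium enhancement (LGE) is the in-vivo reference standard for
imaging myocardial infarction, but gadolinium is contraindicated in
renal insufficiency — roughly a fifth of infarct patients. Native T1
mapping measures the longitudinal relaxation time T1 (ms) pixel by
pixel without contrast; infarcted myocardium shows elevated T1, so the
same remote-referenced threshold analysis used on LGE can be applied to
a T1 map. `infarctmap` implements that analysis end to end and
validates it against exact synthetic ground truth that plays the role
of ex-vivo histology (TTC staining).

## What it computes

- **MOLLI T1 fitting** — per-pixel three-parameter inversion recovery
  `S(TI) = A − B·exp(−TI/T1*)` with the Look-Locker correction
  `T1 = T1*·(B/A − 1)`, from a simulated 3(3)5 MOLLI series.
- **SD-threshold segmentation** — a reference ROI in remote (normal)
  myocardium gives `(μ_remote, σ_remote)`; infarct is every myocardial
  pixel with value `> μ_remote + k·σ_remote`, with `k = 3` on T1 maps
  and `k = 5` on LGE images. Infarct size is reported in mm² and as a
  percentage of the slice's myocardial area.
- **Transmural extent** — ten equidistant transmural radii across the
  infarct's circumferential span, each measuring the percentage of the
  endocardium→epicardium wall path classified as infarct; the slice
  value is their mean.
- **AHA segments** — 16-segment model (6 basal, 6 mid, 4 apical; no
  apical cap), anchored at the anterior RV insertion, with per-segment
  mean T1 and per-modality positivity.
- **Diagnostic validation** — empirical ROC and trapezoidal AUC (equal
  to the Mann-Whitney statistic), sensitivity/specificity and Youden's
  `J = sens + spec − 1` at a cutoff, Youden-optimal cutoff search, the
  DeLong z-test for paired AUCs (continuous T1 score vs dichotomous LGE
  call), Bland-Altman limits of agreement, and simple linear regression.
- **Synthetic phantoms** — short-axis left-ventricular slices modeled
  as a circular annulus with an endocardium-anchored infarct sector,
  Gaussian tissue statistics (remote T1 995 ± 48 ms, infarct
  1347 ± 89 ms; remote LGE 21 ± 8.4, infarct 112.6 ± 17 a.u.), exact
  ground-truth masks, and cohort generation with between-animal
  variation.

## Worked example

```python
import infarctmap as im

ph = im.make_phantom(seed=42)                       # 2-week-infarct-like slice
roi = im.remote_roi_mask(ph.geometry, (ph.infarct.center_angle + 180) % 360)
stats = im.remote_stats(ph.t1_map, roi)
mask = im.threshold_mask(ph.t1_map, ph.myo_mask, stats, k=3)
size = im.infarct_size(mask, ph.myo_mask, ph.geometry.pixel_spacing)
tm = im.transmural_extent(mask, ph.geometry)
```

prints, via the obvious f-strings:

```text
remote T1: 994.6 +/- 43.1 ms  (n=68)
threshold (mean + 3 SD): 1123.8 ms
infarct size: 198.0 mm^2 = 24.8% of slice myocardium (truth 25.0%)
transmural extent: 80.3% (truth 80.0%)
```

The remote ROI (68 pixels opposite the infarct) estimates the normal
tissue distribution; mean + 3 SD lands near 1124 ms, every myocardial
pixel above it is called infarct, and both the size and the ten-radii
transmural extent recover the phantom's ground truth to within the
rasterization error.

The full study — 10 animals × 3 slices, segmentation on both
modalities, AHA tables, ROC/Youden/DeLong, Bland-Altman, regression —
is one call (or `infarctmap run --seed 1 --out results/run`):

```python
report = im.run_study(im.RunConfig(seed=1, n_animals=10))
```

```text
AUC T1 0.983 +/- 0.011, AUC LGE 1.000, DeLong z = -1.56 (p = 0.12)
Youden cutoff 1026 ms, J = 0.922
size bias T1 vs truth: -0.28 pp (LoA -1.62 to 1.05)
```

The Youden-optimal cutoff falls between the remote (995 ms) and
infarct (1347 ms) class means and close to the remote mean + 3 SD
boundary, and the T1-derived infarct size agrees with ground truth with
a small negative bias — the qualitative behavior expected of the
SD-threshold method.

## Command line

`infarctmap simulate | fit-molli | segment | transmurality | aha |
validate | run`, all thin wrappers over the library; maps and masks are
NIfTI with pixel spacing in the header, tables are CSV, configs YAML.

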