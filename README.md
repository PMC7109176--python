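# petgmm

Semi-automated tumor segmentation of PET SUV maps by three-class Gaussian
mixture modelling, with diffusion-MRI biomarker extraction and cohort-level
agreement statistics.

## The problem

Monitoring neoadjuvant treatment response in breast cancer relies on
functional imaging biomarkers — tumor area and the mean apparent diffusion
coefficient (ADC) from diffusion-weighted MRI — measured inside a tumor
region of interest (ROI). The conventional ROI is drawn manually on
dynamic contrast-enhanced (DCE) MRI, which is slow, observer-dependent and
requires gadolinium. On simultaneous PET/MRI the ¹⁸F-FDG uptake map is
intrinsically co-registered with DWI, so a data-driven segmentation of the
PET standardized-uptake-value (SUV) map can replace the manual contour: the
only user input is a rectangular crop around the visible lesion.

`petgmm` implements that segmentation and the evaluation machinery around
it, for image scientists comparing PET segmentation strategies against a
reference contour.

## The method

Within the cropped SUV region, voxel values are modelled as a univariate
three-component Gaussian mixture

  p(x) = Σ_c w_c · N(x; μ_c, σ_c²),  c ∈ {background, unknown, tumor},

fitted by EM with k-means++ initialization and multiple restarts, components
labelled by ascending mean. The intermediate ("unknown") class absorbs
partial-volume rim voxels. To avoid over-estimation, the tumor decision
threshold T is the intersection of the weighted unknown and tumor densities,

  w_u · N(T; μ_u, σ_u²) = w_t · N(T; μ_t, σ_t²),  μ_u < T < μ_t,

solved in closed form (a quadratic in T), and the tumor mask is {SUV > T}.
Two standard comparators are provided: a fixed SUV > 2.5 threshold and an
adaptive threshold at 42 % of the in-crop maximum SUV.

Around the segmenter the package provides: SUV normalization
(SUV = C·weight/dose), perfusion-insensitive ADC mapping by log-linear
fitting of S_b = S₀·e^(−b·ADC) over b ≥ 200 s/mm², ROI biomarkers (area in
cm², mean ADC), spatial agreement metrics (Dice coefficient,
center-of-gravity displacement normalized by the reference lesion size),
paired/two-sample t tests and Pearson correlation with Benjamini–Hochberg
adjustment, and a digital lesion-phantom generator with untreated and
treated (uptake fading, diffusivity rising) conditions.

## Worked example

Generate a phantom case, segment it, fit the ADC map and score the result:

```
$ petgmm phantom --out demo --seed 11
wrote 1 case(s) to demo

$ petgmm segment --suv demo/case000_suv.nii.gz --crop demo/case000_crop.csv \
    --method gmm --seed 3 --out demo/mask.nii.gz --json demo/fit.json
gmm_pet: threshold=6.2642 n_voxels=113 flags=[]

$ petgmm adc --dwi demo/case000_dwi.nii.gz --bvalues demo/case000_bvalues.csv \
    --out demo/adc.nii.gz
ADC fit on b>=200: 9216/9216 valid voxels

$ petgmm metrics --mask-a demo/mask.nii.gz --mask-b demo/case000_reference.nii.gz \
    --adc demo/adc.nii.gz --out demo/row.csv
 n_voxels  area_cm2  mean_adc  ref_area_cm2  ref_mean_adc     dice   cog_mm  cog_normalized flags
      113      4.52  0.000989          4.88      0.001045 0.961702 0.746504        0.033793
```

The mixture fit put the component means at SUV ≈ 0.99 (background), 3.97
(partial-volume rim) and 8.23 (tumor); the unknown/tumor densities cross at
SUV 6.26, and the 113 voxels above it form a 4.52 cm² ROI. Transferred to
the ADC map, the ROI mean ADC is 0.99 × 10⁻³ mm²/s versus 1.05 × 10⁻³ for
the reference contour; Dice 0.96 and a centroid displacement of 0.75 mm
(0.034 of the reference lesion's linear size) quantify the spatial
agreement.

A full cohort evaluation (per-case table, group summaries, BH-adjusted
statistical report) runs with:

```
petgmm cohort --out results_dir --seed 1 --n-untreated 24 --n-treated 29
```

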