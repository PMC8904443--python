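# wallmotion

Temporospatial characterization of ventricular wall motion from real-time
(free-breathing, ungated) short-axis cardiac MR image series.

From a complex-valued 2D+time series and end-diastole/end-systole endocardial
segmentations, the package computes two scalar indices per chamber (LV, RV):

- **temporal periodicity** — the fraction of spectral energy (root sum square)
  of the high-pass-filtered reference wall-motion signal concentrated at the
  positive and negative cardiac-frequency bins.  The reference signal is the
  spatial average of the complex series over the ROI formed by subtracting the
  ES segmentation from the ED segmentation; since the data are complex, its
  spectrum is not conjugate-symmetric and both frequency signs contribute.
- **spatial coherence** — the mean over the ventricular anatomy (union of the
  LV and RV ED masks) of the per-voxel Pearson correlation (complex samples,
  modulus reported by default) between each voxel's filtered time-series and
  the reference signal.

Supporting layers: a deterministic beating-heart phantom with ground truth
(jittered RR schedule, raised-cosine contraction, respiratory amplitude
modulation, complex Gaussian noise, optional regional desynchronization),
method-of-slices volumetrics (EDV/ESV/SV/EF) and SNR/CNR, and a cohort
statistics layer (Anderson–Darling normality, one-tailed Welch t, Pearson
cross-correlation, box-plot summaries and scatter data).

## Library quick start

```python
from wallmotion import characterize_subject, generate_series, healthy_config

series, masks, truth = generate_series(healthy_config(seed=1))
result = characterize_subject(series, masks)
print(result.aggregated["lv"])   # periodicity, coherence, cardiac frequency
```

## CLI

```bash
wallmotion simulate --preset healthy --seed 1 --out demo/        # phantom subject
wallmotion roi --masks demo/masks.json --out demo/roi            # ED minus ES
wallmotion characterize --series demo/series_real.nii \
    --imag demo/series_imag.nii --masks demo/masks.json --out demo/char
wallmotion volumetrics --masks demo/masks.json --out demo/vol.csv
wallmotion compare --table cohort.csv --group-col group --out demo/cmp
wallmotion run --seed 1 --out demo/bundle                        # end-to-end demo
```

Complex series travel as paired real/imaginary NIfTI-1 volumes with the frame
spacing in `pixdim[4]` (seconds); masks as uint8 NIfTI volumes named by a JSON
manifest.  All analysis outputs embed the resolved run configuration and
package version.

## Conventions

- Frames are 0-based; times in seconds; frequencies in Hz; volumes in ml.
- High-pass filter: ideal (brick-wall) spectral mask, zero-phase, symmetric in
  ±f, default cutoff 0.5 Hz (separates respiration from cardiac motion).
- Cardiac search band default (0.7, 3.0) Hz; peak maximizes |S(+f)|²+|S(−f)|².
- Correlation maps: per-voxel series filtered at the reference's cutoff;
  zero-variance voxels contribute R = 0 so the anatomy size M is preserved.
- Slice aggregation: ROI-voxel-weighted mean (configurable).
- Volumes: Σ area × (slice thickness + gap); Welch t by default; quartiles by
  linear interpolation; α = 0.05, no multiplicity correction.

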