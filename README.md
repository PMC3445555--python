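# hrme

Quantitative nuclear-to-cytoplasmic (N/C) ratio analysis for fiber-bundle
fluorescence microendoscopy images of cervical epithelium.

High-resolution microendoscopy (HRME) places a coherent imaging fiber bundle
in contact with proflavine-stained tissue; nuclei fluoresce brightly against
a dimmer cytoplasmic background, and an elevated N/C area ratio is a hallmark
of cervical neoplasia.  This package implements the full quantitative
pipeline from raw frames to a per-site diagnosis:

1. **Frame selection & QC** — pick one representative frame per short movie;
   discard a site if more than 50% of the field of view is out of focus, if
   there is motion artifact, or if it contains significant debris.
2. **Preprocessing** — restrict to an operator-chosen region of interest
   (ROI), apply contrast-limited adaptive histogram equalization (CLAHE),
   then median-filter to remove the honeycomb pattern of the fiber bundle.
3. **Segmentation** — binarize at an adjustable threshold (Otsu-initialized
   within the ROI), label connected components (8-connectivity), and remove
   objects with fewer than 50 px (noise) or more than 1500 px (debris);
   both bounds are strict, so 50 px and 1500 px objects are kept.
4. **Metrics** — per site,

   `N/C = total nuclear area / (ROI area − total nuclear area)`,

   a ratio of totals within the ROI; per cohort, category means ± SEM and
   pairwise two-sample Student's *t*-tests.
5. **Diagnostics** — call a site neoplastic when `N/C > 0.163` (strict),
   where high-grade dysplasia (CIN 2/CIN 3) is the positive class; tabulate
   sensitivity/specificity, and build the ROC curve with trapezoidal AUC and
   the Q-point (the operating point closest to perfect classification).

Because no clinical images are distributed, a first-class synthetic
generator (`hrme.synthetic`) renders fiber-bundle frames with exact ground
truth — a 720 µm circular field of view, a triangular core lattice at ~4 µm
spacing, non-overlapping elliptical nuclei placed to hit a requested true
N/C within 0.005, multiplicative honeycomb modulation, shot/read noise,
defocus and debris artifacts — and samples whole cohorts with per-diagnosis
site counts and category-dependent N/C distributions.

## Worked example

```python
from hrme import (FiberBundleSpec, render_frame, ROIMask, preprocess,
                  segment_frame, nc_ratio, classify_site)

spec = FiberBundleSpec()                      # 720 um FOV, 4 um core spacing
frame, truth = render_frame(0.22, spec, seed=42)
processed, roi = preprocess(frame, ROIMask(truth.roi_mask))
seg = segment_frame(processed, roi)
result = nc_ratio(seg, roi)
print(f"true N/C      : {truth.true_nc_ratio:.3f}")
print(f"measured N/C  : {result.nc_ratio:.3f}")
print(f"nuclei kept   : {len(seg.objects)} objects, {result.nuclear_area_px} px")
print(f"classification: {'neoplastic' if classify_site(result.nc_ratio) else 'non-neoplastic'}")
```

prints

```
true N/C      : 0.218
measured N/C  : 0.205
nuclei kept   : 442 objects, 69408 px
classification: neoplastic
```

A frame rendered at the high-grade exemplar ratio 0.22 is measured at 0.205
by the full CLAHE → median → Otsu → size-filter pipeline (the small
systematic undershoot comes from median-filter edge erosion) and is
correctly called neoplastic at the 0.163 cutoff.

## Command line

```sh
hrme simulate --seed 1 --out cohort/                 # frames + ledger.csv
hrme analyze  --ledger cohort/ledger.csv --out run/  # qc_report.csv, results.csv
hrme evaluate --results run/results.csv --out run/   # group_stats.csv, roc.csv, summary.json
hrme report   --results run/results.csv              # per-category tally
```

All commands accept `--config config.yaml`; flags override the file, and
every output directory receives the fully resolved configuration so runs are
reproducible byte-for-byte at a fixed seed.

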