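# meibokit

Automated analysis of infrared meibography images of the everted upper
eyelid.  Meibomian glands secrete the lipid layer of the tear film;
their atrophy (gland *dropout*) is a leading cause of evaporative dry
eye.  Clinicians grade dropout subjectively on 4-level scales with poor
inter-rater agreement.  `meibokit` implements a fully automatic
alternative for single-frame infrared meibographs (Keratograph-style,
1360 × 1024 px):

1. **ROI detection** — the tarsal conjunctiva is located by detecting
   the eyelid's upper boundary (erosion → unsharp masking → 40 × 40
   median → Otsu → horizontal Sobel → quadratic fits, keeping the curve
   with the smallest positive quadratic coefficient) and lower boundary
   (9 × 9 local-entropy filter → per-column peak map → morphological
   joining → concavity-constrained degree-4 Chebyshev fit), then
   refining the enclosed band with morphological Chan-Vese active
   contouring on a 9 × 9 local-standard-deviation transform.
2. **Gland segmentation** — difference-of-Gaussians band-pass
   (σ = 2 px vs 30 px), locally adaptive thresholding, 5 × 3 median
   smoothing, removal of components under 800 px or oriented outside
   40–140°, left-to-right labeling, and a gated fragmentation pass that
   splits fork-like compound labels (thresholds NlTH = 1, OTH = 50°,
   NoTH = 1, O2TH = 50°, RTH = 3).
3. **Morphometrics** — the dropout area percentage

   DOA = 100 · (N_pxROI − N_pxGL − N_pxR) / N_pxROI

   where N_pxGL counts the gland region (glands plus narrow intergland
   tissue, a radius-20 px disk closing of the gland mask) and N_pxR the
   specular reflections (intensity > 200); per-gland length/width from
   the moment-matched ellipse; relative length against the local eyelid
   height; and a shape-irregularity score that integrates the gland's
   normalized polar boundary profile outside a mean ± 1 SD reference
   envelope.
4. **Grading** — the legacy Meiboscore (0, (0, 32], (32, 65], > 65) and
   an objective scale with limits fitted by exact multi-level Otsu
   clustering of DOA values ([0, 16), [16, 32], (32, 59], (59, 100]),
   plus unweighted Cohen's κ with Landis–Koch categories for
   inter-grader agreement.

A bundled synthetic-image generator renders meibography-like frames
with full ground truth (band geometry, glands, dropout, reflections,
illumination, noise), so every stage is testable without clinical data.

## Worked example

```python
from meibokit import SyntheticParams, analyze, generate_meibography

sample = generate_meibography(SyntheticParams(seed=3, dropout_fraction=0.5))
report = analyze(sample.image)
print(f"truth DOA {sample.truth_doa_percent:.1f}%  "
      f"estimated {report.doa.doa_percent:.1f}%  "
      f"glands {report.n_glands}  "
      f"mean length {report.mean_length_mm:.2f} mm")
```

prints

```
truth DOA 50.0%  estimated 53.8%  glands 17  mean length 8.43 mm
```

— the generator carved dropout covering 50.0% of the tarsal band; the
pipeline, with no access to the truth masks, measured 53.8% (estimates
run a few points high because the detected ROI includes tarsal tissue
beyond the gland tips, the same direction of bias the underlying method
shows on clinical images), found the 17 glands that survive the dropout
regions intact, and measured their mean moment-ellipse length.

The same pipeline runs from the shell:

```bash
meibokit simulate --out-dir demo --seed 3 --dropout-fraction 0.5
meibokit analyze demo/image.png --out report.json
meibokit batch  images/            # one CSV row per frame + failure log
meibokit grade  doas.csv --scale objective
meibokit kappa  confusion.csv
```

## Layout

```
src/meibokit/
  image.py          raster I/O, grayscale conversion, pixel scale
  roi.py            eyelid split, boundary fits, Chan-Vese refinement
  segmentation.py   band-pass, thresholding, labeling, fragmentation
  morphometrics.py  DOA, moment ellipses, radial profiles, irregularity
  grading.py        scales, multi-level Otsu, Cohen's kappa
  synthetic.py      ground-truth image and gland-shape generator
  pipeline.py       single-image and batch orchestration
  cli.py            command-line interface
docs/methods.md     model, parameters, and design notes
```
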