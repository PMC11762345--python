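# endospec

Snapshot RGB-to-visible-hyperspectral conversion for endoscopic imaging.
`endospec` turns ordinary 8-bit sRGB endoscopy frames into 401-band
reflectance hypercubes (380–780 nm, 1 nm step) via a 24-patch color-target
calibration, synthesizes pseudo narrow-band (415/540 nm) composites, and
evaluates object-detector outputs with background-aware confusion matrices
and the usual metric set (sensitivity, precision, specificity, F1, accuracy,
Cohen's kappa, 101-point AP/mAP).

The conversion pipeline is:

1. **Colorimetric front end** (`endospec.color`) — sRGB piecewise decoding,
   3×3 RGB→XYZ conversion (Y-white = 100 scale), polynomial feature
   expansion (`affine` / `poly2` / `poly3` presets), and a pseudoinverse
   least-squares correction matrix mapping expanded camera XYZ onto
   spectrometer-reference XYZ.  CIELAB conversion and CIEDE2000 are included
   for fidelity reporting.
2. **Spectral reconstruction** (`endospec.spectra`) — mean-centered PCA of
   the patch reflectance spectra (default 6 components) plus a regression
   from expanded corrected-XYZ features to principal-component scores; the
   combined transform reconstructs a full spectrum per color.
3. **Hypercube tools** (`endospec.cube`) — vectorized per-pixel image
   conversion with unique-color caching, band extraction, Gaussian-weighted
   narrow-band synthesis (default 415 nm → blue/green, 540 nm → red,
   FWHM 30 nm), detector-input renderings, and cube I/O (ENVI hdr+raw BSQ
   and a compressed `.npz` archive).
4. **Synthetic ground truth** (`endospec.simulate`) — analytic CIE 1931
   observer (multi-lobe Gaussian fit), illuminants, smooth random
   reflectance spectra, ideal tristimulus integration, and a distortable
   virtual camera (gamma mismatch, channel crosstalk, dark offset, noise),
   so the whole pipeline is testable without any measured data.
5. **Detection evaluation** (`endospec.detection`) — YOLO text-format I/O,
   greedy IoU matching with a background class, metric derivation, AP/mAP,
   and four bundled reference confusion matrices (`rgb-wli`, `hsi-wli`,
   `rgb-nbi`, `hsi-nbi`) used as worked examples.

## CLI

```bash
# generate a synthetic calibration target + scene
endospec make-fixtures --seed 42 --out-dir fixtures/

# fit the conversion model (prints XYZ RMSE, spectral RMSE, explained
# variance and mean CIEDE2000)
endospec calibrate --csv fixtures/calibration.csv --out model.json

# convert an image, render narrow-band / detector views
endospec convert --image fixtures/scene.png --model model.json --out scene_cube
endospec nbi --cube scene_cube.npz --out scene_nbi.png
endospec render --cube scene_cube.npz --mode bands-415-540-700 --out view.png

# evaluate detections (YOLO text dirs, or a ready confusion-matrix CSV)
endospec evaluate --pred-dir preds/ --truth-dir truths/ --out metrics.csv
endospec evaluate --confusion cm.csv --out metrics.csv
```

Exit codes: 0 success, 2 validation error, 3 runtime error.  A YAML config
(`--config`) may supply defaults for `term_spec`, `n_pc`, `nbi_centers`,
`nbi_fwhm`, `iou_threshold`, `seed`, `log_level`; explicit flags win.

## Notes on conventions

- XYZ lives on a scale where the reference white has Y = 100; reflectance is
  in percent (0–100).
- Overall accuracy excludes background ground truths from the denominator;
  specificity is one-vs-rest over the full table including the background
  column, and kappa is Cohen's kappa on the full (K+1)² table.
- The CIELAB helper uses the piecewise constants 7.787·n + 0.137931 below
  n = 0.008856.
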