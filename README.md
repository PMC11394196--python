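# ecgpaperkit

Convert photographs of paper-recorded ECGs into calibrated one-dimensional
voltage/time signals.

Paper ECGs — the gridded printouts patients keep — are often the only
surviving record of an acquisition, but a photograph of one is just pixels:
tilted, unevenly lit, with a red millimetre grid behind the trace and no
voltage scale attached. `ecgpaperkit` turns such a photograph into per-lead
series in millivolts against seconds, suitable for waveform software, by

1. **rectifying** the page: Canny edges (Sobel magnitude thresholds
   100/200) feed a Hough transform (180 angular bins, support > 100); the
   frame is split into top/bottom/left/right regions around the image
   centre, lines of consistent orientation (direction cosine > 0.85)
   suppress their shorter twins, the longest survivor per region becomes
   that side of the page, and the four corner intersections define a
   perspective transform that flattens the sheet;
2. **removing the grid** in HSV space: pixels whose hue falls in the red
   bands [0, 10] ∪ [156, 180] (blue: [100, 124]) have their saturation set
   to zero, leaving the dark trace on a white page;
3. **binarizing blockwise**: the page is tiled 4×4, each block is
   gamma-stretched (g_out = g_in^0.8) and thresholded with Otsu's
   between-class-variance criterion independently, so uneven illumination
   cannot defeat a single global threshold; the mask is thinned to a
   1-pixel skeleton;
4. **digitizing**: bottom-up column scanning extracts the trace, a
   second-order Butterworth high-pass (100 Hz, expressed at the
   pixel-column rate) locates the printed 1 mV / 0.2 s calibration square
   wave, and with Δ = |y_low − y_high| pixels the conversions are

       θ = 1/Δ  mV/px,   β = 0.4/Δ  s/px,
       v_i = −θ·(y_i − y_low),   t_i = β·(x_i − x_begin),

   (25 mm/s, 10 mm/mV standard; both rescale for other settings). The
   pulse's low level maps to exactly 0 mV, so amplitudes — not just wave
   shapes — are recovered.

A synthetic renderer (`ecgpaperkit.synth`) closes the loop: it generates
PQRST-like signals, prints them onto a red-grid page with a calibration
pulse, and optionally corrupts the image like a hand-held photo
(perspective warp, illumination ramp, blur, noise), reporting exact ground
truth for every stage.

## Worked example

```sh
# print a 10 s synthetic record onto ECG paper and keep the layout
ecgpaperkit render --synthetic 10 --px-per-mm 8 --seed 4 \
    --out page.png --layout-out layout.json

# digitize it (a clean render is a flat scan, so skip rectification)
ecgpaperkit digitize page.png --layout layout.json --out record.csv --skip-rectify
```

prints

```
wrote page.png (2409x687)
wrote 1 leads to record.csv
```

and `record.csv` holds one row per sample (`lead,t_seconds,v_mV`), e.g.
`II,0,0.00625` — lead II, 6.25 µV above the calibration baseline at the
first retained column. For photographed input drop `--skip-rectify`; add
`--resample 500 --wfdb out/` for uniformly sampled WFDB-compatible output.

The closed-loop benchmark is available directly:

```sh
ecgpaperkit evaluate --seeds 1-15 --distort none --out report.csv
```

which reports per-record time-lagged Pearson r and MAE plus suite means
(clean renders score r ≈ 0.997, MAE ≈ 0.012 mV per record).

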