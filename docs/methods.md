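# Methods

This note documents the algorithms, the defaults and why they hold, what
the synthetic fixtures do and do not emulate, and the numerical choices a
maintainer would want to know.

## Pipeline model

The digitizer assumes a paper ECG is an approximately rectangular sheet
carrying (a) a colored millimetre grid in a narrow hue band, (b) a dark
trace, (c) a printed 1 mV calibration square wave at the start of each
strip, and (d) a fixed lead layout (positions, paper speed, sensitivity)
known from the printing format and supplied as a `LeadLayout`. Everything
else — camera pose, illumination, blur, noise — is treated as nuisance.

### Rectification

The photograph is resized to a fixed 800×600 working frame and smoothed
(Gaussian, 5×5, σ = 1 — conventional pre-Canny smoothing at this
resolution). Sobel gradients give edge strength and an 8-bin quantized
direction; non-maximum suppression along the quantized gradient direction
plus 100/200 hysteresis (on the 0–1020 Sobel magnitude scale) yields the
edge map. A Hough accumulator with 180 angular bins over [0, π) and 1 px
radial bins returns every cell with strictly more than 100 votes.

Boundary selection partitions the frame into top/bottom/left/right regions
about the image centre (a line belongs to the region holding the midpoint
of its in-frame segment; horizontal-ish lines go top/bottom, vertical-ish
left/right). Within a region, pairs of lines with direction cosine
strictly above 0.85 (directions (sin θ, −cos θ), compared via |cos| since
lines are undirected) are one orientation and the shorter member is
dropped. "Length" here is the number of distinct 1 px positions along the
line covered by edge pixels within 2 px — a single accumulator cell
under-counts a long line whose angle falls between bins, and a raw inlier
count over-counts double-edged strokes such as the trace itself. The
winner per region is refined by a total-least-squares fit to its inlier
pixels; bin quantization alone (1°, 1 px) would move a corner several
pixels. Corners are intersections of adjacent refined lines, mapped to
original coordinates by fractional position.

The output rectangle's width is the mean length of the top/bottom edges;
its height follows the aspect ratio. By default the aspect is estimated as
the ratio of mean opposite-edge lengths — adequate for near-frontal
shots — but a perspective photograph fundamentally under-determines the
horizontal/vertical scale ratio, so a layout may carry `page_aspect` (the
known physical sheet shape) as the preferred source. An aspect error maps
directly into a time-scale error of the reconstruction (see Calibration),
which is why the layout-supplied value matters for long records.

After rectification the outermost ~0.4% (≥ 2 px) of the page is cropped:
a vertex error of a pixel leaves a dark sliver of background along the
border that would otherwise anchor block thresholds.

### Grid removal

Pixels whose hue (0–180 half-degree scale) lies in the configured bands —
red [0, 10] ∪ [156, 180], blue [100, 124] — and whose saturation is at
least `hsv.min_saturation` (default 30/255; hue is meaningless on
near-grey pixels) are made achromatic: RGB (r, g, b) → (v, v, v) with
v = max(r, g, b). The operation is idempotent bit-exactly, since a
whitened pixel has zero saturation.

### Blockwise binarization

The grey page (ITU-R 601 luma) is tiled into 4×4 blocks (the last
row/column absorbs remainders). Each block is normalized to [0, 1],
gamma-stretched (γ = 0.8, gain 1 — stretches the dark range where trace
and shading compete), remapped to 8-bit, and thresholded by maximizing the
between-class variance ω0·ω1·(μ0 − μ1)² over all 256 candidate levels; the
dark class is foreground. Local thresholds are the whole point: a single
global threshold fails when illumination shading exceeds the
trace/background contrast.

A blank-block gate precedes thresholding, because Otsu applied to a block
containing only noise, a gentle shading ramp, or light grid residue marks
about half of it foreground — fatal to the bottom-up column scan if that
block sits below the trace. A block is live only if its 32nd-darkest
stretched pixel lies below min(median − 40, 0.78·median). The fixed small
order statistic keeps the gate sensitive to strokes covering well under 1%
of a block (an R-peak sliver); the absolute term rejects noise; the
relative term tracks illumination so pale grid residue (~0.85 of
background) never passes, bright or dark. If every block is blank the page
has no trace and an error is raised.

The mask is thinned to a 1 px skeleton with Zhang's method
(`skimage.morphology.skeletonize`).

### Trace extraction and calibration

Per column of a strip's band, the bottom-most skeleton pixel is taken
(printed labels sit above the curve, so scanning from below never hits
them). Missing columns are linearly interpolated (nearest value at the
ends); above 30% gaps a warning is issued, 100% is an error.

The pixel-domain sampling rate is fs_px = columns / seconds from the
layout. The row sequence is high-pass filtered with a second-order
Butterworth at 100 Hz — clipped to 0.45·fs_px when fs_px < 222 px/s so the
digital filter stays well-posed — applied forward-backward (zero phase, so
the surviving peaks sit on the transition columns rather than being
delayed by the group delay). The filter suppresses the band-limited ECG
but not the near-instantaneous square-wave transitions.

The published peak gate of 0.2 mV presumes an operating point where a
1 mV step leaves a ~0.25 mV peak after this filter; that ratio (0.8 of the
expected transition peak) is the invariant form used here: the gate is
0.8 × (filter's unit-step peak response) × (nominal pulse height in px,
from sensitivity × px/mm). It therefore rescales with both image
resolution and the realized cutoff ratio. Peaks are grouped into events
(gaps under a quarter pulse-width merge); exactly two events in the search
window — the leading 2 × (3 × 0.2 s) of the strip — are the rise and fall.
If the count is not two (a transition resampled onto the rectified grid
can smear over a few columns and dip below the gate), detection retries at
0.15× the gate and keeps the two strongest events, accepted only if their
spacing is within 50% of the pulse's high-level width; a flat trace still
fails, with the event count in the error.

Plateau levels: `detect_square_wave` uses medians of the skeleton plateau
rows. Skeleton rows are integers, so Δ from medians carries ±1 px
quantization; through β that tilts the whole time axis by Δ's relative
error (0.5% at 8 px/mm ≈ 50 ms drift over 10 s, enough to destroy the
correlation with a spiky waveform). `refine_calibration` therefore
re-estimates each plateau from the grey image as the intensity-weighted
centroid of its mean vertical darkness profile, gated at 0.1× its own
column peak: the soft resampling tails of the stroke carry the sub-pixel
position, and since the stroke's point-spread function is identical on
both plateaus, its asymmetry cancels in the difference. Measured accuracy
is ~0.1 px at 8 px/mm.

With Δ fixed, θ = high_mV/Δ and β = sensitivity·high_mV/(paper_speed·Δ)
(0.4/Δ at the standard 25 mm/s, 10 mm/mV — the 1 mV pulse height equals
the width of 0.4 s of paper). Samples convert as v = −θ(y − y_low) (image
rows grow downward, voltage upward) and t = β(x − x_begin), where x_begin
is one high-level width after the fall (the pulse's low and high segments
are equally wide). Leads are cut from each strip by their layout time
windows, discarding 0.1 s on each side of printed seams; each lead's time
axis is re-zeroed.

## Synthetic fixtures

`generate_signal` sums five Gaussians per beat (P, Q, R, S, T with fixed
amplitudes/offsets/widths chosen to look like a normal sinus beat), with
seeded ~3% beat-interval and ~5% R-amplitude jitter and a small 0.25 Hz
baseline wander; output is clipped to ±2 mV. Any plausible ECG-like
morphology suffices — the pipeline is agnostic to it.

`render_paper` prints at a configurable scale (default 8 px/mm; at least
4, or a 1 px skeleton is meaningless), minor grid every 1 mm at 35%
saturation and major every 5 mm at 70% (mimicking thermal-paper contrast
so grid removal is non-trivially exercised), trace in black 2 px strokes
drawn as per-column vertical runs (so every column has trace), and the
calibration pulse with equal 0.2 s low/high/low segments. The sidecar
records exact plateau rows, transition columns, per-column trace
ordinates, and the layout with `page_aspect` filled in.

`distort_image` applies, in order: perspective warp from seeded corner
jitter (fractions of width/height per axis) onto a padded canvas over a
plain or cluttered background, a linear illumination ramp, Gaussian blur,
and additive Gaussian noise; it returns the exact homography, and an
all-zero configuration is a bit-exact no-op.

What the renderer does **not** emulate: paper texture and moiré, rolling
shutter, lens distortion, ink bleed, printed text labels, creases, JPEG
artifacts. Passing the closed loop therefore demonstrates the geometry,
color, thresholding and calibration logic under controlled corruption; it
does not certify performance on arbitrary clinical photographs.

## Scoring

Reconstructions are compared to their generating signals by linear
resampling onto the original time base, maximizing the Pearson
coefficient over integer lags within ±0.5 s (far more than any plausible
start-column error), and reporting the MAE at that lag on the overlap.
The validation suite (15 seeded 10 s records at 8 px/mm, one fixed mild
2% perspective warp) is sized to run in a few minutes on one CPU; clean
single records score r ≈ 0.997.

## Numerical choices and degenerate inputs

- Ties at cosine exactly 0.85 are *not* consistent (strict inequality).
- Constant blocks (and blocks failing the blank gate) binarize to
  background; an all-background page raises an empty-trace error.
- Gap interpolation is linear; edge gaps extend the nearest value.
- A Δ below 2 px is rejected as implausible.
- Resolution equivariance: digitizing a render and its 2× nearest-neighbor
  upscale halves θ and β and agrees to ≲0.02 mV *on average* after lag
  alignment; the pointwise maximum difference is dominated by sub-column
  sampling phase on QRS slopes (slope × half a column, ~0.1 mV) and is not
  a meaningful contract for any column-sampled method.
- WFDB-compatible output (format-16 .dat + header) requires uniformly
  resampled leads; gain is 1/θ so digital units are pixel quanta.

## Known limitations

- Aspect-ratio recovery without a layout-supplied value is heuristic; a
  1% error tilts a 10 s record's time base by 100 ms end-to-end. The
  residual anisotropy left by 1–2 px vertex error (~0.2%) is the dominant
  error source in the closed loop even with the aspect supplied.
- One calibration pulse per printed strip, at its start, is assumed;
  formats with a single shared pulse need a custom layout and are not
  auto-detected.
- Overlapping strips, traces crossing into neighbouring bands, and lead
  labels drawn *below* the curve would corrupt the bottom-up scan.
- Rows without their own calibration pulse are rejected rather than
  borrowing a neighbour's calibration.
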