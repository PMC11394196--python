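"""Synthetic ECG paper: signal generator, page renderer, photo distorter.

The digitizer can only be validated against ground truth, and physical
print-and-photograph loops are not reproducible. This module closes the
loop synthetically: a seeded PQRST generator produces millivolt signals, a
renderer prints them onto a gridded page exactly as an ECG recorder would
(1 mm minor / 5 mm major red grid, black trace at 25 mm/s and 10 mm/mV, a
leading 1 mV calibration pulse with a 0.2 s high level flanked by equal
low segments), and a distorter emulates hand-held capture (perspective
warp, uneven illumination, blur, sensor noise, background clutter) while
reporting the exact homography used. Every render carries a ground-truth
sidecar: calibration anchors and the true per-column trace ordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, warp

from .layout import LeadLayout, single_strip_layout

__all__ = [
    "RenderConfig",
    "DistortionConfig",
    "GroundTruth",
    "generate_signal",
    "render_paper",
    "distort_image",
    "DISTORTION_PRESETS",
]


# P, Q, R, S, T as (amplitude mV, centre offset s from the R peak, width s)
_PQRST = [
    (0.15, -0.22, 0.035),
    (-0.12, -0.045, 0.012),
    (1.10, 0.0, 0.020),
    (-0.22, 0.040, 0.014),
    (0.35, 0.30, 0.060),
]


def generate_signal(
    duration_s: float,
    fs: float,
    heart_rate_bpm: float = 60.0,
    seed: int = 0,
) -> np.ndarray:
    """Seeded sum-of-Gaussians PQRST train, in mV.

    Each beat is a fixed five-Gaussian template with mild seeded
    beat-to-beat jitter in timing (~3%) and R amplitude (~5%); a slow
    low-amplitude baseline wander is added. The waveform stays within
    +-2 mV. Identical arguments give identical arrays.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    period = 60.0 / heart_rate_bpm
    sig = np.zeros_like(t)
    beat_time = 0.35 * period  # first R peak
    while beat_time < duration_s + period:
        amp_jit = 1.0 + 0.05 * rng.standard_normal()
        for amp, off, width in _PQRST:
            a = amp * (amp_jit if abs(amp) > 0.5 else 1.0)
            sig += a * np.exp(-0.5 * ((t - beat_time - off) / width) ** 2)
        beat_time += period * (1.0 + 0.03 * rng.standard_normal())
    wander = 0.05 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    return np.clip(sig + wander, -2.0, 2.0)


@dataclass
class RenderConfig:
    """Printing geometry and colors of the synthetic page."""

    px_per_mm: float = 8.0
    paper_speed: float = 25.0   # mm/s
    sensitivity: float = 10.0   # mm/mV
    grid_color: str = "red"     # or "blue"
    minor_saturation: float = 0.35
    major_saturation: float = 0.70
    minor_spacing_mm: float = 1.0
    major_spacing_mm: float = 5.0
    grid_margin_mm: float = 6.0
    trace_width_px: int = 2
    trace_grey: int = 0         # 0 = solid black ink; higher = fainter print
    band_height_mm: float = 55.0
    antialias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_mm < 4:
            raise ValueError("px_per_mm must be >= 4 for a meaningful 1 px skeleton")


@dataclass
class GroundTruth:
    """Everything the downstream stages can be scored against."""

    y_low: list[float]           # per row
    y_high: list[float]
    x_begin: list[int]
    rise: list[int]
    fall: list[int]
    columns: list[np.ndarray]    # per row: absolute trace columns
    true_y: list[np.ndarray]     # per row: exact trace ordinate per column
    signals: list[np.ndarray]    # per row: the generating signal, mV
    fs: float                    # generating-signal sampling rate
    px_per_mm: float
    layout: LeadLayout
    homography: np.ndarray = field(default_factory=lambda: np.eye(3))

    def to_jsonable(self) -> dict:
        d = {
            "y_low": self.y_low,
            "y_high": self.y_high,
            "x_begin": self.x_begin,
            "rise": self.rise,
            "fall": self.fall,
            "px_per_mm": self.px_per_mm,
            "fs": self.fs,
            "homography": np.asarray(self.homography).tolist(),
        }
        return d


def _grid_rgb(color: str, saturation: float) -> np.ndarray:
    fade = int(round(255 * (1.0 - saturation)))
    if color == "red":
        return np.array([255, fade, fade], dtype=np.uint8)
    if color == "blue":
        return np.array([fade, fade, 255], dtype=np.uint8)
    raise ValueError(f"unknown grid color {color!r}")


def render_paper(
    signals: np.ndarray | list[np.ndarray],
    cfg: RenderConfig | None = None,
    layout: LeadLayout | None = None,
    fs: float = 500.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Print signal(s) onto a gridded page; return the page and its truth.

    ``signals`` holds one mV array per layout row (a single array is
    wrapped). Each row gets a calibration pulse (low/high/low, each
    ``width_s`` wide) followed by the signal at the configured paper speed
    and sensitivity. The returned layout inside the ground truth has its
    ``page_aspect`` filled in, as a printed format description would.
    """
    cfg = cfg or RenderConfig()
    if isinstance(signals, np.ndarray):
        signals = [signals]
    if layout is None:
        if len(signals) != 1:
            raise ValueError("supply a layout for multi-row renders")
        layout = single_strip_layout(seconds=len(signals[0]) / fs)
    if len(signals) != len(layout.rows):
        raise ValueError(
            f"{len(signals)} signals for {len(layout.rows)} layout rows"
        )
    ppmm = cfg.px_per_mm
    px_per_s = layout.paper_speed * ppmm
    px_per_mV = layout.sensitivity * ppmm

    # page size: derive from the first row's span so fractions match
    row0 = layout.rows[0]
    span_cols = int(round(layout.row_total_seconds(row0) * px_per_s))
    span_frac = row0.span[1] - row0.span[0]
    width = int(round(span_cols / span_frac))
    band_frac = row0.band[1] - row0.band[0]
    # band_height_mm is the printed height of one strip
    height = int(round(cfg.band_height_mm * ppmm / band_frac))
    pulse_s = 3.0 * layout.square_wave.width_s
    for row, sig in zip(layout.rows, signals):
        need = (pulse_s + len(sig) / fs) * px_per_s
        have = (row.span[1] - row.span[0]) * width
        if need > have + 1:
            raise ValueError(
                f"signal of {len(sig) / fs:.2f}s does not fit its span"
            )

    page = np.full((height, width, 3), 255, dtype=np.uint8)
    _draw_grid(page, cfg)

    pulse_cols = int(round(layout.square_wave.width_s * px_per_s))
    delta_px = layout.square_wave.high_mV * px_per_mV

    gt = GroundTruth(
        y_low=[], y_high=[], x_begin=[], rise=[], fall=[],
        columns=[], true_y=[], signals=[np.asarray(s, float) for s in signals],
        fs=fs, px_per_mm=ppmm,
        layout=replace(layout, page_aspect=width / height),
    )

    trace = np.zeros((height, width), dtype=bool)
    for row, sig in zip(layout.rows, signals):
        r0, r1 = row.band_px(height)
        c0, _ = row.span_px(width)
        baseline = r0 + int(round(0.55 * (r1 - r0)))
        y_high = baseline - delta_px
        n_sig = int(round(len(sig) / fs * px_per_s))
        cols = np.arange(c0, c0 + 3 * pulse_cols + n_sig)
        ys = np.empty(cols.size, dtype=np.float64)
        ys[:pulse_cols] = baseline
        ys[pulse_cols : 2 * pulse_cols] = y_high
        ys[2 * pulse_cols : 3 * pulse_cols] = baseline
        t_cols = (cols[3 * pulse_cols :] - cols[3 * pulse_cols]) / px_per_s
        v = np.interp(t_cols, np.arange(len(sig)) / fs, sig)
        ys[3 * pulse_cols :] = baseline - v * px_per_mV
        _draw_trace(trace, cols, ys)
        gt.y_low.append(float(baseline))
        gt.y_high.append(float(y_high))
        gt.rise.append(int(c0 + pulse_cols))
        gt.fall.append(int(c0 + 2 * pulse_cols))
        gt.x_begin.append(int(c0 + 3 * pulse_cols))
        gt.columns.append(cols)
        gt.true_y.append(ys)

    if cfg.trace_width_px > 1:
        trace = ndimage.binary_dilation(
            trace, structure=np.ones((cfg.trace_width_px, cfg.trace_width_px), bool)
        )
    page[trace] = cfg.trace_grey
    if cfg.antialias:
        blurred = ndimage.gaussian_filter(
            page.astype(np.float64), sigma=(0.5, 0.5, 0.0)
        )
        page = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
    return page, gt


def _draw_grid(page: np.ndarray, cfg: RenderConfig) -> None:
    h, w = page.shape[:2]
    m = int(round(cfg.grid_margin_mm * cfg.px_per_mm))
    minor = _grid_rgb(cfg.grid_color, cfg.minor_saturation)
    major = _grid_rgb(cfg.grid_color, cfg.major_saturation)
    for spacing, color in (
        (cfg.minor_spacing_mm, minor),
        (cfg.major_spacing_mm, major),
    ):
        step = spacing * cfg.px_per_mm
        xs = np.arange(m, w - m, step)
        for x in np.rint(xs).astype(int):
            page[m : h - m, x] = color
        ys = np.arange(m, h - m, step)
        for y in np.rint(ys).astype(int):
            page[y, m : w - m] = color


def _draw_trace(trace: np.ndarray, cols: np.ndarray, ys: np.ndarray) -> None:
    """Mark, per column, the vertical run connecting adjacent samples so
    the drawn curve is 8-connected with no column gaps."""
    h = trace.shape[0]
    yi = np.clip(np.rint(ys).astype(int), 0, h - 1)
    prev = yi[0]
    for x, y in zip(cols, yi):
        lo, hi = (y, prev) if y <= prev else (prev, y)
        trace[lo : hi + 1, x] = True
        prev = y


@dataclass
class DistortionConfig:
    """Photographic corruption; all-zero settings are a strict no-op."""

    corner_jitter: float = 0.0        # fraction of width (x) / height (y)
    illumination_min: float = 1.0     # darkest relative brightness of the ramp
    illumination_direction: str = "lr"  # lr, rl, tb, bt
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    background: str = "plain"         # plain or cluttered
    seed: int = 0

    def is_identity(self) -> bool:
        return (
            self.corner_jitter == 0
            and self.illumination_min >= 1.0
            and self.blur_sigma == 0
            and self.noise_sigma == 0
        )


DISTORTION_PRESETS = {
    "none": DistortionConfig(),
    "mild": DistortionConfig(
        corner_jitter=0.02, illumination_min=0.75, blur_sigma=0.6, noise_sigma=3.0
    ),
    "harsh": DistortionConfig(
        corner_jitter=0.05,
        illumination_min=0.4,
        blur_sigma=1.2,
        noise_sigma=8.0,
        background="cluttered",
    ),
}


def distort_image(
    img: np.ndarray, cfg: DistortionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt a rendered page like a hand-held photograph.

    Applies, in order: perspective warp onto a padded canvas (seeded
    corner jitter), illumination ramp, Gaussian blur, additive noise, and
    background compositing. Returns the corrupted image together with the
    exact 3x3 homography mapping page coordinates to canvas coordinates
    (identity, and a bit-identical image, when the config is all-zero).
    """
    img = np.asarray(img)
    if cfg.is_identity():
        return img.copy(), np.eye(3)
    rng = np.random.default_rng(cfg.seed)
    h, w = img.shape[:2]
    pad = int(round(0.08 * max(h, w)))
    out_h, out_w = h + 2 * pad, w + 2 * pad

    src = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
    jitter = rng.uniform(-1.0, 1.0, (4, 2)) * np.array(
        [cfg.corner_jitter * w, cfg.corner_jitter * h]
    )
    dst = src + pad + jitter
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:
        raise ValueError("degenerate corner jitter")

    warped = warp(
        img.astype(np.float64), tform.inverse,
        output_shape=(out_h, out_w), order=1, cval=0.0,
    )
    coverage = warp(
        np.ones((h, w)), tform.inverse,
        output_shape=(out_h, out_w), order=1, cval=0.0,
    )[..., None]

    if cfg.background == "cluttered":
        bg = np.full((out_h, out_w, 3), 70.0)
        for _ in range(12):
            r = rng.integers(0, out_h - 1)
            c = rng.integers(0, out_w - 1)
            rh = int(rng.integers(out_h // 10, out_h // 2))
            cw = int(rng.integers(out_w // 10, out_w // 2))
            bg[r : r + rh, c : c + cw] = rng.uniform(20, 160, 3)
    else:
        bg = np.full((out_h, out_w, 3), 70.0)
        bg[..., 2] += 8.0  # slightly bluish, never in the red grid band
    out = coverage * warped + (1.0 - coverage) * bg

    if cfg.illumination_min < 1.0:
        ramp = np.linspace(cfg.illumination_min, 1.0, out_w)
        if cfg.illumination_direction in ("tb", "bt"):
            ramp = np.linspace(cfg.illumination_min, 1.0, out_h)[:, None, None]
            if cfg.illumination_direction == "tb":
                ramp = ramp[::-1]
        else:
            if cfg.illumination_direction == "rl":
                ramp = ramp[::-1]
            ramp = ramp[None, :, None]
        out = out * ramp
    if cfg.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=(cfg.blur_sigma, cfg.blur_sigma, 0.0))
    if cfg.noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.noise_sigma, out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), tform.params.copy()
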