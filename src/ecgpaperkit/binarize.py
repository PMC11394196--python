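"""Grid removal and illumination-robust trace extraction.

ECG paper carries a colored (usually red, sometimes blue) millimetre grid
behind a dark trace. In HSV space the grid occupies a narrow hue band, so
it can be erased by zeroing the saturation of pixels inside the band —
they become achromatic, effectively white against the page. The trace is
then separated from the background with a blockwise threshold: the page is
split into a 4x4 grid, each block is gamma-stretched (gamma 0.8 on the
normalized grey matrix) and thresholded independently with Otsu's
between-class-variance criterion, and the 16 binary tiles are stitched.
Local thresholds are what make the method robust to the uneven
illumination of hand-held photographs. The final mask is thinned to a
1-pixel skeleton for column scanning.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv
from skimage.morphology import skeletonize

from .config import ToolConfig, NAMED_BANDS

__all__ = [
    "EmptyTraceError",
    "remove_grid",
    "gamma_stretch",
    "otsu_threshold",
    "block_slices",
    "binarize_image",
    "skeletonize_mask",
    "binarize",
]


class EmptyTraceError(RuntimeError):
    """No foreground could be separated anywhere on the page."""


def remove_grid(
    img: np.ndarray,
    bands: list[tuple[float, float]] | str = "red",
    min_saturation: float = 30.0,
) -> np.ndarray:
    """Whiten grid pixels by zeroing their saturation.

    ``bands`` are (lo, hi) hue intervals on the circular [0, 180) scale
    (the red grid lives in [0, 10] and [156, 180]; blue grids in
    [100, 124]); a band with lo > hi wraps through 180/0. A pixel is
    touched only when its hue falls in a band *and* its saturation is at
    least ``min_saturation`` (0-255 scale) — hue is meaningless on
    near-grey pixels, which also makes the operation idempotent bit-exact.

    Setting saturation to zero turns RGB (r, g, b) into the achromatic
    (v, v, v) with v = max(r, g, b); value is preserved.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("remove_grid expects an HxWx3 RGB image")
    if isinstance(bands, str):
        bands = NAMED_BANDS[bands]
    hsv = rgb2hsv(img)
    hue = hsv[..., 0] * 180.0
    sat = hsv[..., 1] * 255.0
    in_band = np.zeros(hue.shape, dtype=bool)
    for lo, hi in bands:
        if lo <= hi:
            in_band |= (hue >= lo) & (hue <= hi)
        else:  # wrapping band
            in_band |= (hue >= lo) | (hue <= hi)
    mask = in_band & (sat >= min_saturation)
    out = img.copy()
    value = img.max(axis=2)
    for c in range(3):
        channel = out[..., c]
        channel[mask] = value[mask]
    return out


def gamma_stretch(block: np.ndarray, gamma: float = 0.8, gain: float = 1.0) -> np.ndarray:
    """Power-law grey stretch g_out = gain * g_in**gamma.

    ``block`` must be normalized to [0, 1]; the result is remapped to
    integer grey levels on [0, 255]. gamma < 1 stretches the dark range,
    which widens the trace/background separation before thresholding.
    """
    if gamma <= 0 or gain <= 0:
        raise ValueError("gamma and gain must be positive")
    block = np.asarray(block, dtype=np.float64)
    if block.size and (block.min() < -1e-9 or block.max() > 1 + 1e-9):
        raise ValueError("gamma_stretch expects input normalized to [0, 1]")
    out = gain * np.power(np.clip(block, 0.0, 1.0), gamma)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def otsu_threshold(block: np.ndarray) -> int | None:
    """Otsu's threshold on an 8-bit block.

    Scans every candidate level T and maximizes the between-class variance
    sigma^2 = w0*w1*(mu0 - mu1)^2 of the split {g <= T} vs {g > T}.
    Returns None for a degenerate (single grey level) block.
    """
    block = np.asarray(block)
    hist = np.bincount(block.ravel().astype(np.int64), minlength=256).astype(np.float64)
    total = hist.sum()
    if total == 0:
        return None
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist) / total
    w1 = 1.0 - w0
    cum_mean = np.cumsum(hist * levels) / total
    grand = cum_mean[-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return None  # constant block
    mu0 = np.where(valid, cum_mean / np.where(w0 > 0, w0, 1.0), 0.0)
    mu1 = np.where(valid, (grand - cum_mean) / np.where(w1 > 0, w1, 1.0), 0.0)
    sigma2 = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -1.0)
    return int(np.argmax(sigma2))


def block_slices(shape: tuple[int, int], rows: int = 4, cols: int = 4) -> list[tuple[slice, slice]]:
    """Tile an image into rows x cols blocks; the last row/column absorbs
    any remainder so the tiling is exact."""
    h, w = shape
    r_edges = [int(i * (h // rows)) for i in range(rows)] + [h]
    c_edges = [int(j * (w // cols)) for j in range(cols)] + [w]
    return [
        (slice(r_edges[i], r_edges[i + 1]), slice(c_edges[j], c_edges[j + 1]))
        for i in range(rows)
        for j in range(cols)
    ]


def binarize_image(
    img: np.ndarray,
    cfg: ToolConfig | None = None,
    return_thresholds: bool = False,
):
    """Blockwise gamma + Otsu binarization of a grid-removed page.

    The page is converted to grey (ITU-R 601), tiled into blocks (4x4 by
    default), and each block is gamma-stretched then Otsu-thresholded on
    its own histogram; the dark class (grey <= T) is the trace foreground.
    A block with no dark tail (1st percentile within
    ``blocks.min_contrast`` grey levels of the block median) is treated as
    background-only — blank margins and grid-residual noise must not
    produce foreground.

    Returns a boolean mask (True = trace), plus the per-block threshold
    table when ``return_thresholds`` is set. Raises
    :class:`EmptyTraceError` when every block is background-only.
    """
    if cfg is None:
        from .config import load_config

        cfg = load_config()
    img = np.asarray(img)
    if img.ndim == 3:
        grey = (img.astype(np.float64) @ np.array([0.299, 0.587, 0.114]))
    else:
        grey = img.astype(np.float64)
    grey = np.clip(grey, 0, 255)

    rows, cols = int(cfg["blocks.rows"]), int(cfg["blocks.cols"])
    gamma, gain = cfg["gamma.value"], cfg["gamma.gain"]
    min_contrast = cfg["blocks.min_contrast"]

    mask = np.zeros(grey.shape, dtype=bool)
    thresholds: list[int | None] = []
    any_foreground = False
    for rs, cs in block_slices(grey.shape, rows, cols):
        block = grey[rs, cs]
        stretched = gamma_stretch(block / 255.0, gamma=gamma, gain=gain)
        # blank-block gate: a block holding trace has a dark tail far below
        # its background level; one holding only noise, a gentle shading
        # ramp, or light grid residue does not, and Otsu on such a block
        # would mark ~half of it foreground. A fixed order statistic (32nd
        # darkest pixel) keeps the gate sensitive to thin strokes covering
        # well under 1% of a block; the tail must sit both min_contrast
        # grey levels and a fixed fraction below the block median so the
        # criterion tracks local illumination.
        flat = stretched.ravel()
        k = min(32, flat.size - 1)
        dark_tail = float(np.partition(flat, k)[k])
        background = float(np.median(flat))
        if dark_tail < min(background - min_contrast, 0.78 * background):
            t = otsu_threshold(stretched)
        else:
            t = None
        thresholds.append(t)
        if t is not None:
            mask[rs, cs] = stretched <= t
            any_foreground = True
    if not any_foreground:
        raise EmptyTraceError("every block is background-only; no trace found")
    if return_thresholds:
        return mask, thresholds
    return mask


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Thin the trace mask to a 1-px-wide skeleton, preserving connectivity."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyTraceError("cannot skeletonize an empty mask")
    return skeletonize(mask)


def binarize(img: np.ndarray, cfg: ToolConfig | None = None) -> np.ndarray:
    """Full chain on a rectified page: grid removal, blockwise
    binarization, thinning. Returns the skeleton mask."""
    if cfg is None:
        from .config import load_config

        cfg = load_config()
    cleaned = remove_grid(
        img,
        bands=cfg.hue_bands(),
        min_saturation=cfg["hsv.min_saturation"],
    )
    mask = binarize_image(cleaned, cfg)
    return skeletonize_mask(mask)
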