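"""Document location and perspective correction.

A photographed ECG sheet is an approximately rectangular page seen under an
unknown projective distortion. This module finds the page's four vertices
and flattens it:

1. the photograph is resized to a fixed 800x600 working frame and Gaussian
   smoothed;
2. Sobel gradients give per-pixel edge strength and an 8-bin quantized
   direction; non-maximum suppression plus 100/200 hysteresis yields an
   edge map (the classic Canny chain, kept explicit because its
   intermediates are part of this module's contract);
3. a Hough accumulator with 180 angular bins and 1 px radial bins collects
   lines supported by more than 100 edge points;
4. the frame is partitioned into top/bottom/left/right regions around the
   image centre; within each region, lines of consistent orientation
   (pairwise cosine similarity above 0.85) suppress their shorter twins and
   the best-supported survivor becomes that side of the page;
5. adjacent sides are intersected to get the four vertices, mapped back to
   original-image coordinates by fractional position, and a projective
   transform flattens the page. The output aspect ratio is estimated from
   the mean lengths of opposite quadrilateral edges unless the caller
   supplies a known page aspect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, resize, warp

from .config import ToolConfig

__all__ = [
    "InputError",
    "RectificationError",
    "DegenerateGeometryError",
    "GradientField",
    "PolarLine",
    "Quadrilateral",
    "WORK_WIDTH",
    "WORK_HEIGHT",
    "preprocess_image",
    "to_grayscale",
    "compute_gradients",
    "detect_edges",
    "detect_lines",
    "select_document_edges",
    "compute_vertices",
    "rectify_image",
    "detect_document",
    "rectify",
]

WORK_WIDTH = 800
WORK_HEIGHT = 600

#: ITU-R 601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


class InputError(ValueError):
    """Unreadable or malformed input image."""


class RectificationError(RuntimeError):
    """Document boundary could not be established."""


class DegenerateGeometryError(RectificationError):
    """Numerically parallel boundary lines or a singular transform."""


def _check_image(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[2] != 3 or raw.shape[0] < 3 or raw.shape[1] < 3:
        raise InputError(f"expected an HxWx3 RGB image, got shape {raw.shape}")
    return raw


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma, float64 on the 0-255 scale."""
    return np.asarray(img, dtype=np.float64) @ _LUMA


def preprocess_image(raw: np.ndarray) -> np.ndarray:
    """Resize to the 800x600 working frame and Gaussian-smooth (5x5, sigma 1)."""
    raw = _check_image(raw)
    small = resize(
        raw.astype(np.float64),
        (WORK_HEIGHT, WORK_WIDTH),
        order=1,
        anti_aliasing=raw.shape[0] > WORK_HEIGHT or raw.shape[1] > WORK_WIDTH,
        preserve_range=True,
        mode="edge",
    )
    # sigma 1, radius 2 -> 5x5 kernel; replicate border keeps constants fixed
    smooth = ndimage.gaussian_filter(small, sigma=(1.0, 1.0, 0.0), truncate=2.0, mode="nearest")
    return np.clip(np.rint(smooth), 0, 255).astype(np.uint8)


@dataclass
class GradientField:
    """Sobel gradients with magnitude and 8-bin quantized direction."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray  # degrees, values in {0, 45, ..., 315}


_SOBEL_X = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=np.float64)
_SOBEL_Y = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=np.float64)


def compute_gradients(img: np.ndarray) -> GradientField:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise InputError("compute_gradients expects a single-channel image")
    gx = ndimage.convolve(img, _SOBEL_X, mode="nearest")
    gy = ndimage.convolve(img, _SOBEL_Y, mode="nearest")
    magnitude = np.hypot(gx, gy)
    angle = np.degrees(np.arctan2(gy, gx)) % 360.0
    direction = (np.rint(angle / 45.0).astype(int) % 8) * 45
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, direction=direction)


# neighbor offsets (dy, dx) along the gradient direction, per 45-degree bin
_DIR_OFFSETS = {
    0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1),
    180: (0, -1), 225: (-1, -1), 270: (-1, 0), 315: (-1, 1),
}


def detect_edges(field: GradientField, low: float = 100.0, high: float = 200.0) -> np.ndarray:
    """Non-maximum suppression plus two-threshold hysteresis.

    Pixels with magnitude above ``high`` are strong edges; pixels in
    [low, high] survive only when 8-connected to a strong edge; pixels
    below ``low`` are discarded.
    """
    if not 0 < low < high:
        raise ValueError("thresholds must satisfy 0 < low < high")
    mag = field.magnitude
    h, w = mag.shape
    padded = np.pad(mag, 1, mode="constant")
    keep = np.ones_like(mag, dtype=bool)
    for ang, (dy, dx) in _DIR_OFFSETS.items():
        sel = field.direction == (ang % 360)
        if not sel.any():
            continue
        fwd = padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        bwd = padded[1 - dy : 1 - dy + h, 1 - dx : 1 - dx + w]
        keep &= ~sel | ((mag >= fwd) & (mag >= bwd))
    candidate = keep & (mag >= low)
    strong = candidate & (mag > high)
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(candidate)
    good = np.zeros(n + 1, dtype=bool)
    good[np.unique(labels[strong])] = True
    good[0] = False
    return good[labels]


@dataclass
class PolarLine:
    """A line x*cos(theta) + y*sin(theta) = r with its Hough support."""

    r: float
    theta: float        # radians in [0, pi)
    support: int
    theta_idx: int = -1
    r_idx: int = -1

    def direction(self) -> np.ndarray:
        """Unit vector along the line: (sin theta, -cos theta)."""
        return np.array([math.sin(self.theta), -math.cos(self.theta)])


def detect_lines(
    edges: np.ndarray,
    theta_bins: int = 180,
    min_support: int = 100,
) -> list[PolarLine]:
    """Hough line detection on a binary edge map.

    The angle axis is split into ``theta_bins`` intervals over [0, pi) and
    the radius is binned at 1 px. Every accumulator cell gathering strictly
    more than ``min_support`` votes is returned (sorted by support,
    descending); collinear duplicates are left for the orientation filter
    downstream, which removes the shorter of two consistent lines.
    """
    ys, xs = np.nonzero(np.asarray(edges))
    if xs.size == 0:
        raise InputError("empty edge map")
    thetas = np.arange(theta_bins) * math.pi / theta_bins
    h, w = edges.shape
    diag = int(math.ceil(math.hypot(h, w)))
    offset = diag  # r in [-diag, diag]
    nr = 2 * diag + 1
    lines: list[PolarLine] = []
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    for k in range(theta_bins):
        r = np.rint(xs * cos_t[k] + ys * sin_t[k]).astype(np.int64) + offset
        counts = np.bincount(r, minlength=nr)
        for r_idx in np.nonzero(counts > min_support)[0]:
            lines.append(
                PolarLine(
                    r=float(r_idx - offset),
                    theta=float(thetas[k]),
                    support=int(counts[r_idx]),
                    theta_idx=k,
                    r_idx=int(r_idx),
                )
            )
    lines.sort(key=lambda ln: (-ln.support, ln.theta_idx, ln.r_idx))
    return lines


def _segment_midpoint(line: PolarLine, w: int, h: int) -> tuple[float, float]:
    """Midpoint of the line's intersection with the image rectangle."""
    c, s, r = math.cos(line.theta), math.sin(line.theta), line.r
    pts = []
    if abs(s) > 1e-12:
        for x in (0.0, w - 1.0):
            y = (r - x * c) / s
            if -1.0 <= y <= h:
                pts.append((x, y))
    if abs(c) > 1e-12:
        for y in (0.0, h - 1.0):
            x = (r - y * s) / c
            if -1.0 <= x <= w:
                pts.append((x, y))
    if not pts:
        # line misses the frame entirely; fall back to the foot of the
        # perpendicular from the origin
        return r * c, r * s
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return (min(xs) + max(xs)) / 2.0, (min(ys) + max(ys)) / 2.0


def _region_of(line: PolarLine, w: int, h: int) -> str:
    mx, my = _segment_midpoint(line, w, h)
    horizontal = abs(math.sin(line.theta)) >= abs(math.cos(line.theta))
    if horizontal:
        return "top" if my < h / 2.0 else "bottom"
    return "left" if mx < w / 2.0 else "right"


def _cosine(l1: PolarLine, l2: PolarLine) -> float:
    return abs(float(l1.direction() @ l2.direction()))


def _refine_line(line: PolarLine, edges: np.ndarray, tol: float = 2.0) -> PolarLine:
    """Total-least-squares refit of a line to its inlier edge pixels.

    The accumulator quantizes theta to 1 degree and r to 1 px, which is too
    coarse for sub-pixel vertex recovery; the refit removes that bias while
    leaving the accumulator output untouched.
    """
    ys, xs = np.nonzero(edges)
    d = np.abs(xs * math.cos(line.theta) + ys * math.sin(line.theta) - line.r)
    sel = d <= tol
    if sel.sum() < 2:
        return line
    x, y = xs[sel].astype(float), ys[sel].astype(float)
    mx, my = x.mean(), y.mean()
    cov = np.cov(np.vstack([x - mx, y - my]))
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    normal = evecs[:, 0]  # eigenvector of the smaller eigenvalue
    theta = math.atan2(normal[1], normal[0]) % math.pi
    # the centroid lies on the line, so its projection on the normal is r
    r = mx * math.cos(theta) + my * math.sin(theta)
    return PolarLine(r=float(r), theta=float(theta), support=line.support,
                     theta_idx=line.theta_idx, r_idx=line.r_idx)


def _inlier_extent(line: PolarLine, xs: np.ndarray, ys: np.ndarray, tol: float = 2.0) -> int:
    """Length of the edge along the line: the number of distinct 1 px
    positions (projected onto the line) covered by inlier edge pixels.
    Counting distinct positions, not pixels, keeps a thick double-edged
    stroke from outscoring a longer single edge."""
    c, s = math.cos(line.theta), math.sin(line.theta)
    d = np.abs(xs * c + ys * s - line.r)
    sel = d <= tol
    if not sel.any():
        return 0
    along = np.rint(xs[sel] * s - ys[sel] * c).astype(np.int64)
    return int(np.unique(along).size)


def select_document_edges(
    lines: list[PolarLine],
    dims: tuple[int, int] = (WORK_WIDTH, WORK_HEIGHT),
    edges: np.ndarray | None = None,
    cosine_threshold: float = 0.85,
) -> dict[str, PolarLine]:
    """Pick one boundary line per region (top/bottom/left/right).

    Within a region, any pair of lines whose direction cosine strictly
    exceeds ``cosine_threshold`` is treated as the same orientation and the
    shorter member is removed; the longest survivor wins. Length is the
    line's inlier count on the edge map when it is supplied (a single
    accumulator cell undercounts a long line whose angle falls between
    bins), otherwise the accumulator support. Winners are refined by a
    total-least-squares fit to their inlier pixels.
    """
    if len(lines) < 4:
        raise RectificationError(
            f"need at least 4 candidate lines, got {len(lines)}"
        )
    w, h = dims
    if edges is not None:
        eys, exs = np.nonzero(edges)

        def length(ln: PolarLine) -> int:
            return _inlier_extent(ln, exs, eys)
    else:
        def length(ln: PolarLine) -> int:
            return ln.support

    by_region: dict[str, list[PolarLine]] = {"top": [], "bottom": [], "left": [], "right": []}
    for line in lines:
        by_region[_region_of(line, w, h)].append(line)

    chosen: dict[str, PolarLine] = {}
    for region, members in by_region.items():
        if not members:
            raise RectificationError(f"no boundary line found in region {region!r}")
        alive = sorted(members, key=lambda ln: -length(ln))
        removed = [False] * len(alive)
        for i in range(len(alive)):
            if removed[i]:
                continue
            for j in range(i + 1, len(alive)):
                if not removed[j] and _cosine(alive[i], alive[j]) > cosine_threshold:
                    removed[j] = True  # the shorter edge goes
        survivors = [ln for ln, dead in zip(alive, removed) if not dead]
        winner = survivors[0]
        if edges is not None:
            winner = _refine_line(winner, edges)
        chosen[region] = winner
    return chosen


@dataclass
class Quadrilateral:
    """Document vertices in original-image coordinates.

    Ordered bottom-left, top-left, bottom-right, top-right.
    """

    bottom_left: tuple[float, float]
    top_left: tuple[float, float]
    bottom_right: tuple[float, float]
    top_right: tuple[float, float]

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.bottom_left, self.top_left, self.bottom_right, self.top_right]
        )

    def validate(self, width: int | None = None, height: int | None = None, tol: float = 5.0) -> None:
        pts = self.as_array()
        for i in range(4):
            for j in range(i + 1, 4):
                if np.allclose(pts[i], pts[j]):
                    raise DegenerateGeometryError("coincident vertices")
        for trio in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            a, b, c = pts[list(trio)]
            area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if abs(area2) < 1e-6:
                raise DegenerateGeometryError("three vertices are collinear")
        if width is not None and height is not None:
            if (pts[:, 0] < -tol).any() or (pts[:, 0] > width - 1 + tol).any() \
                    or (pts[:, 1] < -tol).any() or (pts[:, 1] > height - 1 + tol).any():
                raise DegenerateGeometryError("vertices fall outside the image bounds")


def _intersect(l1: PolarLine, l2: PolarLine) -> tuple[float, float]:
    a = np.array(
        [[math.cos(l1.theta), math.sin(l1.theta)],
         [math.cos(l2.theta), math.sin(l2.theta)]]
    )
    b = np.array([l1.r, l2.r])
    det = np.linalg.det(a)
    if abs(det) < 1e-9:
        raise DegenerateGeometryError("adjacent boundary lines are numerically parallel")
    x, y = np.linalg.solve(a, b)
    return float(x), float(y)


def compute_vertices(
    boundary: dict[str, PolarLine],
    resize_factors: tuple[float, float] = (1.0, 1.0),
    original_dims: tuple[int, int] | None = None,
) -> Quadrilateral:
    """Intersect adjacent boundary lines and rescale to original coordinates.

    ``resize_factors`` = (sx, sy) multiply working-frame coordinates to get
    original-image coordinates (the fractional-position remapping).
    """
    sx, sy = resize_factors

    def scaled(p: tuple[float, float]) -> tuple[float, float]:
        return p[0] * sx, p[1] * sy

    quad = Quadrilateral(
        bottom_left=scaled(_intersect(boundary["bottom"], boundary["left"])),
        top_left=scaled(_intersect(boundary["top"], boundary["left"])),
        bottom_right=scaled(_intersect(boundary["bottom"], boundary["right"])),
        top_right=scaled(_intersect(boundary["top"], boundary["right"])),
    )
    if original_dims is not None:
        quad.validate(width=original_dims[0], height=original_dims[1])
    else:
        quad.validate()
    return quad


def _edge_mean_aspect(quad: Quadrilateral) -> float:
    tl, tr = np.array(quad.top_left), np.array(quad.top_right)
    bl, br = np.array(quad.bottom_left), np.array(quad.bottom_right)
    width = (np.linalg.norm(tr - tl) + np.linalg.norm(br - bl)) / 2.0
    height = (np.linalg.norm(bl - tl) + np.linalg.norm(br - tr)) / 2.0
    if height <= 0:
        raise DegenerateGeometryError("degenerate quadrilateral height")
    return width / height


def rectify_image(
    raw: np.ndarray,
    quad: Quadrilateral,
    aspect_ratio: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten the quadrilateral into an axis-aligned image.

    Returns ``(rectified, matrix)`` where ``matrix`` is the 3x3 projective
    transform mapping output (x, y, 1) to source coordinates. The output
    width is the mean length of the top/bottom edges; the height follows
    the estimated (or supplied) aspect ratio.
    """
    raw = _check_image(raw)
    quad.validate()
    tl, tr = np.array(quad.top_left), np.array(quad.top_right)
    bl, br = np.array(quad.bottom_left), np.array(quad.bottom_right)
    width = (np.linalg.norm(tr - tl) + np.linalg.norm(br - bl)) / 2.0
    aspect = aspect_ratio if aspect_ratio is not None else _edge_mean_aspect(quad)
    out_w = max(2, int(round(width)) + 1)
    out_h = max(2, int(round(width / aspect)) + 1)

    dst_rect = np.array(
        [[0, 0], [out_w - 1, 0], [out_w - 1, out_h - 1], [0, out_h - 1]],
        dtype=float,
    )
    src_quad = np.array([quad.top_left, quad.top_right, quad.bottom_right, quad.bottom_left])
    tform = ProjectiveTransform.from_estimate(dst_rect, src_quad)
    if not tform:
        raise DegenerateGeometryError("could not estimate a perspective transform")
    if abs(np.linalg.det(tform.params)) < 1e-12:
        raise DegenerateGeometryError("singular perspective matrix")
    out = warp(
        raw.astype(np.float64),
        tform,
        output_shape=(out_h, out_w),
        order=1,
        mode="edge",
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), tform.params.copy()


def detect_document(raw: np.ndarray, cfg: ToolConfig | None = None) -> Quadrilateral:
    """Locate the sheet's four vertices in a photograph."""
    if cfg is None:
        from .config import load_config

        cfg = load_config()
    raw = _check_image(raw)
    work = preprocess_image(raw)
    field = compute_gradients(to_grayscale(work))
    edges = detect_edges(field, low=cfg["canny.low"], high=cfg["canny.high"])
    lines = detect_lines(
        edges,
        theta_bins=int(cfg["hough.theta_bins"]),
        min_support=int(cfg["hough.min_support"]),
    )
    if len(lines) < 4:
        raise RectificationError(
            f"only {len(lines)} candidate lines with sufficient support"
        )
    boundary = select_document_edges(
        lines,
        dims=(WORK_WIDTH, WORK_HEIGHT),
        edges=edges,
        cosine_threshold=cfg["orientation.cosine_threshold"],
    )
    h, w = raw.shape[:2]
    return compute_vertices(
        boundary,
        resize_factors=(w / WORK_WIDTH, h / WORK_HEIGHT),
        original_dims=(w, h),
    )


def rectify(
    raw: np.ndarray,
    cfg: ToolConfig | None = None,
    aspect_ratio: float | None = None,
) -> tuple[np.ndarray, Quadrilateral, np.ndarray]:
    """Full chain: detect the document and flatten it.

    Returns (rectified image, detected quadrilateral, perspective matrix).
    """
    if cfg is None:
        from .config import load_config

        cfg = load_config()
    if aspect_ratio is None:
        aspect_ratio = cfg["rectify.aspect_ratio"]
    quad = detect_document(raw, cfg)
    rectified, matrix = rectify_image(raw, quad, aspect_ratio=aspect_ratio)
    return rectified, quad, matrix
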