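"""Reference-card detection and pixel-per-metric calibration.

The card is the only object of known physical size in frame (a standard
85.6 mm x 54.0 mm card), so its detected pixel dimensions calibrate the
image: ``pixel_per_metric`` (px/mm) converts body-segment pixel lengths to
millimetres.  Detection is colour/contour based: the card region is
segmented by its colour signature, a convex quadrilateral is fitted to the
region's hull, and corners are refined to subpixel precision by fitting a
total-least-squares line to each boundary edge and intersecting adjacent
lines.  The provider is pluggable so a learned detector can replace the
classical one without touching downstream code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.draw import polygon2mask

from .synthetic import CARD_HEIGHT_MM, CARD_WIDTH_MM, SceneImage, order_quad


@dataclass(frozen=True)
class CardSpec:
    """Physical size of the reference card (mm)."""

    width_mm: float = CARD_WIDTH_MM
    height_mm: float = CARD_HEIGHT_MM

    @property
    def aspect_ratio(self) -> float:
        return self.width_mm / self.height_mm


@dataclass
class CardDetection:
    """Detected card quadrilateral and derived pixel scales."""

    success: bool
    reason: str | None = None
    quad_px: np.ndarray | None = None  # (4, 2), clockwise from origin-nearest
    mask: np.ndarray | None = field(default=None, repr=False)
    scale_w: float = float("nan")  # px per mm along the card width
    scale_h: float = float("nan")  # px per mm along the card height
    pixel_per_metric: float = float("nan")
    mask_quad_iou: float = float("nan")


def _quad_area(q: np.ndarray) -> float:
    x, y = q[:, 0], q[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _max_area_quad(hull_pts: np.ndarray) -> np.ndarray:
    """Maximum-area quadrilateral whose vertices are hull vertices."""
    n = len(hull_pts)
    if n == 4:
        return hull_pts
    best, best_area = None, -1.0
    for idx in itertools.combinations(range(n), 4):
        q = hull_pts[list(idx)]
        a = _quad_area(q)
        if a > best_area:
            best, best_area = q, a
    return best


def _refine_quad(excess: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Subpixel corner refinement from intensity-profile edge crossings.

    For each approximate edge, the card-colour excess field is sampled along
    outward normals at several stations; the half-contrast crossing of each
    profile localises the physical edge to subpixel precision.  A total
    least-squares line is fitted per edge and adjacent lines intersected.
    Falls back to the input quad when any edge lacks reliable crossings.
    """
    h, w = excess.shape
    centroid = quad.mean(axis=0)
    lines = []
    for i in range(4):
        p, q = quad[i], quad[(i + 1) % 4]
        d = q - p
        length = float(np.linalg.norm(d))
        if length < 8.0:
            return quad
        u = d / length
        n = np.array([-u[1], u[0]])
        if np.dot(n, p + 0.5 * d - centroid) < 0:
            n = -n
        n_samples = max(10, int(length / 5))
        t = np.linspace(0.12, 0.88, n_samples)
        base = p[None, :] + (t * length)[:, None] * u[None, :]
        # Window wide enough to straddle a motion/defocus-blurred edge.
        offsets = np.arange(-6.0, 6.01, 0.5)
        pts = base[:, None, :] + offsets[None, :, None] * n[None, None, :]
        xs = np.clip(pts[..., 0], 0, w - 1)
        ys = np.clip(pts[..., 1], 0, h - 1)
        prof = ndi.map_coordinates(excess, [ys.ravel(), xs.ravel()], order=1)
        prof = prof.reshape(base.shape[0], len(offsets))
        inner = prof[:, offsets <= -4.5].mean(axis=1)
        outer = prof[:, offsets >= 4.5].mean(axis=1)
        good = inner - outer > 12.0
        crossings = []
        mid = 0.5 * (inner + outer)
        for j in np.nonzero(good)[0]:
            row = prof[j]
            below = row < mid[j]
            k = np.argmax(below)  # first offset index past the edge
            if k == 0 or not below[k:].all() or below[:k].any():
                continue  # non-monotone profile: occlusion or second edge
            o0, o1 = offsets[k - 1], offsets[k]
            v0, v1 = row[k - 1], row[k]
            off = o0 + (v0 - mid[j]) / (v0 - v1) * (o1 - o0)
            crossings.append(base[j] + off * n)
        if len(crossings) < 6:
            return quad
        edge_pts = np.asarray(crossings)
        c = edge_pts.mean(axis=0)
        cov = np.cov((edge_pts - c).T)
        evals, evecs = np.linalg.eigh(cov)
        lines.append((c, evecs[:, np.argmax(evals)]))
    corners = []
    for i in range(4):
        c1, d1 = lines[i - 1]
        c2, d2 = lines[i]
        a = np.column_stack([d1, -d2])
        if abs(np.linalg.det(a)) < 1e-9:
            return quad
        tt = np.linalg.solve(a, c2 - c1)
        corner = c1 + tt[0] * d1
        if np.linalg.norm(corner - quad[i]) > 4.0:
            return quad
        corners.append(corner)
    return order_quad(np.array(corners))


def detect_card(
    image: SceneImage | np.ndarray,
    card: CardSpec = CardSpec(),
    *,
    color_threshold: float = 20.0,
    min_area_px: int = 150,
    max_hull_vertices: int = 48,
) -> CardDetection:
    """Locate the card and compute its pixel-per-metric calibration.

    The card-coloured region (blue excess ``B - R`` above
    ``color_threshold``) is segmented, its largest connected component kept,
    and the maximum-area quadrilateral inscribed in the component's convex
    hull fitted, then refined to subpixel corners.  Returns
    ``success=False`` with ``reason='card_not_found'`` when no adequate
    region exists.
    """
    arr = image.pixels if isinstance(image, SceneImage) else np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3 or arr.size == 0:
        raise ValueError("expected a non-empty RGB image")
    excess = arr[:, :, 2].astype(np.int16) - arr[:, :, 0].astype(np.int16)
    raw = excess > color_threshold
    if raw.sum() < min_area_px:
        return CardDetection(success=False, reason="card_not_found")
    labels = measure.label(raw)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    if mask.sum() < min_area_px:
        return CardDetection(success=False, reason="card_not_found")

    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    try:
        hull = ConvexHull(pts)
    except Exception:
        return CardDetection(success=False, reason="degenerate_region")
    hull_pts = pts[hull.vertices]
    if len(hull_pts) > max_hull_vertices:
        step = int(np.ceil(len(hull_pts) / max_hull_vertices))
        hull_pts = hull_pts[::step]
    if len(hull_pts) < 4:
        return CardDetection(success=False, reason="degenerate_region")
    quad = order_quad(_max_area_quad(hull_pts))
    quad = _refine_quad(excess.astype(float), quad)
    try:
        scale_w, scale_h, ppm = pixel_per_metric(quad, card)
    except ValueError:
        return CardDetection(success=False, reason="degenerate_region")
    iou = mask_quad_agreement(mask, quad)
    return CardDetection(
        success=True,
        quad_px=quad,
        mask=mask,
        scale_w=scale_w,
        scale_h=scale_h,
        pixel_per_metric=ppm,
        mask_quad_iou=iou,
    )


def pixel_per_metric(
    quad_px: np.ndarray, card: CardSpec = CardSpec()
) -> tuple[float, float, float]:
    """Pixel scales from an ordered card quadrilateral.

    The two longer opposite edges are assigned to the card width (85.6 mm)
    and the shorter pair to its height (54.0 mm), which resolves 90-degree
    card rotations; each scale is the mean of its opposite-edge pixel
    lengths over the physical dimension, and ``pixel_per_metric`` is the
    arithmetic mean of the two scales.

    Raises
    ------
    ValueError
        for a degenerate quadrilateral (near-zero edge).
    """
    quad = np.asarray(quad_px, dtype=float)
    if quad.shape != (4, 2):
        raise ValueError("quad_px must be 4 x 2")
    edges = np.linalg.norm(np.roll(quad, -1, axis=0) - quad, axis=1)
    if edges.min() < 1e-6:
        raise ValueError("degenerate quadrilateral: near-zero edge")
    pair_a = 0.5 * (edges[0] + edges[2])
    pair_b = 0.5 * (edges[1] + edges[3])
    long_px, short_px = max(pair_a, pair_b), min(pair_a, pair_b)
    scale_w = long_px / card.width_mm
    scale_h = short_px / card.height_mm
    return scale_w, scale_h, 0.5 * (scale_w + scale_h)


def mask_quad_agreement(mask: np.ndarray, quad_px: np.ndarray) -> float:
    """Intersection-over-union between a segmentation mask and a filled quad.

    Feeds the improper-card-segmentation warning; an empty mask scores 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return 0.0
    quad = np.asarray(quad_px, dtype=float)
    filled = polygon2mask(mask.shape, quad[:, ::-1])  # (row, col) order
    inter = np.logical_and(mask, filled).sum()
    union = np.logical_or(mask, filled).sum()
    if union == 0:
        return 0.0
    return float(inter) / float(union)
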