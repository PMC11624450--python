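"""Automated per-image quality warnings (W0-W3).

Four warnings annotate each image before prediction; an image raising none
of them is "high quality".  They are pure functions of the detected
geometry:

W0
    card and body overlapping (card quad intersects the body bounding box);
W1
    incorrect card aspect ratio;
W2
    improper card segmentation (mask/quad IoU below threshold);
W3
    width and height pixel scales too different.

W1 and W3 both respond to an oblique (tilted) capture.  The W1 statistic is
the worst per-corner ratio of adjacent edge lengths: unlike the mean of
opposite-edge pairs it also reacts to keystone convergence, which is the
only signature left when the card happens to lie near the ground footprint
of a tilted camera (where the local view is perpendicular and anisotropy
vanishes).  Default tolerances were calibrated on the synthetic projection
geometry so that a 15-degree tilt is flagged reliably while defect-free
scenes stay below a 5% false-positive rate; they sit well below the printed
aspect deviations a grossly wrong detection produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, box

from .card import CardDetection, CardSpec
from .landmarks import LandmarkSet


@dataclass(frozen=True)
class WarningConfig:
    """Thresholds for the four warnings (fractions, strict inequality)."""

    w1_aspect_tol: float = 0.008
    w2_iou_threshold: float = 0.90
    w3_scale_tol: float = 0.005
    body_bbox_pad_frac: float = 0.15


@dataclass(frozen=True)
class WarningSet:
    """The four per-image warnings."""

    w0_card_body_overlap: bool
    w1_card_aspect_ratio: bool
    w2_card_segmentation: bool
    w3_scale_mismatch: bool

    @property
    def any(self) -> bool:
        return (
            self.w0_card_body_overlap
            or self.w1_card_aspect_ratio
            or self.w2_card_segmentation
            or self.w3_scale_mismatch
        )

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.w0_card_body_overlap,
            self.w1_card_aspect_ratio,
            self.w2_card_segmentation,
            self.w3_scale_mismatch,
        )

    def as_set(self) -> frozenset[str]:
        return frozenset(
            name
            for name, val in zip(("W0", "W1", "W2", "W3"), self.as_tuple())
            if val
        )


NO_WARNINGS = WarningSet(False, False, False, False)


def flag_w0(
    quad_px: np.ndarray, body_bbox: tuple[float, float, float, float]
) -> bool:
    """Card/body overlap: true iff the filled quad and the body bounding box
    share interior area (touching along an edge or point does not count)."""
    quad = Polygon(np.asarray(quad_px, dtype=float))
    bbox = box(*body_bbox)
    return quad.intersection(bbox).area > 0.0


def observed_aspect_ratio(quad_px: np.ndarray) -> float:
    """Worst per-corner aspect ratio (long/short of adjacent edges)."""
    quad = np.asarray(quad_px, dtype=float)
    e = np.linalg.norm(np.roll(quad, -1, axis=0) - quad, axis=1)
    if e.min() < 1e-9:
        return float("inf")
    ratios = [
        max(e[i], e[(i + 1) % 4]) / min(e[i], e[(i + 1) % 4]) for i in range(4)
    ]
    target = CardSpec().aspect_ratio
    return ratios[int(np.argmax([abs(r - target) for r in ratios]))]


def flag_w1(
    quad_px: np.ndarray, card: CardSpec = CardSpec(), tol: float = 0.008
) -> bool:
    """Incorrect card aspect ratio (strict: exactly-at-tolerance passes)."""
    ar = observed_aspect_ratio(quad_px)
    if not np.isfinite(ar):
        return True
    return bool(abs(ar - card.aspect_ratio) / card.aspect_ratio > tol)


def flag_w2(iou: float, threshold: float = 0.90) -> bool:
    """Improper card segmentation: mask/quad IoU strictly below threshold."""
    return iou < threshold


def flag_w3(scale_w: float, scale_h: float, tol: float = 0.005) -> bool:
    """Width/height pixel scales too different (strict inequality)."""
    if scale_w <= 0 or scale_h <= 0:
        raise ValueError("scales must be positive")
    return bool(abs(scale_w - scale_h) / (0.5 * (scale_w + scale_h)) > tol)


def body_bbox_from_landmarks(
    landmarks: LandmarkSet, pad_frac: float = 0.15
) -> tuple[float, float, float, float]:
    """Axis-aligned body box from landmarks, padded toward the silhouette.

    Landmarks sit inside the body outline, so the box is expanded on every
    side by ``pad_frac`` times the shoulder span (an available proxy for
    body width).
    """
    pts = np.array([p for p, _ in landmarks.points.values()])
    pad = pad_frac * float(
        np.linalg.norm(
            landmarks.point("left_shoulder") - landmarks.point("right_shoulder")
        )
    )
    return (
        float(pts[:, 0].min() - pad),
        float(pts[:, 1].min() - pad),
        float(pts[:, 0].max() + pad),
        float(pts[:, 1].max() + pad),
    )


def evaluate_warnings(
    detection: CardDetection,
    landmarks: LandmarkSet,
    config: WarningConfig = WarningConfig(),
    card: CardSpec = CardSpec(),
) -> WarningSet:
    """Compute all four warnings for an image with successful extraction.

    Raises
    ------
    ValueError
        if either extraction failed (such images are prediction failures,
        not warning candidates).
    """
    if not (detection.success and landmarks.success):
        raise ValueError("warnings require successful card and pose extraction")
    bbox = body_bbox_from_landmarks(landmarks, config.body_bbox_pad_frac)
    return WarningSet(
        w0_card_body_overlap=flag_w0(detection.quad_px, bbox),
        w1_card_aspect_ratio=flag_w1(
            detection.quad_px, card, config.w1_aspect_tol
        ),
        w2_card_segmentation=flag_w2(
            detection.mask_quad_iou, config.w2_iou_threshold
        ),
        w3_scale_mismatch=flag_w3(
            detection.scale_w, detection.scale_h, config.w3_scale_tol
        ),
    )
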