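"""Seeded synthetic top-view scenes of a supine infant with a reference card.

The generator emulates the capture protocol the length-estimation pipeline
assumes: a child lying on a flat support surface, photographed from above
with a pinhole camera that is nominally perpendicular to the surface, and a
standard-size card (85.6 mm x 54.0 mm) placed on the same surface near the
body.  Every scene carries full ground truth (world and pixel coordinates of
all landmarks and card corners, camera pose, injected defects) so each stage
of the pipeline can be validated against an exact oracle.

Controllable defect classes mirror the failure modes seen in real capture:

``tilt``
    camera views the scene center obliquely instead of from the zenith.
``card_off_plane``
    the card rests above the support plane (e.g. on a folded blanket), so
    its pixel scale overstates the body's pixel-per-metric value.
``blur``
    Gaussian blur simulating motion/defocus.
``baggy_contour``
    widened, irregular body silhouette (loose clothing).
``low_contrast``
    intensity compression toward the mean gray.
``occluded_part``
    a body region (and its landmarks) hidden under a cover.
``card_body_overlap``
    the card resting against/on the child, half of it over the torso.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFilter
from skimage.draw import polygon2mask

CARD_WIDTH_MM = 85.6
CARD_HEIGHT_MM = 54.0

#: Recognised defect class names.
DEFECTS = (
    "tilt",
    "card_off_plane",
    "blur",
    "baggy_contour",
    "low_contrast",
    "occluded_part",
    "card_body_overlap",
)

#: Body-segment chain measured by the pipeline, crown to heel.
SEGMENTS = (
    "crown_shoulder",
    "shoulder_hip",
    "hip_knee",
    "knee_ankle",
    "ankle_heel",
)

#: Landmarks that must be visible for pose extraction to succeed.
REQUIRED_LANDMARKS = (
    "crown",
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_heel",
    "right_heel",
)

OPTIONAL_LANDMARKS = ("nose", "left_eye", "right_eye")

# Flat-shaded render palette (R, G, B).  The card carries a blue excess so
# that a colour-based detector can segment it; body and background are gray.
BACKGROUND_COLOR = (118, 118, 118)
BODY_COLOR = (52, 52, 52)
CARD_COLOR = (182, 182, 246)
COVER_COLOR = (96, 96, 96)


class GeometryError(ValueError):
    """A point cannot be projected (e.g. it lies behind the camera)."""


class RenderError(RuntimeError):
    """Scene geometry cannot be rasterised into the frame."""


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticipantSpec:
    """Anthropometric description of one synthetic child.

    ``segment_proportions`` are the fractions of ``true_length_mm`` assigned
    to the five chain segments (crown->shoulder, shoulder->hip, hip->knee,
    knee->ankle, ankle->heel); they must be positive and sum to one.
    """

    participant_id: str
    age_months: float
    true_length_mm: float
    segment_proportions: tuple[float, float, float, float, float]
    body_half_width_mm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.age_months <= 18.0:
            raise ValueError(f"age_months out of range: {self.age_months}")
        if not 400.0 <= self.true_length_mm <= 900.0:
            raise ValueError(
                f"true_length_mm out of range: {self.true_length_mm}"
            )
        props = np.asarray(self.segment_proportions, dtype=float)
        if props.shape != (5,) or np.any(props <= 0):
            raise ValueError("segment_proportions must be 5 positive values")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("segment_proportions must sum to 1")


@dataclass(frozen=True)
class CameraSpec:
    """Pinhole camera above the support plane.

    ``tilt_deg`` is the zenith angle of the optical axis: 0 encodes the ideal
    perpendicular capture.  A tilted camera sits displaced toward
    ``tilt_azimuth_deg`` on a sphere of radius ``height_mm`` and is aimed at
    the scene origin, which is how a photographer leaning to one side holds
    the phone while keeping the child centred.
    """

    height_mm: float = 1150.0
    tilt_deg: float = 0.0
    tilt_azimuth_deg: float = 0.0
    focal_px: float = 1280.0
    image_size_px: tuple[int, int] = (1280, 960)

    def __post_init__(self) -> None:
        if self.focal_px <= 0:
            raise ValueError("focal_px must be positive")
        if self.height_mm <= 0:
            raise ValueError("height_mm must be positive")

    @property
    def plane_scale(self) -> float:
        """Pixel-per-mm scale of the support plane at zero tilt."""
        return self.focal_px / self.height_mm


def _camera_pose(camera: CameraSpec) -> tuple[np.ndarray, np.ndarray]:
    """Camera centre and world->camera rotation (rows e_x, e_y, e_z).

    World frame: x rightward, y downward in the image at zero tilt, z up
    from the support plane.  The camera looks at the world origin.
    """
    tau = math.radians(camera.tilt_deg)
    psi = math.radians(camera.tilt_azimuth_deg)
    center = camera.height_mm * np.array(
        [math.sin(tau) * math.cos(psi), math.sin(tau) * math.sin(psi), math.cos(tau)]
    )
    e_z = -center / np.linalg.norm(center)  # view direction, toward origin
    # Choose e_x orthogonal to e_z, continuous with the identity at tau=0.
    up = np.array([0.0, 1.0, 0.0])
    e_x = np.cross(up, e_z)
    n = np.linalg.norm(e_x)
    if n < 1e-12:  # degenerate: view along +-y
        e_x = np.array([1.0, 0.0, 0.0])
    else:
        e_x = e_x / n
    if e_x[0] < 0:
        e_x = -e_x
    e_y = np.cross(e_z, e_x)
    return center, np.vstack([e_x, e_y, e_z])


def project_world_to_pixels(
    world_point: Sequence[float] | np.ndarray, camera: CameraSpec
) -> np.ndarray:
    """Project world points (mm, on or above the support plane) to pixels.

    Accepts a single point or an ``(n, 2|3)`` array; 2-D points are taken to
    lie on the support plane (z = 0).  At ``tilt_deg = 0`` the map restricted
    to the plane is a similarity: uniform scale ``focal_px / height_mm`` plus
    a translation to the image centre.

    Raises
    ------
    GeometryError
        if any point is at or behind the camera.
    """
    pts = np.atleast_2d(np.asarray(world_point, dtype=float))
    if pts.shape[-1] == 2:
        pts = np.hstack([pts, np.zeros((len(pts), 1))])
    center, rot = _camera_pose(camera)
    cam = (pts - center) @ rot.T
    z = cam[:, 2]
    if np.any(z <= 1e-9):
        raise GeometryError("point at or behind the camera")
    w, h = camera.image_size_px
    uv = np.empty((len(pts), 2))
    uv[:, 0] = camera.focal_px * cam[:, 0] / z + w / 2.0
    uv[:, 1] = camera.focal_px * cam[:, 1] / z + h / 2.0
    if np.asarray(world_point).ndim == 1:
        return uv[0]
    return uv


def order_quad(quad: np.ndarray) -> np.ndarray:
    """Order 4 corners clockwise (on screen, y down) starting nearest origin."""
    quad = np.asarray(quad, dtype=float)
    c = quad.mean(axis=0)
    ang = np.arctan2(quad[:, 1] - c[1], quad[:, 0] - c[0])
    quad = quad[np.argsort(ang)]  # increasing angle = clockwise with y down
    start = int(np.argmin(np.hypot(quad[:, 0], quad[:, 1])))
    return np.roll(quad, -start, axis=0)


# --------------------------------------------------------------------------
# Scene truth
# --------------------------------------------------------------------------


@dataclass
class SceneTruth:
    """Exact geometry of one synthetic scene."""

    participant: ParticipantSpec
    camera: CameraSpec
    image_id: str
    card_corners_world_mm: np.ndarray  # (4, 3)
    card_corners_px: np.ndarray  # (4, 2), clockwise from corner nearest origin
    landmarks_world_mm: dict[str, np.ndarray]  # name -> (3,)
    landmarks_px: dict[str, np.ndarray]  # name -> (2,)
    defects: frozenset[str]
    occluded: frozenset[str]
    rng_seed: int
    measured_length_mm: float
    render_params: dict = field(default_factory=dict)

    def body_bbox_px(self) -> tuple[float, float, float, float]:
        pts = np.array(list(self.landmarks_px.values()))
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )


@dataclass
class SceneImage:
    """A raster scene plus (for synthetic data) its attached ground truth.

    Pixels are rendered lazily and deterministically from the truth so large
    cohorts can be streamed without holding every frame in memory.
    """

    truth: SceneTruth
    _pixels: np.ndarray | None = field(default=None, repr=False)

    @property
    def pixels(self) -> np.ndarray:
        if self._pixels is None:
            return render(self.truth).pixels_cached
        return self._pixels

    @property
    def pixels_cached(self) -> np.ndarray:
        if self._pixels is None:
            self._pixels = render(self.truth)._pixels
        return self._pixels


# --------------------------------------------------------------------------
# Body and card layout
# --------------------------------------------------------------------------

# Lateral offsets of paired joints as fractions of body half width.
_LATERAL_FRACTION = {
    "shoulder": 0.72,
    "hip": 0.55,
    "knee": 0.40,
    "ankle": 0.33,
    "heel": 0.30,
}

#: Default segment proportions for an infant (crown->shoulder includes the
#: head; values are jittered per participant and renormalised).
BASE_PROPORTIONS = np.array([0.235, 0.305, 0.195, 0.195, 0.070])


def _body_layout(participant: ParticipantSpec) -> dict[str, np.ndarray]:
    """Landmark coordinates in the body frame (axis +x crown->heel, mm).

    Paired joints sit symmetrically about the axis, and the along-axis gaps
    are chosen so every chain segment (using mid-shoulder/mid-hip for the
    upper body and per-side legs) has exactly its prescribed length; the
    measured chain therefore sums to ``true_length_mm`` by construction.
    """
    L = participant.true_length_mm
    w = participant.body_half_width_mm
    seg = np.asarray(participant.segment_proportions) * L
    lat = {k: f * w for k, f in _LATERAL_FRACTION.items()}

    x_crown = 0.0
    x_sh = x_crown + seg[0]
    x_hip = x_sh + seg[1]
    dy_hk = lat["knee"] - lat["hip"]
    x_knee = x_hip + math.sqrt(seg[2] ** 2 - dy_hk**2)
    dy_ka = lat["ankle"] - lat["knee"]
    x_ankle = x_knee + math.sqrt(seg[3] ** 2 - dy_ka**2)
    dy_ah = lat["heel"] - lat["ankle"]
    x_heel = x_ankle + math.sqrt(seg[4] ** 2 - dy_ah**2)

    pts = {"crown": np.array([x_crown, 0.0])}
    for side, s in (("left", -1.0), ("right", 1.0)):
        pts[f"{side}_shoulder"] = np.array([x_sh, s * lat["shoulder"]])
        pts[f"{side}_hip"] = np.array([x_hip, s * lat["hip"]])
        pts[f"{side}_knee"] = np.array([x_knee, s * lat["knee"]])
        pts[f"{side}_ankle"] = np.array([x_ankle, s * lat["ankle"]])
        pts[f"{side}_heel"] = np.array([x_heel, s * lat["heel"]])
    # Face points inside the head region, auxiliary only.
    head_r = 0.45 * seg[0]
    pts["nose"] = np.array([x_crown + head_r, 0.0])
    pts["left_eye"] = np.array([x_crown + 0.75 * head_r, -0.35 * head_r])
    pts["right_eye"] = np.array([x_crown + 0.75 * head_r, 0.35 * head_r])
    # Centre the body on the origin.
    shift = x_heel / 2.0
    return {k: v - [shift, 0.0] for k, v in pts.items()}


def _rotate2(points: np.ndarray, theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return points @ rot.T


def _card_corners_body_frame(
    center: np.ndarray, angle_rad: float, z_mm: float
) -> np.ndarray:
    hw, hh = CARD_WIDTH_MM / 2.0, CARD_HEIGHT_MM / 2.0
    base = np.array([[-hw, -hh], [hw, -hh], [hw, hh], [-hw, hh]])
    xy = _rotate2(base, angle_rad) + center
    return np.hstack([xy, np.full((4, 1), z_mm)])


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable study conditions for cohort generation (mm, px, degrees)."""

    length_range_mm: tuple[float, float] = (450.0, 850.0)
    half_width_fraction: tuple[float, float] = (0.09, 0.13)
    camera_height_range_mm: tuple[float, float] = (1000.0, 1300.0)
    focal_px: float = 1280.0
    image_size_px: tuple[int, int] = (1280, 960)
    body_rotation_deg: float = 8.0
    body_translation_mm: float = 20.0
    card_gap_range_mm: tuple[float, float] = (10.0, 100.0)
    card_angle_jitter_deg: float = 10.0
    tilt_range_deg: tuple[float, float] = (15.0, 30.0)
    tilt_azimuth_jitter_deg: float = 10.0
    card_off_plane_range_mm: tuple[float, float] = (20.0, 60.0)
    blur_sigma_range_px: tuple[float, float] = (1.5, 3.0)
    low_contrast_factor: float = 0.45
    baggy_width_factor: float = 1.7
    pixel_noise_sigma: float = 2.0
    measurement_noise_sigma_mm: float = 2.0


DEFAULT_CONFIG = GeneratorConfig()


def _sample_participant(
    rng: np.random.Generator, index: int, config: GeneratorConfig
) -> ParticipantSpec:
    lo, hi = config.length_range_mm
    length = float(rng.uniform(lo, hi))
    props = BASE_PROPORTIONS * np.exp(rng.normal(0.0, 0.04, size=5))
    props = props / props.sum()
    wf = float(rng.uniform(*config.half_width_fraction))
    return ParticipantSpec(
        participant_id=f"P{index:04d}",
        age_months=float(rng.uniform(0.0, 18.0)),
        true_length_mm=length,
        segment_proportions=tuple(props),
        body_half_width_mm=wf * length,
    )


def _sample_defects(
    rng: np.random.Generator, defect_rates: Mapping[str, float]
) -> frozenset[str]:
    return frozenset(
        name for name in DEFECTS if rng.random() < defect_rates.get(name, 0.0)
    )


def _place_scene(
    participant: ParticipantSpec,
    rng: np.random.Generator,
    defects: frozenset[str],
    config: GeneratorConfig,
    image_id: str,
    rng_seed: int,
    measured_length_mm: float,
) -> SceneTruth:
    """Lay out one scene; retries shrink pose jitter until all geometry fits."""
    for attempt in range(12):
        shrink = 0.5**attempt
        truth = _try_place_scene(
            participant, rng, defects, config, image_id, rng_seed,
            measured_length_mm, shrink,
        )
        if truth is not None:
            return truth
    raise RenderError(
        f"could not fit scene for {participant.participant_id} in frame"
    )


def _try_place_scene(
    participant: ParticipantSpec,
    rng: np.random.Generator,
    defects: frozenset[str],
    config: GeneratorConfig,
    image_id: str,
    rng_seed: int,
    measured_length_mm: float,
    shrink: float,
) -> SceneTruth | None:
    height = float(rng.uniform(*config.camera_height_range_mm))
    if "tilt" in defects:
        tilt = float(rng.uniform(*config.tilt_range_deg))
        azimuth = float(
            rng.integers(0, 4) * 90.0
            + rng.uniform(-1.0, 1.0) * config.tilt_azimuth_jitter_deg
        )
    else:
        tilt, azimuth = 0.0, 0.0
    camera = CameraSpec(
        height_mm=height,
        tilt_deg=tilt,
        tilt_azimuth_deg=azimuth,
        focal_px=config.focal_px,
        image_size_px=config.image_size_px,
    )

    theta = math.radians(
        rng.uniform(-1.0, 1.0) * config.body_rotation_deg * shrink
    )
    trans = rng.uniform(-1.0, 1.0, size=2) * config.body_translation_mm * shrink

    body = _body_layout(participant)
    world2 = {
        k: _rotate2(v[None, :], theta)[0] + trans for k, v in body.items()
    }

    # Card: beside the body (left/right of the axis) at a gap from the
    # silhouette edge, roughly aligned with the body axis; under the torso
    # when the overlap defect is injected.
    w = participant.body_half_width_mm
    card_angle = theta + math.radians(
        rng.uniform(-1.0, 1.0) * config.card_angle_jitter_deg
        + rng.integers(0, 2) * 90.0
    )
    z_card = (
        float(rng.uniform(*config.card_off_plane_range_mm))
        if "card_off_plane" in defects
        else 0.0
    )
    if "card_body_overlap" in defects:
        # Card resting against/on the child: centred at the torso's lateral
        # edge so roughly half of it lies over the body.
        mid = 0.5 * (world2["left_hip"] + world2["right_hip"])
        sh = 0.5 * (world2["left_shoulder"] + world2["right_shoulder"])
        torso = 0.5 * (mid + sh)
        side = -1.0 if rng.random() < 0.5 else 1.0
        lateral = _rotate2(np.array([[0.0, side * 0.9 * w]]), theta)[0]
        card_center = torso + lateral
    else:
        side = -1.0 if rng.random() < 0.5 else 1.0
        gap = float(rng.uniform(*config.card_gap_range_mm))
        # Conservative half-extent of the rotated card across the body axis.
        card_half = 0.5 * math.hypot(CARD_WIDTH_MM, CARD_HEIGHT_MM)
        offset = np.array([0.0, side * (w + gap + card_half)])
        along = rng.uniform(-0.25, 0.25) * participant.true_length_mm
        center_bf = np.array([along, 0.0]) + offset
        card_center = _rotate2(center_bf[None, :], theta)[0] + trans
    card_world = _card_corners_body_frame(card_center, card_angle, z_card)

    # Occlusion: hide one body region.
    occluded: frozenset[str] = frozenset()
    if "occluded_part" in defects:
        region = rng.integers(0, 3)
        occluded = (
            frozenset({"left_ankle", "right_ankle", "left_heel", "right_heel"}),
            frozenset({"left_knee", "right_knee"}),
            frozenset({"crown", "nose", "left_eye", "right_eye"}),
        )[region]

    try:
        lm_world = {k: np.array([v[0], v[1], 0.0]) for k, v in world2.items()}
        lm_px = {
            k: project_world_to_pixels(v, camera) for k, v in lm_world.items()
        }
        card_px = project_world_to_pixels(card_world, camera)
    except GeometryError:
        return None

    wpx, hpx = config.image_size_px
    margin = 8.0
    all_pts = np.vstack([np.array(list(lm_px.values())), card_px])
    if (
        all_pts[:, 0].min() < margin
        or all_pts[:, 1].min() < margin
        or all_pts[:, 0].max() > wpx - margin
        or all_pts[:, 1].max() > hpx - margin
    ):
        return None

    order = order_quad(card_px)
    # Reorder world corners consistently with the pixel ordering.
    idx = [
        int(np.argmin(np.hypot(*(card_px - q).T))) for q in order
    ]
    render_params = {
        "blur_sigma": (
            float(rng.uniform(*config.blur_sigma_range_px))
            if "blur" in defects
            else 0.0
        ),
        "low_contrast_factor": config.low_contrast_factor,
        "baggy_width_factor": config.baggy_width_factor,
        "pixel_noise_sigma": config.pixel_noise_sigma,
        "body_theta": theta,
    }
    return SceneTruth(
        participant=participant,
        camera=camera,
        image_id=image_id,
        card_corners_world_mm=card_world[idx],
        card_corners_px=order,
        landmarks_world_mm=lm_world,
        landmarks_px=lm_px,
        defects=defects,
        occluded=occluded,
        rng_seed=rng_seed,
        measured_length_mm=measured_length_mm,
        render_params=render_params,
    )


def generate_truths(
    n_participants: int,
    images_per_participant: int,
    seed: int,
    defect_rates: Mapping[str, float] | None = None,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> list[SceneTruth]:
    """Generate ground truths for a cohort (no rasterisation).

    Each participant keeps one true length across images; the recorded
    (length-board style) measurement adds small zero-mean error once per
    participant, rounded to 1 mm.  Deterministic for fixed arguments.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if images_per_participant < 1:
        raise ValueError("images_per_participant must be >= 1")
    rates = dict(defect_rates or {})
    for name, p in rates.items():
        if name not in DEFECTS:
            raise ValueError(f"unknown defect: {name}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"defect rate out of [0, 1]: {name}={p}")

    root = np.random.SeedSequence(seed)
    truths: list[SceneTruth] = []
    for i, child_ss in enumerate(root.spawn(n_participants)):
        streams = child_ss.spawn(images_per_participant + 1)
        prng = np.random.default_rng(streams[0])
        participant = _sample_participant(prng, i, config)
        measured = participant.true_length_mm + prng.normal(
            0.0, config.measurement_noise_sigma_mm
        )
        measured = round(measured)  # recorded to 0.1 cm
        for j in range(images_per_participant):
            irng = np.random.default_rng(streams[j + 1])
            rng_seed = int(streams[j + 1].generate_state(1)[0] % (2**31))
            defects = _sample_defects(irng, rates)
            truths.append(
                _place_scene(
                    participant,
                    irng,
                    defects,
                    config,
                    image_id=f"{participant.participant_id}_I{j:02d}",
                    rng_seed=rng_seed,
                    measured_length_mm=float(measured),
                )
            )
    return truths


def generate_cohort(
    n_participants: int,
    images_per_participant: int,
    seed: int,
    defect_rates: Mapping[str, float] | None = None,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> list[SceneImage]:
    """Generate a cohort of scenes; pixels render lazily on access."""
    return [
        SceneImage(t)
        for t in generate_truths(
            n_participants, images_per_participant, seed, defect_rates, config
        )
    ]


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def _draw_capsule(draw: ImageDraw.ImageDraw, a, b, radius: float, color) -> None:
    draw.line([tuple(a), tuple(b)], fill=color, width=max(1, int(round(2 * radius))))
    for p in (a, b):
        draw.ellipse(
            [p[0] - radius, p[1] - radius, p[0] + radius, p[1] + radius],
            fill=color,
        )


def _draw_body(
    draw: ImageDraw.ImageDraw,
    truth: SceneTruth,
    rng: np.random.Generator,
) -> None:
    lm = truth.landmarks_px
    scale = truth.camera.plane_scale
    w_px = truth.participant.body_half_width_mm * scale
    baggy = "baggy_contour" in truth.defects
    factor = truth.render_params.get("baggy_width_factor", 1.7) if baggy else 1.0

    mid_sh = 0.5 * (lm["left_shoulder"] + lm["right_shoulder"])
    mid_hip = 0.5 * (lm["left_hip"] + lm["right_hip"])
    # Torso capsule.
    _draw_capsule(draw, mid_sh, mid_hip, w_px * factor, BODY_COLOR)
    # Head: circle tangent to the crown from inside.
    head_r = 0.40 * np.linalg.norm(mid_sh - lm["crown"]) * (1.15 if baggy else 1.0)
    axis = mid_sh - lm["crown"]
    axis = axis / (np.linalg.norm(axis) + 1e-9)
    head_c = lm["crown"] + head_r * axis
    draw.ellipse(
        [
            head_c[0] - head_r,
            head_c[1] - head_r,
            head_c[0] + head_r,
            head_c[1] + head_r,
        ],
        fill=BODY_COLOR,
    )
    # Neck/shoulder fill.
    _draw_capsule(draw, head_c, mid_sh, 0.55 * w_px * factor, BODY_COLOR)
    # Legs.
    leg_r = 0.30 * w_px * factor
    for side in ("left", "right"):
        chain = [lm[f"{side}_hip"], lm[f"{side}_knee"], lm[f"{side}_ankle"], lm[f"{side}_heel"]]
        for a, b in zip(chain[:-1], chain[1:]):
            _draw_capsule(draw, a, b, leg_r, BODY_COLOR)
    if baggy:
        # Irregular bumps along the torso edge.
        for _ in range(5):
            t = rng.uniform(0.0, 1.0)
            p = mid_sh + t * (mid_hip - mid_sh)
            off = rng.uniform(-1.0, 1.0, size=2) * w_px * 0.6
            r = rng.uniform(0.3, 0.6) * w_px
            draw.ellipse(
                [p[0] + off[0] - r, p[1] + off[1] - r, p[0] + off[0] + r, p[1] + off[1] + r],
                fill=BODY_COLOR,
            )


def render(truth: SceneTruth) -> SceneImage:
    """Rasterise a scene: flat-shaded card and body, defects applied last.

    Raises
    ------
    RenderError
        if a non-occluded landmark falls outside the frame.
    """
    w, h = truth.camera.image_size_px
    for name, p in truth.landmarks_px.items():
        if name in truth.occluded:
            continue
        if not (0 <= p[0] < w and 0 <= p[1] < h):
            raise RenderError(f"landmark {name} outside frame at {p}")

    rng = np.random.default_rng(np.random.SeedSequence([truth.rng_seed, 97]))
    # Rasterise at 2x and box-downsample: edge pixels then carry fractional
    # coverage, emulating the soft edges of a real photograph and enabling
    # subpixel card localisation downstream.
    ss = 2
    half = 0.5 * (ss - 1)  # box-filter centre alignment
    scaled = replace(
        truth,
        landmarks_px={k: ss * v + half for k, v in truth.landmarks_px.items()},
        camera=replace(truth.camera, focal_px=ss * truth.camera.focal_px),
    )
    quad = ss * truth.card_corners_px + half
    card_mask = polygon2mask((h * ss, w * ss), quad[:, ::-1])

    def _paint_card(image: Image.Image) -> Image.Image:
        arr = np.asarray(image).copy()
        arr[card_mask] = CARD_COLOR
        return Image.fromarray(arr)

    img = Image.new("RGB", (w * ss, h * ss), BACKGROUND_COLOR)
    # Card is painted after the body: in an overlap scene it rests on the
    # child, so it stays fully visible (a card slid fully underneath would
    # simply be an unsuccessful card segmentation).
    _draw_body(ImageDraw.Draw(img), scaled, rng)
    img = _paint_card(img)
    img = img.resize((w, h), Image.BOX)

    if truth.render_params.get("blur_sigma", 0.0) > 0:
        img = img.filter(
            ImageFilter.GaussianBlur(truth.render_params["blur_sigma"])
        )

    arr = np.asarray(img, dtype=float)
    if "low_contrast" in truth.defects:
        f = truth.render_params.get("low_contrast_factor", 0.45)
        arr = arr.mean() + (arr - arr.mean()) * f

    if truth.occluded:
        pts = np.array([truth.landmarks_px[n] for n in truth.occluded])
        pad = 0.35 * truth.participant.body_half_width_mm * truth.camera.plane_scale + 25
        x0 = max(0, int(pts[:, 0].min() - pad))
        x1 = min(w, int(pts[:, 0].max() + pad))
        y0 = max(0, int(pts[:, 1].min() - pad))
        y1 = min(h, int(pts[:, 1].max() + pad))
        arr[y0:y1, x0:x1] = COVER_COLOR

    sigma = truth.render_params.get("pixel_noise_sigma", 2.0)
    if sigma > 0:
        arr = arr + rng.normal(0.0, sigma, size=arr.shape)
    pixels = np.clip(arr, 0, 255).astype(np.uint8)
    return SceneImage(truth, pixels)


# --------------------------------------------------------------------------
# Disk I/O
# --------------------------------------------------------------------------

_CSV_FIELDS = (
    ["participant_id", "image_id", "true_length_mm", "measured_length_mm",
     "body_half_width_mm", "rng_seed", "defects", "occluded",
     "camera_height_mm", "camera_tilt_deg", "camera_azimuth_deg",
     "focal_px", "image_w", "image_h"]
    + [f"card_{i}_{ax}" for i in range(4) for ax in "xy"]
)


def write_cohort(scenes: Iterable[SceneImage], out_dir: str | Path) -> Path:
    """Write PNG frames plus a ground-truth CSV sidecar; returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = sorted(set(REQUIRED_LANDMARKS) | set(OPTIONAL_LANDMARKS))
    fields = _CSV_FIELDS + [f"lm_{n}_{ax}" for n in names for ax in "xy"]
    csv_path = out / "truth.csv"
    with open(csv_path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=fields)
        wr.writeheader()
        for scene in scenes:
            t = scene.truth
            Image.fromarray(scene.pixels).save(out / f"{t.image_id}.png")
            row = {
                "participant_id": t.participant.participant_id,
                "image_id": t.image_id,
                "true_length_mm": t.participant.true_length_mm,
                "measured_length_mm": t.measured_length_mm,
                "body_half_width_mm": t.participant.body_half_width_mm,
                "rng_seed": t.rng_seed,
                "defects": "|".join(sorted(t.defects)),
                "occluded": "|".join(sorted(t.occluded)),
                "camera_height_mm": t.camera.height_mm,
                "camera_tilt_deg": t.camera.tilt_deg,
                "camera_azimuth_deg": t.camera.tilt_azimuth_deg,
                "focal_px": t.camera.focal_px,
                "image_w": t.camera.image_size_px[0],
                "image_h": t.camera.image_size_px[1],
            }
            for i in range(4):
                row[f"card_{i}_x"] = t.card_corners_px[i, 0]
                row[f"card_{i}_y"] = t.card_corners_px[i, 1]
            for n in names:
                if n in t.landmarks_px:
                    row[f"lm_{n}_x"] = t.landmarks_px[n][0]
                    row[f"lm_{n}_y"] = t.landmarks_px[n][1]
            wr.writerow(row)
    return csv_path


def read_cohort(data_dir: str | Path) -> list[SceneImage]:
    """Load a cohort written by :func:`write_cohort` (truth from sidecar CSV)."""
    data_dir = Path(data_dir)
    csv_path = data_dir / "truth.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"no truth.csv in {data_dir}")
    scenes: list[SceneImage] = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            lm_px = {}
            for key, val in row.items():
                if key.startswith("lm_") and key.endswith("_x") and val:
                    name = key[3:-2]
                    lm_px[name] = np.array(
                        [float(val), float(row[f"lm_{name}_y"])]
                    )
            card_px = np.array(
                [
                    [float(row[f"card_{i}_x"]), float(row[f"card_{i}_y"])]
                    for i in range(4)
                ]
            )
            camera = CameraSpec(
                height_mm=float(row["camera_height_mm"]),
                tilt_deg=float(row["camera_tilt_deg"]),
                tilt_azimuth_deg=float(row["camera_azimuth_deg"]),
                focal_px=float(row["focal_px"]),
                image_size_px=(int(row["image_w"]), int(row["image_h"])),
            )
            true_len = float(row["true_length_mm"])
            participant = ParticipantSpec(
                participant_id=row["participant_id"],
                age_months=0.0,
                true_length_mm=true_len,
                segment_proportions=tuple(BASE_PROPORTIONS),
                body_half_width_mm=float(row["body_half_width_mm"]),
            )
            truth = SceneTruth(
                participant=participant,
                camera=camera,
                image_id=row["image_id"],
                card_corners_world_mm=np.zeros((4, 3)),
                card_corners_px=card_px,
                landmarks_world_mm={},
                landmarks_px=lm_px,
                defects=frozenset(
                    d for d in row["defects"].split("|") if d
                ),
                occluded=frozenset(
                    d for d in row["occluded"].split("|") if d
                ),
                rng_seed=int(row["rng_seed"]),
                measured_length_mm=float(row["measured_length_mm"]),
            )
            pixels = np.asarray(
                Image.open(data_dir / f"{truth.image_id}.png").convert("RGB")
            )
            scenes.append(SceneImage(truth, pixels))
    return scenes
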