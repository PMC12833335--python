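"""Synthetic maize-stem field scenes with known ground truth.

A scene emulates the geometry the measurement pipeline operates on: a
near-vertical stem whose cross-section is an ellipse with localized radial
swellings at the nodes, a rough ground disc, and a flat 3x3 checkerboard
scale plate of 15 mm squares. Every point carries a binary label
(0 = background, 1 = stem) and the generator returns the ground-truth
diameters, node heights, axis direction and checkerboard span so that
segmentation, node detection and diameter measurement are all testable
without external data.

The vertical axis of a scene is +y; the ground disc lies in the xz-plane.
Scene coordinates are millimetres unless ``unit_scale`` is set, in which case
all coordinates (and the checkerboard span Q) are multiplied by it to emulate
the unknown global scale of a multi-view reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .cloud import LabeledPointCloud

__all__ = [
    "CheckerboardSpec",
    "SyntheticStemConfig",
    "SceneGroundTruth",
    "generate_stem_scene",
    "generate_checkerboard_plate",
]


@dataclass(frozen=True)
class CheckerboardSpec:
    """Flat checkerboard scale plate (defaults: 3x3 squares of 15 mm)."""

    square_mm: float = 15.0
    rows: int = 3
    cols: int = 3
    center: Tuple[float, float, float] = (130.0, 2.0, 0.0)
    orientation_deg: float = 20.0           # in-plane rotation about +y
    points_per_square: int = 150

    @property
    def span_mm(self) -> float:
        """Edge-to-edge span along either plate axis (45 mm for the default)."""
        if self.rows != self.cols:
            raise ValueError("span is only defined for square plates")
        return self.rows * self.square_mm


@dataclass
class SyntheticStemConfig:
    """Parameters of a synthetic stem scene.

    ``major_diameter`` and ``minor_diameter`` are the stem diameters *at the
    midpoint of the second internode* (between the first two nodes) — the
    quantity the measurement pipeline targets — so the ground truth echoes the
    config exactly. ``taper`` is the fractional diameter change over the full
    stem height, applied relative to that reference height.
    """

    stem_height: float = 450.0              # mm
    major_diameter: float = 32.0            # mm, = 2a at the reference height
    minor_diameter: float = 26.0            # mm, = 2b at the reference height
    taper: float = 0.12                     # fractional change bottom -> top
    node_heights: Sequence[float] = (150.0, 300.0)
    node_swell: float = 0.25                # fractional radial amplification
    node_width: float = 10.0                # mm, Gaussian sigma of the swelling
    axis_tilt_deg: float = 3.0              # tilt from vertical (+y)
    noise_sd: float = 0.4                   # mm, along the local surface normal
    outlier_fraction: float = 0.0
    stem_points: int = 2500
    ground_points: int = 50000              # ~20x the stem, as in real scenes
    ground_radius: float = 250.0            # mm
    ground_roughness_sd: float = 2.0        # mm
    checkerboard: CheckerboardSpec = field(default_factory=CheckerboardSpec)
    unit_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.major_diameter >= self.minor_diameter > 0):
            raise ValueError("require major_diameter >= minor_diameter > 0")
        if self.node_swell < 0:
            raise ValueError("node_swell must be non-negative")
        if len(self.node_heights) < 2:
            raise ValueError("at least two node heights are required")
        if self.stem_points < 1 or self.ground_points < 1:
            raise ValueError("stem_points and ground_points must be >= 1")
        if self.stem_height <= 0 or self.ground_radius <= 0:
            raise ValueError("stem_height and ground_radius must be positive")
        if self.node_width <= 0:
            raise ValueError("node_width must be positive")
        if self.unit_scale <= 0:
            raise ValueError("unit_scale must be positive")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")

    @property
    def reference_height(self) -> float:
        """Axial midpoint of the second internode (between nodes 1 and 2)."""
        return 0.5 * (self.node_heights[0] + self.node_heights[1])

    def radius_profile(self, t) -> Tuple[np.ndarray, np.ndarray]:
        """Semi-axes ``(a(t), b(t))`` in mm at axial position(s) ``t``.

        ``a(t) = (major/2) * shape(t)`` where ``shape`` combines the linear
        taper (relative to the reference height) with multiplicative Gaussian
        swelling bumps centred on the node heights.
        """
        t = np.asarray(t, dtype=float)
        shape = 1.0 - self.taper * (t - self.reference_height) / self.stem_height
        bumps = np.zeros_like(shape)
        for tn in self.node_heights:
            bumps += np.exp(-((t - tn) ** 2) / (2.0 * self.node_width**2))
        shape = shape * (1.0 + self.node_swell * bumps)
        return 0.5 * self.major_diameter * shape, 0.5 * self.minor_diameter * shape


@dataclass(frozen=True)
class SceneGroundTruth:
    """Known quantities of a generated scene.

    ``checkerboard_span_units`` is Q of the scale conversion: the plate
    edge-to-edge distance expressed in scene units.
    """

    true_major_mm: float
    true_minor_mm: float
    node_heights: Tuple[float, ...]
    checkerboard_span_units: float
    axis_direction: np.ndarray
    label_counts: dict

    def __post_init__(self) -> None:
        if self.checkerboard_span_units <= 0:
            raise ValueError("checkerboard_span_units must be positive")
        axis = np.asarray(self.axis_direction, dtype=float)
        if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-9):
            raise ValueError("axis_direction must be unit-length")
        object.__setattr__(self, "axis_direction", axis)


def _orthonormal_frame(axis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``axis``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def generate_checkerboard_plate(
    square_mm: float = 15.0,
    grid: Tuple[int, int] = (3, 3),
    rotation: Optional[np.ndarray] = None,
    translation: Sequence[float] = (0.0, 0.0, 0.0),
    points_per_square: int = 150,
    seed: int = 0,
) -> LabeledPointCloud:
    """Planar checkerboard point set with alternating square shading.

    In the plate frame the board lies in the xz-plane centred at the origin,
    spanning ``cols*square_mm`` along x and ``rows*square_mm`` along z; the
    rigid pose ``(rotation, translation)`` is then applied. All points are
    labeled 0 (background) and square shading is stored in the colors.
    """
    if square_mm <= 0:
        raise ValueError("square_mm must be positive")
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one row and column")
    if points_per_square < 1:
        raise ValueError("points_per_square must be >= 1")
    rng = np.random.default_rng(seed)
    pts = []
    shade = []
    for i in range(rows):
        for j in range(cols):
            u = (j + rng.random(points_per_square)) * square_mm - cols * square_mm / 2
            v = (i + rng.random(points_per_square)) * square_mm - rows * square_mm / 2
            pts.append(np.column_stack([u, np.zeros_like(u), v]))
            shade.append(np.full(points_per_square, 0.95 if (i + j) % 2 == 0 else 0.05))
    coords = np.concatenate(pts)
    shade = np.concatenate(shade)
    if rotation is not None:
        coords = coords @ np.asarray(rotation, dtype=float).T
        normal = np.asarray(rotation, dtype=float) @ np.array([0.0, 1.0, 0.0])
    else:
        normal = np.array([0.0, 1.0, 0.0])
    coords = coords + np.asarray(translation, dtype=float)
    colors = np.column_stack([shade, shade, shade])
    normals = np.tile(normal, (coords.shape[0], 1))
    labels = np.zeros(coords.shape[0], dtype=int)
    return LabeledPointCloud(coords, colors=colors, normals=normals, labels=labels,
                             meta={"kind": "checkerboard", "square_mm": square_mm, "grid": grid})


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def generate_stem_scene(config: SyntheticStemConfig) -> Tuple[LabeledPointCloud, SceneGroundTruth]:
    """Generate a full scene (stem + ground + checkerboard) with ground truth.

    Deterministic given ``config.seed``: the same config always yields the
    same cloud. Stem points are sampled on the elliptical generalized
    cylinder ``r(theta, t) * (1 + node bumps)`` with Gaussian noise along the
    local surface normal; ground points form a rough disc; the checkerboard
    plate sits flat near the stem. Labels: stem 1, everything else 0.
    """
    rng = np.random.default_rng(config.seed)

    # --- stem axis ------------------------------------------------------
    tilt = np.deg2rad(config.axis_tilt_deg)
    azimuth = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.sin(tilt) * np.cos(azimuth), np.cos(tilt), np.sin(tilt) * np.sin(azimuth)])
    e1, e2 = _orthonormal_frame(axis)
    ellipse_az = rng.uniform(0, 2 * np.pi)
    rot = _rotation_about(axis, ellipse_az)
    e1, e2 = rot @ e1, rot @ e2

    # --- stem surface ----------------------------------------------------
    t = rng.uniform(0.0, config.stem_height, config.stem_points)
    theta = rng.uniform(0.0, 2 * np.pi, config.stem_points)
    a, b = config.radius_profile(t)
    radial = (a * np.cos(theta))[:, None] * e1 + (b * np.sin(theta))[:, None] * e2
    surf_n = (np.cos(theta) / a)[:, None] * e1 + (np.sin(theta) / b)[:, None] * e2
    surf_n /= np.linalg.norm(surf_n, axis=1, keepdims=True)
    stem = t[:, None] * axis + radial
    if config.noise_sd > 0:
        stem = stem + rng.normal(0.0, config.noise_sd, config.stem_points)[:, None] * surf_n
    n_out = int(round(config.outlier_fraction * config.stem_points))
    if n_out:
        which = rng.choice(config.stem_points, n_out, replace=False)
        stem[which] += rng.normal(0.0, 10.0, (n_out, 3))
    stem_colors = np.clip(
        np.array([0.20, 0.55, 0.22]) + rng.normal(0.0, 0.05, (config.stem_points, 3)), 0, 1
    )

    # --- ground disc with smooth roughness -------------------------------
    r = config.ground_radius * np.sqrt(rng.random(config.ground_points))
    phi = rng.uniform(0, 2 * np.pi, config.ground_points)
    gx, gz = r * np.cos(phi), r * np.sin(phi)
    height = np.zeros_like(gx)
    # wavelengths scale with the disc so scenes are unit-coherent
    k_scale = 1.0 / (0.24 * config.ground_radius)
    for _ in range(6):
        k = rng.normal(0.0, k_scale, 2)
        height += rng.normal(0.0, 1.0) * np.sin(gx * k[0] + gz * k[1] + rng.uniform(0, 2 * np.pi))
    sd = height.std()
    if sd > 0:
        height *= config.ground_roughness_sd / sd
    ground = np.column_stack([gx, height, gz])
    ground_colors = np.clip(
        np.array([0.45, 0.35, 0.25]) + rng.normal(0.0, 0.05, (config.ground_points, 3)), 0, 1
    )
    ground_normals = np.tile([0.0, 1.0, 0.0], (config.ground_points, 1))

    # --- checkerboard plate ----------------------------------------------
    cb = config.checkerboard
    plate_rot = _rotation_about(np.array([0.0, 1.0, 0.0]), np.deg2rad(cb.orientation_deg))
    plate = generate_checkerboard_plate(
        square_mm=cb.square_mm,
        grid=(cb.rows, cb.cols),
        rotation=plate_rot,
        translation=cb.center,
        points_per_square=cb.points_per_square,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    # --- assemble ---------------------------------------------------------
    coords = np.vstack([stem, ground, plate.coords])
    colors = np.vstack([stem_colors, ground_colors, plate.colors])
    normals = np.vstack([surf_n, ground_normals, plate.normals])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    labels = np.concatenate([
        np.ones(config.stem_points, dtype=int),
        np.zeros(config.ground_points, dtype=int),
        plate.labels,
    ])
    coords = coords * config.unit_scale

    cloud = LabeledPointCloud(
        coords, colors=colors, normals=normals, labels=labels,
        meta={"kind": "synthetic_stem_scene", "seed": config.seed,
              "stem_frame": {"axis": axis, "e1": e1, "e2": e2}},
    )
    n_plate = plate.n_points
    truth = SceneGroundTruth(
        true_major_mm=config.major_diameter,
        true_minor_mm=config.minor_diameter,
        node_heights=tuple(float(h) for h in config.node_heights),
        checkerboard_span_units=cb.span_mm * config.unit_scale,
        axis_direction=axis,
        label_counts={0: config.ground_points + n_plate, 1: config.stem_points},
    )
    return cloud, truth
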