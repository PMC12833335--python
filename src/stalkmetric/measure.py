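"""Stem diameter measurement from a segmented stem point cloud.

The measurement proceeds in three steps:

1. **Principal axis** — PCA of the stem points: the top eigenvector of the
   coordinate covariance matrix approximates the growth axis. The axis sign
   is oriented so the lower (ground-facing) end has the smaller axial
   coordinate.
2. **Node detection** — the stem is uniformly partitioned into ``n_slices``
   (default 15) along the axis; each slice is projected onto the plane
   perpendicular to the axis and ellipse-fitted. Nodes swell radially, so the
   slice-wise major-axis sequence shows an increase–peak–decrease pattern;
   the first two prominent peaks are the first two nodes and the region
   strictly between them is the second-internode ROI.
3. **Diameter** — three thin cross-sections evenly spaced inside the ROI are
   ellipse-fitted; the mean major/minor axis lengths are converted to
   millimetres with the checkerboard scale factor ``S = 45 * L / Q``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cloud import LabeledPointCloud

__all__ = [
    "AxisFrame",
    "EllipseFit",
    "SliceProfile",
    "StemMeasurement",
    "MeasurementError",
    "NodeDetectionError",
    "principal_axis",
    "fit_ellipse",
    "slice_profiles",
    "detect_node_peaks",
    "extract_second_internode",
    "measure_stem_diameter",
    "scale_to_mm",
    "measure_stem",
    "CHECKERBOARD_SPAN_MM",
]

#: Physical edge-to-edge span of the 3x3 checkerboard scale plate.
CHECKERBOARD_SPAN_MM = 45.0


class MeasurementError(RuntimeError):
    """Raised when the geometric pipeline cannot produce a measurement."""


class NodeDetectionError(MeasurementError):
    """Fewer than two node peaks found; carries the diagnostic sequence."""

    def __init__(self, message: str, sequence: Optional[np.ndarray] = None):
        super().__init__(message)
        self.sequence = sequence


@dataclass(frozen=True)
class AxisFrame:
    """PCA frame of the stem: mean, covariance, orthonormal eigenvectors.

    ``v1`` (the top eigenvector) is the principal axis; ``v2``/``v3`` span the
    cross-section plane. ``elongation`` = lambda1/lambda2 flags degenerate,
    non-elongated inputs when small.
    """

    mean: np.ndarray
    covariance: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    eigvals: np.ndarray            # descending
    degenerate: bool

    @property
    def elongation(self) -> float:
        return float(self.eigvals[0] / self.eigvals[1])

    def axial(self, coords: np.ndarray) -> np.ndarray:
        """Axial coordinate t of points along v1, relative to the mean."""
        return (np.asarray(coords) - self.mean) @ self.v1

    def project(self, coords: np.ndarray) -> np.ndarray:
        """2D coordinates of points in the (v2, v3) cross-section plane."""
        rel = np.asarray(coords) - self.mean
        return np.column_stack([rel @ self.v2, rel @ self.v3])


@dataclass(frozen=True)
class EllipseFit:
    """Fitted ellipse in a slice plane: ``a >= b > 0``, orientation in [0, pi)."""

    center: np.ndarray
    semi_major: float
    semi_minor: float
    orientation: float
    rms_residual: float

    @property
    def major_axis_len(self) -> float:
        return 2.0 * self.semi_major

    @property
    def minor_axis_len(self) -> float:
        return 2.0 * self.semi_minor


@dataclass(frozen=True)
class SliceProfile:
    """One of the uniform axial slices used for node detection."""

    index: int
    t_lo: float
    t_hi: float
    n_points: int
    ellipse: Optional[EllipseFit]
    valid: bool


@dataclass(frozen=True)
class StemMeasurement:
    """Major/minor stem diameters, in scene units and (once scaled) in mm."""

    per_section: Tuple[Optional[EllipseFit], ...]
    major_units: float
    minor_units: float
    scale_q: Optional[float] = None
    major_mm: Optional[float] = None
    minor_mm: Optional[float] = None

    def with_scale(self, checkerboard_span_units: float) -> "StemMeasurement":
        """Apply the checkerboard scale conversion to both diameters."""
        return replace(
            self,
            scale_q=float(checkerboard_span_units),
            major_mm=scale_to_mm(self.major_units, checkerboard_span_units),
            minor_mm=scale_to_mm(self.minor_units, checkerboard_span_units),
        )


# ---------------------------------------------------------------------------
# Step 1: principal axis
# ---------------------------------------------------------------------------


def principal_axis(
    stem: LabeledPointCloud,
    ground_reference: Optional[np.ndarray] = None,
    degenerate_ratio: float = 4.0,
) -> AxisFrame:
    """PCA principal axis of the stem points.

    ``v1`` maximizes the projected variance v^T C v. The sign is chosen so
    that the lower end has the smaller axial coordinate: if a
    ``ground_reference`` point (e.g. the background centroid) is given, it
    must sit below the stem's axial median; otherwise the canonical up
    direction +y is used. A warning flag is set when lambda1/lambda2 < 4
    (the cloud is not convincingly elongated).
    """
    coords = stem.coords
    if coords.shape[0] < 3:
        raise ValueError("principal_axis requires at least 3 points")
    mean = coords.mean(axis=0)
    centered = coords - mean
    cov = centered.T @ centered / coords.shape[0]
    vals, vecs = np.linalg.eigh(cov)               # ascending
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    v1, v2, v3 = vecs[:, order[0]], vecs[:, order[1]], vecs[:, order[2]]

    if ground_reference is not None:
        t_ground = (np.asarray(ground_reference, dtype=float) - mean) @ v1
        t_median = np.median(centered @ v1)
        if t_ground > t_median:
            v1 = -v1
    elif v1[1] < 0:                                # canonical up = +y
        v1 = -v1
    v3 = np.cross(v1, v2)                          # keep right-handed frame
    v3 /= np.linalg.norm(v3)

    degenerate = bool(vals[1] > 0 and vals[0] / vals[1] < degenerate_ratio)
    if degenerate:
        warnings.warn(
            f"principal axis is degenerate (elongation {vals[0] / vals[1]:.2f} < "
            f"{degenerate_ratio})",
            RuntimeWarning,
            stacklevel=2,
        )
    return AxisFrame(mean=mean, covariance=cov, v1=v1, v2=v2, v3=v3,
                     eigvals=vals, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Step 2: ellipse fitting and slicing
# ---------------------------------------------------------------------------


def _ellipse_from_conic(coef: np.ndarray) -> Tuple[np.ndarray, float, float, float]:
    """Geometric parameters (center, a, b, angle) from conic coefficients.

    Conic: A x^2 + B xy + C y^2 + D x + E y + F = 0 with B^2 - 4AC < 0.
    Writing the quadratic part as u^T M u, the semi-axis along eigenvector i
    of M is sqrt(-G / lambda_i) where G is the conic value at the center; the
    major axis belongs to the smaller eigenvalue.
    """
    A, B, C, D, E, F = coef
    m = np.array([[A, B / 2.0], [B / 2.0, C]])
    if np.linalg.det(m) <= 0:
        raise MeasurementError("conic is not an ellipse")
    center = np.linalg.solve(m, [-D / 2.0, -E / 2.0])
    g = F + 0.5 * (D * center[0] + E * center[1])
    vals, vecs = np.linalg.eigh(m)                 # ascending eigenvalues
    if vals[1] <= 0:                               # negative-definite scaling
        vals, g = -vals[::-1], -g
        vecs = vecs[:, ::-1]
    radicand = -g / vals
    if np.any(radicand <= 0):
        raise MeasurementError("degenerate ellipse parameters")
    a, b = np.sqrt(radicand[0]), np.sqrt(radicand[1])   # a >= b (vals ascending)
    major_vec = vecs[:, 0]
    angle = float(np.arctan2(major_vec[1], major_vec[0]) % np.pi)
    return center, float(a), float(b), angle


def _moment_ellipse(pts: np.ndarray) -> EllipseFit:
    """Second-moment ellipse of points sampled on a contour (fallback fit).

    For points on an ellipse boundary the coordinate variances along the
    principal directions are a^2/2 and b^2/2, so the semi-axes are
    sqrt(2 * eigenvalue).
    """
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / pts.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    a = float(np.sqrt(max(2.0 * vals[1], 0.0)))
    b = float(np.sqrt(max(2.0 * vals[0], 0.0)))
    if a <= 0 or b <= 0:
        raise MeasurementError("all points are collinear; ellipse fit failed")
    angle = float(np.arctan2(vecs[1, 1], vecs[0, 1]) % np.pi)
    return EllipseFit(center=center, semi_major=a, semi_minor=b,
                      orientation=angle, rms_residual=float("nan"))


def fit_ellipse(points2d: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit (stable Fitzgibbon formulation).

    Solves the constrained algebraic problem min ||D w|| s.t.
    4 A C - B^2 = 1, which always returns an ellipse, using the numerically
    stable block decomposition of Halir & Flusser. Axis lengths are invariant
    under rigid motion of the inputs. Falls back to the second-moment ellipse
    when the constrained eigenproblem fails.
    """
    pts = np.asarray(points2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points2d must be (M, 2)")
    if pts.shape[0] < 6:
        raise ValueError("ellipse fitting requires at least 6 points")
    shift = pts.mean(axis=0)
    scale = pts.std()
    if scale <= 0:
        raise MeasurementError("all points coincide; ellipse fit failed")
    q = (pts - shift) / scale
    x, y = q[:, 0], q[:, 1]
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    c1inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    try:
        t_mat = -np.linalg.solve(s3, s2.T)
        m = c1inv @ (s1 + s2 @ t_mat)
        vals, vecs = np.linalg.eig(m)
        # admissible eigenvector: 4ac - b^2 > 0
        cond = 4 * vecs[0] * vecs[2] - vecs[1] ** 2
        good = np.where(np.isreal(vals) & (cond > 0))[0]
        if len(good) == 0:
            raise np.linalg.LinAlgError("no ellipse solution")
        w1 = np.real(vecs[:, good[0]])
        w = np.concatenate([w1, t_mat @ w1])
        center_n, a_n, b_n, angle = _ellipse_from_conic(w)
        center = center_n * scale + shift
        a, b = a_n * scale, b_n * scale
        design = np.column_stack([d1, d2])
        residual = float(np.sqrt(np.mean((design @ w) ** 2)))
    except (np.linalg.LinAlgError, MeasurementError):
        fit = _moment_ellipse(pts)
        return fit
    return EllipseFit(center=center, semi_major=float(a), semi_minor=float(b),
                      orientation=float(angle), rms_residual=residual)


def slice_profiles(
    stem: LabeledPointCloud,
    frame: AxisFrame,
    n_slices: int = 15,
    min_points: int = 30,
) -> List[SliceProfile]:
    """Uniformly partition the stem along the axis and ellipse-fit each slice.

    Returns exactly ``n_slices`` profiles covering the axial extent, indexed
    from the lower end. Slices with fewer than ``min_points`` points, or
    whose ellipse fit fails, are marked invalid.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    t = frame.axial(stem.coords)
    t_min, t_max = float(t.min()), float(t.max())
    if t_max <= t_min:
        raise MeasurementError("stem has no axial extent")
    edges = np.linspace(t_min, t_max, n_slices + 1)
    bins = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_slices - 1)
    pts2d = frame.project(stem.coords)
    profiles: List[SliceProfile] = []
    for i in range(n_slices):
        mask = bins == i
        count = int(mask.sum())
        ellipse = None
        valid = False
        if count >= max(min_points, 6):
            try:
                ellipse = fit_ellipse(pts2d[mask])
                valid = True
            except (ValueError, MeasurementError):
                ellipse = None
        profiles.append(SliceProfile(index=i, t_lo=float(edges[i]), t_hi=float(edges[i + 1]),
                                     n_points=count, ellipse=ellipse, valid=valid))
    if not any(p.valid for p in profiles):
        raise MeasurementError("every slice is invalid; cannot build a profile")
    return profiles


# ---------------------------------------------------------------------------
# Node peak detection
# ---------------------------------------------------------------------------


def _plateau_local_maxima(values: np.ndarray) -> List[int]:
    """Indices of strict interior local maxima; plateaus report their first index."""
    n = len(values)
    peaks = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        # run [i, j] of equal values; interior peak if both sides are lower
        if j < n - 1 and values[i - 1] < values[i] and values[j + 1] < values[i]:
            peaks.append(i)
        i = j + 1
    return peaks


def _prominence(values: np.ndarray, peak: int) -> float:
    """Topographic prominence of ``values[peak]`` (O(n) two-sided scan)."""
    v = values[peak]
    left = values[:peak]
    higher_left = np.where(left > v)[0]
    lmin = left[higher_left[-1] + 1:].min() if len(higher_left) else (left.min() if len(left) else v)
    right = values[peak + 1:]
    higher_right = np.where(right > v)[0]
    rmin = right[: higher_right[0]].min() if len(higher_right) else (right.min() if len(right) else v)
    return float(v - max(lmin, rmin))


def detect_node_peaks(
    profiles: Sequence[SliceProfile],
    prominence_frac: float = 0.05,
) -> List[int]:
    """Slice indices of the node peaks, ordered from the lower end.

    Operates on the major-axis-length sequence of the valid slices; a node is
    a local maximum (plateaus report their first index) whose topographic
    prominence exceeds ``prominence_frac`` times the median major-axis
    length. At least two peaks are required (nodes one and two).
    """
    valid = [p for p in profiles if p.valid]
    if len(valid) < 3:
        raise NodeDetectionError("need at least 3 valid slices for node detection")
    values = np.array([p.ellipse.major_axis_len for p in valid])
    indices = np.array([p.index for p in valid])
    threshold = prominence_frac * float(np.median(values))
    peaks = [k for k in _plateau_local_maxima(values) if _prominence(values, k) >= threshold]
    slice_ids = [int(indices[k]) for k in peaks]
    if len(slice_ids) < 2:
        raise NodeDetectionError(
            f"fewer than two nodes detected (found {len(slice_ids)})", sequence=values
        )
    return slice_ids


# ---------------------------------------------------------------------------
# Step 3: ROI extraction and diameter measurement
# ---------------------------------------------------------------------------


def extract_second_internode(
    stem: LabeledPointCloud,
    frame: AxisFrame,
    profiles: Sequence[SliceProfile],
    peaks: Sequence[int],
) -> LabeledPointCloud:
    """Points strictly between the first two node-peak slices (the ROI).

    The ROI spans from the upper edge of the first peak's slice to the lower
    edge of the second peak's slice, exclusive on both sides.
    """
    if len(peaks) < 2:
        raise MeasurementError("need at least two node peaks for the second internode")
    by_index = {p.index: p for p in profiles}
    lo = by_index[peaks[0]].t_hi
    hi = by_index[peaks[1]].t_lo
    t = frame.axial(stem.coords)
    mask = (t > lo) & (t < hi)
    if not mask.any():
        raise MeasurementError("second-internode ROI is empty")
    roi = stem.select(mask)
    roi.meta["roi_axial_interval"] = (float(lo), float(hi))
    return roi


def measure_stem_diameter(
    roi: LabeledPointCloud,
    frame: AxisFrame,
    n_sections: int = 3,
    section_thickness: Optional[float] = None,
) -> StemMeasurement:
    """Ellipse-fit ``n_sections`` thin cross-sections of the ROI.

    Sections are centred at the interior fractions 1/(n+1), ..., n/(n+1) of
    the ROI's axial extent (1/4, 1/2, 3/4 for the default three) with
    thickness ``ROI extent / 15`` unless overridden. The reported diameters
    are arithmetic means of the valid sections' axis lengths, in scene units.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if roi.n_points == 0:
        raise MeasurementError("ROI is empty")
    t = frame.axial(roi.coords)
    t_min, t_max = float(t.min()), float(t.max())
    extent = t_max - t_min
    if extent <= 0:
        raise MeasurementError("ROI has no axial extent")
    thick = extent / 15.0 if section_thickness is None else float(section_thickness)
    pts2d = frame.project(roi.coords)
    sections: List[Optional[EllipseFit]] = []
    majors, minors = [], []
    for i in range(n_sections):
        c = t_min + extent * (i + 1) / (n_sections + 1)
        mask = np.abs(t - c) <= thick / 2
        fit = None
        if int(mask.sum()) >= 6:
            try:
                fit = fit_ellipse(pts2d[mask])
            except (ValueError, MeasurementError):
                fit = None
        sections.append(fit)
        if fit is not None:
            majors.append(fit.major_axis_len)
            minors.append(fit.minor_axis_len)
    if not majors:
        raise MeasurementError("no valid cross-section in the ROI")
    return StemMeasurement(
        per_section=tuple(sections),
        major_units=float(np.mean(majors)),
        minor_units=float(np.mean(minors)),
    )


def scale_to_mm(length_units: float, checkerboard_span_units: float) -> float:
    """Checkerboard scale conversion ``S = 45 * L / Q`` (millimetres).

    ``L`` is an axis length in reconstruction units and ``Q`` the measured
    edge-to-edge span of the 45 mm checkerboard plate in the same units.
    """
    if checkerboard_span_units <= 0:
        raise ValueError("checkerboard span Q must be positive")
    if length_units < 0:
        raise ValueError("length must be non-negative")
    return CHECKERBOARD_SPAN_MM * length_units / checkerboard_span_units


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def measure_stem(
    cloud: LabeledPointCloud,
    q_units: Optional[float] = None,
    n_slices: int = 15,
    n_sections: int = 3,
    min_points: int = 30,
) -> Tuple[StemMeasurement, AxisFrame, List[SliceProfile], List[int]]:
    """Full pipeline on a labeled scene: axis, slices, peaks, ROI, diameters.

    ``cloud`` must carry labels; stem points (label 1) are measured and the
    background centroid orients the axis. When ``q_units`` is given, the
    measurement includes the millimetre conversion.
    """
    if cloud.labels is None:
        raise ValueError("measure_stem requires a labeled cloud")
    stem = cloud.select(cloud.labels == 1)
    bg = cloud.coords[cloud.labels == 0]
    ground_ref = bg.mean(axis=0) if len(bg) else None
    frame = principal_axis(stem, ground_reference=ground_ref)
    profiles = slice_profiles(stem, frame, n_slices=n_slices, min_points=min_points)
    peaks = detect_node_peaks(profiles)
    roi = extract_second_internode(stem, frame, profiles, peaks)
    measurement = measure_stem_diameter(roi, frame, n_sections=n_sections)
    if q_units is not None:
        measurement = measurement.with_scale(q_units)
    return measurement, frame, profiles, peaks
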