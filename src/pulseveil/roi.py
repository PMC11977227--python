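"""Region-of-interest masks from facial landmarks.

The concealment pipeline edits one of three regions per frame:

* ``full_frame`` — every pixel;
* ``facial_skin`` — the filled convex hull of all face landmarks with the
  eye and mouth polygons subtracted;
* ``forehead_cheeks`` — the union of three separate convex hulls (forehead,
  left cheek, right cheek), the strongest pulse-carrying patches.

Rasterization convention (fixed so tests can be bit-exact): coordinates are
0-based with the origin at the top-left corner; pixel (row i, col j) has its
center at (x, y) = (j + 0.5, i + 0.5); a pixel belongs to a polygon iff its
center is inside or on the boundary of the polygon's convex hull.

Landmark providers are pluggable: the synthetic provider returns the exact
generating geometry of a synthetic scene. An adapter for an external face-mesh
detector can implement the same two-method interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DetectionError, GeometryError
from .io_media import Frame

SEMANTIC_GROUPS = (
    "outer_face", "left_eye", "right_eye", "mouth",
    "forehead", "left_cheek", "right_cheek", "nose",
)

#: Pixel centers on or inside a hull facet within this distance count as inside.
_BOUNDARY_TOL = 1e-9


@dataclass
class LandmarkSet:
    """Facial landmarks for one frame.

    ``points`` is an (N, 2) float array of (x, y) pixel coordinates;
    ``groups`` maps semantic names to index lists into ``points``.
    """

    points: np.ndarray
    groups: Mapping[str, Sequence[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.groups = {k: list(v) for k, v in self.groups.items()}

    def group_points(self, name: str) -> np.ndarray:
        """The (x, y) coordinates of one semantic group."""
        idx = self.groups.get(name, [])
        return self.points[np.asarray(idx, dtype=int)] if idx else np.empty((0, 2))

    def translated(self, dx: float, dy: float) -> "LandmarkSet":
        return LandmarkSet(self.points + np.array([dx, dy]), self.groups)


@dataclass
class ROIMask:
    """A binary H×W mask selecting the pixels eligible for modification."""

    mask: np.ndarray
    roi_kind: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise GeometryError(f"mask must be 2-D, got shape {self.mask.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


class LandmarkProvider(Protocol):
    """Anything that yields a LandmarkSet per frame index."""

    def landmarks(self, frame: Frame, t: int) -> LandmarkSet: ...


class SyntheticLandmarkProvider:
    """Ground-truth landmarks of a synthetic scene; exact and deterministic."""

    def __init__(self, landmark_sets: Sequence[LandmarkSet]):
        self._sets = list(landmark_sets)

    def landmarks(self, frame: Frame, t: int) -> LandmarkSet:
        if not 0 <= t < len(self._sets):
            raise DetectionError(f"no landmarks for frame {t}")
        return self._sets[t]


def detect_landmarks(frame: Frame, provider: LandmarkProvider, t: int = 0) -> LandmarkSet:
    """Run a landmark provider on one frame; raises DetectionError (with the
    frame index) when no face is found."""
    try:
        return provider.landmarks(frame, t)
    except DetectionError:
        raise
    except Exception as exc:
        raise DetectionError(f"landmark detection failed at frame {t}: {exc}") from exc


def _fill_convex_hull(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the convex hull of ``points`` onto an (m, n) grid.

    Uses the hull's half-plane representation: a pixel center is inside iff it
    satisfies every facet inequality up to the boundary tolerance.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise GeometryError(f"need ≥3 points for a hull, got {pts.shape[0]}")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate hull (collinear points?): {exc}") from exc
    m, n = shape
    ys, xs = np.mgrid[0:m, 0:n]
    centers = np.stack([xs.ravel() + 0.5, ys.ravel() + 0.5], axis=1)
    # hull.equations rows are (a, b, c) with a·x + b·y + c ≤ 0 inside
    vals = centers @ hull.equations[:, :2].T + hull.equations[:, 2]
    inside = np.all(vals <= _BOUNDARY_TOL, axis=1)
    return inside.reshape(m, n)


def full_frame_mask(frame: Frame) -> ROIMask:
    """All-ones mask covering the whole frame."""
    return ROIMask(np.ones(frame.shape[:2], dtype=bool), "full_frame")


def facial_skin_mask(landmarks: LandmarkSet, shape: tuple[int, int]) -> ROIMask:
    """Face hull minus the eyes and mouth.

    The face region is the filled convex hull of *all* landmark points; the
    exclusions are the filled convex hulls of the left_eye, right_eye and
    mouth groups (hulls, not raw rings, so landmark ordering is irrelevant).
    """
    face = _fill_convex_hull(landmarks.points, shape)
    for name in ("left_eye", "right_eye", "mouth"):
        pts = landmarks.group_points(name)
        if pts.shape[0] >= 3:
            face &= ~_fill_convex_hull(pts, shape)
    return ROIMask(face, "facial_skin")


def forehead_cheeks_mask(landmarks: LandmarkSet, shape: tuple[int, int]) -> ROIMask:
    """Union of three separate convex hulls: forehead, left cheek, right cheek."""
    mask = np.zeros(shape, dtype=bool)
    for name in ("forehead", "left_cheek", "right_cheek"):
        pts = landmarks.group_points(name)
        if pts.shape[0] < 3:
            raise GeometryError(f"group {name!r} has {pts.shape[0]} points, need ≥3")
        mask |= _fill_convex_hull(pts, shape)
    return ROIMask(mask, "forehead_cheeks")


def save_mask_png(mask: ROIMask, path) -> None:
    """Export a mask as an inspectable 0/255 grayscale PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def make_mask(roi_kind: str, frame: Frame, landmarks: LandmarkSet | None) -> ROIMask:
    """Dispatch on roi_kind; landmarks are required unless roi_kind is full_frame."""
    if roi_kind == "full_frame":
        return full_frame_mask(frame)
    if landmarks is None:
        raise GeometryError(f"roi_kind {roi_kind!r} needs landmarks")
    if roi_kind == "facial_skin":
        return facial_skin_mask(landmarks, frame.shape[:2])
    if roi_kind == "forehead_cheeks":
        return forehead_cheeks_mask(landmarks, frame.shape[:2])
    raise GeometryError(f"unknown roi_kind {roi_kind!r}")
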