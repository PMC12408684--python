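"""Pinhole and stereo geometry for an active-stereo RGB-D rig.

Implements the four elementary operations a depth-to-color alignment needs:
depth from disparity (Z = f*B/d), pixel+depth deprojection into the camera
frame, rigid extrinsic transforms between the depth and color camera frames,
and projection back onto the image plane.  Chaining the last three maps each
depth pixel to its corresponding RGB pixel.

Conventions (fixed throughout the package): pixel origin at the top-left
corner, x = column, y = row; camera frame X right, Y down, Z along the
optical axis.  Depth frames store unsigned integer sensor units (millimeters
for the common 0.001 depth scale); all geometry operates in meters.
Pixel coordinates are continuous — rounding to the integer grid happens only
when indexing a depth frame (nearest neighbor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "GeometryError",
    "InvalidDisparityError",
    "InvalidDepthError",
    "BehindCameraError",
    "InvalidTransformError",
    "CameraIntrinsics",
    "StereoRig",
    "RigidTransform",
    "PixelCoord",
    "Point3D",
    "DepthFrame",
    "depth_from_disparity",
    "deproject",
    "project",
    "transform_point",
    "align_depth_pixel",
]


class GeometryError(ValueError):
    """Base class for geometry-domain errors."""


class InvalidDisparityError(GeometryError):
    """Disparity <= 0: point at infinity or a stereo-matching failure."""


class InvalidDepthError(GeometryError):
    """Depth <= 0 cannot be deprojected."""


class BehindCameraError(GeometryError):
    """A point with Z <= 0 has no image under the pinhole model."""


class InvalidTransformError(GeometryError):
    """Rotation matrix is not orthonormal with determinant +1."""


class PixelCoord(NamedTuple):
    """Continuous image coordinate: ``x`` = column, ``y`` = row (pixels)."""

    x: float
    y: float


class Point3D(NamedTuple):
    """Camera-frame point in meters: X right, Y down, Z forward."""

    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point, in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise GeometryError(f"focal lengths must be positive, got ({self.fx}, {self.fy})")
        if not (0 <= self.cx < self.width) or not (0 <= self.cy < self.height):
            raise GeometryError(
                f"principal point ({self.cx}, {self.cy}) outside {self.width}x{self.height} frame"
            )


@dataclass(frozen=True)
class StereoRig:
    """Rectified stereo pair: shared focal length ``f`` (px), baseline ``B`` (m)."""

    f: float
    B: float

    def __post_init__(self) -> None:
        if self.f <= 0 or self.B <= 0:
            raise GeometryError(f"focal length and baseline must be positive, got f={self.f}, B={self.B}")


_ROT_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion [R|T]: rotation (3x3, unitless) and translation (m)."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        T = np.asarray(self.T, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidTransformError(f"R must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ROT_TOL):
            raise InvalidTransformError("R is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise InvalidTransformError(f"det(R) = {np.linalg.det(R):.6f}, expected +1")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        """Inverse motion: (R^T, -R^T @ T)."""
        return RigidTransform(self.R.T, -self.R.T @ self.T)


@dataclass(frozen=True)
class DepthFrame:
    """A grid of raw depth readings.

    ``values`` holds non-negative integer sensor units (uint16-range); zero
    encodes "no measurement" (dropout).  ``depth_scale`` converts units to
    meters (0.001 for the millimeter convention of RealSense-class sensors).
    """

    values: np.ndarray
    depth_scale: float = 0.001

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise GeometryError(f"depth frame must be 2-D, got shape {v.shape}")
        if np.issubdtype(v.dtype, np.floating) or (v.size and v.min() < 0):
            raise GeometryError("depth frame values must be non-negative integers")
        if self.depth_scale <= 0:
            raise GeometryError(f"depth_scale must be positive, got {self.depth_scale}")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def depth_at(self, p: PixelCoord | tuple) -> float:
        """Depth in meters at a (continuous) pixel, nearest-neighbor lookup.

        Returns 0.0 for dropout pixels.
        """
        x, y = p
        col = int(round(x))
        row = int(round(y))
        if not (0 <= col < self.width and 0 <= row < self.height):
            raise GeometryError(f"pixel ({x}, {y}) outside {self.width}x{self.height} frame")
        return float(self.values[row, col]) * self.depth_scale


def depth_from_disparity(rig: StereoRig, d: float) -> float:
    """Depth Z = f*B/d of a matched point with disparity ``d`` (pixels).

    Strictly decreasing in ``d``; raises :class:`InvalidDisparityError` for
    d <= 0 (a point at infinity or a correlator failure).
    """
    if d <= 0:
        raise InvalidDisparityError(f"disparity must be positive, got {d}")
    return rig.f * rig.B / d


def deproject(p: PixelCoord | tuple, depth: float, K: CameraIntrinsics) -> Point3D:
    """Back-project pixel ``p`` with metric ``depth`` into the camera frame.

    X = (x - cx) * Z / fx,  Y = (y - cy) * Z / fy,  Z = depth.
    """
    if depth <= 0:
        raise InvalidDepthError(f"depth must be positive, got {depth}")
    x, y = p
    return Point3D((x - K.cx) * depth / K.fx, (y - K.cy) * depth / K.fy, depth)


def project(q: Point3D | tuple, K: CameraIntrinsics) -> PixelCoord:
    """Pinhole projection: x = fx*X/Z + cx, y = fy*Y/Z + cy."""
    X, Y, Z = q
    if Z <= 0:
        raise BehindCameraError(f"cannot project point with Z={Z} <= 0")
    return PixelCoord(K.fx * X / Z + K.cx, K.fy * Y / Z + K.cy)


def transform_point(q: Point3D | tuple, E: RigidTransform) -> Point3D:
    """Apply the rigid motion: q' = R @ q + T."""
    v = E.R @ np.asarray(q, dtype=float) + E.T
    return Point3D(*v)


def align_depth_pixel(
    p: PixelCoord | tuple,
    depth: float,
    K_depth: CameraIntrinsics,
    E: RigidTransform,
    K_rgb: CameraIntrinsics,
) -> PixelCoord:
    """Map a depth-image pixel to its corresponding RGB-image pixel.

    Composition deproject (depth intrinsics) -> extrinsic transform ->
    project (color intrinsics); this is the per-pixel depth-to-color
    alignment the sensor SDK performs.
    """
    return project(transform_point(deproject(p, depth, K_depth), E), K_rgb)
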