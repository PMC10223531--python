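"""Oriented-square ROI geometry from the four finger-web keypoints.

The dorsal ROI is constructed in a local coordinate frame anchored on the
keypoints: the X-axis runs along P1->P3, the origin P4 is the midpoint of
P1P3, |P1P3| is the unit length, and the Y-axis is perpendicular to P1P3,
positively oriented toward the half-plane containing P0 (the thumb-side web,
which sits wrist-ward of the P1P3 line, so the square lands on the dorsum).
The ROI center P5 is the origin displaced by 5/6 of the unit length along
+Y, and the square's side equals the unit length.

All geometry is done in image coordinates (y grows downward); no sign flip
is hidden from the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

ROI_CENTER_OFFSET = 5.0 / 6.0  # fraction of |P1P3| along +Y


@dataclass
class LocalFrame:
    origin: np.ndarray      # P4, midpoint of P1P3
    x_axis: np.ndarray      # unit vector along P1 -> P3
    y_axis: np.ndarray      # unit vector perpendicular, toward P0
    unit_length: float      # |P1P3| in pixels


@dataclass
class ROIBox:
    center: np.ndarray      # P5
    side: float
    corners: np.ndarray     # (4, 2): (-,-), (+,-), (+,+), (-,+) in the frame
    rotation: float         # degrees of the frame x-axis in image coords


def build_frame(keypoints: np.ndarray) -> LocalFrame:
    """Local frame from P0..P3; errors on degenerate configurations."""
    kps = np.asarray(keypoints, dtype=float)
    if kps.shape != (4, 2):
        raise ValueError(f"expected (4, 2) keypoints, got {kps.shape}")
    p0, p1, p3 = kps[0], kps[1], kps[3]
    d = p3 - p1
    length = float(np.linalg.norm(d))
    if length < 1e-9:
        raise ValueError("degenerate keypoints: P1 == P3")
    x_axis = d / length
    y_axis = np.array([-x_axis[1], x_axis[0]])
    origin = 0.5 * (p1 + p3)
    side = float(y_axis @ (p0 - origin))
    if abs(side) < 1e-9 * length:
        raise ValueError("degenerate keypoints: P0 collinear with P1P3")
    if side < 0:
        y_axis = -y_axis
    return LocalFrame(origin=origin, x_axis=x_axis, y_axis=y_axis,
                      unit_length=length)


def locate_roi(frame: LocalFrame) -> ROIBox:
    """Oriented square: center P5 = P4 + (5/6)|P1P3| along +Y, side |P1P3|."""
    s = frame.unit_length
    center = frame.origin + ROI_CENTER_OFFSET * s * frame.y_axis
    half = 0.5 * s
    corners = np.array([
        center - half * frame.x_axis - half * frame.y_axis,
        center + half * frame.x_axis - half * frame.y_axis,
        center + half * frame.x_axis + half * frame.y_axis,
        center - half * frame.x_axis + half * frame.y_axis,
    ])
    rotation = float(np.degrees(np.arctan2(frame.x_axis[1], frame.x_axis[0])))
    return ROIBox(center=center, side=s, corners=corners, rotation=rotation)


def extract_roi(keypoints: np.ndarray) -> ROIBox:
    """Convenience: build_frame then locate_roi."""
    return locate_roi(build_frame(keypoints))


def crop_roi(image: np.ndarray, box: ROIBox,
             out_size: int = 128) -> tuple[np.ndarray, float]:
    """Bilinearly resample the oriented square into an out_size square.

    Out-of-bounds samples are zero-filled; the returned coverage fraction is
    the share of sample points that fell inside the image.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    cx, cy = box.center
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError(f"ROI center {box.center} outside image {img.shape}")
    if out_size < 8:
        raise ValueError("out_size must be >= 8")
    x_axis = (box.corners[1] - box.corners[0]) / box.side
    y_axis = (box.corners[3] - box.corners[0]) / box.side
    t = (np.arange(out_size) + 0.5) / out_size * box.side
    P = (box.corners[0][None, None, :]
         + t[None, :, None] * x_axis[None, None, :]
         + t[:, None, None] * y_axis[None, None, :])
    xs, ys = P[..., 0], P[..., 1]
    out = map_coordinates(img, [ys, xs], order=1, mode="constant", cval=0.0)
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    return out, float(inside.mean())
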