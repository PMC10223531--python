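"""Synthetic near-infrared dorsal-hand image generator with exact keypoints.

A hand is modelled as one ellipse (the palm/dorsum) plus five capsules
(fingers) whose roots sit just above the palm boundary.  Under NIR
illumination the hand scatters light back (bright) while the background and
the hemoglobin-filled veins absorb it (dark), so rendering uses a bright hand
on a darker, mode-dependent background with dark curvilinear vein strokes on
the dorsum.

The four finger-web valley keypoints are not annotated but *constructed*:
each is the apex of the wedge between two adjacent finger capsules, i.e. the
intersection of their facing boundary lines.  Because every transform applied
to the geometry (pitch foreshortening, mirroring for left hands, global
rotation) is applied to the skeleton before the valleys are solved, the
returned keypoints are exact for the rendered silhouette.

Keypoint order is P0..P3 from the thumb-index web to the ring-little web.
Coordinates are 0-based pixel centers, (x = column, y = row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

BACKGROUND_MODES = ("clean", "glare", "clutter")

# canonical skeleton, thumb..little; fractions of the palm semi-axes
# Finger roots sit on a shallow arc above the palm ellipse; a "knuckle bar"
# capsule just below the root line joins the finger bases to the palm, so the
# web valleys (wedge apexes a few px above the root line) stay on the
# silhouette boundary.
_ROOT_X = np.array([-0.62, -0.31, 0.0, 0.31, 0.62])
_BASE_ANGLES = np.array([-34.0, -16.0, -2.0, 12.0, 25.0])  # deg from vertical
_ARC_FLATTEN = 0.10   # root arc: y = -b * (0.97 - _ARC_FLATTEN * fx^2)
_BAR_RADIUS = 0.12    # knuckle-bar radius / offset, fraction of the b axis


class InvalidHandError(ValueError):
    """Raised when hand parameters produce a geometrically invalid hand."""


@dataclass
class HandParams:
    """Full geometric and photometric description of one rendered hand."""

    palm_center: tuple[float, float]
    palm_radii: tuple[float, float]
    global_rotation: float           # degrees, about palm_center
    finger_angles: tuple[float, ...]   # 5 values, deg from vertical, thumb..little
    finger_lengths: tuple[float, ...]  # px
    finger_widths: tuple[float, ...]   # px (full width)
    foreshorten: float = 1.0         # vertical scale in (0, 1], pitch emulation
    occlusion_fraction: float = 0.0  # in [0, 0.3]
    background_mode: str = "clean"
    vein_count: int = 6
    noise_sigma: float = 5.0
    left_hand: bool = False
    image_size: tuple[int, int] = (128, 128)   # (H, W)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.foreshorten <= 1.0):
            raise InvalidHandError(f"foreshorten {self.foreshorten} outside (0, 1]")
        if not (0.0 <= self.occlusion_fraction <= 0.3):
            raise InvalidHandError("occlusion_fraction outside [0, 0.3]")
        if self.background_mode not in BACKGROUND_MODES:
            raise InvalidHandError(f"unknown background_mode {self.background_mode!r}")
        for name in ("finger_angles", "finger_lengths", "finger_widths"):
            if len(getattr(self, name)) != 5:
                raise InvalidHandError(f"{name} must have 5 entries")


@dataclass
class AnnotatedSample:
    image: np.ndarray                  # uint8 (H, W)
    keypoints: np.ndarray              # float (4, 2), (x, y), P0..P3 thumb->little
    params: HandParams
    hand_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# skeleton geometry


def _rot_mat(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def _skeleton(params: HandParams):
    """Finger roots, directions, knuckle bar and palm axes in image coords."""
    a, b = params.palm_radii
    f = params.foreshorten
    roots = np.empty((5, 2))
    roots[:, 0] = _ROOT_X * a
    roots[:, 1] = -b * (0.97 - _ARC_FLATTEN * _ROOT_X ** 2)
    ang = np.deg2rad(np.asarray(params.finger_angles))
    dirs = np.stack([np.sin(ang), -np.cos(ang)], axis=1)
    tips = roots + dirs * np.asarray(params.finger_lengths)[:, None]
    rbar = _BAR_RADIUS * b
    bar = np.stack([roots[0], roots[4]]) + np.array([0.0, rbar])
    # shoulders: finger-half-width capsules running from just below the outer
    # finger roots down to the palm flanks, so the outer fingers blend into
    # the palm without leaving deep spurious notches in the silhouette
    widths = np.asarray(params.finger_widths)
    lengths0 = np.asarray(params.finger_lengths)
    phi = np.deg2rad(65.0)
    shoulders = np.array([
        [roots[0] - 0.15 * lengths0[0] * dirs[0],
         [-a * np.sin(phi), -b * np.cos(phi)]],
        [roots[4] - 0.15 * lengths0[4] * dirs[4],
         [a * np.sin(phi), -b * np.cos(phi)]],
    ])
    shoulder_radii = np.array([0.5 * widths[0], 0.5 * widths[4]])
    # pitch foreshortening: compress y about the palm center
    for arr in (roots, tips, bar):
        arr[:, 1] *= f
    shoulders[:, :, 1] *= f
    rbar *= f
    if params.left_hand:
        for arr in (roots, tips, bar):
            arr[:, 0] *= -1.0
        shoulders[:, :, 0] *= -1.0
    R = _rot_mat(params.global_rotation)
    roots = roots @ R.T
    tips = tips @ R.T
    bar = bar @ R.T
    shoulders = shoulders @ R.T
    seg = tips - roots
    lengths = np.linalg.norm(seg, axis=1)
    dirs = seg / lengths[:, None]
    center = np.asarray(params.palm_center)
    return roots + center, dirs, lengths, tips + center, (a, b * f), \
        (bar + center, rbar, shoulders + center, shoulder_radii)


def _valley(rA, uA, wA, rB, uB, wB):
    """Apex of the wedge between two adjacent capsules.

    Returns (point, tA, tB): the intersection of the two facing boundary
    lines and the arc-length parameters along each finger axis.
    """
    def inner_normal(u, toward):
        n = np.array([-u[1], u[0]])
        return n if float(n @ toward) > 0 else -n

    nA = inner_normal(uA, rB - rA)
    nB = inner_normal(uB, rA - rB)
    pA = rA + 0.5 * wA * nA
    pB = rB + 0.5 * wB * nB
    M = np.stack([uA, -uB], axis=1)
    det = np.linalg.det(M)
    if abs(det) < 1e-9:
        return None, 0.0, 0.0
    t = np.linalg.solve(M, pB - pA)
    return pA + t[0] * uA, float(t[0]), float(t[1])


def _ellipse_val(pt, center, axes, rotation_deg):
    d = (np.asarray(pt) - np.asarray(center)) @ _rot_mat(rotation_deg)
    return (d[0] / axes[0]) ** 2 + (d[1] / axes[1]) ** 2


def _seg_dist(p, r, t):
    """Distance from point(s) p to segment r-t; p may be (..., 2)."""
    seg = t - r
    L2 = float(seg @ seg)
    w = np.clip(((p - r) @ seg) / max(L2, 1e-12), 0.0, 1.0)
    proj = r + w[..., None] * seg
    return np.linalg.norm(p - proj, axis=-1)


def compute_keypoints(params: HandParams) -> np.ndarray:
    """Analytic web-valley keypoints P0..P3; raises InvalidHandError when the
    finger configuration does not produce four valid valleys."""
    params.validate()
    roots, dirs, lengths, tips, axes, (bar, rbar, shoulders, shrad) = _skeleton(params)
    widths = np.asarray(params.finger_widths)
    h, w = params.image_size
    kps = np.empty((4, 2))
    for i in range(4):
        v, tA, tB = _valley(roots[i], dirs[i], widths[i],
                            roots[i + 1], dirs[i + 1], widths[i + 1])
        if v is None:
            raise InvalidHandError(f"valley {i}: fingers nearly parallel")
        for t, L, which in ((tA, lengths[i], i), (tB, lengths[i + 1], i + 1)):
            if not (1.5 < t < 0.6 * L):
                raise InvalidHandError(f"valley {i}: apex off finger {which} shaft")
        if _ellipse_val(v, params.palm_center, axes, params.global_rotation) < 1.05:
            raise InvalidHandError(f"valley {i}: apex buried in the palm")
        if _seg_dist(v, bar[0], bar[1]) < rbar + 1.0:
            raise InvalidHandError(f"valley {i}: apex buried in the knuckle bar")
        for sh, r_sh in zip(shoulders, shrad):
            if _seg_dist(v, sh[0], sh[1]) < r_sh + 0.75:
                raise InvalidHandError(f"valley {i}: apex buried in a shoulder")
        for j in range(5):
            if j in (i, i + 1):
                continue
            if _seg_dist(v, roots[j], tips[j]) < 0.5 * widths[j] + 1.5:
                raise InvalidHandError(f"valley {i}: apex inside finger {j}")
        if not (2.0 <= v[0] <= w - 3.0 and 2.0 <= v[1] <= h - 3.0):
            raise InvalidHandError(f"valley {i}: outside image")
        kps[i] = v
    # non-adjacent fingers must not intersect
    for i in range(5):
        for j in range(i + 2, 5):
            gap = _min_seg_gap(roots[i], tips[i], roots[j], tips[j])
            if gap < 0.5 * (widths[i] + widths[j]) + 1.0:
                raise InvalidHandError(f"fingers {i} and {j} intersect")
    # fingertips (plus cap radius) must stay inside the frame
    margin = widths / 2 + 2.0
    if (tips[:, 0] < margin).any() or (tips[:, 0] > w - 1 - margin).any() \
            or (tips[:, 1] < margin).any() or (tips[:, 1] > h - 1 - margin).any():
        raise InvalidHandError("fingertip outside image")
    return kps


def _min_seg_gap(a0, a1, b0, b1, n: int = 12) -> float:
    ta = np.linspace(0.0, 1.0, n)
    pa = a0 + ta[:, None] * (a1 - a0)
    return min(float(_seg_dist(pa, b0, b1).min()),
               float(_seg_dist(np.stack([b0, b1]), a0, a1).min()))


# ---------------------------------------------------------------------------
# rasterization


def _field_at(X: np.ndarray, Y: np.ndarray, params: HandParams) -> np.ndarray:
    """Signed silhouette field (px, > 0 inside) sampled at coordinate grids.

    Capsule terms are exact signed distances; the palm-ellipse term is a
    first-order approximation, adequate for silhouette compositing.
    """
    roots, dirs, lengths, tips, axes, (bar, rbar, shoulders, shrad) = _skeleton(params)
    pts = np.stack([X, Y], axis=-1)
    cx, cy = params.palm_center
    R = _rot_mat(params.global_rotation)
    dx, dy = X - cx, Y - cy
    xe = R[0, 0] * dx + R[1, 0] * dy
    ye = R[0, 1] * dx + R[1, 1] * dy
    val = np.sqrt((xe / axes[0]) ** 2 + (ye / axes[1]) ** 2)
    field = (1.0 - val) * min(axes)
    field = np.maximum(field, rbar - _seg_dist(pts, bar[0], bar[1]))
    for sh, r_sh in zip(shoulders, shrad):
        field = np.maximum(field, r_sh - _seg_dist(pts, sh[0], sh[1]))
    for i in range(5):
        field = np.maximum(
            field, 0.5 * params.finger_widths[i] - _seg_dist(pts, roots[i], tips[i]))
    return field


def hand_field(params: HandParams) -> np.ndarray:
    """Signed silhouette field on the full image grid."""
    h, w = params.image_size
    Y, X = np.mgrid[0:h, 0:w].astype(np.float64)
    return _field_at(X, Y, params)


def hand_mask(params: HandParams) -> np.ndarray:
    """Boolean silhouette (palm ellipse + knuckle bar + finger capsules)."""
    return hand_field(params) >= 0.0


def boundary_distance(params: HandParams, point, radius: float = 4.0,
                      step: float = 0.25) -> float:
    """Distance (px) from a point to the subpixel silhouette boundary.

    Evaluates the signed field on a locally supersampled grid and measures
    the distance to its zero contour, which resolves the narrow finger-web
    crack that a 1-px raster cannot.
    """
    from skimage import measure

    point = np.asarray(point, dtype=float)
    xs = np.arange(point[0] - radius, point[0] + radius + 1e-9, step)
    ys = np.arange(point[1] - radius, point[1] + radius + 1e-9, step)
    X, Y = np.meshgrid(xs, ys)
    f = _field_at(X, Y, params)
    contours = measure.find_contours(f, 0.0)
    if not contours:
        return float("inf")
    allp = np.vstack(contours)
    pxy = np.stack([xs[0] + allp[:, 1] * step, ys[0] + allp[:, 0] * step], axis=1)
    return float(np.min(np.linalg.norm(pxy - point, axis=1)))


def _palm_interior(params: HandParams, shrink: float = 0.88) -> np.ndarray:
    h, w = params.image_size
    Y, X = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = params.palm_center
    R = _rot_mat(params.global_rotation)
    a, b = params.palm_radii[0], params.palm_radii[1] * params.foreshorten
    dx, dy = X - cx, Y - cy
    xe = R[0, 0] * dx + R[1, 0] * dy
    ye = R[0, 1] * dx + R[1, 1] * dy
    return (xe / (a * shrink)) ** 2 + (ye / (b * shrink)) ** 2 <= 1.0


def _render_veins(params: HandParams, rng: np.random.Generator) -> np.ndarray:
    """Dark curvilinear strokes: smoothed random walks inside the dorsum."""
    h, w = params.image_size
    canvas = np.zeros((h, w))
    interior = _palm_interior(params)
    ys, xs = np.nonzero(interior)
    if len(xs) == 0 or params.vein_count == 0:
        return canvas
    a, bf = params.palm_radii[0], params.palm_radii[1] * params.foreshorten
    n_steps = int(2.2 * bf)
    for _ in range(params.vein_count):
        k = rng.integers(0, len(xs))
        p = np.array([xs[k], ys[k]], dtype=float)
        ang = rng.uniform(0, 2 * np.pi)
        stroke = np.zeros((h, w))
        for _ in range(n_steps):
            xi, yi = int(round(p[0])), int(round(p[1]))
            if not (0 <= xi < w and 0 <= yi < h) or not interior[yi, xi]:
                break
            stroke[yi, xi] = 1.0
            ang += rng.normal(0.0, 0.35)
            p += 1.6 * np.array([np.cos(ang), np.sin(ang)])
        sigma = rng.uniform(0.7, 1.5)
        stroke = gaussian_filter(stroke, sigma)
        m = stroke.max()
        if m > 0:
            canvas += (stroke / m) * rng.uniform(20.0, 60.0)
    return np.minimum(canvas, 70.0)


def _render_background(params: HandParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_size
    base = rng.uniform(10.0, 60.0)
    bg = base + gaussian_filter(rng.normal(0.0, 1.0, (h, w)), max(h, w) / 10) * 12.0
    mode = params.background_mode
    if mode == "glare":
        # fluorescent-lamp style bright blobs
        for _ in range(rng.integers(1, 3)):
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            sx, sy = rng.uniform(w / 8, w / 3), rng.uniform(h / 8, h / 3)
            Y, X = np.mgrid[0:h, 0:w]
            blob = np.exp(-(((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2))
            bg += rng.uniform(60.0, 150.0) * blob
    elif mode == "clutter":
        # clothing patterns, desk objects: hard-edged shapes of varied intensity
        for _ in range(rng.integers(7, 15)):
            val = rng.uniform(30.0, 170.0)
            if rng.random() < 0.5:
                x0, y0 = rng.integers(0, w), rng.integers(0, h)
                dw, dh = rng.integers(w // 10, w // 2), rng.integers(h // 10, h // 2)
                bg[y0:y0 + dh, x0:x0 + dw] = val
            else:
                cx, cy = rng.uniform(0, w), rng.uniform(0, h)
                rx, ry = rng.uniform(w / 16, w / 4), rng.uniform(h / 16, h / 4)
                Y, X = np.mgrid[0:h, 0:w]
                bg[((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0] = val
    return bg


def _apply_occlusion(img: np.ndarray, mask: np.ndarray, params: HandParams,
                     rng: np.random.Generator) -> None:
    """Dark polygon covering about occlusion_fraction of the hand (<= 0.3)."""
    frac = params.occlusion_fraction
    if frac <= 0.0:
        return
    h, w = img.shape
    ys, xs = np.nonzero(mask)
    hand_area = len(xs)
    if hand_area == 0:
        return
    k = rng.integers(0, len(xs))
    cx, cy = float(xs[k]), float(ys[k])
    ang = rng.uniform(0, np.pi)
    half = np.sqrt(frac * hand_area) / 2.0 * 1.2
    Y, X = np.mgrid[0:h, 0:w]
    dx, dy = X - cx, Y - cy
    u = dx * np.cos(ang) + dy * np.sin(ang)
    v = -dx * np.sin(ang) + dy * np.cos(ang)
    for _ in range(8):
        occ = (np.abs(u) <= half) & (np.abs(v) <= half * rng.uniform(0.5, 1.0))
        got = (occ & mask).sum() / hand_area
        if got <= frac or half < 2.0:
            break
        half *= 0.85
    img[occ] = rng.uniform(15.0, 45.0)


def render_hand(params: HandParams, keep_mask: bool = False) -> AnnotatedSample:
    """Render one annotated sample; deterministic given params (incl. seed).

    The hand's intensity canvas (shading, low-frequency texture, veins) is
    generated in a canonical hand frame and warped with the hand, so rotating
    or pitching the hand rotates its texture and vein pattern with it; the
    background stays in the scene frame.
    """
    import dataclasses

    kps = compute_keypoints(params)  # validates geometry
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    field = hand_field(params)
    mask = field >= 0.0
    alpha = np.clip(field + 0.5, 0.0, 1.0)  # antialiased silhouette edge
    img = _render_background(params, rng)
    # bright hand with mild shading and low-frequency texture, hand frame
    canon = dataclasses.replace(params, global_rotation=0.0, foreshorten=1.0)
    base = rng.uniform(160.0, 215.0)
    gdir = rng.uniform(0, 2 * np.pi)
    Y, X = np.mgrid[0:h, 0:w]
    grad = ((X * np.cos(gdir) + Y * np.sin(gdir)) / max(h, w) - 0.5) * rng.uniform(8.0, 30.0)
    tex = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), max(h, w) / 16) * 20.0
    canvas = np.clip(base + grad + tex, 140.0, 235.0) - _render_veins(canon, rng)
    # warp the canonical canvas with the hand: invert rotation, then pitch
    cx, cy = params.palm_center
    R = _rot_mat(params.global_rotation)
    dx, dy = X - cx, Y - cy
    xc = cx + R[0, 0] * dx + R[1, 0] * dy
    yc = cy + (R[0, 1] * dx + R[1, 1] * dy) / params.foreshorten
    from scipy.ndimage import map_coordinates
    hand = map_coordinates(canvas, [yc, xc], order=1, mode="nearest")
    img = img * (1.0 - alpha) + hand * alpha
    _apply_occlusion(img, mask, params, rng)
    img += rng.normal(0.0, params.noise_sigma, (h, w))
    img = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedSample(image=img, keypoints=kps, params=params,
                           hand_mask=mask if keep_mask else None)


# ---------------------------------------------------------------------------
# parameter sampling and dataset creation


DEFAULT_DISTRIBUTION: dict = {
    "palm_center_x": (0.42, 0.58),     # fraction of width
    "palm_center_y": (0.55, 0.68),     # fraction of height
    "palm_a": (0.13, 0.165),            # fraction of min(H, W)
    "palm_b": (0.19, 0.245),
    "rotation": (-35.0, 35.0),
    "angle_jitter": (4.0, 3.0, 3.0, 3.0, 4.0),
    "length": ((0.13, 0.17), (0.25, 0.30), (0.28, 0.33), (0.26, 0.31), (0.20, 0.25)),
    "width": ((0.066, 0.078), (0.054, 0.066), (0.056, 0.068), (0.054, 0.066),
              (0.044, 0.054)),
    "foreshorten": (0.80, 1.0),
    "occlusion_prob": 0.3,
    "occlusion_fraction": (0.05, 0.3),
    "background_modes": BACKGROUND_MODES,
    "vein_count": (4, 9),
    "noise_sigma": (3.0, 7.0),
    "left_hand_prob": 0.5,
}

MAX_ATTEMPTS = 200


def sample_params(rng: np.random.Generator, image_size: tuple[int, int] = (128, 128),
                  distribution: dict | None = None,
                  background_mode: str | None = None) -> HandParams:
    """Draw one valid HandParams from the study-condition distribution,
    rejecting and resampling geometrically invalid hands."""
    dist = dict(DEFAULT_DISTRIBUTION)
    if distribution:
        dist.update(distribution)
    h, w = image_size
    s = min(h, w)
    for _ in range(MAX_ATTEMPTS):
        angles = _BASE_ANGLES + rng.normal(0.0, np.asarray(dist["angle_jitter"]))
        mode = background_mode or str(rng.choice(list(dist["background_modes"])))
        occ = 0.0
        if rng.random() < dist["occlusion_prob"]:
            occ = rng.uniform(*dist["occlusion_fraction"])
        params = HandParams(
            palm_center=(rng.uniform(*dist["palm_center_x"]) * w,
                         rng.uniform(*dist["palm_center_y"]) * h),
            palm_radii=(rng.uniform(*dist["palm_a"]) * s,
                        rng.uniform(*dist["palm_b"]) * s),
            global_rotation=rng.uniform(*dist["rotation"]),
            finger_angles=tuple(angles),
            finger_lengths=tuple(rng.uniform(lo, hi) * s for lo, hi in dist["length"]),
            finger_widths=tuple(rng.uniform(lo, hi) * s for lo, hi in dist["width"]),
            foreshorten=rng.uniform(*dist["foreshorten"]),
            occlusion_fraction=occ,
            background_mode=mode,
            vein_count=int(rng.integers(*dist["vein_count"])),
            noise_sigma=rng.uniform(*dist["noise_sigma"]),
            left_hand=bool(rng.random() < dist["left_hand_prob"]),
            image_size=image_size,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        try:
            compute_keypoints(params)
        except InvalidHandError:
            continue
        return params
    raise InvalidHandError(f"no valid hand found in {MAX_ATTEMPTS} attempts")


def make_samples(n: int, seed: int, image_size: tuple[int, int] = (128, 128),
                 distribution: dict | None = None,
                 background_mode: str | None = None,
                 keep_mask: bool = False) -> list[AnnotatedSample]:
    """Generate n annotated samples in memory; reproducible from seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [render_hand(sample_params(rng, image_size, distribution, background_mode),
                        keep_mask=keep_mask) for _ in range(n)]


def labelme_dict(sample: AnnotatedSample, image_path: str) -> dict:
    h, w = sample.image.shape
    return {
        "version": "5.0.0",
        "flags": {},
        "imagePath": image_path,
        "imageHeight": int(h),
        "imageWidth": int(w),
        "imageData": None,
        "shapes": [
            {"label": f"P{i}", "points": [[float(x), float(y)]],
             "shape_type": "point", "group_id": None, "flags": {}}
            for i, (x, y) in enumerate(sample.keypoints)
        ],
    }


def read_labelme(path) -> np.ndarray:
    """Read P0..P3 point annotations from a Labelme-style JSON file."""
    with open(path) as fh:
        data = json.load(fh)
    pts = {s["label"]: s["points"][0] for s in data["shapes"]
           if s.get("shape_type") == "point"}
    return np.array([pts[f"P{i}"] for i in range(4)], dtype=float)


def make_dataset(n: int, seed: int, out_dir,
                 image_size: tuple[int, int] = (128, 128),
                 distribution: dict | None = None,
                 background_mode: str | None = None) -> pd.DataFrame:
    """Write n PNG + Labelme-JSON pairs plus a manifest.csv; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = make_samples(n, seed, image_size, distribution, background_mode)
    rows = []
    for i, s in enumerate(samples):
        img_name, json_name = f"hand_{i:05d}.png", f"hand_{i:05d}.json"
        Image.fromarray(s.image, mode="L").save(out / img_name)
        with open(out / json_name, "w") as fh:
            json.dump(labelme_dict(s, img_name), fh, indent=1)
        rows.append({"image_path": img_name, "json_path": json_name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_sample(root, image_path: str, json_path: str) -> AnnotatedSample:
    root = Path(root)
    img = np.asarray(Image.open(root / image_path).convert("L"))
    kps = read_labelme(root / json_path)
    params = HandParams(palm_center=(0, 0), palm_radii=(1, 1), global_rotation=0,
                        finger_angles=(0,) * 5, finger_lengths=(1,) * 5,
                        finger_widths=(1,) * 5, image_size=img.shape)
    return AnnotatedSample(image=img, keypoints=kps, params=params)
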