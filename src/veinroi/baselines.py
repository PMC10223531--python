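"""Classical image-processing baselines for finger-valley keypoint detection.

Both methods binarize the image with Otsu's global threshold, keep the
largest connected component as the hand candidate, and trace its outer
contour.  The convexity-defect method takes the four deepest defect far
points of the contour's convex hull; the centroid-distance method takes the
four deepest smoothed local minima of the contour-to-centroid distance
profile.  Both are deterministic, and both are expected to break down on
cluttered backgrounds where global thresholding merges the hand with
background structure — which is the contrast they are meant to exhibit
against the learned detector.

Outputs are ordered along the contour; they carry no left/right-hand
semantics, so evaluation matches them to labelled keypoints by proximity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.filters import threshold_otsu

# defect depth threshold, relative to the hand bounding-box diagonal
DEFECT_PROMINENCE = 0.05
# smoothing window for the centroid-distance profile, fraction of contour length
PROFILE_SMOOTH = 0.02
# plausible hand area as a fraction of the image (an open hand fills well
# under half the frame; a near-full foreground is a thresholding artifact)
AREA_BOUNDS = (0.04, 0.6)


@dataclass
class BaselineResult:
    keypoints: np.ndarray | None   # (4, 2) (x, y) or None
    reason: str = "ok"

    @property
    def ok(self) -> bool:
        return self.keypoints is not None


def binarize_hand(image: np.ndarray) -> np.ndarray | None:
    """Otsu threshold + largest connected component; None when no plausible
    hand-sized foreground exists."""
    img = np.asarray(image)
    if np.ptp(img) == 0:
        return None
    try:
        t = threshold_otsu(img)
    except ValueError:
        return None
    mask = img > t
    if not mask.any():
        return None
    lab = measure.label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    comp = lab == sizes.argmax()
    frac = comp.mean()
    if not (AREA_BOUNDS[0] <= frac <= AREA_BOUNDS[1]):
        return None
    return comp


def _outer_contour(mask: np.ndarray) -> np.ndarray | None:
    """Longest closed 0.5-level contour, as (n, 2) (x, y) points."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    c = max(contours, key=len)
    if len(c) < 20:
        return None
    return c[:, ::-1]  # (row, col) -> (x, y)


def convexity_defect_keypoints(image: np.ndarray) -> BaselineResult:
    """Four deepest convexity-defect far points of the hand contour."""
    mask = binarize_hand(image)
    if mask is None:
        return BaselineResult(None, "no-contour")
    contour = _outer_contour(mask)
    if contour is None:
        return BaselineResult(None, "no-contour")
    try:
        hull = ConvexHull(contour)
    except Exception:
        return BaselineResult(None, "no-contour")
    hull_idx = np.sort(hull.vertices)
    ys, xs = np.nonzero(mask)
    diag = np.hypot(xs.max() - xs.min(), ys.max() - ys.min())
    defects = []  # (depth, contour index)
    n_hull = len(hull_idx)
    for k in range(n_hull):
        i0, i1 = hull_idx[k], hull_idx[(k + 1) % n_hull]
        seg = contour[i1] - contour[i0]
        norm = np.linalg.norm(seg)
        if norm < 1e-9:
            continue
        if i1 > i0:
            between = np.arange(i0, i1 + 1)
        else:  # wrap around the closed contour
            between = np.concatenate([np.arange(i0, len(contour)),
                                      np.arange(0, i1 + 1)])
        pts = contour[between]
        # perpendicular distance to the hull edge
        u = seg / norm
        rel = pts - contour[i0]
        d = np.abs(u[0] * rel[:, 1] - u[1] * rel[:, 0])
        j = int(np.argmax(d))
        if d[j] >= DEFECT_PROMINENCE * diag:
            defects.append((float(d[j]), int(between[j])))
    if len(defects) < 4:
        return BaselineResult(None, "too-few-defects")
    defects.sort(reverse=True)
    chosen = sorted(idx for _, idx in defects[:4])
    return BaselineResult(contour[chosen], "ok")


def _circular_peaks(signal: np.ndarray, prominence: float) -> np.ndarray:
    n = len(signal)
    ext = np.concatenate([signal, signal[: n // 2]])
    peaks, _ = find_peaks(ext, prominence=prominence)
    return np.unique(peaks % n)


def centroid_distance_keypoints(image: np.ndarray) -> BaselineResult:
    """Valley minima of the contour-to-centroid distance profile.

    The smoothed profile has a prominent maximum per fingertip; the four
    valleys are the profile minima inside the four shortest gaps between
    consecutive fingertip maxima (the wrist-side gap is the long one).  When
    no five-fingertip structure is found, falls back to the four smallest
    prominent minima.
    """
    mask = binarize_hand(image)
    if mask is None:
        return BaselineResult(None, "no-contour")
    contour = _outer_contour(mask)
    if contour is None:
        return BaselineResult(None, "no-contour")
    ys, xs = np.nonzero(mask)
    centroid = np.array([xs.mean(), ys.mean()])
    prof = np.linalg.norm(contour - centroid, axis=1)
    win = max(3, int(PROFILE_SMOOTH * len(prof)))
    smooth = uniform_filter1d(prof, win, mode="wrap")
    n = len(smooth)
    tips = _circular_peaks(smooth, 0.05 * smooth.max())
    if len(tips) < 5:
        return BaselineResult(None, "too-few-minima")
    # the five fingertip maxima are consecutive along the contour: pick the
    # circular window of five maxima with the smallest span (the finger fan),
    # excluding wrist-side maxima, then take the deepest point in each gap
    spans = [(int((tips[(k + 4) % len(tips)] - tips[k]) % n), k)
             for k in range(len(tips))]
    _, k0 = min(spans)
    fan = [int(tips[(k0 + j) % len(tips)]) for j in range(5)]
    chosen = []
    for i0, i1 in zip(fan[:4], fan[1:]):
        idx = np.arange(i0, i0 + ((i1 - i0) % n)) % n
        chosen.append(int(idx[np.argmin(smooth[idx])]))
    return BaselineResult(contour[np.sort(chosen)], "ok")


def match_to_labels(pred: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Permute predicted points to the labelled P0..P3 order by proximity
    (evaluation-time only; the baselines cannot know handedness)."""
    from scipy.optimize import linear_sum_assignment

    cost = np.linalg.norm(pred[:, None, :] - labels[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    out = np.empty_like(pred)
    out[cols] = pred[rows]
    return out
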