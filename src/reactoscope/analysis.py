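"""Online image analysis: segmentation, tracking, quantification, masks.

Segmentation is Otsu thresholding on the inverted brightfield image followed
by hole filling and small-object removal — adequate for the synthetic scenes
this package renders (well-separated ellipses at modest density). Tracking is
globally-minimal centroid assignment (rectangular assignment on the distance
matrix) with a displacement gate. Per-cell fluorescence is the mean pixel
intensity over the cell's segmented mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, erosion

__all__ = [
    "SegmentationResult",
    "TrackedCell",
    "Tracker",
    "segment",
    "quantify",
    "link_tracks",
    "erode_mask",
    "snr",
]


@dataclass
class SegmentationResult:
    """Labelled segmentation of one frame.

    ``label_image`` holds contiguous positive integer labels (0 = background);
    ``centroids[label]`` is the (row, col) centroid and ``areas[label]`` the
    area in px^2.
    """

    label_image: np.ndarray
    centroids: dict[int, tuple] = field(default_factory=dict)
    areas: dict[int, float] = field(default_factory=dict)

    @property
    def labels(self) -> list[int]:
        return sorted(self.centroids)

    def mask_of(self, label: int) -> np.ndarray:
        return self.label_image == label


@dataclass
class TrackedCell:
    """Observed cell track across frames."""

    track_id: int
    frames: list = field(default_factory=list)  # frame indices present
    centroids: dict = field(default_factory=dict)  # frame -> (row, col)
    labels: dict = field(default_factory=dict)  # frame -> segmentation label
    fluorescence: dict = field(default_factory=dict)  # frame -> {channel: mean}
    group: int | None = None
    targeted: bool = False

    def last_centroid(self) -> tuple:
        return self.centroids[self.frames[-1]]

    def present_at(self, frame: int) -> bool:
        return frame in self.centroids


def segment(image: np.ndarray, min_area: float = 20.0,
            smooth_sigma: float = 1.5) -> SegmentationResult:
    """Segment a brightfield frame by Otsu threshold on the inverted image.

    A light Gaussian smoothing suppresses shot-noise speckle before
    thresholding; components below ``min_area`` px^2 are dropped.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment expects a 2-D image")
    if smooth_sigma > 0:
        image = ndimage.gaussian_filter(image, smooth_sigma)
    inverted = image.max() - image
    if np.allclose(inverted, inverted.flat[0]):
        return SegmentationResult(np.zeros(image.shape, dtype=np.int32))
    thr = threshold_otsu(inverted)
    fg = inverted > thr
    fg = ndimage.binary_fill_holes(fg)
    lab, _ = ndimage.label(fg)
    result = SegmentationResult(np.zeros(image.shape, dtype=np.int32))
    next_label = 1
    for prop in regionprops(lab):
        if prop.area < min_area:
            continue
        result.label_image[lab == prop.label] = next_label
        result.centroids[next_label] = tuple(prop.centroid)
        result.areas[next_label] = float(prop.area)
        next_label += 1
    return result


def quantify(seg: SegmentationResult, fluor_image: np.ndarray) -> dict[int, float]:
    """Mean fluorescence pixel intensity per segmented cell."""
    fluor_image = np.asarray(fluor_image)
    if fluor_image.shape != seg.label_image.shape:
        raise ValueError("fluorescence image shape does not match labels")
    out: dict[int, float] = {}
    if not seg.centroids:
        return out
    labels = seg.labels
    means = ndimage.mean(fluor_image, labels=seg.label_image, index=labels)
    for lab, m in zip(labels, np.atleast_1d(means)):
        out[lab] = float(m)
    return out


def background_mask(seg: SegmentationResult, dilation_px: int = 3) -> np.ndarray:
    """Background = complement of the dilated union of cell masks."""
    fg = seg.label_image > 0
    if dilation_px > 0:
        fg = ndimage.binary_dilation(fg, structure=disk(dilation_px))
    return ~fg


def snr(seg: SegmentationResult, fluor_image: np.ndarray) -> float:
    """Mean intracellular fluorescence divided by mean background fluorescence."""
    fluor_image = np.asarray(fluor_image)
    cells = seg.label_image > 0
    bg = background_mask(seg)
    if not cells.any() or not bg.any():
        raise ValueError("need at least one cell pixel and one background pixel")
    bg_mean = float(fluor_image[bg].mean())
    if bg_mean == 0:
        raise ValueError("background mean is zero")
    return float(fluor_image[cells].mean()) / bg_mean


def link_tracks(
    tracks: list[TrackedCell],
    curr: SegmentationResult,
    frame: int,
    max_disp: float = 10.0,
    next_track_id: int | None = None,
) -> list[TrackedCell]:
    """Extend tracks with the current frame's segmentation.

    Active tracks (present in the previous frame) are matched to current
    labels by minimum total squared centroid displacement, with matches
    farther than ``max_disp`` forbidden. Unmatched labels start new tracks;
    unmatched tracks are simply absent this frame. Ties resolve to the lowest
    total squared displacement, then lowest track id (the assignment solver
    is deterministic given the distance matrix).
    """
    active = [t for t in tracks if t.frames and t.frames[-1] == frame - 1]
    active.sort(key=lambda t: t.track_id)
    labels = curr.labels
    if next_track_id is None:
        next_track_id = max((t.track_id for t in tracks), default=-1) + 1
    assigned: set[int] = set()
    if active and labels:
        cost = np.full((len(active), len(labels)), 4.0 * max_disp ** 2 + 1.0)
        for i, t in enumerate(active):
            pr, pc = t.last_centroid()
            for j, lab in enumerate(labels):
                cr, cc = curr.centroids[lab]
                d2 = (pr - cr) ** 2 + (pc - cc) ** 2
                if d2 <= max_disp ** 2:
                    cost[i, j] = d2
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] > max_disp ** 2:
                continue
            t = active[i]
            lab = labels[j]
            t.frames.append(frame)
            t.centroids[frame] = curr.centroids[lab]
            t.labels[frame] = lab
            assigned.add(lab)
    for lab in labels:
        if lab in assigned:
            continue
        t = TrackedCell(track_id=next_track_id)
        next_track_id += 1
        t.frames.append(frame)
        t.centroids[frame] = curr.centroids[lab]
        t.labels[frame] = lab
        tracks.append(t)
    return tracks


class Tracker:
    """Stateful frame-to-frame tracker wrapping :func:`link_tracks`."""

    def __init__(self, max_disp: float = 10.0):
        self.max_disp = max_disp
        self.tracks: list[TrackedCell] = []
        self._next_id = 0

    def update(self, seg: SegmentationResult, frame: int) -> list[TrackedCell]:
        link_tracks(self.tracks, seg, frame, self.max_disp, self._next_id)
        self._next_id = max((t.track_id for t in self.tracks), default=-1) + 1
        return self.tracks

    def quantify_frame(self, seg: SegmentationResult, frame: int,
                       channel: str, fluor_image: np.ndarray) -> None:
        means = quantify(seg, fluor_image)
        for t in self.tracks:
            if t.present_at(frame):
                t.fluorescence.setdefault(frame, {})[channel] = means[t.labels[frame]]


def erode_mask(label_mask: np.ndarray, radius: int) -> np.ndarray:
    """Erode a boolean mask by a disk; fall back to the centroid pixel.

    Anti-extensive and monotone in radius. If erosion empties the mask, the
    single pixel nearest the mask centroid is returned so that a targeted
    cell always receives some light.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    label_mask = np.asarray(label_mask, dtype=bool)
    if radius == 0 or not label_mask.any():
        return label_mask.copy()
    eroded = erosion(label_mask, disk(radius))
    if eroded.any():
        return eroded
    rr, cc = np.nonzero(label_mask)
    crow, ccol = rr.mean(), cc.mean()
    i = int(np.argmin((rr - crow) ** 2 + (cc - ccol) ** 2))
    out = np.zeros_like(label_mask)
    out[rr[i], cc[i]] = True
    return out
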