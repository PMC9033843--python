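"""Single-cell light-targeting strategies for recombination experiments.

Two selection strategies: *ring targeting* permanently marks every tracked
cell whose centroid ever lies inside a fixed annulus, and *islet selection*
dynamically picks cells far from all previously targeted cells to seed
isolated recombined micro-colonies. Targeted cells are stimulated with the
union of their eroded masks for 1 s at every 6-min stimulation tick until
the end of the experiment; at the endpoint, a recombined / non-recombined
phenotype is called from the reporter fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analysis import SegmentationResult, TrackedCell, erode_mask
from .microscope import StimulationMask

__all__ = [
    "RingRegion",
    "TargetRegistry",
    "ring_update",
    "islet_select",
    "build_stimulation_mask",
    "classify_endpoint",
    "EndpointSummary",
]


@dataclass(frozen=True)
class RingRegion:
    """Annulus in the field of view, in pixel coordinates."""

    center: tuple  # (row, col)
    r_inner: float
    r_outer: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_inner < self.r_outer:
            raise ValueError("require 0 <= r_inner < r_outer")

    def contains(self, point: tuple) -> bool:
        d = math.hypot(point[0] - self.center[0], point[1] - self.center[1])
        return self.r_inner <= d <= self.r_outer


@dataclass
class TargetRegistry:
    """Permanently targeted tracks and the stimulation schedule.

    Once a track is targeted it stays targeted to the end of the experiment;
    stimulation is 1 pulse of ``pulse_ms`` every ``period_min``.
    """

    targets: dict = field(default_factory=dict)  # track_id -> first-target frame
    period_min: float = 6.0
    pulse_ms: float = 1000.0

    def add(self, track_id: int, frame: int) -> bool:
        if track_id in self.targets:
            return False
        self.targets[track_id] = frame
        return True

    def is_targeted(self, track_id: int) -> bool:
        return track_id in self.targets


def ring_update(tracks: list[TrackedCell], region: RingRegion,
                registry: TargetRegistry, frame: int, log=None) -> TargetRegistry:
    """Target every track whose current centroid lies inside the annulus."""
    for t in tracks:
        if not t.present_at(frame) or registry.is_targeted(t.track_id):
            continue
        if region.contains(t.centroids[frame]):
            registry.add(t.track_id, frame)
            if log is not None:
                log.info("targeting", "track targeted (ring)",
                         track_id=t.track_id, frame=frame)
            t.targeted = True
    return registry


def islet_select(tracks: list[TrackedCell], registry: TargetRegistry,
                 frame: int, d_min: float, max_new: int = 1,
                 log=None) -> TargetRegistry:
    """Target up to ``max_new`` cells far from all currently targeted cells.

    Candidates are visited in deterministic order — descending distance to
    the nearest targeted cell's current centroid (untargeted-field distance
    is infinite), ties to the lower track id — and accepted iff their
    distance to every targeted cell exceeds ``d_min``. Distances are taken
    between centroids at the moment of selection.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    present = [t for t in tracks if t.present_at(frame)]
    targeted_pts = [t.centroids[frame] for t in present
                    if registry.is_targeted(t.track_id)]
    # fall back to last known centroid for targeted tracks lost this frame
    for t in tracks:
        if registry.is_targeted(t.track_id) and not t.present_at(frame) and t.frames:
            targeted_pts.append(t.last_centroid())

    def nearest_target_dist(pt):
        if not targeted_pts:
            return math.inf
        return min(math.hypot(pt[0] - q[0], pt[1] - q[1]) for q in targeted_pts)

    candidates = [t for t in present if not registry.is_targeted(t.track_id)]

    def isolation(t):
        # with no targets yet, prefer the cell most isolated from its peers
        pt = t.centroids[frame]
        if targeted_pts:
            return nearest_target_dist(pt)
        others = [u.centroids[frame] for u in present if u is not t]
        if not others:
            return math.inf
        return min(math.hypot(pt[0] - q[0], pt[1] - q[1]) for q in others)

    candidates.sort(key=lambda t: (-isolation(t), t.track_id))
    added = 0
    for t in candidates:
        if added >= max_new:
            break
        if nearest_target_dist(t.centroids[frame]) > d_min:
            registry.add(t.track_id, frame)
            targeted_pts.append(t.centroids[frame])
            t.targeted = True
            added += 1
            if log is not None:
                log.info("targeting", "track targeted (islet)",
                         track_id=t.track_id, frame=frame)
    return registry


def build_stimulation_mask(
    tracks: list[TrackedCell],
    registry: TargetRegistry,
    seg: SegmentationResult,
    frame: int,
    erosion_radius: int = 2,
    log=None,
) -> StimulationMask:
    """Union of the eroded masks of targeted cells present this frame.

    A targeted track absent from the current segmentation is skipped and
    logged (tracking-loss accounting).
    """
    pixels = np.zeros(seg.label_image.shape, dtype=bool)
    for t in tracks:
        if not registry.is_targeted(t.track_id):
            continue
        if not t.present_at(frame):
            if log is not None:
                log.warning("targeting", "targeted track absent this frame",
                            track_id=t.track_id, frame=frame)
            continue
        mask = seg.mask_of(t.labels[frame])
        pixels |= erode_mask(mask, erosion_radius)
    return StimulationMask(pixels=pixels, duration_ms=registry.pulse_ms,
                           intensity=1.0, frame_index=frame)


@dataclass
class EndpointSummary:
    phenotype: dict  # track_id -> bool (recombined call)
    targeted_fluorescence: list
    non_targeted_fluorescence: list
    targeted_not_recombined: list
    recombined_not_targeted: list


def classify_endpoint(
    tracks: list[TrackedCell],
    final_fluorescence: dict,
    registry: TargetRegistry,
    threshold: float,
) -> EndpointSummary:
    """Attribute a recombined / non-recombined phenotype at the endpoint.

    ``final_fluorescence[track_id]`` is the end-of-experiment reporter
    fluorescence; phenotype is recombined iff it exceeds ``threshold``.
    Returns the fluorescence distributions of targeted vs non-targeted cells
    and the two outlier lists the tails of those distributions reveal.
    """
    phenotype: dict = {}
    tgt_fl, non_fl = [], []
    tnr, rnt = [], []
    for t in tracks:
        if t.track_id not in final_fluorescence:
            continue
        fl = final_fluorescence[t.track_id]
        rec = fl > threshold
        phenotype[t.track_id] = rec
        if registry.is_targeted(t.track_id):
            tgt_fl.append(fl)
            if not rec:
                tnr.append(t.track_id)
        else:
            non_fl.append(fl)
            if rec:
                rnt.append(t.track_id)
    return EndpointSummary(phenotype=phenotype,
                           targeted_fluorescence=tgt_fl,
                           non_targeted_fluorescence=non_fl,
                           targeted_not_recombined=sorted(tnr),
                           recombined_not_targeted=sorted(rnt))
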