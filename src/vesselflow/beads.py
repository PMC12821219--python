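"""Bead-perfusion velocimetry: spot detection, linking, track filtering.

Fluorescent microbeads (10 um) perfused through the network are detected
per frame with a band-pass (difference-of-Gaussians) filter at the bead
scale followed by local-maximum picking and sub-pixel centroid
refinement. Detections are linked frame-to-frame by greedy
mutual-nearest-neighbor assignment with a maximum step gate, short tracks
are discarded, and surviving tracks are filtered by net displacement
before the mean track speeds are reported. Tracking is 2D (maximum
intensity projections) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

BEAD_DIAMETER_UM = 10.0
MAX_STEP_UM = 150.0
MIN_TRACK_FRAMES = 3
MIN_DISPLACEMENT_UM = 125.0


@dataclass
class Spot:
    frame: int
    position: np.ndarray          # (x, y) or (x, y, z) um
    intensity: float
    quality: float


@dataclass
class SpotSet:
    spots: list                    # list[list[Spot]] per frame
    frame_shape: tuple
    spacing: float                 # um per pixel

    def n_frames(self) -> int:
        return len(self.spots)

    def positions(self, frame: int) -> np.ndarray:
        s = self.spots[frame]
        if not s:
            return np.empty((0, 2))
        return np.array([sp.position for sp in s])


@dataclass
class Track:
    id: int
    frames: np.ndarray             # strictly increasing frame indices
    positions: np.ndarray          # (n, d) um
    times: np.ndarray              # seconds

    @property
    def path_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.positions, axis=0),
                                    axis=1).sum())

    @property
    def displacement(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def mean_speed(self) -> float:
        """Path length over duration, um/s."""
        return self.path_length / self.duration if self.duration > 0 \
            else np.nan


@dataclass
class TrackSet:
    tracks: list = field(default_factory=list)

    def speeds(self) -> np.ndarray:
        return np.array([t.mean_speed for t in self.tracks])

    def summary(self) -> pd.DataFrame:
        rows = [{"track_id": t.id, "n_frames": len(t.frames),
                 "path_length_um": t.path_length,
                 "displacement_um": t.displacement,
                 "duration_s": t.duration, "mean_speed_um_s": t.mean_speed}
                for t in self.tracks]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def detect_spots(frames, spacing: float = 1.0,
                 diameter: float = BEAD_DIAMETER_UM,
                 intensity_threshold: float | None = None,
                 quality_threshold: float | None = None,
                 min_quality_fraction: float = 0.01,
                 mask=None) -> SpotSet:
    """Detect bead-scale blobs in each frame.

    Band-pass at the bead scale (difference of Gaussians with
    sigma = d/4 and sqrt(2) d/4 in pixels), local maxima over a window of
    one bead diameter, then intensity-weighted sub-pixel centroid
    refinement on the raw frame. Quality is the band-pass peak response
    (an operational stand-in for instrument-specific scores; thresholds
    are plain config), and peaks below ``min_quality_fraction`` of the
    strongest response in a frame are discarded as ripple. ``mask``
    (2D bool) excludes regions, e.g. stuck beads.
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    d_px = diameter / spacing
    if d_px > min(frames.shape[1:]):
        raise ValueError("bead diameter exceeds the image size")
    if d_px <= 0:
        raise ValueError("diameter must be positive")
    s1 = max(d_px / 4.0, 0.5)
    s2 = np.sqrt(2.0) * s1
    win = max(3, int(round(d_px)) | 1)

    per_frame = []
    for fi, frame in enumerate(frames):
        f = frame.copy()
        if mask is not None:
            f = np.where(mask, 0.0, f)
        dog = ndimage.gaussian_filter(f, s1) - ndimage.gaussian_filter(f, s2)
        mx = ndimage.maximum_filter(dog, size=win, mode="constant")
        peaks = (dog == mx) & (dog > 0)
        if peaks.any() and min_quality_fraction > 0:
            # drop residual ripples far below the strongest response
            peaks &= dog >= min_quality_fraction * dog[peaks].max()
        if quality_threshold is not None:
            peaks &= dog > quality_threshold
        if intensity_threshold is not None:
            peaks &= f > intensity_threshold
        # collapse plateau ties (a bead centered between pixels maximizes
        # two adjacent pixels exactly) to a single representative peak
        lab, nlab = ndimage.label(peaks)
        if nlab:
            centers = ndimage.center_of_mass(peaks, lab,
                                             range(1, nlab + 1))
            peaks = np.zeros_like(peaks)
            for cx, cy in centers:
                peaks[int(round(cx)), int(round(cy))] = True
        spots = []

        def parabolic_offset(vals):
            """Sub-pixel peak offset from a 3-point parabola."""
            denom = vals[0] - 2 * vals[1] + vals[2]
            if denom >= 0:
                return 0.0
            return float(np.clip(0.5 * (vals[0] - vals[2]) / denom,
                                 -0.5, 0.5))

        for px, py in np.argwhere(peaks):
            cx, cy = float(px), float(py)
            if 0 < px < f.shape[0] - 1:
                cx += parabolic_offset(dog[px - 1:px + 2, py])
            if 0 < py < f.shape[1] - 1:
                cy += parabolic_offset(dog[px, py - 1:py + 2])
            pos = (np.array([cx, cy]) + 0.5) * spacing
            spots.append(Spot(fi, pos, float(f[px, py]), float(dog[px, py])))
        per_frame.append(spots)
    return SpotSet(per_frame, frames.shape[1:], spacing)


# --------------------------------------------------------------------------
# Linking
# --------------------------------------------------------------------------

def link_tracks(spots: SpotSet, max_step: float = MAX_STEP_UM,
                min_frames: int = MIN_TRACK_FRAMES,
                frame_interval: float = 1.0,
                predictive: bool = True) -> TrackSet:
    """Greedy mutual-nearest frame-to-frame linking with a step gate.

    Candidate pairs between consecutive frames are sorted by distance and
    assigned greedily (each end used once), never linking across more
    than ``max_step`` um. With ``predictive`` (default) each track's
    match distance is taken from its constant-velocity extrapolated
    position, which prevents identity swaps when a fast bead overtakes a
    slow neighbor; the gate still applies to the measured step. Tracks
    spanning fewer than ``min_frames`` detections are discarded.
    ``frame_interval`` (s) sets track times.
    """
    active: list[list[tuple[int, np.ndarray]]] = []
    finished: list[list[tuple[int, np.ndarray]]] = []
    for fi in range(spots.n_frames()):
        pos = spots.positions(fi)
        claimed_spot = np.zeros(len(pos), bool)
        next_active = []
        if active and len(pos):
            last = np.array([tr[-1][1] for tr in active])
            last_frame = np.array([tr[-1][0] for tr in active])
            if predictive:
                pred = last.copy()
                for k, tr in enumerate(active):
                    if len(tr) >= 2 and tr[-1][0] - tr[-2][0] == 1:
                        pred[k] = tr[-1][1] + (tr[-1][1] - tr[-2][1])
            else:
                pred = last
            d = np.linalg.norm(pred[:, None, :] - pos[None, :, :], axis=2)
            step = np.linalg.norm(last[:, None, :] - pos[None, :, :],
                                  axis=2)
            d[step > max_step] = np.inf          # gate on the actual step
            d[last_frame != fi - 1] = np.inf     # only consecutive frames
            ti, si = np.where(d <= max_step)
            order = np.argsort(d[ti, si], kind="stable")
            used_track = np.zeros(len(active), bool)
            for k in order:
                a, b = ti[k], si[k]
                if used_track[a] or claimed_spot[b]:
                    continue
                used_track[a] = True
                claimed_spot[b] = True
                active[a].append((fi, pos[b]))
            for a, tr in enumerate(active):
                if used_track[a]:
                    next_active.append(tr)
                else:
                    finished.append(tr)
        else:
            finished.extend(active)
        for b in range(len(pos)):
            if not claimed_spot[b]:
                next_active.append([(fi, pos[b])])
        active = next_active
    finished.extend(active)

    tracks = []
    for chain in finished:
        if len(chain) < min_frames:
            continue
        fr = np.array([c[0] for c in chain])
        ps = np.array([c[1] for c in chain])
        tracks.append(Track(len(tracks), fr, ps, fr * frame_interval))
    return TrackSet(tracks)


def filter_and_summarize(tracks: TrackSet,
                         min_displacement: float = MIN_DISPLACEMENT_UM
                         ) -> tuple[TrackSet, pd.DataFrame]:
    """Drop tracks with net displacement below ``min_displacement`` um and
    return the surviving tracks plus their speed summary table."""
    kept = [t for t in tracks.tracks if t.displacement >= min_displacement]
    out = TrackSet([Track(i, t.frames, t.positions, t.times)
                    for i, t in enumerate(kept)])
    return out, out.summary()
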