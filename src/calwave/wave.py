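"""Evoked calcium-wave quantification.

The measurement model: a movie is acquired at fixed frame interval; the
frames before electrical stimulation define the basal fluorescence F_b
(pixelwise mean), every trace is normalised to dF/F = (F - F_b)/F_b, and a
cell (ROI) counts as *recruited* when its dF/F exceeds a threshold for a
sustained run of frames after the stimulus.  Recruited cells are binned
into concentric 50-um rings around the stimulation site; the wave's maximum
length is the largest recruited-cell distance and its speed is
(maximum length)/(t1 - t0), with t0 the first post-stimulus activation time
and t1 the activation time at maximum distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max


class DeadROIError(ValueError):
    """Raised when basal fluorescence is non-positive (dead/empty ROI)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class Movie:
    """A time-lapse fluorescence movie with acquisition metadata.

    ``frames`` is (T, H, W) in arbitrary units; ``stim_site`` is (x, y) in
    pixels; ``channel2``, when present, is a static H x W image of the
    second (co-label) channel.
    """

    frames: np.ndarray
    frame_interval: float                # s
    pixel_size: float                    # um/px
    stim_frame: int
    stim_site: tuple[float, float]
    channel2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if not (1 <= self.stim_frame < self.frames.shape[0]):
            raise ValueError("stim_frame must satisfy 1 <= stim_frame < T")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if self.channel2 is not None:
            self.channel2 = np.asarray(self.channel2)
            if self.channel2.shape != self.frames.shape[1:]:
                raise ValueError("channel2 must match the movie frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ROISet:
    """Disjoint circular ROIs on the imaging plane.

    ``labels`` is an H x W integer image, 0 = background and ``i + 1``
    marking pixels of ROI ``i``.  Overlapping disks are resolved by
    assigning each pixel to the nearest centroid, so ROIs are disjoint by
    construction.
    """

    centroids: np.ndarray                # (n, 2) as (x, y) px
    labels: np.ndarray                   # (H, W) int
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if self.ids is None:
            self.ids = np.arange(len(self.centroids))
        self.ids = np.asarray(self.ids)

    def __len__(self) -> int:
        return len(self.centroids)

    def mask(self, i: int) -> np.ndarray:
        return self.labels == i + 1

    @classmethod
    def from_centroids(cls, centroids, shape: tuple[int, int],
                       radius_px: float, ids=None) -> "ROISet":
        """Build disjoint disk ROIs of ``radius_px`` around ``centroids``."""
        centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
        h, w = shape
        labels = np.zeros((h, w), dtype=np.int32)
        if len(centroids):
            yy, xx = np.mgrid[0:h, 0:w]
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            tree = cKDTree(centroids)
            dist, idx = tree.query(pts)
            inside = dist <= radius_px
            labels.ravel()[inside] = idx[inside] + 1
        return cls(centroids=centroids, labels=labels, ids=ids)

    @classmethod
    def from_csv(cls, path, shape: tuple[int, int], radius_px: float) -> "ROISet":
        """Load ROI centroids from a CSV with columns id, x, y."""
        df = pd.read_csv(path)
        return cls.from_centroids(df[["x", "y"]].to_numpy(), shape,
                                  radius_px, ids=df["id"].to_numpy())


@dataclass
class Trace:
    """One ROI's raw fluorescence time course and its dF/F normalisation."""

    values: np.ndarray                   # (T,) a.u.
    fb: float                            # basal fluorescence, a.u.

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fb <= 0:
            raise DeadROIError(f"basal fluorescence must be > 0, got {self.fb}")

    @property
    def dff(self) -> np.ndarray:
        return (self.values - self.fb) / self.fb


@dataclass
class RecruitmentCall:
    """Per-ROI recruitment decision and geometry."""

    roi_id: int
    recruited: bool
    activation_frame: int | None
    peak_amplitude: float                # peak raw dF, a.u.
    peak_dff: float                      # peak dF/F, dimensionless
    distance: float                      # um from stimulation site
    ring_index: int
    colabeled: bool | None = None


@dataclass
class WaveMetrics:
    """Per-slice summary of one evoked wave."""

    cells_per_ring: list[int]
    total_recruited: int
    max_length: float                    # um (nan when nothing recruited)
    t0: float                            # s
    t1: float                            # s
    speed: float                         # um/s (nan when undefined)
    mean_amplitude: float                # a.u.
    auc_per_cell: float                  # a.u.*s, mean over recruited cells

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["cells_per_ring"] = list(self.cells_per_ring)
        return d


# ---------------------------------------------------------------------------
# elementary operations


def basal_fluorescence(movie: Movie, pre_frames: int | None = None) -> np.ndarray:
    """Pixelwise mean of the pre-stimulus frames (the F_b image).

    ``pre_frames`` defaults to ``movie.stim_frame``, i.e. the whole
    pre-stimulus window (15 frames at 1 Hz under the default protocol).
    """
    if pre_frames is None:
        pre_frames = movie.stim_frame
    if pre_frames <= 0:
        raise ValueError("pre_frames must be >= 1: F_b is undefined on an "
                         "empty window")
    if pre_frames > movie.stim_frame:
        raise ValueError("pre_frames cannot extend past the stimulus frame")
    return movie.frames[:pre_frames].mean(axis=0)


def dff_trace(values: np.ndarray, fb: float) -> np.ndarray:
    """Elementwise (F - F_b)/F_b.  Raises :class:`DeadROIError` if fb <= 0."""
    if fb <= 0:
        raise DeadROIError(f"basal fluorescence must be > 0, got {fb}")
    return (np.asarray(values, dtype=float) - fb) / fb


def assign_ring(centroid, stim_site, pixel_size: float,
                ring_width: float = 50.0) -> tuple[float, int]:
    """Distance (um) from the stimulation site and its concentric-ring index.

    Rings are half-open annuli [k*w, (k+1)*w); a cell at exactly 50 um with
    the default 50-um rings falls in ring 1.
    """
    dx = (centroid[0] - stim_site[0]) * pixel_size
    dy = (centroid[1] - stim_site[1]) * pixel_size
    distance = math.hypot(dx, dy)
    return distance, int(distance // ring_width)


def classify_recruited(dff: np.ndarray, stim_frame: int,
                       threshold_k: float = 2.5, min_frames: int = 3,
                       dff_floor: float = 0.2) -> tuple[bool, int | None]:
    """First sustained threshold crossing of a dF/F trace after the stimulus.

    The threshold is ``threshold_k`` times the SD of the pre-stimulus dF/F;
    when that SD is exactly zero (noiseless input) the absolute
    ``dff_floor`` is used instead.  Returns ``(recruited, activation_frame)``
    where the activation frame is the first frame of the first run of at
    least ``min_frames`` consecutive supra-threshold frames at
    t >= stim_frame.  Pre-stimulus activity never triggers recruitment.
    """
    dff = np.asarray(dff, dtype=float)
    if stim_frame < 1 or stim_frame >= len(dff):
        raise ValueError("dff must cover pre- and post-stimulus frames")
    pre = dff[:stim_frame]
    sd = pre.std(ddof=1) if len(pre) > 1 else 0.0
    thr = threshold_k * sd if sd > 0 else dff_floor
    above = dff >= thr
    run = 0
    for t in range(stim_frame, len(dff)):
        run = run + 1 if above[t] else 0
        if run >= min_frames:
            return True, t - min_frames + 1
    return False, None


def transient_auc(dff: np.ndarray, window: tuple[int, int],
                  frame_interval: float) -> float:
    """Trapezoidal area under the dF/F curve over ``window`` (a.u.*s)."""
    start, stop = window
    dff = np.asarray(dff, dtype=float)
    if not (0 <= start < stop <= len(dff)):
        raise ValueError("window must lie within the trace")
    seg = dff[start:stop]
    if len(seg) < 2:
        raise ValueError("AUC window must contain at least 2 samples")
    return float(np.trapezoid(seg, dx=frame_interval))


def wave_speed(max_length: float, t0: float, t1: float) -> float:
    """(maximum length)/(t1 - t0) in um/s; nan when t1 <= t0."""
    if t1 <= t0:
        return float("nan")
    return max_length / (t1 - t0)


def wave_metrics(calls: Sequence[RecruitmentCall], frame_interval: float,
                 aucs: dict[int, float] | None = None) -> WaveMetrics:
    """Per-slice wave summary from a set of recruitment calls.

    t0 is the activation time of the earliest-activating recruited cell;
    t1 is the activation time of the recruited cell attaining the maximum
    distance (earliest among ties, which never inflates the speed).  With
    no recruited cells, or t1 == t0, the affected metrics are nan and a
    warning is emitted.
    """
    rec = [c for c in calls if c.recruited]
    if not rec:
        warnings.warn("no recruited cells: wave metrics undefined",
                      stacklevel=2)
        return WaveMetrics([], 0, float("nan"), float("nan"), float("nan"),
                           float("nan"), float("nan"), float("nan"))
    max_length = max(c.distance for c in rec)
    times = {c.roi_id: c.activation_frame * frame_interval for c in rec}
    t0 = min(times.values())
    t1 = min(times[c.roi_id] for c in rec if c.distance == max_length)
    speed = wave_speed(max_length, t0, t1)
    if math.isnan(speed):
        warnings.warn("t1 == t0: wave speed undefined", stacklevel=2)
    n_rings = max(c.ring_index for c in rec) + 1
    per_ring = [0] * n_rings
    for c in rec:
        per_ring[c.ring_index] += 1
    mean_amp = float(np.mean([c.peak_amplitude for c in rec]))
    if aucs:
        mean_auc = float(np.mean([aucs[c.roi_id] for c in rec
                                  if c.roi_id in aucs]))
    else:
        mean_auc = float("nan")
    return WaveMetrics(per_ring, len(rec), max_length, t0, t1, speed,
                       mean_amp, mean_auc)


# ---------------------------------------------------------------------------
# ROI detection and trace extraction


def detect_rois(movie: Movie, expected_radius: float,
                noise_k: float = 5.0) -> ROISet:
    """Detect responsive cells on the peak post-stimulus dF/F projection.

    The per-pixel maximum of dF/F over post-stimulus frames is smoothed at
    half the expected cell radius; local maxima exceeding the background
    median by ``noise_k`` robust SDs (1.4826 x MAD) become ROI centroids,
    each given a disk mask of ``expected_radius``.  Deterministic given the
    inputs; may return an empty set on a blank movie.
    """
    fb = basal_fluorescence(movie)
    fb_safe = np.maximum(fb, max(1e-9, 1e-6 * float(np.abs(fb).max() or 1.0)))
    proj = (movie.frames[movie.stim_frame:].max(axis=0) - fb) / fb_safe
    r_px = expected_radius / movie.pixel_size
    sm = gaussian_filter(proj, sigma=max(1.0, r_px / 2.0))
    med = float(np.median(sm))
    mad = float(np.median(np.abs(sm - med)))
    thr = med + noise_k * max(1.4826 * mad, 1e-9)
    min_dist = max(1, int(round(1.2 * r_px)))
    peaks = peak_local_max(sm, min_distance=min_dist, threshold_abs=thr,
                           exclude_border=False)
    centroids = peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)
    return ROISet.from_centroids(centroids, movie.shape, r_px)


def extract_traces(movie: Movie, rois: ROISet) -> np.ndarray:
    """Mean intensity inside each ROI per frame; shape (n_rois, T)."""
    labels = rois.labels.ravel()
    n = len(rois)
    counts = np.bincount(labels, minlength=n + 1)[1:]
    if np.any(counts == 0):
        raise ValueError("every ROI must contain at least one pixel")
    out = np.empty((n, movie.n_frames))
    flat = movie.frames.reshape(movie.n_frames, -1)
    for t in range(movie.n_frames):
        sums = np.bincount(labels, weights=flat[t], minlength=n + 1)[1:]
        out[:, t] = sums / counts
    return out
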