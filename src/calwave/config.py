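"""Configuration types for the simulators and the analysis pipeline.

A :class:`SimulationConfig` describes one evoked-wave imaging session: field
geometry, stimulation site, the planted wave (per-ring recruitment
probabilities, amplitude decay with distance, propagation speed), transient
kinetics and noise.  A :class:`MorphPhantomSpec` describes one geometric cell
phantom with analytically known volume and branching, used as the oracle for
the 3-D morphometry pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence


class ConfigurationError(ValueError):
    """Raised when a configuration violates one of its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class SimulationConfig:
    """Parameters of one simulated calcium-imaging movie.

    Defaults reproduce the acquisition protocol the analysis assumes:
    200 frames at 1 Hz with the first 15 frames as the pre-stimulus window,
    a 400 x 400 um field imaged at 2.5 um/px, and a wave propagating at
    27.3 um/s from the field centre.  Amplitudes are in arbitrary
    fluorescence units (a.u.) on top of ``baseline``.
    """

    n_frames: int = 200
    frame_interval: float = 1.0          # s
    pre_stim_frames: int = 15
    height: int = 160                    # px
    width: int = 160                     # px
    pixel_size: float = 2.5              # um/px
    stim_site: tuple[float, float] | None = None   # (x, y) px; default centre
    n_cells: int = 120
    cell_radius: float = 5.0             # um
    recruitment_prob_per_ring: Sequence[float] = (0.9, 0.8, 0.6, 0.4, 0.2)
    amplitude_at_origin: float = 150.0   # a.u. peak dF at distance 0
    amplitude_decay_length: float = 150.0  # um, exponential decay constant
    wave_speed: float = 27.3             # um/s
    tau_rise: float = 2.0                # s
    tau_decay: float = 10.0              # s
    colabel_prob: float = 0.5
    baseline: float = 100.0              # a.u.
    noise_sd: float = 3.0                # a.u. per pixel per frame
    seed: int = 0
    # Stimulus electrical parameters: metadata only, no effect on pixels.
    stim_metadata: dict = field(
        default_factory=lambda: {"n_pulses": 20, "amplitude_uA": 200, "rate_hz": 10}
    )

    def __post_init__(self) -> None:
        _require(self.pre_stim_frames >= 1,
                 "pre_stim_frames must be >= 1 (basal window undefined)")
        _require(self.n_frames > self.pre_stim_frames,
                 "n_frames must exceed pre_stim_frames")
        _require(self.frame_interval > 0, "frame_interval must be > 0")
        _require(self.pixel_size > 0, "pixel_size must be > 0")
        _require(self.wave_speed > 0, "wave_speed must be > 0")
        _require(self.tau_rise > 0 and self.tau_decay > 0,
                 "tau_rise and tau_decay must be > 0")
        _require(self.height > 0 and self.width > 0, "field must be non-empty")
        _require(self.n_cells >= 0, "n_cells must be >= 0")
        _require(self.cell_radius > 0, "cell_radius must be > 0")
        _require(self.baseline > 0, "baseline must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(0.0 <= self.colabel_prob <= 1.0,
                 "colabel_prob must lie in [0, 1]")
        probs = list(self.recruitment_prob_per_ring)
        _require(len(probs) >= 1, "recruitment_prob_per_ring must be non-empty")
        _require(all(0.0 <= p <= 1.0 for p in probs),
                 "recruitment probabilities must lie in [0, 1]")
        if self.stim_site is None:
            self.stim_site = ((self.width - 1) / 2.0, (self.height - 1) / 2.0)

    @property
    def stim_frame(self) -> int:
        return self.pre_stim_frames

    @property
    def stim_onset(self) -> float:
        """Stimulus onset time in seconds (end of pre-stimulus window)."""
        return self.pre_stim_frames * self.frame_interval

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["recruitment_prob_per_ring"] = list(self.recruitment_prob_per_ring)
        d["stim_site"] = list(self.stim_site)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("stim_site") is not None:
            d["stim_site"] = tuple(d["stim_site"])
        return cls(**d)


@dataclass
class MorphPhantomSpec:
    """A geometric cell phantom with analytically known ground truth.

    ``shape`` is one of ``cylinder``, ``Y_tree``, ``H_tree``, ``sphere``,
    ``random_tree``.  ``segment_lengths`` are the generating segment lengths
    in um (for ``sphere`` the single entry is the radius).  ``expected_*``
    fields are filled by the phantom factories from the exact geometry
    (e.g. cylinder volume = pi r^2 L before voxelisation); after
    voxelisation the realised voxel volume is recorded in
    ``realized_volume``.
    """

    shape: str
    segment_lengths: Sequence[float]
    segment_radius: float
    voxel_size: float                    # um, isotropic
    expected_volume: float = 0.0         # um^3, analytic
    expected_branchpoints: int = 0
    expected_branch_lengths: Sequence[float] = ()
    seed: int = 0
    realized_volume: float | None = None  # um^3, voxel count x voxel volume

    _SHAPES = ("cylinder", "Y_tree", "H_tree", "sphere", "random_tree")

    def __post_init__(self) -> None:
        _require(self.shape in self._SHAPES,
                 f"shape must be one of {self._SHAPES}, got {self.shape!r}")
        _require(self.voxel_size > 0, "voxel_size must be > 0")
        _require(self.segment_radius > 0, "segment_radius must be > 0")
        _require(len(self.segment_lengths) >= 1 and
                 all(l > 0 for l in self.segment_lengths),
                 "segment_lengths must be positive")

    @property
    def expected_branches(self) -> int:
        return len(self.expected_branch_lengths)


@dataclass
class AnalysisParams:
    """Tunable parameters of the wave-quantification pipeline.

    ``threshold_k`` multiplies the pre-stimulus SD of the dF/F trace to set
    the recruitment threshold; a crossing must persist ``min_frames``
    consecutive frames.  ``dff_floor`` is the absolute fallback threshold
    when the pre-stimulus trace has zero variance (noiseless input).
    """

    threshold_k: float = 2.5
    min_frames: int = 3
    dff_floor: float = 0.2
    ring_width: float = 50.0             # um
    expected_radius: float = 5.0         # um, ROI disk radius
    detect_noise_k: float = 5.0          # MAD multiples over background
    min_overlap: float = 0.5             # co-label ROI overlap fraction
    alpha: float = 0.05
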