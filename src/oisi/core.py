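"""Core containers for trial-structured multispectral frame stacks.

The acquisition model is a one-condition evoked-response protocol: a short
pre-stimulus baseline, a stimulation train, and a long recovery, imaged as a
sequence of frames per illumination band.  Everything downstream (smoothing,
illumination correction, OIS mapping, spectral decomposition) consumes these
containers.

Conventions
-----------
* pixel coordinates are 0-based ``(row, col)``;
* time 0 is the trial start; the stimulus onset is at ``Protocol.baseline_s``;
* intensities are camera counts (arbitrary linear units);
* relative signals are dimensionless fractions internally and are converted
  to percent only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Protocol",
    "FrameStack",
    "TrialSet",
    "ROIMask",
    "OISMap",
    "TimeCourse",
    "LFPTrace",
]

Mode = Literal["reflectance", "transmission"]
Polarity = Literal["activation-positive", "raw"]


@dataclass(frozen=True)
class Protocol:
    """Trial timing: baseline, stimulation train and recovery, plus frame rate.

    Defaults correspond to 5 s baseline, 10 s stimulation, 45 s recovery at
    5 Hz per diode (300 frames per trial).
    """

    baseline_s: float = 5.0
    stim_s: float = 10.0
    recovery_s: float = 45.0
    frame_rate_hz: float = 5.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "stim_s", "recovery_s", "frame_rate_hz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Protocol.{name} must be finite and > 0, got {v!r}")
        n = self.duration_s * self.frame_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "protocol duration must be an integer number of frames; "
                f"got {n} frames"
            )

    @property
    def duration_s(self) -> float:
        return self.baseline_s + self.stim_s + self.recovery_s

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def stim_onset_s(self) -> float:
        return self.baseline_s

    @property
    def stim_offset_s(self) -> float:
        return self.baseline_s + self.stim_s

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds from trial start."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def window_slice(self, start_s: float, end_s: float) -> slice:
        """Frame-index slice for ``start_s <= t < end_s``."""
        t = self.times()
        idx = np.flatnonzero((t >= start_s - 1e-12) & (t < end_s - 1e-12))
        if idx.size == 0:
            raise ValueError(f"empty window [{start_s}, {end_s}) s")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def baseline_slice(self) -> slice:
        return self.window_slice(0.0, self.baseline_s)

    def stim_slice(self) -> slice:
        return self.window_slice(self.stim_onset_s, self.stim_offset_s)

    def to_dict(self) -> dict:
        return {
            "baseline_s": self.baseline_s,
            "stim_s": self.stim_s,
            "recovery_s": self.recovery_s,
            "frame_rate_hz": self.frame_rate_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(**{k: d[k] for k in ("baseline_s", "stim_s", "recovery_s", "frame_rate_hz")})


@dataclass
class FrameStack:
    """One band's ``(n_frames, height, width)`` intensity stack + metadata."""

    data: np.ndarray
    band: str
    protocol: Protocol
    mode: Mode = "reflectance"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"frame stack must be (T, H, W), got shape {self.data.shape}")
        if self.data.shape[0] != self.protocol.n_frames:
            raise ValueError(
                f"stack has {self.data.shape[0]} frames but the protocol "
                f"defines {self.protocol.n_frames}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("frame stack contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "FrameStack":
        return replace(self, data=data)


@dataclass
class TrialSet:
    """Repeated trials of one band; all stacks share shape and metadata."""

    trials: list[FrameStack]

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("TrialSet requires at least one trial")
        ref = self.trials[0]
        for k, tr in enumerate(self.trials):
            if tr.shape != ref.shape:
                raise ValueError(f"trial {k} shape {tr.shape} != {ref.shape}")
            if tr.band != ref.band:
                raise ValueError(f"trial {k} band {tr.band!r} != {ref.band!r}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def band(self) -> str:
        return self.trials[0].band


@dataclass
class ROIMask:
    """Boolean region-of-interest mask with its role in the analysis."""

    mask: np.ndarray
    role: Literal["reference", "active"]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask has no true pixels")
        if self.role not in ("reference", "active"):
            raise ValueError(f"unknown mask role {self.role!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class OISMap:
    """Stimulus-evoked relative intensity change per pixel (dimensionless)."""

    values: np.ndarray
    mode: Mode = "reflectance"
    band: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("OIS map must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OIS map contains non-finite values")


@dataclass
class TimeCourse:
    """ROI-averaged relative signal vs. time.

    ``polarity`` records whether the reflectance sign flip has been applied
    ("activation-positive") or the trace carries the raw relative intensity
    change ("raw", darkening negative in reflectance).
    """

    t: np.ndarray
    y: np.ndarray
    stim_onset_s: float
    mode: Mode = "reflectance"
    polarity: Polarity = "activation-positive"
    band: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be equal-length 1-D arrays")
        dt = np.diff(self.t)
        if self.t.size > 1 and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]):
            raise ValueError("t must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else float("nan")


@dataclass
class LFPTrace:
    """Local field potential trace (microvolts) on a dense time grid."""

    t: np.ndarray
    v: np.ndarray
    stim_onset_s: float
    stim_rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be equal-length 1-D arrays")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])
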