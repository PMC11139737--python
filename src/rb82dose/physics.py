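"""Nuclide constants, frame-schedule arithmetic and decay-correction algebra.

Everything downstream (TAC extraction, kinetic fitting, voxel integration)
goes through the conversions defined here.  All internal times are seconds;
the single seconds->hours conversion used for reporting time-integrated
activity lives in :func:`seconds_to_hours`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "NuclideSpec",
    "FrameSchedule",
    "decay_constant",
    "frame_decay_correction_factor",
    "seconds_to_hours",
    "load_nuclide",
    "load_schedule",
]

S_PER_H = 3600.0


def seconds_to_hours(t_s: float) -> float:
    """Convert seconds to hours (the only place this conversion happens)."""
    return t_s / S_PER_H


@dataclass(frozen=True)
class NuclideSpec:
    """Physical decay and emission-energy constants of a positron emitter.

    Parameters
    ----------
    half_life_s:
        Physical half-life in seconds (76 s for Rb-82).
    positron_yield:
        Positrons per decay, in [0, 1].
    mean_energy_per_decay_MeV:
        Mean locally deposited energy per decay (MeV); an external
        nuclear-data constant supplied by configuration.
    photon_fraction:
        Fraction of the per-decay energy assigned to kernel transport
        instead of local deposition (0 in local-deposition mode).
    """

    name: str
    half_life_s: float
    positron_yield: float = 1.0
    mean_energy_per_decay_MeV: float = 0.0
    photon_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.half_life_s > 0:
            raise ValueError(f"half_life_s must be > 0, got {self.half_life_s}")
        if not 0.0 <= self.positron_yield <= 1.0:
            raise ValueError("positron_yield must be in [0, 1]")
        if self.mean_energy_per_decay_MeV < 0:
            raise ValueError("mean_energy_per_decay_MeV must be >= 0")
        if not 0.0 <= self.photon_fraction <= 1.0:
            raise ValueError("photon_fraction must be in [0, 1]")

    @property
    def decay_constant_per_s(self) -> float:
        return decay_constant(self)


def decay_constant(spec: NuclideSpec) -> float:
    """lambda = ln 2 / T_half, per second.  Derived, never stored."""
    return math.log(2.0) / spec.half_life_s


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping acquisition frames (start_s, end_s).

    ``reference_time_s`` is the time the scanner's decay correction refers
    to; 0 = scan start (= injection start in this protocol).
    """

    frames: tuple[tuple[float, float], ...]
    reference_time_s: float = 0.0

    def __post_init__(self) -> None:
        frames = tuple((float(a), float(b)) for a, b in self.frames)
        object.__setattr__(self, "frames", frames)
        if len(frames) == 0:
            raise ValueError("schedule must contain at least one frame")
        for start, end in frames:
            if not start < end:
                raise ValueError(f"frame ({start}, {end}) has non-positive duration")
        starts = [f[0] for f in frames]
        if starts != sorted(starts):
            raise ValueError("frames must be sorted by start time")
        for (s0, e0), (s1, _) in zip(frames, frames[1:]):
            if s1 < e0:
                raise ValueError(f"frames ({s0},{e0}) and starting {s1} overlap")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames])

    @property
    def ends(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames])

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts


def frame_decay_correction_factor(
    frame: tuple[float, float],
    lam: float,
    reference_time_s: float = 0.0,
) -> float:
    """Factor turning a frame-averaged physically decaying activity into the
    activity decay-corrected to ``reference_time_s``.

    For a source A(t) = A0 * exp(-lam*t), the frame average over
    [t1, t2] is A0 * exp(-lam*t1) * (1 - exp(-lam*dt)) / (lam*dt); the
    returned factor f satisfies (frame average) * f = A0 * exp(-lam*ref),
    i.e. f = lam*dt * exp(lam*(t1 - ref)) / (1 - exp(-lam*dt)).  For
    lam = 0 the factor is exp(0) = 1.  The inverse operation (removing
    the correction) is division by f.
    """
    t1, t2 = float(frame[0]), float(frame[1])
    dt = t2 - t1
    if dt <= 0:
        raise ValueError(f"frame ({t1}, {t2}) has non-positive duration")
    if lam < 0:
        raise ValueError("decay constant must be >= 0")
    if lam == 0.0:
        return 1.0
    x = lam * dt
    # -expm1(-x) = 1 - exp(-x), accurate for small x
    return x * math.exp(lam * (t1 - reference_time_s)) / (-math.expm1(-x))


def schedule_correction_factors(schedule: FrameSchedule, lam: float) -> np.ndarray:
    """Vector of decay-correction factors, one per frame."""
    return np.array(
        [
            frame_decay_correction_factor(f, lam, schedule.reference_time_s)
            for f in schedule.frames
        ]
    )


# ---------------------------------------------------------------------------
# configuration loaders

_DATA_DIR = Path(__file__).parent / "data"


def load_nuclide(path: str | Path | None = None) -> NuclideSpec:
    """Load a NuclideSpec from JSON; default is the bundled Rb-82 config."""
    p = Path(path) if path is not None else _DATA_DIR / "rb82.json"
    with open(p) as fh:
        cfg = json.load(fh)
    return NuclideSpec(**cfg)


def load_schedule(path: str | Path | None = None) -> FrameSchedule:
    """Load a FrameSchedule from JSON; default is the bundled 7-frame
    0-30-60-90-120-180-270-420 s schedule."""
    p = Path(path) if path is not None else _DATA_DIR / "quadra_7frame.json"
    with open(p) as fh:
        cfg = json.load(fh)
    if isinstance(cfg, list):  # bare list of [start, end]
        return FrameSchedule(frames=tuple(tuple(f) for f in cfg))
    return FrameSchedule(
        frames=tuple(tuple(f) for f in cfg["frames"]),
        reference_time_s=float(cfg.get("reference_time_s", 0.0)),
    )
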