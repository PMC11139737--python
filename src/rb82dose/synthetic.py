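"""Synthetic 7-frame dynamic PET studies with known ground-truth kinetics.

The generator emulates what the dosimetry pipeline actually consumes: an
integer organ label map and a 4-D stack of activity-concentration frames,
decay-corrected to scan start, with organ-wise biexponential biological
curves modulated by the 76-s physical decay of Rb-82 and (optionally)
Poisson noise.  Geometry is deliberately schematic (axis-aligned
ellipsoids/boxes in a body ellipsoid, at a reduced scale) -- the dosimetry
math never sees geometry, only voxel memberships and volumes.

Ground truth is returned alongside the images so that every downstream
estimator (TAC extraction, biexponential fitting, voxel trapezoid+tail
integration) can be checked against the exact integrals it tries to
estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .physics import (
    FrameSchedule,
    NuclideSpec,
    decay_constant,
    schedule_correction_factors,
)

__all__ = [
    "OrganKinetics",
    "LabelMap",
    "DynamicImage",
    "Component",
    "OrganSpec",
    "generate_phantom",
    "true_activity",
    "simulate_frames",
    "default_phantom",
    "single_organ_phantom",
    "noise_scale_for_cv",
    "DEFAULT_ORGAN_NAMES",
    "REMAINDER_NAME",
]

REMAINDER_NAME = "Total body (remainder)"

# The 11 segmented source organs carried through the study's TIA tables.
DEFAULT_ORGAN_NAMES = (
    "Adrenals",
    "Gallbladder content",
    "Stomach content",
    "Heart content",
    "Heart wall",
    "Kidneys",
    "Liver",
    "Lungs",
    "Spleen",
    "Thyroid",
    "Urinary bladder content",
)


@dataclass(frozen=True)
class OrganKinetics:
    """Ground-truth biological (decay-corrected) curve of one organ.

    c(t) = a1*exp(-mu1*t) + a2*exp(-mu2*t), in kBq/mL; a2 < 0 encodes
    uptake from zero.  The curve must be non-negative on [0, 420 s].
    """

    organ_id: int
    name: str
    a1: float
    a2: float
    mu1: float
    mu2: float
    volume_mL: float

    def __post_init__(self) -> None:
        if self.mu1 < 0 or self.mu2 < 0:
            raise ValueError("biological rates must be >= 0")
        if self.volume_mL <= 0:
            raise ValueError("organ volume must be > 0")
        t = np.linspace(0.0, 420.0, 841)
        c = self.concentration(t)
        if np.min(c) < -1e-9 * max(1.0, np.max(np.abs(c))):
            raise ValueError(f"kinetics of {self.name!r} go negative on [0, 420 s]")

    def concentration(self, t):
        """Biological (decay-corrected) concentration at time t [kBq/mL]."""
        t = np.asarray(t, dtype=float)
        return self.a1 * np.exp(-self.mu1 * t) + self.a2 * np.exp(-self.mu2 * t)

    def frame_average_corrected(self, schedule: FrameSchedule, lam: float) -> np.ndarray:
        """Exact decay-corrected frame values the scanner would report.

        Frame-average of the physical curve c(t)*exp(-lam*t), multiplied by
        the frame decay-correction factor -- closed form, no quadrature.
        """
        f = schedule_correction_factors(schedule, lam)
        avg = np.zeros(len(schedule))
        for amp, mu in ((self.a1, self.mu1), (self.a2, self.mu2)):
            k = mu + lam
            avg += amp * _exp_frame_average(k, schedule)
        return avg * f

    def tia_normalized_true(self, injected_MBq: float, lam: float) -> float:
        """Exact normalized TIA [MBq*h/MBq]: (V/A_inj) * sum a_i/(lam+mu_i),
        with kBq->MBq and s->h folded in."""
        total = self.a1 / (lam + self.mu1) + self.a2 / (lam + self.mu2)
        return total * self.volume_mL / 1000.0 / 3600.0 / injected_MBq


def _exp_frame_average(k: float, schedule: FrameSchedule) -> np.ndarray:
    """Frame averages of exp(-k t) over each frame (k >= 0)."""
    t1, dt = schedule.starts, schedule.durations
    if k == 0.0:
        return np.ones(len(schedule))
    x = k * dt
    return np.exp(-k * t1) * (-np.expm1(-x)) / x


def true_activity(kin: OrganKinetics, t, lam: float):
    """Physical (decaying) activity concentration at time t [kBq/mL]."""
    t = np.asarray(t, dtype=float)
    return kin.concentration(t) * np.exp(-lam * t)


@dataclass(frozen=True)
class LabelMap:
    """Integer organ segmentation; 0 = unlabeled background body."""

    voxels: np.ndarray  # 3-D int array
    legend: dict  # organ_id -> name, excludes 0
    voxel_size_mm: tuple[float, float, float]
    body_mask: np.ndarray | None = None  # 3-D bool; defaults to voxels > 0

    def __post_init__(self) -> None:
        ids = set(np.unique(self.voxels)) - {0}
        missing = set(self.legend) - ids
        if missing:
            raise ValueError(f"legend ids absent from label array: {sorted(missing)}")

    @property
    def voxel_volume_mL(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz / 1000.0

    def organ_mask(self, organ_id: int) -> np.ndarray:
        if organ_id == 0:
            body = self.body_mask if self.body_mask is not None else self.voxels > 0
            return body & (self.voxels == 0)
        return self.voxels == organ_id

    def organ_volume_mL(self, organ_id: int) -> float:
        return float(np.count_nonzero(self.organ_mask(organ_id))) * self.voxel_volume_mL


@dataclass(frozen=True)
class DynamicImage:
    """4-D activity-concentration frames (x, y, z, frame) in kBq/mL."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule
    decay_corrected: bool

    def __post_init__(self) -> None:
        if self.voxels.ndim != 4:
            raise ValueError("DynamicImage requires a 4-D array")
        if self.voxels.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame axis ({self.voxels.shape[3]}) does not match schedule "
                f"({len(self.schedule)} frames)"
            )

    @property
    def voxel_volume_mL(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz / 1000.0


# ---------------------------------------------------------------------------
# phantom geometry


@dataclass(frozen=True)
class Component:
    """One geometric building block of an organ."""

    shape: str  # "ellipsoid" | "box" | "shell"
    center: tuple[float, float, float]
    half: tuple[float, float, float]  # half-axes / half-sizes in voxels
    inner_half: tuple[float, float, float] | None = None  # for "shell"


@dataclass(frozen=True)
class OrganSpec:
    """Geometry plus kinetic shape of one phantom organ.

    ``plateau_fraction`` is the fraction of the injected activity this
    organ holds at its biological plateau; the generator converts it to a
    concentration amplitude using the organ's actual voxel volume.
    """

    organ_id: int
    name: str
    components: tuple[Component, ...]
    plateau_fraction: float
    mu1: float = 0.0
    mu2: float = 0.03


def _component_mask(comp: Component, grid_shape) -> np.ndarray:
    x, y, z = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    cx, cy, cz = comp.center
    hx, hy, hz = comp.half
    if comp.shape == "box":
        return (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy) & (np.abs(z - cz) <= hz)
    r2 = ((x - cx) / hx) ** 2 + ((y - cy) / hy) ** 2 + ((z - cz) / hz) ** 2
    if comp.shape == "ellipsoid":
        return r2 < 1.0
    if comp.shape == "shell":
        ix, iy, iz = comp.inner_half
        ri2 = ((x - cx) / ix) ** 2 + ((y - cy) / iy) ** 2 + ((z - cz) / iz) ** 2
        return (r2 < 1.0) & (ri2 >= 1.0)
    raise ValueError(f"unknown component shape {comp.shape!r}")


def generate_phantom(
    grid_shape: tuple[int, int, int],
    organ_specs: Sequence[OrganSpec],
    seed: int,
    *,
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
    injected_MBq: float = 407.0,
    body: Component | None = None,
    remainder_fraction: float = 0.72,
    remainder_mu2: float = 0.04,
    jitter: float = 0.08,
    activity_budget: float = 0.98,
) -> tuple[LabelMap, list[OrganKinetics]]:
    """Lay out organs on the grid and derive seeded ground-truth kinetics.

    Organ amplitudes are jittered per seed (lognormal, sigma = ``jitter``
    on amplitudes, 1.25*jitter on uptake rates) and then, if necessary,
    rescaled so that total body activity never exceeds
    ``activity_budget`` * injected activity (no excretion pathway exists
    at this half-life, so activity conservation is the only hard bound).

    Returns the label map (legend excludes background) and the kinetics
    list, which includes a final entry for the unsegmented body remainder
    (organ_id 0).
    """
    labels = np.zeros(grid_shape, dtype=np.int16)
    for spec in organ_specs:
        if spec.organ_id <= 0:
            raise ValueError("organ ids must be positive")
        mask = np.zeros(grid_shape, dtype=bool)
        for comp in spec.components:
            mask |= _component_mask(comp, grid_shape)
        if not mask.any():
            raise ValueError(f"organ {spec.name!r} covers no voxels")
        if (labels[mask] != 0).any():
            raise ValueError(f"organ {spec.name!r} overlaps a previously placed organ")
        labels[mask] = spec.organ_id

    if body is None:
        body = Component(
            "ellipsoid",
            tuple((s - 1) / 2.0 for s in grid_shape),
            tuple(0.97 * s / 2.0 for s in grid_shape),
        )
    body_mask = _component_mask(body, grid_shape) | (labels > 0)

    legend = {s.organ_id: s.name for s in organ_specs}
    lm = LabelMap(labels, legend, voxel_size_mm, body_mask=body_mask)

    rng = np.random.default_rng(seed)
    entries = list(organ_specs) + [
        OrganSpec(0, REMAINDER_NAME, (), remainder_fraction, 2e-4, remainder_mu2)
    ]
    fracs, mus = [], []
    for spec in entries:
        amp_f = float(np.exp(rng.normal(0.0, jitter)))
        rate_f = float(np.exp(rng.normal(0.0, 1.25 * jitter)))
        fracs.append(spec.plateau_fraction * amp_f)
        mus.append((spec.mu1, spec.mu2 * rate_f))
    total = sum(fracs)
    if total > activity_budget:
        fracs = [f * activity_budget / total for f in fracs]

    kinetics = []
    organ_total = sum(fracs[:-1])
    for spec, frac, (mu1, mu2) in zip(entries, fracs, mus):
        vol = lm.organ_volume_mL(spec.organ_id)
        if spec.organ_id == 0:
            # the remainder (blood/background pool) holds the injected bolus
            # at t=0 and washes out into the organs: total body activity is
            # then non-increasing after physical decay is restored
            a1 = frac * injected_MBq * 1000.0 / vol
            a2 = organ_total * injected_MBq * 1000.0 / vol
        else:
            a1 = frac * injected_MBq * 1000.0 / vol  # kBq/mL at plateau
            a2 = -a1
        kinetics.append(
            OrganKinetics(spec.organ_id, spec.name, a1, a2, mu1, mu2, vol)
        )
    return lm, kinetics


def simulate_frames(
    labelmap: LabelMap,
    kinetics: Sequence[OrganKinetics],
    schedule: FrameSchedule,
    nuclide: NuclideSpec,
    noise_scale: float = 0.0,
    seed: int | None = None,
) -> DynamicImage:
    """Render the 7-frame decay-corrected dynamic image.

    Each voxel/frame value is the exact frame average of the organ's
    physical activity, decay-corrected to scan start.  ``noise_scale`` is
    the expected count per (kBq/mL) per second of frame duration; counts
    are Poisson-drawn per voxel and rescaled back to concentration
    (a simplification of tomographic noise, adequate for estimator tests).
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    lam = decay_constant(nuclide)
    shape = labelmap.voxels.shape
    n_frames = len(schedule)
    img = np.zeros(shape + (n_frames,), dtype=float)
    for kin in kinetics:
        mask = labelmap.organ_mask(kin.organ_id)
        values = kin.frame_average_corrected(schedule, lam)
        img[mask, :] = values
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        durations = schedule.durations
        for k in range(n_frames):
            expected = img[..., k] * noise_scale * durations[k]
            img[..., k] = rng.poisson(expected) / (noise_scale * durations[k])
    np.clip(img, 0.0, None, out=img)
    return DynamicImage(img, labelmap.voxel_size_mm, schedule, decay_corrected=True)


def noise_scale_for_cv(
    kin: OrganKinetics,
    schedule: FrameSchedule,
    lam: float,
    n_voxels: int,
    target_cv: float = 0.05,
) -> float:
    """Noise scale giving a mean per-frame CV of ``target_cv`` for the
    organ-mean value of ``kin`` over ``n_voxels`` voxels.

    Per-voxel counts in frame k are Poisson with mean v_k*ns*dt_k, so the
    organ-mean CV is 1/sqrt(v_k*ns*dt_k*V); the scale is solved so the
    average CV across frames equals the target.
    """
    v = kin.frame_average_corrected(schedule, lam)
    dt = schedule.durations
    if np.any(v <= 0):
        raise ValueError("kinetics produce non-positive frame values")
    mean_inv = float(np.mean(1.0 / np.sqrt(v * dt * n_voxels)))
    return (mean_inv / target_cv) ** 2


# ---------------------------------------------------------------------------
# bundled phantoms

_STRESS_FACTORS = {
    # direction of rest->stress changes seen in the study's TIA table
    "Heart content": 1.08,
    "Heart wall": 1.15,
    "Liver": 1.15,
    "Kidneys": 0.90,
    "Spleen": 0.93,
    "Lungs": 0.90,
}


def _default_specs(condition: str) -> list[OrganSpec]:
    E, B, S = "ellipsoid", "box", "shell"
    base = [
        # (id, name, components, plateau fraction, mu1, mu2)
        (1, "Adrenals", [Component(E, (30, 24, 18), (2.2, 2.2, 2.2))], 0.0001, 0.0, 0.03),
        (2, "Gallbladder content", [Component(E, (18, 24, 18), (2.8, 2.8, 2.8))], 0.00016, 0.0, 0.02),
        (3, "Stomach content", [Component(E, (12, 30, 30), (5.0, 5.0, 5.0))], 0.009, 0.0, 0.02),
        (4, "Heart content", [Component(E, (24, 24, 44), (5.0, 5.0, 5.0))], 0.036, 3e-4, 0.05),
        (5, "Heart wall", [Component(S, (24, 24, 44), (7.0, 7.0, 7.0), (5.0, 5.0, 5.0))], 0.010, 0.0, 0.03),
        (6, "Kidneys", [Component(E, (13, 24, 14), (4.0, 4.0, 4.0)),
                        Component(E, (35, 24, 14), (4.0, 4.0, 4.0))], 0.033, 0.0, 0.035),
        (7, "Liver", [Component(B, (32, 24, 28), (10.0, 10.0, 6.0))], 0.045, 0.0, 0.025),
        (8, "Lungs", [Component(E, (13, 24, 56), (8.0, 8.0, 9.0)),
                      Component(E, (35, 24, 56), (8.0, 8.0, 9.0))], 0.075, 3e-4, 0.05),
        (9, "Spleen", [Component(E, (12, 16, 30), (4.5, 4.5, 4.5))], 0.009, 0.0, 0.04),
        (10, "Thyroid", [Component(E, (24, 24, 66), (3.2, 3.2, 3.2))], 0.0011, 0.0, 0.03),
        (11, "Urinary bladder content", [Component(E, (24, 24, 7), (3.8, 3.8, 3.8))], 0.0006, 0.0, 0.01),
    ]
    specs = []
    for oid, name, comps, frac, mu1, mu2 in base:
        if condition == "stress":
            frac *= _STRESS_FACTORS.get(name, 1.0)
        specs.append(OrganSpec(oid, name, tuple(comps), frac, mu1, mu2))
    return specs


def default_phantom(
    seed: int,
    *,
    injected_MBq: float = 407.0,
    condition: str = "rest",
    grid_shape: tuple[int, int, int] = (48, 48, 72),
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> tuple[LabelMap, list[OrganKinetics]]:
    """The bundled 11-organ study phantom (reduced-scale body).

    Organ plateau fractions mirror the relative source strengths of the
    study's TIA table (lungs and the unsegmented body dominate, the heart
    blood pool is concentrated); uptake rates give the rapid rise that
    stabilises after ~2 min seen in the measured TACs.
    """
    if condition not in ("rest", "stress"):
        raise ValueError("condition must be 'rest' or 'stress'")
    body = Component("ellipsoid", (23.5, 23.5, 35.5), (23.0, 23.0, 35.0))
    return generate_phantom(
        grid_shape,
        _default_specs(condition),
        seed,
        voxel_size_mm=voxel_size_mm,
        injected_MBq=injected_MBq,
        body=body,
    )


def single_organ_phantom(
    seed: int,
    *,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    injected_MBq: float = 400.0,
) -> tuple[LabelMap, list[OrganKinetics]]:
    """A one-organ phantom for estimator-recovery replicates.

    One ~640-voxel sphere with heart-wall-like uptake kinetics whose
    amplitude and rate are jittered per seed; the remainder holds the rest
    of the body activity.
    """
    spec = OrganSpec(
        1, "organ", (Component("ellipsoid", (11.5, 11.5, 11.5), (5.4, 5.4, 5.4)),),
        plateau_fraction=0.01, mu1=0.0, mu2=0.03,
    )
    return generate_phantom(
        grid_shape, [spec], seed,
        injected_MBq=injected_MBq, remainder_fraction=0.7,
    )
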