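"""Per-organ time-activity curves and decay-correction state management.

A TAC row is the arithmetic mean activity concentration over an organ's
labelled voxels in one frame.  The table tracks whether its values are
decay-corrected to scan start; the kinetic fit consumes corrected values
and the voxel branch consumes uncorrected (physical) values, so the
correction state is explicit and the conversions are involutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .physics import FrameSchedule
from .synthetic import DynamicImage, LabelMap, REMAINDER_NAME

__all__ = [
    "TACTable",
    "MissingOrganError",
    "extract_tacs",
    "whole_body_tac",
    "add_remainder",
    "uncorrect_decay",
    "recorrect_decay",
    "write_tac_csv",
    "read_tac_csv",
]

REMAINDER_ID = 0


class MissingOrganError(ValueError):
    pass


@dataclass(frozen=True)
class TACTable:
    """Per-organ, per-frame mean concentrations plus organ metadata.

    ``frame`` holds one row per (organ_id, frame_index) with the mean
    concentration in kBq/mL; ``organs`` holds one row per organ_id with
    name, volume_mL and density_g_per_mL (default 1.0).
    """

    frames: pd.DataFrame
    organs: pd.DataFrame  # index organ_id: organ, volume_mL, density_g_per_mL
    schedule: FrameSchedule
    decay_corrected: bool
    injected_MBq: float

    def __post_init__(self) -> None:
        if self.injected_MBq <= 0:
            raise ValueError("injected activity must be > 0")
        if (self.frames["mean_kBq_per_mL"] < 0).any():
            raise ValueError("mean concentrations must be >= 0")
        counts = self.frames.groupby("organ_id").size()
        if not (counts == len(self.schedule)).all():
            raise ValueError("every organ needs one row per frame")

    @property
    def organ_ids(self) -> list[int]:
        return list(self.organs.index)

    def organ_name(self, organ_id: int) -> str:
        return str(self.organs.loc[organ_id, "organ"])

    def organ_volume_mL(self, organ_id: int) -> float:
        return float(self.organs.loc[organ_id, "volume_mL"])

    def concentrations(self, organ_id: int) -> np.ndarray:
        sub = self.frames[self.frames["organ_id"] == organ_id]
        return sub.sort_values("frame_index")["mean_kBq_per_mL"].to_numpy()

    def activities_MBq(self, organ_id: int) -> np.ndarray:
        """Organ total activity per frame [MBq] = mean conc x volume."""
        return self.concentrations(organ_id) * self.organ_volume_mL(organ_id) / 1000.0


def extract_tacs(
    dynamic: DynamicImage,
    labels: LabelMap,
    injected_MBq: float,
    densities: dict[int, float] | None = None,
) -> TACTable:
    """Mean concentration per labelled organ per frame.

    Volumes come from voxel counts; the decay-corrected flag is inherited
    from the image.  Raises MissingOrganError for legend entries without
    voxels and a shape error for mismatched grids.
    """
    if dynamic.voxels.shape[:3] != labels.voxels.shape:
        raise ValueError(
            f"image grid {dynamic.voxels.shape[:3]} does not match label grid "
            f"{labels.voxels.shape}"
        )
    densities = densities or {}
    frame_rows, organ_rows = [], []
    starts, ends = dynamic.schedule.starts, dynamic.schedule.ends
    for organ_id, name in sorted(labels.legend.items()):
        mask = labels.organ_mask(organ_id)
        n = int(np.count_nonzero(mask))
        if n == 0:
            raise MissingOrganError(f"organ {name!r} (id {organ_id}) has no voxels")
        means = dynamic.voxels[mask, :].mean(axis=0)
        for k, m in enumerate(means):
            frame_rows.append(
                {
                    "organ_id": organ_id,
                    "organ": name,
                    "frame_index": k,
                    "frame_start_s": starts[k],
                    "frame_end_s": ends[k],
                    "mean_kBq_per_mL": float(m),
                }
            )
        organ_rows.append(
            {
                "organ_id": organ_id,
                "organ": name,
                "volume_mL": n * labels.voxel_volume_mL,
                "density_g_per_mL": densities.get(organ_id, 1.0),
            }
        )
    return TACTable(
        frames=pd.DataFrame(frame_rows),
        organs=pd.DataFrame(organ_rows).set_index("organ_id"),
        schedule=dynamic.schedule,
        decay_corrected=dynamic.decay_corrected,
        injected_MBq=injected_MBq,
    )


def whole_body_tac(dynamic: DynamicImage, body_mask: np.ndarray) -> np.ndarray:
    """Whole-body activity per frame [MBq] over the given body mask."""
    if body_mask.shape != dynamic.voxels.shape[:3]:
        raise ValueError("body mask grid does not match image grid")
    vol = dynamic.voxel_volume_mL
    return dynamic.voxels[body_mask, :].sum(axis=0) * vol / 1000.0


def add_remainder(
    tacs: TACTable,
    dynamic: DynamicImage,
    labels: LabelMap,
    body_mask: np.ndarray | None = None,
) -> TACTable:
    """Append the 'total body (remainder)' pseudo-organ.

    Its per-frame activity is whole-body activity minus the sum of
    segmented-organ activities (floored at zero; a deficit beyond 0.1% of
    the whole body raises an inconsistency warning before clamping).
    """
    if body_mask is None:
        if labels.body_mask is not None:
            body_mask = labels.body_mask
        else:
            body_mask = labels.voxels > 0
    wb = whole_body_tac(dynamic, body_mask)
    organ_sum = np.zeros_like(wb)
    organ_voxels = 0
    for organ_id in tacs.organ_ids:
        organ_sum += tacs.activities_MBq(organ_id)
        organ_voxels += int(np.count_nonzero(labels.organ_mask(organ_id)))
    remainder = wb - organ_sum
    deficit = remainder < -1e-3 * wb
    if deficit.any():
        warnings.warn(
            "remainder activity negative beyond tolerance in frames "
            f"{np.nonzero(deficit)[0].tolist()}; clamping to 0",
            stacklevel=2,
        )
    remainder = np.clip(remainder, 0.0, None)
    n_rem = int(np.count_nonzero(body_mask)) - organ_voxels
    # organs may tile the whole body: keep a nominal one-voxel volume so the
    # (then ~zero) remainder row stays well-defined
    vol_rem = max(n_rem, 1) * labels.voxel_volume_mL
    starts, ends = tacs.schedule.starts, tacs.schedule.ends
    rows = [
        {
            "organ_id": REMAINDER_ID,
            "organ": REMAINDER_NAME,
            "frame_index": k,
            "frame_start_s": starts[k],
            "frame_end_s": ends[k],
            "mean_kBq_per_mL": float(remainder[k] * 1000.0 / vol_rem),
        }
        for k in range(len(tacs.schedule))
    ]
    frames = pd.concat([tacs.frames, pd.DataFrame(rows)], ignore_index=True)
    organs = pd.concat(
        [
            tacs.organs,
            pd.DataFrame(
                [{"organ": REMAINDER_NAME, "volume_mL": vol_rem, "density_g_per_mL": 1.0}],
                index=pd.Index([REMAINDER_ID], name="organ_id"),
            ),
        ]
    )
    return replace(tacs, frames=frames, organs=organs)


def uncorrect_decay(tacs: TACTable, lam: float) -> TACTable:
    """Remove the to-scan-start decay correction (frame-internal correction
    is retained): each frame value is divided by exp(lam * midpoint)."""
    if not tacs.decay_corrected:
        raise ValueError("TAC table is already decay-uncorrected")
    mids = tacs.schedule.midpoints
    frames = tacs.frames.copy()
    factor = np.exp(-lam * mids[frames["frame_index"].to_numpy()])
    frames["mean_kBq_per_mL"] = frames["mean_kBq_per_mL"].to_numpy() * factor
    return replace(tacs, frames=frames, decay_corrected=False)


def recorrect_decay(tacs: TACTable, lam: float) -> TACTable:
    """Inverse of :func:`uncorrect_decay`."""
    if tacs.decay_corrected:
        raise ValueError("TAC table is already decay-corrected")
    mids = tacs.schedule.midpoints
    frames = tacs.frames.copy()
    factor = np.exp(lam * mids[frames["frame_index"].to_numpy()])
    frames["mean_kBq_per_mL"] = frames["mean_kBq_per_mL"].to_numpy() * factor
    return replace(tacs, frames=frames, decay_corrected=True)


def write_tac_csv(tacs: TACTable, path) -> None:
    df = tacs.frames.merge(
        tacs.organs[["volume_mL"]], left_on="organ_id", right_index=True
    )
    df["decay_corrected"] = tacs.decay_corrected
    df["injected_MBq"] = tacs.injected_MBq
    cols = [
        "organ_id", "organ", "frame_start_s", "frame_end_s",
        "mean_kBq_per_mL", "volume_mL", "decay_corrected", "injected_MBq",
    ]
    df[cols].to_csv(path, index=False)


def read_tac_csv(path) -> TACTable:
    df = pd.read_csv(path)
    frames = df[["organ_id", "organ", "frame_start_s", "frame_end_s", "mean_kBq_per_mL"]].copy()
    frames["frame_index"] = frames.groupby("organ_id").cumcount()
    organs = (
        df.groupby("organ_id")
        .agg(organ=("organ", "first"), volume_mL=("volume_mL", "first"))
        .assign(density_g_per_mL=1.0)
    )
    first = df[df["organ_id"] == df["organ_id"].iloc[0]]
    schedule = FrameSchedule(
        frames=tuple(zip(first["frame_start_s"], first["frame_end_s"]))
    )
    return TACTable(
        frames=frames,
        organs=organs,
        schedule=schedule,
        decay_corrected=bool(df["decay_corrected"].iloc[0]),
        injected_MBq=float(df["injected_MBq"].iloc[0]),
    )
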