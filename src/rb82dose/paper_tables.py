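"""Loaders for the bundled study tables (transcribed reference results).

These CSVs carry the published per-subject TIA, organ-dose and
effective-dose values for the three rest/stress Rb-82 examinations; they
drive the summary statistics and serve as comparison fixtures.  Absolute
organ doses cannot be recomputed here (the reference-phantom S-values
behind them are proprietary), so these tables are inputs, not outputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mird import DoseReport

_DIR = Path(__file__).parent / "data" / "paper_tables"

SUBJECTS = ("p1", "p2", "p3")
CONDITIONS = ("rest", "stress")


def load_subjects() -> pd.DataFrame:
    """Subject characteristics and injected activities (rest/stress)."""
    return pd.read_csv(_DIR / "table1_subjects.csv")


def load_tia_table() -> pd.DataFrame:
    """Normalized TIA [MBq*h/MBq] per source organ and examination,
    including the reference-biokinetics comparison column."""
    return pd.read_csv(_DIR / "table2_tia.csv")


def load_mird_doses() -> pd.DataFrame:
    """Normalized absorbed organ doses [uGy/MBq], MIRD/reference-phantom
    path; NA cells are sex-specific organs."""
    return pd.read_csv(_DIR / "table3_doses.csv")


def load_voxel_doses() -> pd.DataFrame:
    """Normalized organ doses [uGy/MBq] from the voxel-dosimetry path."""
    return pd.read_csv(_DIR / "table4_voxel_doses.csv")


def load_effective_doses() -> pd.DataFrame:
    """Normalized total-body effective dose [uSv/MBq] per examination."""
    return pd.read_csv(_DIR / "table5_effective.csv")


def tia_column(column: str) -> pd.Series:
    """One TIA column (e.g. 'p1_rest' or 'icrp128') as organ -> value."""
    df = load_tia_table()
    return df.set_index("source_organ")[column].dropna()


def _reports(df: pd.DataFrame, organ_col: str, phantom: str) -> list[DoseReport]:
    out = []
    for subj in SUBJECTS:
        for cond in CONDITIONS:
            col = f"{subj}_{cond}"
            doses = df.set_index(organ_col)[col]
            out.append(
                DoseReport(doses, phantom_id=phantom, subject=subj.upper(), condition=cond)
            )
    return out


def mird_dose_reports() -> list[DoseReport]:
    """Six per-examination dose reports from the MIRD-path table."""
    return _reports(load_mird_doses(), "target_organ", "reference_mird")


def voxel_dose_reports() -> list[DoseReport]:
    """Six per-examination dose reports from the voxel-path table."""
    return _reports(load_voxel_doses(), "target_organ", "reference_voxel")


def effective_dose_values() -> dict[tuple[str, str], float]:
    """(subject, condition) -> effective dose [uSv/MBq]."""
    row = load_effective_doses().iloc[0]
    return {
        (s.upper(), c): float(row[f"{s}_{c}"]) for s in SUBJECTS for c in CONDITIONS
    }
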