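"""MIRD-schema organ doses, ICRP-103 effective dose and summary statistics.

The absorbed dose to a target organ is D(r_T) = sum_S A~(r_S) * S(r_T <- r_S)
with A~ the normalized time-integrated activity [MBq*h/MBq] and S the
phantom-specific dose per unit cumulated activity [mGy/(MBq*h)].  S-value
tables are pluggable: a CSV loader handles open phantom exports, a toy
fixture serves exact tests, and a self-consistent synthetic table can be
generated from organ masses for end-to-end demonstrations (proprietary
reference-phantom S-values are deliberately not bundled).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SValueTable",
    "DoseReport",
    "TissueWeights",
    "OrganMappingError",
    "load_svalues",
    "synthetic_svalue_table",
    "organ_doses",
    "load_tissue_weights",
    "effective_dose",
    "rest_stress_relative_difference",
    "dose_range_summary",
    "normalize_organ_name",
]

_DATA_DIR = Path(__file__).parent / "data"

MEV_TO_J = 1.602e-13
DECAYS_PER_MBQ_H = 3.6e9


class OrganMappingError(KeyError):
    pass


def normalize_organ_name(name: str) -> str:
    return "_".join(str(name).strip().lower().split())


# variant spellings -> canonical S-table vocabulary
SOURCE_ALIASES = {
    "heart_content": "heart_contents",
    "urinary_bladder_content": "urinary_bladder_contents",
    "urinary_bladder": "urinary_bladder_contents",
    "stomach_content": "stomach_contents",
    "stomach": "stomach_contents",
    "gallbladder_content": "gallbladder_contents",
    "gallbladder": "gallbladder_contents",
    "total_body_(remainder)": "total_body",
    "remainder": "total_body",
    "rest_of_body": "total_body",
    "lung": "lungs",
}


def resolve_organ_name(name: str, vocabulary=None) -> str:
    """Canonical organ key; if a vocabulary is given, the raw normalized
    form is kept whenever the alias target is absent from it."""
    norm = normalize_organ_name(name)
    canon = SOURCE_ALIASES.get(norm, norm)
    if vocabulary is not None:
        if canon in vocabulary:
            return canon
        if norm in vocabulary:
            return norm
        raise OrganMappingError(
            f"organ {name!r} (normalized {norm!r}) not found in S-value vocabulary"
        )
    return canon


@dataclass(frozen=True)
class SValueTable:
    """(source, target) -> S [mGy per MBq*h] for one phantom."""

    phantom_id: str
    entries: dict  # (source, target) normalized -> float

    def __post_init__(self) -> None:
        for (s, t), v in self.entries.items():
            if v < 0:
                raise ValueError(f"negative S-value for ({s}, {t})")
        for t in self.targets:
            self_s = self.entries.get((t, t))
            if self_s is None:
                continue
            for s in self.sources:
                cross = self.entries.get((s, t))
                if s != t and cross is not None and cross > self_s:
                    warnings.warn(
                        f"cross-dose S({t}<-{s}) exceeds self-dose S({t}<-{t}); "
                        "physically suspicious table",
                        stacklevel=2,
                    )

    @property
    def sources(self) -> set:
        return {s for s, _ in self.entries}

    @property
    def targets(self) -> set:
        return {t for _, t in self.entries}

    def get(self, source: str, target: str) -> float:
        s = resolve_organ_name(source, self.sources)
        t = resolve_organ_name(target, self.targets)
        return self.entries[(s, t)]


def load_svalues(csv_path) -> SValueTable:
    """Load a CSV with header ``phantom,source,target,s_mGy_per_MBq_h``."""
    df = pd.read_csv(csv_path)
    required = {"phantom", "source", "target", "s_mGy_per_MBq_h"}
    if not required.issubset(df.columns):
        raise ValueError(f"S-value CSV must have columns {sorted(required)}")
    phantom = str(df["phantom"].iloc[0])
    entries = {}
    for _, row in df.iterrows():
        key = (normalize_organ_name(row["source"]), normalize_organ_name(row["target"]))
        if key in entries:
            raise ValueError(f"duplicate S-value entry for {key}")
        s = float(row["s_mGy_per_MBq_h"])
        if s < 0:
            raise ValueError(f"negative S-value for {key}")
        entries[key] = s
    return SValueTable(phantom, entries)


def synthetic_svalue_table(
    organ_masses_g: dict[str, float],
    mean_energy_per_decay_MeV: float,
    body_mass_g: float,
    *,
    cross_fraction: float = 0.02,
    phantom_id: str = "synthetic_local",
) -> SValueTable:
    """Generate a SYNTHETIC, physically self-consistent S-value table.

    Each organ absorbs (1 - cross_fraction) of its own decay energy
    locally, while cross_fraction of every source's energy is spread
    uniformly over the whole body; the unsegmented remainder appears as
    the source/target ``total_body``.  This is a stand-in for
    reference-phantom S-values (which are proprietary), intended for
    demonstrations and internal consistency checks, not for clinical use.
    """
    k = DECAYS_PER_MBQ_H * mean_energy_per_decay_MeV * MEV_TO_J  # J per MBq*h
    uniform = 1000.0 * cross_fraction * k / (body_mass_g / 1000.0)  # mGy/MBq*h
    entries = {}
    names = [normalize_organ_name(n) for n in organ_masses_g]
    masses = {normalize_organ_name(n): m for n, m in organ_masses_g.items()}
    all_sources = names + ["total_body"]
    for s in all_sources:
        for t in names:
            local = 0.0
            if s == t:
                local = 1000.0 * (1.0 - cross_fraction) * k / (masses[t] / 1000.0)
            entries[(s, t)] = local + uniform
        # mass-averaged whole-body target row
        entries[(s, "total_body")] = 1000.0 * k / (body_mass_g / 1000.0)
    return SValueTable(phantom_id, entries)


@dataclass(frozen=True)
class DoseReport:
    """Normalized absorbed doses per target organ [uGy/MBq]."""

    doses: pd.Series  # index: target organ names
    phantom_id: str = ""
    subject: str = ""
    condition: str = ""  # "rest" | "stress"

    def __post_init__(self) -> None:
        if (self.doses.dropna() < 0).any():
            raise ValueError("absorbed doses must be >= 0")

    def get(self, organ: str) -> float:
        norm = {normalize_organ_name(k): k for k in self.doses.index}
        key = normalize_organ_name(organ)
        key = SOURCE_ALIASES.get(key, key) if key not in norm else key
        if key not in norm:
            raise OrganMappingError(f"organ {organ!r} absent from dose report")
        val = self.doses[norm[key]]
        if pd.isna(val):
            raise OrganMappingError(f"organ {organ!r} is NA in dose report")
        return float(val)

    def has(self, organ: str) -> bool:
        try:
            self.get(organ)
            return True
        except OrganMappingError:
            return False


def organ_doses(tia, svalues: SValueTable, **metadata) -> DoseReport:
    """MIRD sum over sources: dose [uGy/MBq] = sum TIA * S * 1000.

    ``tia`` is a TIATable or a Series organ -> MBq*h/MBq.  Every source
    (including the remainder row, mapped to the table's ``total_body``
    source) must resolve in the S-table; unresolved sources raise an
    explicit mapping error rather than being dropped.
    """
    series = tia.series() if hasattr(tia, "series") else pd.Series(tia)
    resolved = {}
    for organ, value in series.items():
        try:
            src = resolve_organ_name(organ, svalues.sources)
        except OrganMappingError as err:
            if normalize_organ_name(organ).startswith("total_body"):
                raise ValueError(
                    "S-value table has no remainder/total_body source row; "
                    "refusing to silently drop the remainder TIA"
                ) from err
            raise
        resolved[src] = resolved.get(src, 0.0) + float(value)
    targets = sorted(svalues.targets)
    doses = {}
    for t in targets:
        total = 0.0
        for src in sorted(resolved):  # sorted accumulation: order-stable
            s_val = svalues.entries.get((src, t))
            if s_val is None:
                raise OrganMappingError(
                    f"S-value table {svalues.phantom_id!r} lacks entry ({src}, {t})"
                )
            total += resolved[src] * s_val
        doses[t] = total * 1000.0  # mGy/MBq -> uGy/MBq
    return DoseReport(pd.Series(doses), phantom_id=svalues.phantom_id, **metadata)


# ---------------------------------------------------------------------------
# effective dose (ICRP 103 tissue weighting)

# weight-table organ -> candidate report organs (mean over those present)
_WEIGHT_CANDIDATES = {
    "red_marrow": ["red marrow"],
    "colon": ["left colon", "right colon"],
    "lung": ["lungs", "lung"],
    "stomach_wall": ["stomach wall", "stomach content"],
    "breasts": ["breasts"],
    "gonads": ["ovaries", "testes"],
    "urinary_bladder_wall": ["urinary bladder wall", "urinary bladder content"],
    "esophagus": ["esophagus"],
    "liver": ["liver"],
    "thyroid": ["thyroid"],
    "bone_surface": ["osteogenic cells", "bone surface"],
    "brain": ["brain"],
    "salivary_glands": ["salivary glands"],
    "skin": ["skin"],
}

# ICRP 103 remainder tissues -> candidate report organs
_REMAINDER_CANDIDATES = [
    ["adrenals"],
    ["extrathoracic region"],
    ["gallbladder wall", "gallbladder content"],
    ["heart wall"],
    ["kidneys"],
    ["lymphatic nodes"],
    ["muscle"],
    ["oral mucosa"],
    ["pancreas"],
    ["prostate"],
    ["small intestine wall"],
    ["spleen"],
    ["thymus"],
    ["uterus"],
]


@dataclass(frozen=True)
class TissueWeights:
    """ICRP 103 tissue weighting factors; must sum to exactly 1."""

    weights: dict  # normalized organ -> w_T (includes "remainder")

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"tissue weights sum to {total}, expected 1.0")


def load_tissue_weights(path=None) -> TissueWeights:
    p = Path(path) if path is not None else _DATA_DIR / "icrp103_weights.csv"
    df = pd.read_csv(p)
    return TissueWeights(
        {normalize_organ_name(r["organ"]): float(r["w_T"]) for _, r in df.iterrows()}
    )


def _mean_present(report: DoseReport, candidates) -> float | None:
    vals = [report.get(c) for c in candidates if report.has(c)]
    return float(np.mean(vals)) if vals else None


def effective_dose(
    report: DoseReport,
    weights: TissueWeights,
    radiation_weighting: float = 1.0,
) -> float:
    """E = sum_T w_T * H_T [uSv/MBq], H_T = dose * radiation weighting.

    Remainder tissues are averaged over those present (ICRP 103 rule);
    named tissues absent from the report contribute 0 with a warning.
    """
    total = 0.0
    for organ, w in weights.weights.items():
        if organ == "remainder":
            vals = [
                v for cand in _REMAINDER_CANDIDATES
                if (v := _mean_present(report, cand)) is not None
            ]
            if vals:
                total += w * float(np.mean(vals)) * radiation_weighting
            else:
                warnings.warn("no remainder tissues present; remainder contributes 0")
            continue
        cand = _WEIGHT_CANDIDATES.get(organ, [organ.replace("_", " ")])
        h = _mean_present(report, cand)
        if h is None:
            warnings.warn(f"tissue {organ!r} absent from report; contributes 0")
            continue
        total += w * h * radiation_weighting
    return total


def rest_stress_relative_difference(rest_value: float, stress_value: float) -> float:
    """100 * (rest - stress) / stress, rounded to 1 decimal."""
    if stress_value <= 0:
        raise ValueError("stress value must be > 0")
    return round(100.0 * (rest_value - stress_value) / stress_value, 1)


def dose_range_summary(reports, organ: str) -> tuple[float, float]:
    """(min, max) absorbed dose for one organ across subject/condition
    reports; reports where the organ is NA or absent are skipped."""
    values = [r.get(organ) for r in reports if r.has(organ)]
    if not values:
        raise OrganMappingError(f"organ {organ!r} absent from all reports")
    return (min(values), max(values))
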