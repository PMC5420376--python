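"""Composite laxity metrics and per-subject analysis records.

The central quantity is the Joint Play Envelope (JPE): total leg rotation
(degrees) multiplied by the KT-1000 anterior translation at manual-maximum
force (mm), giving mm·deg.  Combining the rotational and translational
envelopes into one number captures the three-dimensional play of the limb
that neither measure reflects alone.  JPE is computed limb-wise: the rotation
and the KT value belong to the same limb.

Satisfaction grouping follows the VAS rules: Group 1 (higher satisfaction)
VAS >= 80, Group 2 (lower satisfaction) 50 < VAS < 80, Group 3 (outliers)
VAS < 50.  A VAS of exactly 50 falls in the gap left by the strict
inequalities; it is assigned to Group 3 by default (the gap is closed
downward, since Group 2's lower bound is strict) and the choice is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import CurveFeatures

__all__ = [
    "JPEValue",
    "SubjectRecord",
    "joint_play_envelope",
    "assign_group",
    "side_to_side_difference",
    "build_analysis_table",
    "assemble_subjects",
]

ANALYSIS_COLUMNS = [
    "subject_id",
    "limb",
    "total_rot_deg",
    "kt_manmax_mm",
    "jpe_mmdeg",
    "vas",
    "group",
]


@dataclass(frozen=True)
class JPEValue:
    """Joint Play Envelope with its audit components."""

    value: float          # mm * deg
    total_rotation: float  # deg
    kt_manmax: float       # mm


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's assembled analysis record."""

    subject_id: str
    features: dict            # limb status -> CurveFeatures
    kt: dict                  # limb status -> {force label -> mm}
    vas: float
    group: int
    pivot_shift_grade: dict = field(default_factory=dict)
    lachman_grade: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.vas <= 100:
            raise ValueError("VAS out of [0, 100]")
        for limb, forces in self.kt.items():
            vals = [forces[k] for k in ("kt_67", "kt_89", "kt_133", "kt_manmax")
                    if k in forces]
            if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"KT values for {self.subject_id}/{limb} not nondecreasing in force"
                )


def joint_play_envelope(total_rotation: float, kt_manmax: float) -> JPEValue:
    """JPE = total leg rotation (deg) x KT manual-maximum translation (mm)."""
    if not (np.isfinite(total_rotation) and np.isfinite(kt_manmax)):
        raise ValueError("JPE components must be finite")
    if total_rotation < 0 or kt_manmax < 0:
        raise ValueError("laxity magnitudes are nonnegative")
    return JPEValue(
        value=total_rotation * kt_manmax,
        total_rotation=total_rotation,
        kt_manmax=kt_manmax,
    )


def assign_group(vas: float, vas50_group: int = 3) -> int:
    """Satisfaction group from the VAS score.

    >= 80 -> Group 1; strictly between 50 and 80 -> Group 2; < 50 ->
    Group 3.  Exactly 50 goes to ``vas50_group`` (default 3).
    """
    if not np.isfinite(vas) or not 0 <= vas <= 100:
        raise ValueError(f"VAS must lie in [0, 100], got {vas!r}")
    if vas >= 80:
        return 1
    if vas > 50:
        return 2
    if vas < 50:
        return 3
    if vas50_group not in (2, 3):
        raise ValueError("vas50_group must be 2 or 3")
    return vas50_group


def side_to_side_difference(reconstructed: float, healthy: float) -> float:
    """Signed reconstructed-minus-healthy difference of a per-limb measure.

    Both values must be the same measurement (mm with mm, degrees with
    degrees); the function is unit-agnostic but rejects non-finite input.
    """
    if not (np.isfinite(reconstructed) and np.isfinite(healthy)):
        raise ValueError("side-to-side difference needs finite inputs")
    return reconstructed - healthy


def _kt_manmax_value(row: pd.Series, examiner_policy: str) -> float:
    """KT manual max, averaging two examiner columns when present.

    ``examiner_policy``: "mean" averages kt_manmax and kt_manmax_2 when the
    second examiner's column exists; "first" uses kt_manmax alone.
    """
    if examiner_policy == "mean" and "kt_manmax_2" in row.index and np.isfinite(
        row.get("kt_manmax_2", np.nan)
    ):
        return 0.5 * (row["kt_manmax"] + row["kt_manmax_2"])
    return row["kt_manmax"]


def build_analysis_table(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    examiner_policy: str = "mean",
    vas50_group: int = 3,
) -> pd.DataFrame:
    """Join the cohort and features tables into the per-limb analysis table.

    Emits one row per limb with the JPE and its components, the VAS and the
    VAS-derived group (recomputed from the score; a stored group column in
    the cohort table is validated against it).
    """
    if examiner_policy not in ("mean", "first"):
        raise ValueError("examiner_policy must be 'mean' or 'first'")
    merged = cohort.merge(features, on=["subject_id", "limb"], validate="1:1")
    rows = []
    for _, row in merged.iterrows():
        group = assign_group(row["vas"], vas50_group=vas50_group)
        if "group" in row.index and int(row["group"]) != group:
            raise ValueError(
                f"stored group {row['group']} inconsistent with VAS "
                f"{row['vas']} for {row['subject_id']}"
            )
        kt = _kt_manmax_value(row, examiner_policy)
        jpe = joint_play_envelope(row["total_rot_deg"], kt)
        rows.append(
            {
                "subject_id": row["subject_id"],
                "limb": row["limb"],
                "total_rot_deg": jpe.total_rotation,
                "kt_manmax_mm": jpe.kt_manmax,
                "jpe_mmdeg": jpe.value,
                "vas": row["vas"],
                "group": group,
            }
        )
    return pd.DataFrame(rows, columns=ANALYSIS_COLUMNS)


def assemble_subjects(
    cohort: pd.DataFrame,
    features_by_limb: dict,
    vas50_group: int = 3,
) -> list[SubjectRecord]:
    """Build SubjectRecord objects from the cohort table and extracted features.

    ``features_by_limb`` maps (subject_id, limb) -> CurveFeatures.
    """
    records = []
    for sid, grp in cohort.groupby("subject_id", sort=True):
        feats: dict[str, CurveFeatures] = {}
        kt: dict[str, dict] = {}
        pivot: dict[str, int] = {}
        lachman: dict[str, int] = {}
        vas = float(grp["vas"].iloc[0])
        for _, row in grp.iterrows():
            limb = row["limb"]
            feats[limb] = features_by_limb[(sid, limb)]
            kt[limb] = {
                k: float(row[k]) for k in ("kt_67", "kt_89", "kt_133", "kt_manmax")
            }
            pivot[limb] = int(row.get("pivot_shift_grade", 0))
            lachman[limb] = int(row.get("lachman_grade", 0))
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                features=feats,
                kt=kt,
                vas=vas,
                group=assign_group(vas, vas50_group=vas50_group),
                pivot_shift_grade=pivot,
                lachman_grade=lachman,
            )
        )
    return records
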