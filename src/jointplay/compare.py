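"""Group and limb comparisons of laxity features and full curves.

Two designs mirror the study's analysis plan: paired comparisons between the
reconstructed and healthy limbs of the same subjects, and unpaired
comparisons between limbs of the higher- and lower-satisfaction groups.
Unpaired tests use the Welch (unequal-variance) form, appropriate for the
small, unequal group sizes.  Whole load-deformation curves are compared by
registering each limb's branch onto a common torque grid (the protocol is
torque-limited, so torque is the natural registration axis) and running a
pointwise t test per grid point — uncorrected by default, with an optional
Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curves import RotationRecording

__all__ = [
    "ComparisonResult",
    "RegisteredCurveSet",
    "compare_feature",
    "register_curves",
    "pointwise_t",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One two-arm comparison: means, mean difference (a - b), two-sided p."""

    name: str
    design: str  # "paired" | "unpaired"
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    mean_difference: float
    t_statistic: float
    p_value: float
    flags: tuple = ()


def compare_feature(
    values_a,
    values_b,
    design: str,
    name: str = "",
) -> ComparisonResult:
    """Compare a feature between two arms.

    ``design="paired"`` runs a paired t test (arms must be equal-length,
    ordered by subject); ``design="unpaired"`` runs Welch's two-sample
    t test.  Zero variance in both arms leaves p undefined (NaN, flagged);
    identical arms in a paired design likewise flag a degenerate p.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values in comparison arms")
    if design == "paired" and a.size != b.size:
        raise ValueError("paired design requires complete pairs")
    if min(a.size, b.size) < 2:
        raise ValueError("each arm needs at least 2 observations")

    flags: list = []
    if design == "paired":
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            t_stat, p = np.nan, np.nan
            flags.append("zero variance of paired differences; p undefined")
        else:
            t_stat, p = stats.ttest_rel(a, b)
    else:
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            t_stat, p = np.nan, np.nan
            flags.append("zero variance in both arms; p undefined")
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        name=name,
        design=design,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_difference=float(a.mean() - b.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class RegisteredCurveSet:
    """Per-limb angles interpolated onto a common torque grid (one branch)."""

    torque_grid: np.ndarray          # Nm, strictly increasing
    angles: np.ndarray               # (n_limbs, n_grid) degrees
    limb_ids: tuple                  # (subject_id, limb) per row
    branch_direction: int            # +1 loading toward ER, -1 toward IR

    def __post_init__(self) -> None:
        grid = np.asarray(self.torque_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
            raise ValueError("torque grid must be strictly increasing")
        if self.angles.shape != (len(self.limb_ids), grid.size):
            raise ValueError("angles shape inconsistent with grid/limb ids")

    @property
    def n_limbs(self) -> int:
        return len(self.limb_ids)


def register_curves(
    recordings: list[RotationRecording],
    torque_grid,
    branch_direction: int = 1,
) -> RegisteredCurveSet:
    """Interpolate each limb's branch angle onto a common torque grid.

    Within the requested direction branch, the samples are sorted by torque
    and the angle is linearly interpolated at each grid torque.  A limb
    whose branch does not span the grid is excluded with a warning.
    """
    grid = np.asarray(torque_grid, dtype=float)
    rows = []
    ids = []
    for rec in recordings:
        sel = rec.direction == branch_direction
        if sel.sum() < 2:
            warnings.warn(
                f"{rec.subject_id}/{rec.limb_status}: branch missing; excluded",
                stacklevel=2,
            )
            continue
        torque = rec.torque_nm[sel]
        angle = rec.angle_deg[sel]
        order = np.argsort(torque, kind="stable")
        torque, angle = torque[order], angle[order]
        if torque[0] > grid[0] or torque[-1] < grid[-1]:
            warnings.warn(
                f"{rec.subject_id}/{rec.limb_status}: branch covers "
                f"[{torque[0]:.3g}, {torque[-1]:.3g}] Nm, not the grid "
                f"[{grid[0]:.3g}, {grid[-1]:.3g}]; excluded",
                stacklevel=2,
            )
            continue
        rows.append(np.interp(grid, torque, angle))
        ids.append((rec.subject_id, rec.limb_status))
    if not rows:
        raise ValueError("no recording covers the requested torque grid")
    return RegisteredCurveSet(
        torque_grid=grid,
        angles=np.vstack(rows),
        limb_ids=tuple(ids),
        branch_direction=branch_direction,
    )


def common_torque_grid(
    recordings: list[RotationRecording],
    branch_direction: int = 1,
    n_points: int = 30,
    trim: float = 0.01,
) -> np.ndarray:
    """A torque grid covered by every limb's branch: the intersection of the
    branch torque ranges, trimmed by ``trim`` of its width at both ends."""
    lo = -np.inf
    hi = np.inf
    for rec in recordings:
        sel = rec.direction == branch_direction
        torque = rec.torque_nm[sel]
        lo = max(lo, torque.min())
        hi = min(hi, torque.max())
    if not lo < hi:
        raise ValueError("recordings share no common torque range")
    width = hi - lo
    return np.linspace(lo + trim * width, hi - trim * width, n_points)


def pointwise_t(
    set_a: RegisteredCurveSet,
    set_b: RegisteredCurveSet,
    correction: str | None = None,
) -> pd.DataFrame:
    """Unpaired two-sided Welch t test of angle at every grid torque.

    Returns a frame with one row per grid point: torque, per-arm means,
    difference, t, p (and p_adjusted under Bonferroni).  Points where an
    arm has fewer than 2 limbs, or where both arms are constant, carry NaN
    p and a flag.
    """
    if correction not in (None, "bonferroni"):
        raise ValueError("correction must be None or 'bonferroni'")
    if set_a.torque_grid.shape != set_b.torque_grid.shape or not np.allclose(
        set_a.torque_grid, set_b.torque_grid
    ):
        raise ValueError("curve sets are registered on different grids")
    rows = []
    m = set_a.torque_grid.size
    for j, torque in enumerate(set_a.torque_grid):
        a = set_a.angles[:, j]
        b = set_b.angles[:, j]
        flag = ""
        if a.size < 2 or b.size < 2:
            t_stat, p = np.nan, np.nan
            flag = "arm too small"
        elif np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
            t_stat = np.nan
            p = 1.0 if np.isclose(a.mean(), b.mean()) else np.nan
            flag = "zero variance"
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "torque_nm": float(torque),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "diff": float(a.mean() - b.mean()),
                "t": float(t_stat),
                "p": float(p),
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p"] * m)
    return out
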