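"""Load-deformation curve representation and feature extraction.

A torque-limited axial-rotation test produces a hysteresis loop in the
torque-angle plane: the limb is rotated toward external rotation (ER) until
the torque limit is reached, reversed toward internal rotation (IR) until the
opposite limit, and rotated back.  This module segments such a recording into
its loading/unloading branches and extracts the standard laxity features:

* maximum external rotation (deg),
* maximum internal rotation (deg, reported as a magnitude),
* rotational position at 0 Nm of torque (midpoint of the two zero crossings),
* play at 0 Nm (width of the hysteresis loop at zero torque),
* endpoint slope (Nm/deg), a least-squares stiffness over the last 10 % of the
  rotation range approaching each reversal,
* total leg rotation = max ER + max IR.

Sign convention: external rotation positive, internal rotation negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RotationRecording",
    "CurveFeatures",
    "FeatureConfig",
    "Branches",
    "segment_branches",
    "extract_features",
    "total_leg_rotation",
    "normalized_endpoint_slope",
    "write_recordings_csv",
    "read_recordings_csv",
    "features_frame",
]


class FeatureExtractionWarning(UserWarning):
    """Raised when a feature had to be computed under a degraded rule."""


@dataclass(frozen=True)
class RotationRecording:
    """One full hysteresis cycle of a single limb.

    ``direction`` is +1 while the motor drives toward external rotation and
    -1 while it drives toward internal rotation.  Samples are in acquisition
    order; angles are device angles in degrees, torques in Nm.
    """

    subject_id: str
    limb_status: str  # "reconstructed" | "healthy"
    angle_deg: np.ndarray
    torque_nm: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        angle = np.asarray(self.angle_deg, dtype=float)
        torque = np.asarray(self.torque_nm, dtype=float)
        direction = np.asarray(self.direction, dtype=int)
        object.__setattr__(self, "angle_deg", angle)
        object.__setattr__(self, "torque_nm", torque)
        object.__setattr__(self, "direction", direction)
        if self.limb_status not in ("reconstructed", "healthy"):
            raise ValueError(f"unknown limb_status {self.limb_status!r}")
        if not (angle.shape == torque.shape == direction.shape):
            raise ValueError("angle, torque and direction must be equal length")
        if angle.size < 20:
            raise ValueError(f"recording too short ({angle.size} samples, need >= 20)")
        if not (np.isfinite(angle).all() and np.isfinite(torque).all()):
            raise ValueError("non-finite samples in recording")
        if not set(np.unique(direction)) <= {-1, 1}:
            raise ValueError("direction flags must be +1 or -1")
        if not ((direction == 1).any() and (direction == -1).any()):
            raise ValueError("recording must contain both motion directions")

    @property
    def n_samples(self) -> int:
        return int(self.angle_deg.size)

    def shifted(self, offset_deg: float) -> "RotationRecording":
        """Same recording with a rigid rotation offset added to all angles."""
        return replace(self, angle_deg=self.angle_deg + offset_deg)


@dataclass(frozen=True)
class CurveFeatures:
    """The extracted load-deformation features of one limb.

    ``max_internal_rotation`` is stored as a magnitude (positive degrees);
    the signed IR extreme is ``-max_internal_rotation``.
    ``total_rotation == max_external_rotation + max_internal_rotation``
    holds exactly by construction.
    """

    max_external_rotation: float
    max_internal_rotation: float
    position_at_zero_torque: float
    play_at_zero_torque: float
    endpoint_slope_er: float
    endpoint_slope_ir: float
    total_rotation: float
    flags: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if np.isfinite(self.play_at_zero_torque) and self.play_at_zero_torque < -1e-9:
            raise ValueError("play at 0 Nm cannot be negative")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the extraction procedure.

    endpoint_fraction
        Fraction of the branch rotation range used for the endpoint-slope
        fit (default 0.10, i.e. the last 10 % of the curve).
    endpoint_branch
        "loading" fits the branch moving toward the reversal (direction +1
        for ER, -1 for IR); "unloading" uses the opposite branch.
    signed_ir
        If True, report the IR extreme signed (negative) instead of as a
        magnitude.
    min_window_samples
        If the 10 % window holds fewer samples than this the window is
        widened to exactly this many samples, with a warning.
    """

    endpoint_fraction: float = 0.10
    endpoint_branch: str = "loading"
    signed_ir: bool = False
    min_window_samples: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.endpoint_fraction < 1:
            raise ValueError("endpoint_fraction must be in (0, 1)")
        if self.endpoint_branch not in ("loading", "unloading"):
            raise ValueError("endpoint_branch must be 'loading' or 'unloading'")


@dataclass(frozen=True)
class Branches:
    """Index arrays partitioning a recording by direction flag and torque sign."""

    loading_er: np.ndarray    # direction +1, torque >= 0
    unloading_er: np.ndarray  # direction -1, torque >= 0
    loading_ir: np.ndarray    # direction -1, torque < 0
    unloading_ir: np.ndarray  # direction +1, torque < 0


def segment_branches(rec: RotationRecording, min_samples: int = 5) -> Branches:
    """Partition the samples of one cycle into its four hysteresis branches.

    The reversal points are the extreme-angle samples; when several samples
    share the extreme angle, the first one in acquisition order is the
    reversal.  A branch with fewer than ``min_samples`` samples is rejected.
    """
    d = rec.direction
    t = rec.torque_nm
    idx = np.arange(rec.n_samples)
    parts = {
        "loading_er": idx[(d == 1) & (t >= 0)],
        "unloading_er": idx[(d == -1) & (t >= 0)],
        "loading_ir": idx[(d == -1) & (t < 0)],
        "unloading_ir": idx[(d == 1) & (t < 0)],
    }
    for name, part in parts.items():
        if part.size < min_samples:
            raise ValueError(
                f"branch {name} has {part.size} samples (< {min_samples}); "
                "recording does not cover a full hysteresis cycle"
            )
    return Branches(**parts)


def _direction_runs(direction: np.ndarray) -> list[slice]:
    """Contiguous runs of constant direction flag, in acquisition order."""
    change = np.flatnonzero(np.diff(direction) != 0) + 1
    bounds = np.concatenate(([0], change, [direction.size]))
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _zero_crossings_in_run(angle: np.ndarray, torque: np.ndarray) -> list[float]:
    """All linearly interpolated zero-torque crossings within one run."""
    out: list[float] = []
    exact = np.flatnonzero(torque == 0.0)
    out.extend(angle[exact])
    prod = torque[:-1] * torque[1:]
    straddle = np.flatnonzero(prod < 0)
    for i in straddle:
        t0, t1 = torque[i], torque[i + 1]
        a0, a1 = angle[i], angle[i + 1]
        out.append(a0 + (a1 - a0) * (-t0) / (t1 - t0))
    return out


def _branch_zero_crossing(rec: RotationRecording, direction: int) -> float:
    """Zero-torque crossing of one direction branch.

    Crossings are interpolated between straddling sample pairs within each
    contiguous run of the requested direction (never across a reversal).
    With measurement noise a branch can straddle zero several times; the
    median of the interpolated crossings is returned, which is unbiased
    under symmetric noise and equals the single crossing when noiseless.
    Returns NaN when the branch never crosses zero.
    """
    crossings: list[float] = []
    for run in _direction_runs(rec.direction):
        if rec.direction[run.start] != direction:
            continue
        crossings.extend(
            _zero_crossings_in_run(rec.angle_deg[run], rec.torque_nm[run])
        )
    if not crossings:
        return float("nan")
    return float(np.median(crossings))


def _endpoint_window_slope(
    angle: np.ndarray,
    torque: np.ndarray,
    extreme: float,
    window: float,
    min_samples: int,
    flags: list,
    label: str,
) -> float:
    """Least-squares torque-vs-angle slope over the endpoint window."""
    dist = np.abs(extreme - angle)
    mask = dist <= window + 1e-12
    if mask.sum() < min_samples:
        # widen to the nearest min_samples samples
        order = np.argsort(dist)[:min_samples]
        mask = np.zeros_like(mask)
        mask[order] = True
        msg = f"endpoint window for {label} widened to {min_samples} samples"
        flags.append(msg)
        warnings.warn(msg, FeatureExtractionWarning, stacklevel=3)
    a = angle[mask]
    t = torque[mask]
    slope = np.polyfit(a, t, 1)[0]
    return float(slope)


def extract_features(
    rec: RotationRecording, config: FeatureConfig | None = None
) -> CurveFeatures:
    """Extract the load-deformation features from one recorded cycle.

    Max ER/IR are the reversal (extreme-angle) samples.  Zero-torque
    crossings are located by linear interpolation between straddling samples
    on each direction branch; play is the distance between the two branch
    crossings and the position at 0 Nm is their midpoint.  The endpoint
    slope toward each reversal is a least-squares line fitted over the last
    ``endpoint_fraction`` of the branch rotation range.
    """
    if config is None:
        config = FeatureConfig()
    flags: list = []

    max_angle = float(rec.angle_deg.max())
    min_angle = float(rec.angle_deg.min())
    max_er = max_angle
    max_ir_signed = min_angle

    cross_pos = _branch_zero_crossing(rec, +1)
    cross_neg = _branch_zero_crossing(rec, -1)
    if np.isnan(cross_pos) or np.isnan(cross_neg):
        flags.append("play undefined: a branch never crosses 0 Nm")
        warnings.warn(flags[-1], FeatureExtractionWarning, stacklevel=2)
        play = float("nan")
        pos0 = float("nan")
    else:
        play = abs(cross_neg - cross_pos)
        pos0 = 0.5 * (cross_neg + cross_pos)

    # branch selection for the endpoint fits
    er_dir = +1 if config.endpoint_branch == "loading" else -1
    ir_dir = -1 if config.endpoint_branch == "loading" else +1
    slopes = {}
    for label, direction, extreme in (
        ("er", er_dir, max_angle),
        ("ir", ir_dir, min_angle),
    ):
        sel = rec.direction == direction
        a = rec.angle_deg[sel]
        t = rec.torque_nm[sel]
        branch_range = float(a.max() - a.min())
        window = config.endpoint_fraction * branch_range
        slopes[label] = _endpoint_window_slope(
            a, t, extreme, window, config.min_window_samples, flags, label
        )

    max_ir = max_ir_signed if config.signed_ir else abs(max_ir_signed)
    total = max_er + abs(max_ir_signed)
    return CurveFeatures(
        max_external_rotation=max_er,
        max_internal_rotation=max_ir,
        position_at_zero_torque=pos0,
        play_at_zero_torque=play,
        endpoint_slope_er=slopes["er"],
        endpoint_slope_ir=slopes["ir"],
        total_rotation=total,
        flags=tuple(flags),
    )


def total_leg_rotation(f: CurveFeatures) -> float:
    """Total leg rotation: max external plus max internal rotation, degrees."""
    return f.max_external_rotation + abs(f.max_internal_rotation)


def normalized_endpoint_slope(
    rec: RotationRecording, config: FeatureConfig | None = None
) -> dict[str, float]:
    """Endpoint slopes as a percentage of the mid-curve slope.

    A steeper endpoint relative to the middle of the curve marks a stiffer
    limb; this secondary transform reports 100 x endpoint/mid-curve slope per
    direction, where the mid-curve slope is a least-squares fit over the
    central 20 % of the loading branch's rotation range.
    """
    if config is None:
        config = FeatureConfig()
    feats = extract_features(rec, config)
    out = {}
    for label, direction, endpoint in (
        ("er", +1, feats.endpoint_slope_er),
        ("ir", -1, feats.endpoint_slope_ir),
    ):
        sel = rec.direction == direction
        a = rec.angle_deg[sel]
        t = rec.torque_nm[sel]
        mid = 0.5 * (a.max() + a.min())
        half = 0.10 * (a.max() - a.min())
        mask = np.abs(a - mid) <= half
        if mask.sum() < 2:
            mask = np.argsort(np.abs(a - mid))[:3]
        mid_slope = np.polyfit(a[mask], t[mask], 1)[0]
        out[label] = float(100.0 * endpoint / mid_slope)
    return out


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

RECORDING_COLUMNS = [
    "subject_id",
    "limb",
    "sample_index",
    "angle_deg",
    "torque_Nm",
    "direction",
]

FEATURE_COLUMNS = [
    "max_er_deg",
    "max_ir_deg",
    "pos0_deg",
    "play0_deg",
    "slope_er_nm_per_deg",
    "slope_ir_nm_per_deg",
    "total_rot_deg",
]


def recordings_frame(recordings: list[RotationRecording]) -> pd.DataFrame:
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "limb": rec.limb_status,
                    "sample_index": np.arange(rec.n_samples),
                    "angle_deg": rec.angle_deg,
                    "torque_Nm": rec.torque_nm,
                    "direction": rec.direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[RECORDING_COLUMNS]


def write_recordings_csv(recordings: list[RotationRecording], path) -> None:
    recordings_frame(recordings).to_csv(path, index=False)


def read_recordings_csv(path_or_frame) -> list[RotationRecording]:
    """Read recordings from the CSV dialect (or an already-loaded frame)."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, comment="#")
    missing = set(RECORDING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"recording CSV missing columns: {sorted(missing)}")
    recs = []
    for (sid, limb), grp in df.groupby(["subject_id", "limb"], sort=True):
        grp = grp.sort_values("sample_index")
        recs.append(
            RotationRecording(
                subject_id=str(sid),
                limb_status=str(limb),
                angle_deg=grp["angle_deg"].to_numpy(),
                torque_nm=grp["torque_Nm"].to_numpy(),
                direction=grp["direction"].to_numpy(dtype=int),
            )
        )
    return recs


def features_frame(
    features: dict[tuple[str, str], CurveFeatures]
) -> pd.DataFrame:
    """Tabulate features keyed by (subject_id, limb) into the features CSV layout."""
    rows = []
    for (sid, limb), f in features.items():
        rows.append(
            {
                "subject_id": sid,
                "limb": limb,
                "max_er_deg": f.max_external_rotation,
                "max_ir_deg": abs(f.max_internal_rotation),
                "pos0_deg": f.position_at_zero_torque,
                "play0_deg": f.play_at_zero_torque,
                "slope_er_nm_per_deg": f.endpoint_slope_er,
                "slope_ir_nm_per_deg": f.endpoint_slope_ir,
                "total_rot_deg": f.total_rotation,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "limb"] + FEATURE_COLUMNS)
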