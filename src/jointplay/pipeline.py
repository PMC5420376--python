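"""End-to-end reproducible pipeline: generate -> extract -> metrics ->
screen -> compare.

A single master seed deterministically spawns per-stage substreams, so
disabling a late stage can never perturb the randomness of an earlier one,
and a rerun under an identical configuration is byte-identical.  Every
output CSV carries the seed and a hash of the configuration in a leading
comment line; all tabular I/O uses the CSV dialects of the other modules.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as cmp
from . import curves, metrics, screening
from .generator import CohortSpec, ProtocolConfig, default_study_means, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

ALL_STAGES = ("generate", "extract", "metrics", "screen", "compare")

# friendly criterion names -> analysis-table columns
CRITERION_COLUMNS = {
    "jpe": "jpe_mmdeg",
    "kt_manmax": "kt_manmax_mm",
    "total_rotation": "total_rot_deg",
    "pivot_shift": "pivot_shift_grade",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Stage toggles select which stages execute; a disabled stage's outputs
    must already exist in ``outdir`` for its consumers to run.  Thresholds:
    continuous criteria default to the exhaustive search policy, the
    pivot-shift grade to the fixed cut "grade >= 1 is positive".
    """

    seed: int
    outdir: str = "jointplay_run"
    n_group1: int = 9
    n_group2: int = 6
    n_group3: int = 2
    torque_limit: float = 5.65
    angle_step: float = 0.1
    torque_noise_sd: float = 0.001
    sd_rotation: float = 8.0
    sd_slope: float = 0.04
    sd_kt: float = 1.5
    sd_play: float = 2.0
    stages: tuple = ALL_STAGES
    criteria: tuple = ("jpe", "kt_manmax", "total_rotation", "pivot_shift")
    threshold_policy: str = "search"
    exclude_group3: bool = True
    examiner_policy: str = "mean"
    figures: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if self.torque_limit <= 0:
            raise ValueError("torque_limit must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        unknown = set(self.criteria) - set(CRITERION_COLUMNS)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        self.stages = tuple(self.stages)
        self.criteria = tuple(self.criteria)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a config from TOML or JSON (by file extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(text)
        elif path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            raise ValueError("config must be a .toml or .json file")
        if "seed" not in data:
            raise ValueError("config must set a seed")
        return cls(**data)

    # execution controls: where outputs go and which stages run; excluded
    # from the config hash so toggling a late stage or relocating a run
    # cannot change the bytes of upstream artifacts
    _EXECUTION_FIELDS = ("outdir", "stages", "figures")

    def config_hash(self) -> str:
        """Hash of the scientific configuration."""
        payload = {
            k: v for k, v in asdict(self).items()
            if k not in self._EXECUTION_FIELDS
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_seed(master: int, index: int) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    child = np.random.SeedSequence(master).spawn(len(ALL_STAGES))[index]
    return int(child.generate_state(1)[0] % (2**31))


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# jointplay seed={config.seed} config={config.config_hash()}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(f"required input {path.name} missing (stage disabled?)")
    return pd.read_csv(path, comment="#")


def _log(lines: list, message: str) -> None:
    lines.append(message)
    print(message, file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns {artifact name: path}.

    Stage failures abort the run with the stage name and, where known, the
    offending record in the error message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "recordings": out / "recordings.csv",
        "features": out / "features.csv",
        "analysis": out / "analysis.csv",
        "screening": out / "screening.csv",
        "comparisons": out / "comparisons.csv",
        "pointwise": out / "pointwise.csv",
        "report": out / "report.txt",
        "log": out / "run.log",
    }
    log: list = []
    _log(log, f"jointplay run: seed={config.seed} config={config.config_hash()}")

    stage = "generate"
    try:
        if stage in config.stages:
            spec = CohortSpec(
                seed=_stage_seed(config.seed, 0),
                n_group1=config.n_group1,
                n_group2=config.n_group2,
                n_group3=config.n_group3,
                sd_rotation=config.sd_rotation,
                sd_slope=config.sd_slope,
                sd_kt=config.sd_kt,
                sd_play=config.sd_play,
                angle_step=config.angle_step,
                torque_noise_sd=config.torque_noise_sd,
                means=default_study_means(),
                protocol=ProtocolConfig(torque_limit=config.torque_limit),
            )
            cohort = generate_cohort(spec)
            _write_csv(cohort.cohort_frame(), paths["cohort"], config)
            _write_csv(
                curves.recordings_frame(cohort.recordings()),
                paths["recordings"],
                config,
            )
            _log(log, f"generate: {spec.n_subjects} subjects, "
                      f"{2 * spec.n_subjects} limbs")

        stage = "extract"
        if stage in config.stages:
            recs = curves.read_recordings_csv(_read_csv(paths["recordings"]))
            feats = {}
            for rec in recs:
                try:
                    feats[(rec.subject_id, rec.limb_status)] = curves.extract_features(rec)
                except Exception as exc:  # noqa: BLE001 - annotate record id
                    raise PipelineError(
                        f"stage extract failed on {rec.subject_id}/{rec.limb_status}: {exc}"
                    ) from exc
            _write_csv(curves.features_frame(feats), paths["features"], config)
            _log(log, f"extract: {len(feats)} limbs")

        stage = "metrics"
        if stage in config.stages:
            cohort_df = _read_csv(paths["cohort"])
            features_df = _read_csv(paths["features"])
            analysis = metrics.build_analysis_table(
                cohort_df, features_df, examiner_policy=config.examiner_policy
            )
            _write_csv(analysis, paths["analysis"], config)
            _log(log, f"metrics: {len(analysis)} limb records")

        stage = "screen"
        if stage in config.stages:
            analysis = _read_csv(paths["analysis"])
            cohort_df = _read_csv(paths["cohort"])
            analysis = analysis.merge(
                cohort_df[["subject_id", "limb", "pivot_shift_grade"]],
                on=["subject_id", "limb"],
            )
            rows = []
            for name in config.criteria:
                column = CRITERION_COLUMNS[name]
                threshold = (
                    0.5 if name == "pivot_shift" else config.threshold_policy
                )
                res = screening.DiagnosticScreen(
                    analysis, column, exclude_group3=config.exclude_group3
                ).fit(threshold=threshold)
                frame = res.to_frame()
                frame.insert(0, "name", name)
                rows.append(frame)
            screening_df = pd.concat(rows, ignore_index=True)
            _write_csv(screening_df, paths["screening"], config)
            _log(log, f"screen: {len(screening_df)} criteria")

        stage = "compare"
        if stage in config.stages:
            analysis = _read_csv(paths["analysis"])
            features_df = _read_csv(paths["features"])
            cohort_df = _read_csv(paths["cohort"])
            merged = features_df.merge(
                cohort_df[["subject_id", "limb", "kt_manmax", "group"]],
                on=["subject_id", "limb"],
            )
            merged = merged.merge(
                analysis[["subject_id", "limb", "jpe_mmdeg"]],
                on=["subject_id", "limb"],
            )
            comparisons = _feature_comparisons(merged)
            _write_csv(comparisons, paths["comparisons"], config)
            pw = _pointwise_comparison(paths["recordings"], cohort_df)
            _write_csv(pw, paths["pointwise"], config)
            _log(log, f"compare: {len(comparisons)} feature comparisons, "
                      f"{len(pw)} pointwise grid points")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    _write_report(paths, config, log)
    paths["log"].write_text("\n".join(log) + "\n")
    return {k: v for k, v in paths.items() if v.exists()}


_COMPARED_FEATURES = [
    "max_er_deg",
    "max_ir_deg",
    "play0_deg",
    "slope_er_nm_per_deg",
    "total_rot_deg",
    "kt_manmax",
    "jpe_mmdeg",
]


def _feature_comparisons(merged: pd.DataFrame) -> pd.DataFrame:
    """The standard comparison battery on the per-limb feature table."""
    rows = []
    df = merged[merged["group"].isin([1, 2])]

    def record(res: cmp.ComparisonResult):
        rows.append(
            {
                "name": res.name,
                "design": res.design,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "mean_a": res.mean_a,
                "mean_b": res.mean_b,
                "diff": res.mean_difference,
                "p": res.p_value,
            }
        )

    for feature in _COMPARED_FEATURES:
        # paired: reconstructed vs healthy within each group
        for group in (1, 2):
            sub = df[df["group"] == group].pivot(
                index="subject_id", columns="limb", values=feature
            )
            record(
                cmp.compare_feature(
                    sub["reconstructed"], sub["healthy"], "paired",
                    name=f"{feature}: recon vs healthy (group {group})",
                )
            )
        # unpaired: group 1 vs group 2 within each limb status
        for limb in ("reconstructed", "healthy"):
            a = df[(df["group"] == 2) & (df["limb"] == limb)][feature]
            b = df[(df["group"] == 1) & (df["limb"] == limb)][feature]
            record(
                cmp.compare_feature(
                    a, b, "unpaired",
                    name=f"{feature}: group 2 vs group 1 ({limb})",
                )
            )
    return pd.DataFrame(rows)


def _pointwise_comparison(recordings_path: Path, cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Pointwise curve comparison: group 2 vs group 1 healthy limbs, loading branch."""
    recs = curves.read_recordings_csv(_read_csv(recordings_path))
    group_of = {
        (str(r.subject_id), r.limb): int(r.group)
        for r in cohort_df.itertuples()
    }
    healthy = [r for r in recs if r.limb_status == "healthy"
               and group_of[(r.subject_id, "healthy")] in (1, 2)]
    grid = cmp.common_torque_grid(healthy, branch_direction=1)
    reg = cmp.register_curves(healthy, grid, branch_direction=1)
    rows_a = [i for i, (sid, limb) in enumerate(reg.limb_ids)
              if group_of[(sid, limb)] == 2]
    rows_b = [i for i, (sid, limb) in enumerate(reg.limb_ids)
              if group_of[(sid, limb)] == 1]
    set_a = cmp.RegisteredCurveSet(
        reg.torque_grid, reg.angles[rows_a], tuple(reg.limb_ids[i] for i in rows_a), 1
    )
    set_b = cmp.RegisteredCurveSet(
        reg.torque_grid, reg.angles[rows_b], tuple(reg.limb_ids[i] for i in rows_b), 1
    )
    return cmp.pointwise_t(set_a, set_b)


def _write_report(paths: dict, config: RunConfig, log: list) -> None:
    lines = [
        "jointplay pipeline report",
        f"seed: {config.seed}   config: {config.config_hash()}",
        "",
    ]
    if paths["screening"].exists():
        df = pd.read_csv(paths["screening"], comment="#")
        lines.append("Diagnostic screening values (percent; Fisher exact p)")
        lines.append("-" * 72)
        lines.append(
            f"{'criterion':<16}{'sens':>6}{'spec':>6}{'ppv':>6}{'npv':>6}{'p':>12}"
        )
        for r in df.itertuples():
            lines.append(
                f"{r.name:<16}{r.sensitivity:>6.0f}{r.specificity:>6.0f}"
                f"{r.ppv:>6.0f}{r.npv:>6.0f}{r.p_value:>12.4g}"
            )
        lines.append("")
    if paths["comparisons"].exists():
        df = pd.read_csv(paths["comparisons"], comment="#")
        lines.append("Feature comparisons")
        lines.append("-" * 72)
        for r in df.itertuples():
            p = "undef" if pd.isna(r.p) else f"{r.p:.4g}"
            lines.append(
                f"{r.name:<52} diff={r.diff:+8.2f}  p={p}"
            )
        lines.append("")
    paths["report"].write_text("\n".join(lines) + "\n")
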