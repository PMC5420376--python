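"""Figures regenerated from the pipeline's CSV artifacts.

Plots are always rebuilt from the written CSVs, never from in-memory state,
so a figure can be reproduced from any archived run directory.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import curves

__all__ = ["plot_hysteresis", "plot_jpe_scatter", "render_run_figures"]


def plot_hysteresis(recordings_csv, subject_id: str, limb: str, ax=None):
    """One limb's torque-angle loop annotated with the extracted features:
    (a) max ER, (b) max IR, (c) position at 0 Nm, (d) play at 0 Nm,
    (e) endpoint slope windows."""
    recs = curves.read_recordings_csv(recordings_csv)
    rec = next(
        (r for r in recs if r.subject_id == str(subject_id) and r.limb_status == limb),
        None,
    )
    if rec is None:
        raise ValueError(f"no recording for {subject_id}/{limb}")
    f = curves.extract_features(rec)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(rec.angle_deg, rec.torque_nm, lw=0.8, color="tab:blue")
    ax.axhline(0, color="0.6", lw=0.5)
    ax.axvline(f.max_external_rotation, color="tab:red", ls="--", lw=0.8,
               label=f"(a) max ER {f.max_external_rotation:.1f} deg")
    ax.axvline(-f.max_internal_rotation, color="tab:orange", ls="--", lw=0.8,
               label=f"(b) max IR {f.max_internal_rotation:.1f} deg")
    ax.plot([f.position_at_zero_torque], [0], "ko", ms=5,
            label=f"(c) pos at 0 Nm {f.position_at_zero_torque:.1f} deg")
    half = 0.5 * f.play_at_zero_torque
    ax.plot(
        [f.position_at_zero_torque - half, f.position_at_zero_torque + half],
        [0, 0], lw=3, color="tab:green",
        label=f"(d) play {f.play_at_zero_torque:.1f} deg",
    )
    ax.set_xlabel("rotation (deg, ER positive)")
    ax.set_ylabel("torque (Nm)")
    ax.set_title(f"{rec.subject_id} {rec.limb_status} "
                 f"(e) slopes {f.endpoint_slope_er:.2f}/{f.endpoint_slope_ir:.2f} Nm/deg")
    ax.legend(fontsize=7, loc="upper left")
    return ax


def plot_jpe_scatter(analysis_csv, ax=None):
    """KT manual max vs total rotation per limb, coloured by satisfaction group;
    iso-JPE hyperbolas show the composite's level sets."""
    df = (
        analysis_csv
        if isinstance(analysis_csv, pd.DataFrame)
        else pd.read_csv(analysis_csv, comment="#")
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    palette = {1: "tab:blue", 2: "tab:red", 3: "tab:gray"}
    for group, sub in df.groupby("group"):
        ax.scatter(
            sub["total_rot_deg"], sub["kt_manmax_mm"],
            c=palette.get(int(group), "k"), s=25,
            marker="o" if group != 3 else "x",
            label=f"group {group}",
        )
    import numpy as np

    x = np.linspace(df["total_rot_deg"].min() * 0.9,
                    df["total_rot_deg"].max() * 1.05, 100)
    for level in np.quantile(df["jpe_mmdeg"], [0.25, 0.5, 0.75]):
        ax.plot(x, level / x, color="0.8", lw=0.6, zorder=0)
    ax.set_xlabel("total leg rotation (deg)")
    ax.set_ylabel("KT manual max (mm)")
    ax.set_title("Joint Play Envelope by satisfaction group")
    ax.legend(fontsize=8)
    return ax


def render_run_figures(outdir) -> list:
    """Render the standard figures from a pipeline run directory."""
    out = Path(outdir)
    made = []
    rec_csv = out / "recordings.csv"
    if rec_csv.exists():
        df = pd.read_csv(rec_csv, comment="#", nrows=1)
        sid = str(df["subject_id"].iloc[0])
        fig, ax = plt.subplots(figsize=(6, 4))
        plot_hysteresis(pd.read_csv(rec_csv, comment="#"), sid, "healthy", ax=ax)
        path = out / "hysteresis.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    ana_csv = out / "analysis.csv"
    if ana_csv.exists():
        fig, ax = plt.subplots(figsize=(5, 4))
        plot_jpe_scatter(ana_csv, ax=ax)
        path = out / "jpe_scatter.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    return made
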