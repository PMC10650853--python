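"""End-to-end analysis: manifest -> strides -> curves -> metrics -> statistics.

A run is deterministic given its seed, quarantines unreadable or
unsegmentable trials instead of failing (unless a whole analysis cell
empties), and writes a self-describing run directory: group curves, a
limb-comparison table and a condition-comparison table, a stats JSON, SPM
cluster table, QC report, resolved-config snapshot, log file and (optional)
figures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .curves import GRID, EnsembleCurve, stride_velocity, subject_mean_curves
from .impulse import (
    ASYMMETRY_FLAG_THRESHOLD,
    asymmetry_index,
    condition_difference,
    impulse_mean,
)
from .segmentation import cut_segments, detect_strides
from .stats import DegenerateTestError, SpmResult, paired_test, spm_paired

logger = logging.getLogger(__name__)

SPM_PANELS = ("left", "right", "both")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    manifest: str
    out_dir: str
    window: tuple[int, int] = (30, 60)
    min_stride_s: float = 0.4
    max_stride_s: float = 1.6
    prominence_frac: float = 0.3
    alpha: float = 0.05
    n_perm: int = 10000
    seed: int = 0
    smoothing: bool = False
    figures: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (0 <= lo < hi <= 100):
            raise ValueError("impulse window must lie inside [0, 100] with "
                             "start < end")
        self.window = (int(lo), int(hi))


@dataclass
class AnalysisResult:
    """In-memory results of one run."""

    group_curves: dict[tuple, EnsembleCurve]
    subject_curves: dict[tuple, EnsembleCurve]
    impulse: pd.DataFrame            # subject, foot, condition, axis, value
    table1: pd.DataFrame             # left-vs-right per condition x axis
    table2: pd.DataFrame             # condition effect per foot x axis
    spm: dict[tuple[str, str], SpmResult]
    qc: dict


def _moving_average(x: np.ndarray, width: int = 3) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def analyze_trials(trials: list[fio.ImuTrial], cfg: RunConfig) -> AnalysisResult:
    """Run segmentation, curve reduction, impulse metrics and statistics."""
    stride_curves: dict[tuple, list] = {}
    qc_trials = {}
    for trial in trials:
        if cfg.smoothing:
            smoothed = fio.ImuTrial(
                trial.subject_id, trial.foot, trial.condition,
                trial.sampling_rate, trial.t,
                _moving_average(trial.dpf), _moving_average(trial.inev),
                _moving_average(trial.abdadd),
            )
            trial = smoothed
        strides = detect_strides(
            trial,
            min_stride_s=cfg.min_stride_s,
            max_stride_s=cfg.max_stride_s,
            prominence_frac=cfg.prominence_frac,
        )
        segments = cut_segments(strides)
        for axis in fio.AXES:
            key = (trial.subject_id, trial.foot, trial.condition, axis)
            curves = [
                stride_velocity(seg[axis], trial.sampling_rate, axis=axis)
                for seg in segments
            ]
            stride_curves.setdefault(key, []).extend(curves)
        qc_trials["|".join(trial.key)] = {
            "n_strides": strides.n,
            "n_dropped": len(strides.dropped),
        }

    subject_curves, group_curves, missing = subject_mean_curves(stride_curves)
    if missing:
        logger.warning("empty analysis cells: %s", missing)

    # per-subject impulse means
    rows = []
    for (subject, foot, condition, axis), ens in subject_curves.items():
        rows.append(
            {
                "subject": subject,
                "foot": foot,
                "condition": condition,
                "axis": axis,
                "impulse_mean": impulse_mean(ens.mean, window=cfg.window),
            }
        )
    impulse = pd.DataFrame(rows).sort_values(
        ["condition", "axis", "foot", "subject"]
    ).reset_index(drop=True)

    def cell(foot: str, condition: str, axis: str) -> pd.DataFrame:
        m = (
            (impulse["foot"] == foot)
            & (impulse["condition"] == condition)
            & (impulse["axis"] == axis)
        )
        return impulse[m].set_index("subject")["impulse_mean"]

    # limb comparison (left vs right) per condition x axis
    t1_rows = []
    for condition in fio.CONDITIONS:
        for axis in fio.AXES:
            left, right = cell("left", condition, axis), cell("right", condition, axis)
            common = left.index.intersection(right.index)
            l, r = left[common].to_numpy(), right[common].to_numpy()
            row = {
                "condition": condition,
                "axis": axis,
                "n": len(common),
                "left_mean": l.mean(),
                "left_sd": l.std(ddof=1) if len(l) > 1 else 0.0,
                "right_mean": r.mean(),
                "right_sd": r.std(ddof=1) if len(r) > 1 else 0.0,
            }
            row["asymmetry_of_means"] = asymmetry_index(
                row["left_mean"], row["right_mean"]
            )
            per_subj = np.array(
                [asymmetry_index(a, b) for a, b in zip(l, r)]
            )
            row["asymmetry_subject_mean"] = per_subj.mean()
            row["asymmetry_subject_sd"] = (
                per_subj.std(ddof=1) if len(per_subj) > 1 else 0.0
            )
            row["flag_15"] = bool(
                row["asymmetry_of_means"] > ASYMMETRY_FLAG_THRESHOLD
            )
            try:
                res = paired_test(l, r, comparison=f"{condition}/{axis} L-R",
                                  alpha=cfg.alpha)
                row.update(
                    p_value=res.p_value, t=res.t, d_cohen=res.d_cohen,
                    effect_category=res.effect_category,
                    normality_p=res.normality_p,
                )
            except DegenerateTestError as exc:
                logger.warning("limb comparison %s/%s: %s", condition, axis, exc)
                row.update(p_value=np.nan, t=np.nan, d_cohen=np.nan,
                           effect_category="", normality_p=np.nan)
            t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)

    # condition effect (noFO vs FO) per foot x axis
    t2_rows = []
    for foot in fio.FEET:
        for axis in fio.AXES:
            non, fo = cell(foot, "noFO", axis), cell(foot, "FO", axis)
            common = non.index.intersection(fo.index)
            a, b = non[common].to_numpy(), fo[common].to_numpy()
            diff, direction = condition_difference(a.mean(), b.mean())
            row = {
                "foot": foot,
                "axis": axis,
                "n": len(common),
                "noFO_mean": a.mean(),
                "noFO_sd": a.std(ddof=1) if len(a) > 1 else 0.0,
                "FO_mean": b.mean(),
                "FO_sd": b.std(ddof=1) if len(b) > 1 else 0.0,
                "difference": diff,
                "direction": direction,
            }
            try:
                res = paired_test(a, b, comparison=f"{foot}/{axis} noFO-FO",
                                  alpha=cfg.alpha)
                row.update(
                    p_value=res.p_value, t=res.t, d_cohen=res.d_cohen,
                    effect_category=res.effect_category,
                    normality_p=res.normality_p,
                )
            except DegenerateTestError as exc:
                logger.warning("condition comparison %s/%s: %s", foot, axis, exc)
                row.update(p_value=np.nan, t=np.nan, d_cohen=np.nan,
                           effect_category="", normality_p=np.nan)
            t2_rows.append(row)
    table2 = pd.DataFrame(t2_rows)

    # whole-curve SPM, one panel per foot plus both feet pooled, per axis
    spm: dict[tuple[str, str], SpmResult] = {}
    for axis in fio.AXES:
        panels = _spm_panels(subject_curves, axis)
        for panel, (A, B) in panels.items():
            if A is None or A.shape[0] < 5:
                continue
            seed = int(
                np.random.SeedSequence(
                    cfg.seed, spawn_key=(fio.AXES.index(axis),
                                         SPM_PANELS.index(panel))
                ).generate_state(1)[0] % (2 ** 31)
            )
            spm[(axis, panel)] = spm_paired(
                A, B, alpha=cfg.alpha, n_perm=cfg.n_perm, seed=seed
            )

    qc = {
        "trials": dict(sorted(qc_trials.items())),
        "missing_cells": ["|".join(map(str, m)) for m in missing],
    }
    return AnalysisResult(
        group_curves=group_curves,
        subject_curves=subject_curves,
        impulse=impulse,
        table1=table1,
        table2=table2,
        spm=spm,
        qc=qc,
    )


def _spm_panels(subject_curves: dict, axis: str):
    """Per-subject noFO/FO velocity-curve matrices for left, right, pooled."""
    def matrix(foot_filter) -> tuple:
        per_subject: dict[str, dict[str, list[np.ndarray]]] = {}
        for (subject, foot, condition, ax), ens in subject_curves.items():
            if ax != axis or not foot_filter(foot):
                continue
            per_subject.setdefault(subject, {}).setdefault(condition, []).append(
                ens.mean.values
            )
        subjects = sorted(
            s for s, c in per_subject.items() if "noFO" in c and "FO" in c
        )
        if not subjects:
            return None, None
        A = np.vstack(
            [np.mean(per_subject[s]["noFO"], axis=0) for s in subjects]
        )
        B = np.vstack(
            [np.mean(per_subject[s]["FO"], axis=0) for s in subjects]
        )
        return A, B

    return {
        "left": matrix(lambda f: f == "left"),
        "right": matrix(lambda f: f == "right"),
        "both": matrix(lambda f: True),
    }


def _load_trials(cfg: RunConfig) -> tuple[list[fio.ImuTrial], list[dict]]:
    manifest = fio.read_manifest(cfg.manifest, check_files=False)
    trials = []
    quarantined = []
    for entry in manifest.entries:
        path = fio.resolve_entry_path(cfg.manifest, entry)
        try:
            trial = fio.read_trial(
                path,
                subject_id=entry.subject_id,
                foot=entry.foot,
                condition=entry.condition,
            )
            trials.append(trial)
        except Exception as exc:  # quarantine, do not abort the run
            logger.warning("quarantined %s: %s", path, exc)
            quarantined.append(
                {"trial": f"{entry.subject_id}|{entry.foot}|{entry.condition}",
                 "path": str(path), "reason": str(exc)}
            )
    if not trials:
        raise ValueError("manifest produced no loadable trials")
    return trials, quarantined


def run_pipeline(cfg: RunConfig) -> AnalysisResult:
    """Execute a full run and write all artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    for sub in ("curves", "tables", "stats", "qc"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("footvel")
    root.addHandler(handler)
    try:
        trials, quarantined = _load_trials(cfg)
        result = analyze_trials(trials, cfg)
        result.qc["quarantined"] = quarantined
        _write_outputs(result, cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return result


def _write_outputs(result: AnalysisResult, cfg: RunConfig, out: Path) -> None:
    with open(out / "config_resolved.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)

    for (foot, condition), group in _group_by_cell(result.group_curves).items():
        df = pd.DataFrame({"cycle_pct": GRID})
        for axis, ens in sorted(group.items()):
            df[f"{axis}_mean"] = ens.mean.values
            df[f"{axis}_sd"] = ens.sd
            df[f"{axis}_n"] = ens.n
        df.to_csv(out / "curves" / f"group_{foot}_{condition}.csv", index=False)

    result.table1.to_csv(out / "tables" / "limb_comparison.csv", index=False)
    result.table2.to_csv(out / "tables" / "condition_comparison.csv", index=False)
    result.impulse.to_csv(out / "tables" / "impulse_by_subject.csv", index=False)

    stats_doc = {
        "limb_comparison": _df_records(result.table1),
        "condition_comparison": _df_records(result.table2),
        "spm": {
            f"{axis}|{panel}": {
                "threshold": res.threshold,
                "n": res.n,
                "n_perm": res.n_perm,
                "exhaustive": res.exhaustive,
                "clusters": [
                    {"start_pct": c.start, "end_pct": c.end, "p": c.p_value}
                    for c in res.clusters
                ],
            }
            for (axis, panel), res in sorted(result.spm.items())
        },
    }
    with open(out / "stats" / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(stats_doc, fh, indent=1, sort_keys=True)

    cluster_rows = [
        {
            "axis": axis, "panel": panel, "start_pct": c.start,
            "end_pct": c.end, "p": c.p_value,
            "significant": c.p_value <= res.alpha,
        }
        for (axis, panel), res in sorted(result.spm.items())
        for c in res.clusters
    ]
    pd.DataFrame(
        cluster_rows,
        columns=["axis", "panel", "start_pct", "end_pct", "p", "significant"],
    ).to_csv(out / "stats" / "spm_clusters.csv", index=False)

    with open(out / "qc" / "qc.json", "w", encoding="utf-8") as fh:
        json.dump(result.qc, fh, indent=1, sort_keys=True)

    if cfg.figures:
        _plot_figures(result, out)


def _group_by_cell(group_curves: dict) -> dict:
    cells: dict[tuple, dict] = {}
    for (foot, condition, axis), ens in group_curves.items():
        cells.setdefault((foot, condition), {})[axis] = ens
    return cells


def _df_records(df: pd.DataFrame) -> list[dict]:
    recs = df.to_dict(orient="records")
    for r in recs:
        for k, v in r.items():
            if isinstance(v, (np.floating, np.integer)):
                r[k] = v.item()
            if isinstance(v, float) and np.isnan(v):
                r[k] = None
    return recs


def _plot_figures(result: AnalysisResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    (out / "figures").mkdir(exist_ok=True)
    for axis in fio.AXES:
        fig, axs = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
        for ax_plot, panel in zip(axs, SPM_PANELS):
            for condition, color in (("noFO", "tab:blue"), ("FO", "tab:orange")):
                feet = ["left", "right"] if panel == "both" else [panel]
                members = [
                    result.group_curves[(f, condition, axis)]
                    for f in feet
                    if (f, condition, axis) in result.group_curves
                ]
                if not members:
                    continue
                mean = np.mean([m.mean.values for m in members], axis=0)
                sd = np.mean([m.sd for m in members], axis=0)
                ax_plot.plot(GRID, mean, color=color, label=condition)
                ax_plot.fill_between(GRID, mean - sd, mean + sd, color=color,
                                     alpha=0.2)
            res = result.spm.get((axis, panel))
            if res is not None:
                y = ax_plot.get_ylim()[0]
                for c in res.significant_clusters():
                    ax_plot.plot([c.start, c.end], [y, y], "k-", lw=3)
            ax_plot.axvline(30, ls="--", c="gray", lw=0.8)
            ax_plot.axvline(60, ls="--", c="gray", lw=0.8)
            ax_plot.set_title(f"{axis} ({panel})")
            ax_plot.set_xlabel("cycle (%)")
        axs[0].set_ylabel("angular velocity (deg/s)")
        axs[0].legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "figures" / f"velocity_{axis}.png", dpi=120)
        plt.close(fig)


def qc_report(run_dir: str | Path) -> str:
    """Human-readable QC summary of a completed run."""
    run_dir = Path(run_dir)
    qc_path = run_dir / "qc" / "qc.json"
    if not qc_path.exists():
        raise FileNotFoundError(f"no QC artifact at {qc_path}")
    with open(qc_path, "r", encoding="utf-8") as fh:
        qc = json.load(fh)
    lines = ["QC summary", "=========="]
    trials = qc.get("trials", {})
    lines.append(f"analysed trials: {len(trials)}")
    for key, rec in trials.items():
        lines.append(
            f"  {key}: {rec['n_strides']} strides "
            f"({rec['n_dropped']} dropped)"
        )
    quarantined = qc.get("quarantined", [])
    lines.append(f"quarantined trials: {len(quarantined)}")
    for rec in quarantined:
        lines.append(f"  {rec['trial']}: {rec['reason']}")
    missing = qc.get("missing_cells", [])
    if missing:
        lines.append(f"empty cells: {missing}")
    return "\n".join(lines)
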