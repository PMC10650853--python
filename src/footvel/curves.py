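"""Cycle time-normalisation and ensemble mean angle / angular-velocity curves.

Variable-duration stride segments are resampled by linear interpolation
onto a common 0-100% cycle grid of 101 nodes, so the 30% and 60% impulse
landmarks are exact nodes.  Angular velocity is differentiated first in the
time domain (central differences at the raw sampling interval, second-order
one-sided stencils at segment ends) and only then normalised: the mean
velocity curve is the average of per-stride derivatives, not the derivative
of an averaged angle.  Ensemble curves carry the node-wise mean, sample SD
and the number of strides or subjects averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import AXES

N_NODES = 101

#: Cycle-percent grid shared by every curve.
GRID = np.linspace(0.0, 100.0, N_NODES)


@dataclass
class CycleCurve:
    """One variable on the normalised 0-100% cycle grid.

    ``values`` are degrees for kind "angle", degrees/second for kind
    "velocity"; velocity curves carry the stride duration used to scale the
    derivative.
    """

    values: np.ndarray
    kind: str  # "angle" | "velocity"
    axis: str  # "dpf" | "inev" | "abdadd"
    duration: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_NODES,):
            raise ValueError(f"curve must have {N_NODES} nodes, got "
                             f"{self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve contains non-finite values")
        if self.kind not in ("angle", "velocity"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.kind == "velocity" and self.duration is None:
            raise ValueError("velocity curves must record the stride duration")

    @property
    def grid(self) -> np.ndarray:
        return GRID


@dataclass
class EnsembleCurve:
    """Mean +/- SD curve across strides or subjects."""

    mean: CycleCurve
    sd: np.ndarray
    n: int
    level: str  # "stride" | "subject"

    def __post_init__(self) -> None:
        self.sd = np.asarray(self.sd, dtype=float)
        if self.sd.shape != (N_NODES,):
            raise ValueError("sd must be node-wise over the cycle grid")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n == 1 and np.any(self.sd != 0):
            raise ValueError("sd must be zero when n == 1")
        if self.level not in ("stride", "subject"):
            raise ValueError(f"unknown ensemble level {self.level!r}")


def normalize_segment(
    values: Sequence[float],
    duration: float,
    axis: str = "dpf",
    n_nodes: int = N_NODES,
) -> CycleCurve:
    """Resample one angle segment onto the uniform cycle grid.

    Linear interpolation of the samples (assumed uniformly spaced over
    ``duration`` seconds) onto ``n_nodes`` equally spaced cycle nodes;
    segment endpoints are preserved exactly.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("segment must have at least 2 samples")
    if n_nodes != N_NODES:
        raise ValueError("the pipeline's cycle grid is fixed at 101 nodes")
    src = np.linspace(0.0, duration, len(values))
    dst = np.linspace(0.0, duration, n_nodes)
    out = np.interp(dst, src, values)
    out[0] = values[0]
    out[-1] = values[-1]
    return CycleCurve(values=out, kind="angle", axis=axis, duration=duration)


def stride_velocity(
    values: Sequence[float],
    sampling_rate: float,
    axis: str = "dpf",
) -> CycleCurve:
    """Angular velocity of one stride, on the cycle grid, in deg/s.

    The derivative is taken on the original time-domain samples (central
    differences, spacing 1/sampling_rate, second-order one-sided stencils at
    the ends) and the resulting velocity samples are then time-normalised.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("segment must have at least 4 samples to differentiate")
    vel = np.gradient(values, 1.0 / sampling_rate, edge_order=2)
    duration = (len(values) - 1) / sampling_rate
    src = np.linspace(0.0, duration, len(values))
    dst = np.linspace(0.0, duration, N_NODES)
    out = np.interp(dst, src, vel)
    return CycleCurve(values=out, kind="velocity", axis=axis, duration=duration)


def ensemble_mean(curves: Sequence[CycleCurve], level: str = "stride") -> EnsembleCurve:
    """Node-wise arithmetic mean and sample SD (ddof=1) of homogeneous curves."""
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    kind, axis = curves[0].kind, curves[0].axis
    for c in curves[1:]:
        if c.kind != kind or c.axis != axis:
            raise ValueError("cannot average curves of mixed kind or axis")
    stack = np.vstack([c.values for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(N_NODES)
    durations = [c.duration for c in curves if c.duration is not None]
    mean_curve = CycleCurve(
        values=mean,
        kind=kind,
        axis=axis,
        duration=float(np.mean(durations)) if durations else None,
    )
    return EnsembleCurve(mean=mean_curve, sd=sd, n=len(curves), level=level)


def subject_mean_curves(
    stride_curves: dict[tuple, list[CycleCurve]],
) -> tuple[dict[tuple, EnsembleCurve], dict[tuple, EnsembleCurve], list[tuple]]:
    """Two-level aggregation: stride -> subject, then subject -> group.

    ``stride_curves`` maps (subject, foot, condition, axis) to that cell's
    per-stride curves.  Returns (subject-level ensembles keyed like the
    input, group-level ensembles keyed by (foot, condition, axis), and the
    list of empty cells encountered).  Empty cells are reported, never
    imputed.
    """
    subject_level: dict[tuple, EnsembleCurve] = {}
    missing: list[tuple] = []
    for key, curves in stride_curves.items():
        if not curves:
            missing.append(key)
            continue
        subject_level[key] = ensemble_mean(curves, level="stride")
    group_members: dict[tuple, list[CycleCurve]] = {}
    for (subject, foot, condition, axis), ens in subject_level.items():
        group_members.setdefault((foot, condition, axis), []).append(ens.mean)
    group_level = {
        key: ensemble_mean(curves, level="subject")
        for key, curves in group_members.items()
    }
    return subject_level, group_level, missing
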