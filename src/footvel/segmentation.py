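"""Stride detection from the sagittal-plane angle signal.

A stride is one full gait cycle, delimited by successive maxima of the
dorsi-plantar flexion angle; the interior minimum (the plantar-flexion
extreme near the end of stance) is kept as a landmark.  The same boundary
indices cut the frontal and transverse channels, so all three axes share a
common cycle clock.  Incomplete edge cycles are dropped implicitly (a
boundary needs a detected maximum on both sides) and strides whose duration
falls outside [0.5x, 2x] of the trial median are discarded with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import ImuTrial

logger = logging.getLogger(__name__)


class SegmentationError(ValueError):
    """No complete stride could be delimited."""


class DegenerateSignalError(ValueError):
    """Flat sagittal signal; no extrema to segment on."""


@dataclass
class StrideSet:
    """Detected stride boundaries of one trial.

    ``boundaries`` are half-open sample-index pairs [start, end); each
    stride's landmarks are (index of the starting sagittal maximum, index of
    the interior sagittal minimum).
    """

    trial: ImuTrial
    boundaries: list[tuple[int, int]]
    landmarks: list[tuple[int, int]]
    dropped: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.boundaries) < 1:
            raise SegmentationError("stride set must contain at least one stride")
        prev_end = -1
        for (s, e), (pk, mn) in zip(self.boundaries, self.landmarks):
            if not (0 <= s < e <= len(self.trial)):
                raise ValueError(f"boundary ({s}, {e}) outside trial")
            if s < prev_end:
                raise ValueError("boundaries overlap")
            prev_end = e
            if not (s < mn < e - 1):
                raise ValueError(
                    f"stride ({s}, {e}) lacks an interior minimum landmark"
                )

    @property
    def n(self) -> int:
        return len(self.boundaries)

    def durations(self) -> np.ndarray:
        """Stride durations in seconds."""
        fs = self.trial.sampling_rate
        return np.asarray([(e - s) / fs for s, e in self.boundaries])


def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-point moving average used only to localise peaks in noisy signals."""
    if len(x) < 3:
        return x
    out = x.copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return out


def detect_strides(
    trial: ImuTrial,
    min_stride_s: float = 0.4,
    max_stride_s: float = 1.6,
    prominence_frac: float = 0.3,
) -> StrideSet:
    """Delimit strides between successive sagittal-angle maxima.

    Maxima must clear a prominence of ``prominence_frac`` times the sagittal
    peak-to-peak range and be at least ``min_stride_s`` apart; consecutive
    maxima spaced within [min_stride_s, max_stride_s] delimit a stride.
    Defaults reflect running cadence at 2.5 m/s.  Peak positions are
    localised on a lightly smoothed copy of the signal; all cutting happens
    on the raw samples.
    """
    if trial.duration < max_stride_s:
        raise SegmentationError(
            f"trial spans {trial.duration:.2f}s < max_stride_s={max_stride_s}s"
        )
    dpf = trial.dpf
    rng = float(np.ptp(dpf))
    if rng == 0.0:
        raise DegenerateSignalError("sagittal signal is constant")
    fs = trial.sampling_rate
    distance = max(1, int(round(min_stride_s * fs)))
    peaks, _ = find_peaks(
        _smooth3(dpf), prominence=prominence_frac * rng, distance=distance
    )
    if len(peaks) < 2:
        raise SegmentationError(
            f"found {len(peaks)} sagittal maxima; need at least 2 for one stride"
        )
    lo = min_stride_s * fs
    hi = max_stride_s * fs
    candidates = [
        (int(a), int(b))
        for a, b in zip(peaks[:-1], peaks[1:])
        if lo <= (b - a) <= hi
    ]
    if not candidates:
        raise SegmentationError("no inter-peak spacing within the stride band")

    durations = np.asarray([e - s for s, e in candidates], dtype=float)
    med = float(np.median(durations))
    keep = (durations >= 0.5 * med) & (durations <= 2.0 * med)
    dropped = [c for c, k in zip(candidates, keep) if not k]
    kept = [c for c, k in zip(candidates, keep) if k]
    if dropped:
        logger.warning(
            "trial %s: dropped %d outlier stride(s) (duration outside "
            "[0.5x, 2x] median)", trial.key, len(dropped)
        )
    if not kept:
        raise SegmentationError("all candidate strides were duration outliers")

    landmarks = []
    for s, e in kept:
        interior = dpf[s + 1 : e - 1]
        mn = s + 1 + int(np.argmin(interior))
        landmarks.append((s, mn))
    return StrideSet(trial=trial, boundaries=kept, landmarks=landmarks,
                     dropped=dropped)


def cut_segments(strides: StrideSet) -> list[dict[str, np.ndarray]]:
    """Cut all three axes at the stride boundaries.

    Returns one ``{"dpf": ..., "inev": ..., "abdadd": ...}`` mapping per
    stride; within a stride all three segments share the same length.
    """
    trial = strides.trial
    out = []
    for s, e in strides.boundaries:
        if e - s < 4:
            raise SegmentationError(
                f"stride ({s}, {e}) shorter than 4 samples; cannot analyse"
            )
        out.append(
            {
                "dpf": trial.dpf[s:e].copy(),
                "inev": trial.inev[s:e].copy(),
                "abdadd": trial.abdadd[s:e].copy(),
            }
        )
    return out
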