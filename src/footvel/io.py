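"""Data model and delimited-text I/O for foot-mounted IMU angle recordings.

A trial is one foot x condition x subject recording of the three foot angles
(dorsi-plantar flexion, inversion-eversion, abduction-adduction) sampled at a
fixed rate (nominally 30 Hz for the podiatry-grade devices this package
targets).  Trials travel as UTF-8 CSV with a one-line header
``time_s,dpf_deg,inev_deg,abdadd_deg`` and ``# key: value`` metadata comment
lines above it; a session manifest (CSV or YAML) lists the trials of a
measurement session.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FEET = ("left", "right")
CONDITIONS = ("noFO", "FO")
AXES = ("dpf", "inev", "abdadd")

#: CSV column names, fixed dialect.
TIME_COL = "time_s"
ANGLE_COLS = {"dpf": "dpf_deg", "inev": "inev_deg", "abdadd": "abdadd_deg"}

#: Relative tolerance (in samples) for the uniform-sampling invariant.
SAMPLING_TOL_SAMPLES = 0.5


class TrialFormatError(ValueError):
    """Malformed trial file (missing column, bad metadata, non-finite data)."""


class SamplingError(ValueError):
    """Timestamps inconsistent with the declared sampling rate."""


class EmptyTrialError(ValueError):
    """Trial with fewer than two samples."""


@dataclass
class ImuTrial:
    """One foot x condition recording of the three foot angles.

    Angles are in degrees, time in seconds; angular velocities are always
    derived downstream, never stored.  Sign convention: negative values are
    plantar flexion, inversion and abduction.
    """

    subject_id: str
    foot: str
    condition: str
    sampling_rate: float
    t: np.ndarray
    dpf: np.ndarray
    inev: np.ndarray
    abdadd: np.ndarray

    def __post_init__(self) -> None:
        if self.foot not in FEET:
            raise ValueError(f"foot must be one of {FEET}, got {self.foot!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("t", "dpf", "inev", "abdadd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if n < 2:
            raise EmptyTrialError(f"trial has {n} samples; need at least 2")
        for name in ("dpf", "inev", "abdadd"):
            if len(getattr(self, name)) != n:
                raise TrialFormatError(
                    f"channel {name!r} has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
            if not np.all(np.isfinite(getattr(self, name))):
                raise TrialFormatError(f"channel {name!r} contains non-finite samples")
        if not np.all(np.isfinite(self.t)) or np.any(np.diff(self.t) <= 0):
            raise SamplingError("timestamps must be finite and strictly increasing")
        span_samples = self.sampling_rate * (self.t[-1] - self.t[0])
        if abs(span_samples - (n - 1)) > SAMPLING_TOL_SAMPLES:
            raise SamplingError(
                f"time span covers {span_samples:.2f} sampling intervals but the "
                f"trial has {n - 1}; timestamps inconsistent with "
                f"{self.sampling_rate} Hz"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording span in seconds (first to last sample)."""
        return float(self.t[-1] - self.t[0])

    def angles(self, axis: str) -> np.ndarray:
        if axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        return getattr(self, axis)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.foot, self.condition)


@dataclass
class ManifestEntry:
    subject_id: str
    foot: str
    condition: str
    path: str


@dataclass
class SessionManifest:
    """Index of the trial files of one measurement session."""

    entries: list[ManifestEntry] = field(default_factory=list)
    capture_duration: float = 20.0

    def __post_init__(self) -> None:
        keys = [(e.subject_id, e.foot, e.condition) for e in self.entries]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ValueError(f"duplicate (subject, foot, condition) cells: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.subject_id, None)
        return list(seen)


def _repair_gaps(values: np.ndarray, name: str, max_gap: int = 2) -> np.ndarray:
    """Linearly interpolate non-finite runs of length <= max_gap; else raise."""
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    # locate runs of consecutive bad samples
    idx = np.flatnonzero(bad)
    runs: list[list[int]] = [[idx[0]]]
    for i in idx[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    for run in runs:
        if len(run) > max_gap:
            raise TrialFormatError(
                f"channel {name!r}: non-finite gap of {len(run)} samples exceeds "
                f"repairable length {max_gap}"
            )
        if run[0] == 0 or run[-1] == len(values) - 1:
            raise TrialFormatError(
                f"channel {name!r}: non-finite samples at trial edge cannot be "
                "interpolated"
            )
    good = np.flatnonzero(~bad)
    repaired = values.copy()
    repaired[bad] = np.interp(idx, good, values[good])
    logger.warning("repaired %d non-finite samples in channel %s", bad.sum(), name)
    return repaired


def read_trial(
    path: str | os.PathLike,
    *,
    subject_id: str | None = None,
    foot: str | None = None,
    condition: str | None = None,
    sampling_rate: float | None = None,
    repair_gaps: bool = False,
) -> ImuTrial:
    """Read one trial CSV.

    Metadata (subject, foot, condition, sampling rate) is taken from the
    ``# key: value`` comment header and may be overridden by keyword
    arguments.  With ``repair_gaps`` non-finite runs of at most two samples
    are linearly interpolated (and logged); otherwise any non-finite sample
    is a hard :class:`TrialFormatError`.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                break
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyTrialError(f"{path}: no data rows") from None
    missing = [c for c in (TIME_COL, *ANGLE_COLS.values()) if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing required column(s) {missing}")
    if len(df) < 2:
        raise EmptyTrialError(f"{path}: {len(df)} data rows; need at least 2")

    rate = sampling_rate
    if rate is None:
        rate = float(meta.get("sampling_rate_hz", 30.0))
    channels = {}
    for axis, col in ANGLE_COLS.items():
        vals = df[col].to_numpy(dtype=float)
        if repair_gaps:
            vals = _repair_gaps(vals, col)
        channels[axis] = vals
    return ImuTrial(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        foot=foot or meta.get("foot", "left"),
        condition=condition or meta.get("condition", "noFO"),
        sampling_rate=rate,
        t=df[TIME_COL].to_numpy(dtype=float),
        dpf=channels["dpf"],
        inev=channels["inev"],
        abdadd=channels["abdadd"],
    )


def write_trial(trial: ImuTrial, path: str | os.PathLike) -> None:
    """Write a trial CSV that round-trips losslessly through :func:`read_trial`.

    Floats are serialised with ``%.17g`` so the read-back values are
    bit-identical to the in-memory arrays.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# subject_id: {trial.subject_id}\n")
        fh.write(f"# foot: {trial.foot}\n")
        fh.write(f"# condition: {trial.condition}\n")
        fh.write(f"# sampling_rate_hz: {trial.sampling_rate:.17g}\n")
        fh.write(f"{TIME_COL},{ANGLE_COLS['dpf']},{ANGLE_COLS['inev']},"
                 f"{ANGLE_COLS['abdadd']}\n")
        for row in zip(trial.t, trial.dpf, trial.inev, trial.abdadd):
            fh.write(",".join(f"{x:.17g}" for x in row) + "\n")


def read_manifest(path: str | os.PathLike, check_files: bool = True) -> SessionManifest:
    """Read a session manifest (CSV or YAML, by file suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        records = doc.get("trials", [])
        capture = float(doc.get("capture_duration", 20.0))
        entries = [
            ManifestEntry(str(r["subject_id"]), r["foot"], r["condition"], r["path"])
            for r in records
        ]
    else:
        capture = 20.0
        entries = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#") and ":" in line:
                    k, v = line[1:].split(":", 1)
                    if k.strip() == "capture_duration":
                        capture = float(v)
            fh.seek(0)
            reader = csv.DictReader(
                (ln for ln in fh if not ln.startswith("#"))
            )
            for row in reader:
                entries.append(
                    ManifestEntry(
                        row["subject_id"], row["foot"], row["condition"], row["path"]
                    )
                )
    manifest = SessionManifest(entries=entries, capture_duration=capture)
    if check_files:
        base = path.parent
        for e in manifest.entries:
            p = Path(e.path)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
    return manifest


def write_manifest(manifest: SessionManifest, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# capture_duration: {manifest.capture_duration:g}\n")
        fh.write("subject_id,foot,condition,path\n")
        for e in manifest.entries:
            fh.write(f"{e.subject_id},{e.foot},{e.condition},{e.path}\n")


def resolve_entry_path(manifest_path: str | os.PathLike, entry: ManifestEntry) -> Path:
    p = Path(entry.path)
    if p.is_absolute():
        return p
    return Path(manifest_path).parent / p
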