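"""Synthetic running-gait generator with exact ground truth.

Real recordings of the kind this pipeline targets are typically not
shareable, so every downstream stage is validated against trials generated
here.  Each axis of foot motion carries a periodic angle template (a
truncated Fourier series over one gait cycle) whose derivative reproduces
the qualitative angular-velocity shape of slow treadmill running
(2.5 m/s, stride frequency ~1.3 Hz):

* a brief plantar-flexion notch right after initial contact ("foot slap");
* a negative-velocity dip during early stance, placing the signed velocity
  minimum between 10% and 30% of the cycle;
* a sharp positive burst at heel rise, placing the signed maximum between
  30% and 40%;
* a push-off dip followed by the upward zero crossing of the sagittal
  velocity near 60% of the cycle (end of stance);
* a broad positive swing-phase plateau that closes the cycle.

The sagittal (dorsi-plantar flexion) amplitude dominates the frontal and
transverse axes.  Trials add stride-time jitter (log-normal cycle-duration
multipliers), per-stride amplitude jitter, a per-subject amplitude factor
shared across that subject's four cells, additive white sensor noise, an
optional orthosis effect (multiplicative velocity scaling confined to the
30-60% impulse window with a 5% cosine taper), and a left/right amplitude
imbalance realising a requested asymmetry index.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    AXES,
    CONDITIONS,
    FEET,
    ImuTrial,
    ManifestEntry,
    SessionManifest,
    write_manifest,
    write_trial,
)

logger = logging.getLogger(__name__)

#: Nominal stride frequency (Hz) the template velocities are scaled to.
REFERENCE_STRIDE_FREQUENCY = 1.3

#: Impulse-phase window (cycle fractions) and taper width for injected effects.
IMPULSE_WINDOW = (0.30, 0.60)
IMPULSE_TAPER = 0.05

#: Harmonics kept for base templates / condition-modified templates.
_K_BASE = 32
_K_MOD = 64
_FINE = 4096

# Velocity bump catalogue per axis: (center, sigma, amplitude) in cycle
# fraction / cycle fraction / deg/s at the reference stride frequency.  The
# swing-phase bump (center, sigma) has its amplitude solved so each cycle
# integrates to zero (periodic angle).
_BUMPS: dict[str, dict] = {
    "dpf": {
        "fixed": [
            (0.02, 0.030, -60.0),   # foot-slap notch after initial contact
            (0.20, 0.050, -300.0),  # early-stance plantar-flexion dip
            (0.35, 0.030, 320.0),   # heel-rise burst
            (0.50, 0.050, -280.0),  # push-off dip
        ],
        "swing": (0.78, 0.13),
        "scale": 1.0,
    },
    "inev": {
        "fixed": [
            (0.02, 0.030, -60.0),
            (0.20, 0.050, -300.0),
            (0.35, 0.030, 320.0),
            (0.53, 0.050, -280.0),
        ],
        "swing": (0.80, 0.13),
        "scale": 0.12,
    },
    "abdadd": {
        "fixed": [
            (0.02, 0.030, -60.0),
            (0.20, 0.050, -300.0),
            (0.35, 0.030, 320.0),
            (0.52, 0.050, -280.0),
        ],
        "swing": (0.80, 0.13),
        "scale": 0.30,
    },
}


def impulse_taper_window(
    u: np.ndarray,
    lo: float = IMPULSE_WINDOW[0],
    hi: float = IMPULSE_WINDOW[1],
    taper: float = IMPULSE_TAPER,
) -> np.ndarray:
    """Cosine-tapered box on [lo, hi]: 1 on [lo+taper, hi-taper], 0 outside."""
    u = np.asarray(u, dtype=float)
    w = np.zeros_like(u)
    core = (u >= lo + taper) & (u <= hi - taper)
    w[core] = 1.0
    up = (u >= lo) & (u < lo + taper)
    w[up] = 0.5 * (1.0 - np.cos(np.pi * (u[up] - lo) / taper))
    dn = (u > hi - taper) & (u <= hi)
    w[dn] = 0.5 * (1.0 - np.cos(np.pi * (hi - u[dn]) / taper))
    return w


@dataclass
class AxisTemplate:
    """One axis of the cycle model: angle(u) = a0 + c0*u + Fourier series.

    ``a``/``b`` are the cosine/sine angle coefficients in degrees;
    ``c0`` (deg/cycle) is the secular velocity term, zero for periodic base
    templates and nonzero only for condition-modified templates whose cycle
    no longer integrates to zero.
    """

    a0: float
    c0: float
    a: np.ndarray
    b: np.ndarray

    def _arg(self, u: np.ndarray) -> np.ndarray:
        k = np.arange(1, len(self.a) + 1)
        return 2.0 * np.pi * np.multiply.outer(np.asarray(u, dtype=float), k)

    def angle(self, u) -> np.ndarray:
        """Angle in degrees at cycle fraction(s) u."""
        arg = self._arg(u)
        return (
            self.a0
            + self.c0 * np.asarray(u, dtype=float)
            + np.cos(arg) @ self.a
            + np.sin(arg) @ self.b
        )

    def velocity(self, u) -> np.ndarray:
        """d(angle)/du in degrees per cycle at cycle fraction(s) u."""
        k = np.arange(1, len(self.a) + 1)
        arg = self._arg(u)
        return (
            self.c0
            - np.sin(arg) @ (self.a * 2.0 * np.pi * k)
            + np.cos(arg) @ (self.b * 2.0 * np.pi * k)
        )

    @property
    def periodic(self) -> bool:
        return self.c0 == 0.0

    def amplitude(self, n: int = 512) -> float:
        """Peak-to-peak angle amplitude (degrees) over one cycle."""
        u = np.arange(n) / n
        return float(np.ptp(self.angle(u)))


@dataclass
class GaitTemplate:
    """Per-axis periodic angle templates for one gait cycle.

    Invariants: every axis is periodic (pure Fourier series, c0 == 0), the
    template is not flat, and the sagittal (dpf) amplitude strictly
    dominates the other two axes.
    """

    axes: dict[str, AxisTemplate]

    def __post_init__(self) -> None:
        missing = [ax for ax in AXES if ax not in self.axes]
        if missing:
            raise ValueError(f"template missing axes {missing}")
        for ax, mod in self.axes.items():
            if not mod.periodic:
                raise ValueError(f"axis {ax!r} template is not periodic (c0 != 0)")
        amps = {ax: self.axes[ax].amplitude() for ax in AXES}
        if any(a == 0.0 for a in amps.values()):
            raise ValueError("flat (zero-amplitude) axis template rejected")
        if not (amps["dpf"] > amps["inev"] and amps["dpf"] > amps["abdadd"]):
            raise ValueError(
                "dorsi-plantar flexion amplitude must strictly dominate: "
                f"{amps}"
            )


def _velocity_to_angle_model(v_fine: np.ndarray, k_max: int) -> AxisTemplate:
    """Fit an AxisTemplate to a velocity signal (deg/cycle) on the fine grid."""
    m = len(v_fine)
    c0 = float(v_fine.mean())
    spec = np.fft.rfft(v_fine - c0) / m
    k = np.arange(1, k_max + 1)
    v_cos = 2.0 * spec[1 : k_max + 1].real
    v_sin = -2.0 * spec[1 : k_max + 1].imag
    # integrate each harmonic analytically
    a = -v_sin / (2.0 * np.pi * k)
    b = v_cos / (2.0 * np.pi * k)
    return AxisTemplate(a0=0.0, c0=c0, a=a, b=b)


def _wrapped_gauss(u: np.ndarray, center: float, sigma: float) -> np.ndarray:
    d = (u - center + 0.5) % 1.0 - 0.5
    return np.exp(-0.5 * (d / sigma) ** 2)


def make_default_template() -> GaitTemplate:
    """Build the default three-axis gait template.

    The fine-grid velocity shapes are assembled from the bump catalogue,
    the swing-phase amplitude is solved so each cycle integrates to zero,
    and all axes are phase-shifted together so the sagittal angle maximum
    sits exactly at 0% of the cycle (the stride boundary the segmenter
    detects).
    """
    u = np.arange(_FINE) / _FINE
    t_ref = 1.0 / REFERENCE_STRIDE_FREQUENCY
    v_axes: dict[str, np.ndarray] = {}
    for ax, cfg in _BUMPS.items():
        v = np.zeros(_FINE)
        for center, sigma, amp in cfg["fixed"]:
            v += amp * _wrapped_gauss(u, center, sigma)
        sw = _wrapped_gauss(u, *cfg["swing"])
        v += (-v.mean() / sw.mean()) * sw
        v -= v.mean()  # numerical residual
        v_axes[ax] = cfg["scale"] * v * t_ref  # deg/s -> deg/cycle

    # phase-shift all axes so the dpf ANGLE maximum is at u = 0
    theta_dpf = np.concatenate(
        ([0.0], np.cumsum(0.5 * (v_axes["dpf"][1:] + v_axes["dpf"][:-1])) / _FINE)
    )
    shift = int(np.argmax(theta_dpf[:_FINE]))
    axes = {
        ax: _velocity_to_angle_model(np.roll(v, -shift), _K_BASE)
        for ax, v in v_axes.items()
    }
    for mod in axes.values():  # base templates are strictly periodic
        mod.c0 = 0.0
    return GaitTemplate(axes=axes)


def apply_condition_effect(
    template: GaitTemplate, effect: dict[str, float]
) -> dict[str, AxisTemplate]:
    """Scale template velocity inside the tapered impulse window.

    Returns per-axis cycle models whose velocity is
    ``v * (1 + (c - 1) * w(u))`` with ``w`` the cosine-tapered 30-60% window.
    The modified cycle generally no longer integrates to zero; the residual
    appears as the secular term c0 (a per-cycle angle drift), exactly as a
    real change of motion inside one sub-phase would produce.
    """
    u = np.arange(_FINE) / _FINE
    w = impulse_taper_window(u)
    out: dict[str, AxisTemplate] = {}
    for ax in AXES:
        c = float(effect.get(ax, 1.0))
        base = template.axes[ax]
        if c == 1.0:
            out[ax] = base
            continue
        v = base.velocity(u) * (1.0 + (c - 1.0) * w)
        out[ax] = _velocity_to_angle_model(v, _K_MOD)
    return out


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the treadmill protocol the generator emulates: 40
    subjects, 20 s captures at 30 Hz, stride frequency 1.3 Hz (running at
    2.5 m/s), mild stride-to-stride jitter, 0.5 deg additive sensor noise,
    a 10% CV subject-level amplitude factor, an orthosis effect confined to
    the impulse window (slight sagittal decrease, frontal increase,
    transverse decrease), and a left/right imbalance producing asymmetry
    indices of roughly 0/20/25% on the three axes.
    """

    n_subjects: int = 40
    stride_frequency: float = 1.3
    duration: float = 20.0
    sampling_rate: float = 30.0
    stride_time_jitter: float = 0.03
    amplitude_jitter: float = 0.05
    noise_sd: float = 0.5
    subject_effect_sd: float = 0.10
    condition_effect: dict[str, float] = field(
        default_factory=lambda: {"dpf": 0.98, "inev": 1.30, "abdadd": 0.86}
    )
    asymmetry_target: dict[str, float] = field(
        default_factory=lambda: {"dpf": 0.0, "inev": 20.0, "abdadd": 25.0}
    )

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.condition_effect, (int, float)):
            self.condition_effect = {ax: float(self.condition_effect) for ax in AXES}
        if isinstance(self.asymmetry_target, (int, float)):
            self.asymmetry_target = {ax: float(self.asymmetry_target) for ax in AXES}
        for name in (
            "stride_time_jitter",
            "amplitude_jitter",
            "noise_sd",
            "subject_effect_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sampling_rate <= 0 or self.stride_frequency <= 0:
            raise ValueError("rates must be positive")
        if self.stride_frequency * self.duration < 3:
            raise ValueError(
                "duration too short: fewer than 3 strides at the requested "
                "stride frequency"
            )
        for ax, a in self.asymmetry_target.items():
            if not 0.0 <= a < 100.0:
                raise ValueError(f"asymmetry_target[{ax!r}] must be in [0, 100)")


@dataclass
class GroundTruth:
    """Exact bookkeeping of one simulated trial."""

    subject_id: str
    foot: str
    condition: str
    peak_times: list[float]           # sagittal angle maxima inside the record
    stride_bounds: list[tuple[float, float]]  # complete max->max cycles (s)
    stride_durations: list[float]
    amp_factors: dict[str, list[float]]       # per-stride, per-axis
    subject_factors: dict[str, float]
    condition_scale: dict[str, float]
    asymmetry_factor: dict[str, float]

    @property
    def stride_count(self) -> int:
        return len(self.stride_bounds)


def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _trial_rng(cfg: SimConfig, subject_id: str, foot: str, condition: str):
    key = (2, _crc(subject_id), FEET.index(foot), CONDITIONS.index(condition))
    return np.random.default_rng(np.random.SeedSequence(cfg.rng_seed, spawn_key=key))


def _subject_factors(cfg: SimConfig, subject_id: str) -> dict[str, float]:
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.rng_seed, spawn_key=(1, _crc(subject_id)))
    )
    sd = cfg.subject_effect_sd
    return {ax: float(np.exp(rng.normal(0.0, sd))) for ax in AXES}


def simulate_trial(
    template: GaitTemplate,
    cfg: SimConfig,
    subject_id: str,
    foot: str,
    condition: str,
) -> tuple[ImuTrial, GroundTruth]:
    """Simulate one 20 s (by default) trial plus its exact ground truth.

    Randomness is drawn from a stream keyed by (seed, subject, foot,
    condition), so the same cell is bit-identical regardless of generation
    order, and the subject-level amplitude factor is shared across the
    subject's four cells.
    """
    rng = _trial_rng(cfg, subject_id, foot, condition)
    subj = _subject_factors(cfg, subject_id)
    asym = {
        ax: (1.0 - cfg.asymmetry_target[ax] / 100.0) if foot == "left" else 1.0
        for ax in AXES
    }
    if condition == "FO":
        models = apply_condition_effect(template, cfg.condition_effect)
        cond_scale = dict(cfg.condition_effect)
    else:
        models = dict(template.axes)
        cond_scale = {ax: 1.0 for ax in AXES}

    fs = cfg.sampling_rate
    n = int(round(cfg.duration * fs))
    t = np.arange(n) / fs
    t_end = t[-1]
    t0 = 1.0 / cfg.stride_frequency

    # cycle plan: start mid-swing (phase 0.5) so all sagittal maxima are
    # interior to the record, mirroring the discard of transition steps
    starts = [0.0]
    periods: list[float] = []
    u_starts: list[float] = []
    first = True
    while starts[-1] <= t_end:
        mult = float(np.exp(rng.normal(0.0, cfg.stride_time_jitter)))
        period = t0 * mult
        u0 = 0.5 if first else 0.0
        periods.append(period)
        u_starts.append(u0)
        starts.append(starts[-1] + period * (1.0 - u0))
        first = False
    starts_arr = np.asarray(starts)
    n_cycles = len(periods)

    amp_factors = {
        ax: np.exp(rng.normal(0.0, cfg.amplitude_jitter, size=n_cycles))
        for ax in AXES
    }

    cyc = np.clip(np.searchsorted(starts_arr, t, side="right") - 1, 0, n_cycles - 1)
    u_start_arr = np.asarray(u_starts)
    period_arr = np.asarray(periods)
    u = u_start_arr[cyc] + (t - starts_arr[cyc]) / period_arr[cyc]
    u = np.clip(u, 0.0, 1.0)
    channels: dict[str, np.ndarray] = {}
    for ax in AXES:
        model = models[ax]
        gains = subj[ax] * asym[ax] * amp_factors[ax]
        # accumulate angle offsets so the signal is continuous across cycles
        theta_start = np.asarray([float(model.angle(us)) for us in u_starts])
        theta_end = float(model.angle(1.0))
        offsets = np.empty(n_cycles)
        offsets[0] = 0.0
        for k in range(n_cycles - 1):
            offsets[k + 1] = offsets[k] + gains[k] * (theta_end - theta_start[k])
        base = model.angle(u) - theta_start[cyc]
        channels[ax] = offsets[cyc] + gains[cyc] * base
    noise = rng.normal(0.0, cfg.noise_sd, size=(3, n)) if cfg.noise_sd > 0 else 0.0
    trial = ImuTrial(
        subject_id=subject_id,
        foot=foot,
        condition=condition,
        sampling_rate=fs,
        t=t,
        dpf=channels["dpf"] + (noise[0] if cfg.noise_sd > 0 else 0.0),
        inev=channels["inev"] + (noise[1] if cfg.noise_sd > 0 else 0.0),
        abdadd=channels["abdadd"] + (noise[2] if cfg.noise_sd > 0 else 0.0),
    )

    peak_times = [float(s) for s in starts_arr[1:-1] if 0.0 < s < t_end]
    bounds = []
    durations = []
    kept_amp = {ax: [] for ax in AXES}
    for k in range(1, n_cycles):
        s, e = starts_arr[k], starts_arr[k + 1]
        if s >= 0.0 and e <= t_end:
            bounds.append((float(s), float(e)))
            durations.append(float(periods[k]))
            for ax in AXES:
                kept_amp[ax].append(float(amp_factors[ax][k]))
    gt = GroundTruth(
        subject_id=subject_id,
        foot=foot,
        condition=condition,
        peak_times=peak_times,
        stride_bounds=bounds,
        stride_durations=durations,
        amp_factors=kept_amp,
        subject_factors=subj,
        condition_scale=cond_scale,
        asymmetry_factor=asym,
    )
    if gt.stride_count < 3:
        raise ValueError(
            f"duration {cfg.duration}s too short: only {gt.stride_count} "
            "complete strides"
        )
    return trial, gt


@dataclass
class CohortResult:
    manifest: SessionManifest
    trials: dict[tuple[str, str, str], ImuTrial]
    ground_truth: dict[tuple[str, str, str], GroundTruth]


def simulate_cohort(
    cfg: SimConfig,
    template: GaitTemplate | None = None,
    out_dir: str | Path | None = None,
) -> CohortResult:
    """Simulate the full paired cohort (every subject x foot x condition).

    With ``out_dir`` the trials, manifest and ground truth are also written
    to disk (trial CSVs, ``manifest.csv``, ``ground_truth.json``).
    """
    if template is None:
        template = make_default_template()
    trials: dict[tuple[str, str, str], ImuTrial] = {}
    gts: dict[tuple[str, str, str], GroundTruth] = {}
    entries: list[ManifestEntry] = []
    for i in range(cfg.n_subjects):
        subject = f"S{i + 1:03d}"
        for foot in FEET:
            for condition in CONDITIONS:
                trial, gt = simulate_trial(template, cfg, subject, foot, condition)
                key = (subject, foot, condition)
                trials[key] = trial
                gts[key] = gt
                entries.append(
                    ManifestEntry(
                        subject, foot, condition,
                        f"{subject}_{foot}_{condition}.csv",
                    )
                )
    manifest = SessionManifest(entries=entries, capture_duration=cfg.duration)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for e in manifest.entries:
            write_trial(trials[(e.subject_id, e.foot, e.condition)], out / e.path)
        write_manifest(manifest, out / "manifest.csv")
        gt_doc = {
            "|".join(k): dataclasses.asdict(v) for k, v in gts.items()
        }
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(gt_doc, fh, indent=1, sort_keys=True)
        logger.info("wrote %d trials to %s", len(trials), out)
    return CohortResult(manifest=manifest, trials=trials, ground_truth=gts)
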