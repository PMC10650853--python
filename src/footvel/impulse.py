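"""Impulse-phase summaries and the limb-asymmetry index.

The impulse phase spans roughly 30% to 60% of the running cycle (from the
end of the foot-flat phase to the end of stance).  On the 101-node grid
that window is nodes 30..60 inclusive (31 nodes).  The asymmetry index
compares the two limbs' summary magnitudes,

    asymmetry = 100 * (1 - min(|L|, |R|) / max(|L|, |R|)),

so 0 means perfect symmetry and the direction of the imbalance is
deliberately not analysed; values above 15% are flagged, a threshold
associated in the sports-medicine literature with elevated injury risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .curves import CycleCurve

logger = logging.getLogger(__name__)

#: Inclusive node window of the impulse phase on the 101-node grid.
IMPULSE_WINDOW_NODES = (30, 60)

#: Asymmetry above this percentage is flagged as an injury-risk heuristic.
ASYMMETRY_FLAG_THRESHOLD = 15.0


class UndefinedAsymmetryError(ValueError):
    """Asymmetry index is undefined when the larger magnitude is zero."""


@dataclass
class ImpulseSummary:
    """Group impulse-phase mean angular velocity for one analysis cell."""

    axis: str
    foot: str
    condition: str
    value: float  # deg/s, mean over nodes 30..60 of the group velocity curve
    n_subjects: int
    per_subject: np.ndarray  # retained for paired tests

    def __post_init__(self) -> None:
        self.per_subject = np.asarray(self.per_subject, dtype=float)
        if not np.isfinite(self.value):
            raise ValueError("impulse summary value must be finite")


@dataclass
class AsymmetryResult:
    axis: str
    condition: str
    asymmetry: float  # percent
    flag_15: bool

    def __post_init__(self) -> None:
        if self.flag_15 != (self.asymmetry > ASYMMETRY_FLAG_THRESHOLD):
            raise ValueError("flag_15 inconsistent with the 15% threshold")


def impulse_mean(
    curve: CycleCurve, window: tuple[int, int] = IMPULSE_WINDOW_NODES
) -> float:
    """Mean of a velocity curve over the impulse window (nodes inclusive)."""
    if curve.kind != "velocity":
        raise ValueError(f"impulse mean is defined on velocity curves, got "
                         f"{curve.kind!r}")
    lo, hi = window
    if not (0 <= lo < hi <= 100):
        raise ValueError("window must satisfy 0 <= lo < hi <= 100")
    return float(curve.values[lo : hi + 1].mean())


def asymmetry_index(left: float, right: float) -> float:
    """Limb-asymmetry percentage of two summary magnitudes.

    Computed on absolute values, so the sign convention of either limb's
    summary cannot flip the index; the direction of the difference is not
    analysed.
    """
    lo, hi = sorted((abs(left), abs(right)))
    if hi == 0.0:
        raise UndefinedAsymmetryError(
            "asymmetry undefined: both magnitudes are zero"
        )
    # algebraically -100 * (min/max) + 100, arranged so equal magnitudes
    # give exactly zero
    return 100.0 * (1.0 - lo / hi)


def asymmetry_result(left: float, right: float, axis: str, condition: str
                     ) -> AsymmetryResult:
    asym = asymmetry_index(left, right)
    return AsymmetryResult(
        axis=axis,
        condition=condition,
        asymmetry=asym,
        flag_15=asym > ASYMMETRY_FLAG_THRESHOLD,
    )


def condition_difference(nonfo: float, fo: float) -> tuple[float, str]:
    """Magnitude change between conditions and its direction.

    Returns (| |nonfo| - |fo| |, "decrease" if the magnitude drops with the
    orthosis else "increase").  Ties report "decrease" by convention and are
    logged.
    """
    if not (np.isfinite(nonfo) and np.isfinite(fo)):
        raise ValueError("condition difference requires finite inputs")
    a, b = abs(nonfo), abs(fo)
    if a == b:
        logger.info("condition difference tie (|%g| == |%g|); reporting "
                    "'decrease' by convention", nonfo, fo)
        return 0.0, "decrease"
    return abs(a - b), ("decrease" if b < a else "increase")
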