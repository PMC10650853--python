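"""Paired scalar inference and one-dimensional statistical parametric mapping.

Scalars: two-sided paired t test on per-subject differences with a 95%
t-based confidence interval, Cohen's d for paired data (mean difference /
SD of differences) categorised at the 0.2 / 0.5 / 0.8 cutpoints, and a
Shapiro-Wilk normality check on the differences reported as a gate (a
logged caution, never an automatic switch to a nonparametric test).

Curves: the node-wise paired t statistic over the whole 0-100% cycle with
family-wise inference by sign-flipping the subject difference curves.  The
curve-level critical threshold is the (1 - alpha) quantile of the max-|t|
permutation distribution; suprathreshold clusters get cluster-extent
p-values from the same permutations.  For n <= 12 subjects all 2^n sign
patterns are enumerated, making the inference exact and Monte-Carlo-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .curves import N_NODES, CycleCurve

logger = logging.getLogger(__name__)

EXHAUSTIVE_MAX_N = 12

EFFECT_CUTPOINTS = (0.2, 0.5, 0.8)
EFFECT_CATEGORIES = ("insignificant", "small", "medium", "large")


class DegenerateTestError(ValueError):
    """Paired test undefined (zero-variance differences or too few pairs)."""


@dataclass
class PairedResult:
    comparison: str
    n: int
    mean_diff: float
    ci95: tuple[float, float]
    t: float
    p_value: float
    d_cohen: float
    effect_category: str
    normality_p: float


@dataclass
class SpmCluster:
    start: int  # cycle-percent node, inclusive
    end: int    # cycle-percent node, inclusive
    p_value: float

    @property
    def extent(self) -> int:
        return self.end - self.start + 1


@dataclass
class SpmResult:
    t_curve: np.ndarray
    threshold: float
    clusters: list[SpmCluster]
    alpha: float
    n: int
    n_perm: int
    exhaustive: bool

    def significant_clusters(self) -> list[SpmCluster]:
        return [c for c in self.clusters if c.p_value <= self.alpha]


def categorize_effect(d: float) -> str:
    """Effect-size category by |d|: <=0.2 insignificant, <=0.5 small,
    <=0.8 medium, >0.8 large."""
    if not np.isfinite(d):
        raise ValueError("effect size must be finite")
    m = abs(d)
    for cut, cat in zip(EFFECT_CUTPOINTS, EFFECT_CATEGORIES):
        if m <= cut:
            return cat
    return EFFECT_CATEGORIES[-1]


def paired_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    comparison: str = "a vs b",
    alpha: float = 0.05,
) -> PairedResult:
    """Two-sided paired t test of a - b with CI, Cohen's d and normality gate."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    n = len(a)
    if n < 3:
        raise DegenerateTestError(f"need at least 3 pairs, got {n}")
    diff = a - b
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        raise DegenerateTestError("zero-variance differences: t undefined")
    mean = float(diff.mean())
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    tcrit = float(sps.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    d = mean / sd
    norm_p = float(sps.shapiro(diff).pvalue)
    if norm_p < 0.05:
        logger.warning(
            "%s: Shapiro-Wilk p=%.3g < 0.05; paired t reported anyway "
            "(interpret with caution)", comparison, norm_p
        )
    return PairedResult(
        comparison=comparison,
        n=n,
        mean_diff=mean,
        ci95=(mean - tcrit * se, mean + tcrit * se),
        t=float(t),
        p_value=p,
        d_cohen=float(d),
        effect_category=categorize_effect(d),
        normality_p=norm_p,
    )


def _paired_t_curve(diffs: np.ndarray) -> np.ndarray:
    """Node-wise one-sample t of difference curves (rows = subjects)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.zeros(diffs.shape[1])
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    bad = ~ok & (mean != 0)
    t[bad] = np.sign(mean[bad]) * np.inf
    return t


def _max_run_lengths(above: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a boolean matrix."""
    run = np.zeros(above.shape[0], dtype=int)
    best = np.zeros(above.shape[0], dtype=int)
    for j in range(above.shape[1]):
        run = (run + 1) * above[:, j]
        best = np.maximum(best, run)
    return best


def _clusters_above(t_abs: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = t_abs > threshold
    clusters = []
    start = None
    for j, flag in enumerate(above):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            clusters.append((start, j - 1))
            start = None
    if start is not None:
        clusters.append((start, len(above) - 1))
    return clusters


def spm_paired(
    curves_a: list[CycleCurve] | np.ndarray,
    curves_b: list[CycleCurve] | np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = None,
) -> SpmResult:
    """Whole-curve paired comparison with sign-flip permutation inference.

    ``curves_a``/``curves_b`` are the same subjects' cycle curves in the two
    conditions, in matching order (or equivalently (n, 101) arrays).  The
    observed sign pattern is always included in the permutation null, and
    with n <= 12 subjects all 2^n patterns are enumerated exactly.
    """
    A = _as_matrix(curves_a)
    B = _as_matrix(curves_b)
    if A.shape != B.shape:
        raise ValueError("the two conditions must contain the same subjects")
    n = A.shape[0]
    if n < 5:
        raise ValueError(f"SPM needs at least 5 paired subjects, got {n}")
    D = A - B
    t_obs = _paired_t_curve(D)

    if n <= EXHAUSTIVE_MAX_N:
        m = 2 ** n
        bits = (np.arange(m)[:, None] >> np.arange(n)) & 1
        signs = 1.0 - 2.0 * bits
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        signs[0] = 1.0  # include the observed labelling
        m = n_perm
        exhaustive = False

    ssq = (D ** 2).sum(axis=0)
    means = (signs @ D) / n
    var = (ssq[None, :] - n * means ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / np.sqrt(var / n)
    t_perm[~np.isfinite(t_perm)] = 0.0
    t_abs = np.abs(t_perm)
    max_t = t_abs.max(axis=1)
    threshold = float(np.quantile(max_t, 1.0 - alpha, method="higher"))

    clusters = []
    obs_abs = np.abs(t_obs)
    spans = _clusters_above(obs_abs, threshold)
    if spans:
        perm_extents = _max_run_lengths(t_abs > threshold)
        for start, end in spans:
            extent = end - start + 1
            p = float((perm_extents >= extent).mean())
            clusters.append(SpmCluster(start=start, end=end, p_value=p))
    return SpmResult(
        t_curve=t_obs,
        threshold=threshold,
        clusters=clusters,
        alpha=alpha,
        n=n,
        n_perm=m,
        exhaustive=exhaustive,
    )


def _as_matrix(curves) -> np.ndarray:
    if isinstance(curves, np.ndarray):
        mat = np.asarray(curves, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != N_NODES:
            raise ValueError(f"curve matrix must be (n, {N_NODES})")
        return mat
    rows = []
    for c in curves:
        if not isinstance(c, CycleCurve):
            raise TypeError("expected CycleCurve instances or an (n, 101) array")
        rows.append(c.values)
    return np.vstack(rows)
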