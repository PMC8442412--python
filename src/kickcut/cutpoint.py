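"""Cut-score mathematics for the contrasting-groups standard-setting method.

The cutoff between a criterion-meeting ("hi") group and a criterion-failing
("lo") group is the intersection of the two fitted normal densities.  With
equal variances that is the mean midpoint; otherwise equating the densities

    N(x; mu1, s1) = N(x; mu2, s2)

gives the quadratic

    (s1^2 - s2^2) x^2 - 2 (s1^2 mu2 - s2^2 mu1) x
        + s1^2 mu2^2 - s2^2 mu1^2 - 2 s1^2 s2^2 ln(s1/s2) = 0

whose root strictly between the two means is the cutoff.  Candidate integer
levels around the continuous cutoff are validated by classification
accuracy, with exact accuracy ties broken by sensitivity and any residual
tie by the lower (scoring-friendlier) level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "GroupStats",
    "CutpointSolution",
    "ValidityIndices",
    "LevelDecision",
    "IntersectionMethod",
    "IndexBasis",
    "SelectionResult",
    "DegenerateGroupError",
    "InseparableGroupsError",
    "fit_group_stats",
    "gaussian_intersection",
    "intersection_oracle",
    "empirical_validity",
    "model_validity",
    "candidate_levels",
    "select_level",
    "round_half_up",
]


class DegenerateGroupError(ValueError):
    """Group too small or with zero variance to fit normal statistics."""


class InseparableGroupsError(ValueError):
    """The two groups have equal means: no cutoff lies between them."""


class IntersectionMethod(str, Enum):
    EQUAL_VARIANCE_MIDPOINT = "equal_variance_midpoint"
    QUADRATIC = "quadratic"
    #: No quadratic root fell strictly between the means (the crossing of two
    #: nearly-equal-SD densities is ill-conditioned), so the equal-variance
    #: midpoint was used instead.  Only produced with ``midpoint_fallback``.
    MIDPOINT_FALLBACK = "midpoint_fallback"


class IndexBasis(str, Enum):
    EMPIRICAL = "empirical"
    MODEL = "model"


@dataclass(frozen=True)
class GroupStats:
    """Sample size, mean and (n-1 denominator) SD of one contrast group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateGroupError(f"group needs n >= 2, got n={self.n}")
        if not self.sd > 0:
            raise DegenerateGroupError(f"group sd must be positive, got {self.sd}")

    def pdf(self, x: float | np.ndarray) -> float | np.ndarray:
        return norm.pdf(x, self.mean, self.sd)


@dataclass(frozen=True)
class CutpointSolution:
    """Continuous cutoff with all density crossings and the method used."""

    cutoff: float
    all_roots: tuple[float, ...]
    method: IntersectionMethod


@dataclass(frozen=True)
class ValidityIndices:
    """Classification accuracy, sensitivity and specificity at one cutoff."""

    accuracy: float
    sensitivity: float
    specificity: float
    basis: IndexBasis
    counts: Optional[tuple[int, int, int, int]] = None  # (TP, FP, TN, FN)

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class LevelDecision:
    """Outcome of integer-level selection around a continuous cutoff."""

    continuous_cutoff: float
    candidates: tuple[tuple[int, ValidityIndices], ...]
    selected_level: int
    tie_broken: bool

    def __post_init__(self) -> None:
        if self.selected_level not in {lvl for lvl, _ in self.candidates}:
            raise ValueError("selected_level must be one of the candidates")


class SelectionResult(NamedTuple):
    selected_level: int
    tie_broken: bool


def fit_group_stats(impacts: Sequence[float]) -> GroupStats:
    """Fit (n, mean, sample SD) to one group's impact values.

    Raises :class:`DegenerateGroupError` for fewer than two values or zero
    variance.
    """
    arr = np.asarray(impacts, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise DegenerateGroupError(
            f"need at least 2 values to fit group statistics, got {arr.size}"
        )
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise DegenerateGroupError("group has zero variance")
    return GroupStats(n=int(arr.size), mean=float(np.mean(arr)), sd=sd)


_EQUAL_SD_RTOL = 1e-12
_DENSITY_RTOL = 1e-9


def gaussian_intersection(
    hi: GroupStats,
    lo: GroupStats,
    *,
    midpoint_fallback: bool = False,
) -> CutpointSolution:
    """Intersection of the two fitted normal densities between the means.

    Equal SDs (within 1e-12 relative) yield the closed-form mean midpoint;
    otherwise the quadratic above is solved and the unique root strictly
    between the means becomes the cutoff, with both crossings retained in
    ``all_roots``.  The result is label-order invariant.

    When the SDs differ only slightly relative to the mean gap, both
    quadratic roots can legitimately fall outside the open interval between
    the means (the log-variance-ratio term dominates).  By default that
    raises; with ``midpoint_fallback=True`` the equal-variance midpoint is
    returned instead, flagged as :attr:`IntersectionMethod.MIDPOINT_FALLBACK`,
    which is the correct limit when the underlying variances are equal and
    the fitted difference is sampling noise.

    Raises
    ------
    InseparableGroupsError
        If the group means are equal, or (without the fallback) no density
        crossing lies strictly between them.
    """
    if hi.mean == lo.mean:
        raise InseparableGroupsError(
            "groups not separable: equal means, no cutoff between them"
        )
    m_lo, m_hi = sorted((hi.mean, lo.mean))
    if math.isclose(hi.sd, lo.sd, rel_tol=_EQUAL_SD_RTOL):
        cutoff = 0.5 * (hi.mean + lo.mean)
        return CutpointSolution(
            cutoff=cutoff,
            all_roots=(cutoff,),
            method=IntersectionMethod.EQUAL_VARIANCE_MIDPOINT,
        )
    s1sq, s2sq = hi.sd**2, lo.sd**2
    a = s1sq - s2sq
    b = -2.0 * (s1sq * lo.mean - s2sq * hi.mean)
    c = (
        s1sq * lo.mean**2
        - s2sq * hi.mean**2
        - 2.0 * s1sq * s2sq * math.log(hi.sd / lo.sd)
    )
    disc = b * b - 4.0 * a * c
    if disc < 0:  # cannot occur for distinct valid normals, but guard
        raise InseparableGroupsError("densities have no real crossing")
    sqrt_disc = math.sqrt(disc)
    roots = tuple(sorted(((-b - sqrt_disc) / (2 * a), (-b + sqrt_disc) / (2 * a))))
    between = [r for r in roots if m_lo < r < m_hi]
    if len(between) != 1:
        if midpoint_fallback:
            return CutpointSolution(
                cutoff=0.5 * (hi.mean + lo.mean),
                all_roots=roots,
                method=IntersectionMethod.MIDPOINT_FALLBACK,
            )
        raise InseparableGroupsError(
            f"expected exactly one density crossing in ({m_lo}, {m_hi}), "
            f"found {len(between)}"
        )
    cutoff = between[0]
    p_hi, p_lo = float(hi.pdf(cutoff)), float(lo.pdf(cutoff))
    assert math.isclose(p_hi, p_lo, rel_tol=_DENSITY_RTOL * 1e3), (
        f"density mismatch at cutoff: {p_hi} vs {p_lo}"
    )
    return CutpointSolution(
        cutoff=cutoff, all_roots=roots, method=IntersectionMethod.QUADRATIC
    )


def intersection_oracle(hi: GroupStats, lo: GroupStats, step: float = 1e-4) -> float:
    """Brute-force grid search for the density crossing between the means.

    Independent of :func:`gaussian_intersection`; intended as a test
    oracle.  Scans the open interval between the two means at ``step``
    resolution and returns the grid point minimising the absolute density
    difference.
    """
    if hi.mean == lo.mean:
        raise InseparableGroupsError("groups not separable: equal means")
    if step <= 0:
        raise ValueError("step must be positive")
    m_lo, m_hi = sorted((hi.mean, lo.mean))
    if step >= m_hi - m_lo:
        raise ValueError(
            f"step {step} is not finer than the mean gap {m_hi - m_lo}"
        )
    xs = np.arange(m_lo + step, m_hi, step)
    diff = np.abs(
        norm.pdf(xs, hi.mean, hi.sd) - norm.pdf(xs, lo.mean, lo.sd)
    )
    return float(xs[int(np.argmin(diff))])


def empirical_validity(
    hi_impacts: Sequence[float],
    lo_impacts: Sequence[float],
    cutoff: float,
) -> ValidityIndices:
    """Count-based classification indices at ``cutoff``.

    ``hi`` values at or above the cutoff are true positives, ``lo`` values
    below it true negatives.
    """
    hi = np.asarray(hi_impacts, dtype=float)
    lo = np.asarray(lo_impacts, dtype=float)
    if hi.size == 0 or lo.size == 0:
        raise ValueError("both groups must be non-empty")
    tp = int(np.count_nonzero(hi >= cutoff))
    fn = hi.size - tp
    tn = int(np.count_nonzero(lo < cutoff))
    fp = lo.size - tn
    return ValidityIndices(
        accuracy=(tp + tn) / (tp + fp + tn + fn),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        basis=IndexBasis.EMPIRICAL,
        counts=(tp, fp, tn, fn),
    )


def model_validity(hi: GroupStats, lo: GroupStats, cutoff: float) -> ValidityIndices:
    """Model-based (normal CDF) indices at ``cutoff``.

    Sensitivity is the hi-group upper-tail mass beyond the cutoff,
    specificity the lo-group lower-tail mass below it, and accuracy their
    n-weighted mean.
    """
    sensitivity = float(norm.sf(cutoff, hi.mean, hi.sd))
    specificity = float(norm.cdf(cutoff, lo.mean, lo.sd))
    accuracy = (hi.n * sensitivity + lo.n * specificity) / (hi.n + lo.n)
    return ValidityIndices(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        basis=IndexBasis.MODEL,
    )


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (2.5 -> 3)."""
    return int(math.floor(x + 0.5))


def candidate_levels(continuous_cutoff: float, window: int = 1) -> list[int]:
    """Consecutive integer levels centred at the half-up-rounded cutoff.

    Returns up to ``2 * window + 1`` levels; values below level 1 are
    dropped (the scale has no level 0).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    center = round_half_up(continuous_cutoff)
    return [lvl for lvl in range(center - window, center + window + 1) if lvl >= 1]


def select_level(
    candidates: Sequence[tuple[int, ValidityIndices]],
) -> SelectionResult:
    """Pick the integer level maximising accuracy, ties broken by sensitivity.

    Exact accuracy ties fall to the candidate with the larger sensitivity;
    a residual tie falls to the lower level (conservative toward easier
    scoring).  Either tie-break sets ``tie_broken``.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    best_acc = max(idx.accuracy for _, idx in candidates)
    acc_tied = [(lvl, idx) for lvl, idx in candidates if idx.accuracy == best_acc]
    if len(acc_tied) == 1:
        return SelectionResult(acc_tied[0][0], tie_broken=False)
    best_sens = max(idx.sensitivity for _, idx in acc_tied)
    sens_tied = [lvl for lvl, idx in acc_tied if idx.sensitivity == best_sens]
    return SelectionResult(min(sens_tied), tie_broken=True)
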