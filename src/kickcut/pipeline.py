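"""Orchestration: grouping schemes, per-stratum cut-score analysis, and
comparison against the certified threshold table.

Two grouping schemes are supported.  ``win_vs_nonwin`` contrasts the match
winners' kicks (criterion-meeting, "hi") against the non-winners' within
each gender x weight-class stratum.  ``adjacent_classes`` contrasts each
consecutive pair of weight classes within a gender, with the heavier class
as the criterion group.  Both hit types are pooled by default; a hit-type
filter exposes the alternative.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

from .cutpoint import (
    GroupStats,
    LevelDecision,
    SelectionResult,
    ValidityIndices,
    candidate_levels,
    empirical_validity,
    fit_group_stats,
    gaussian_intersection,
    select_level,
)
from .data import (
    CLASSES_BY_GENDER,
    AthleteRole,
    Gender,
    HitType,
    ImpactDataset,
    MatchShareTable,
    ThresholdTable,
    ValidationError,
    WeightClass,
    match_share_table,
)

__all__ = [
    "GroupingScheme",
    "GapDirection",
    "ClassResult",
    "AnalysisReport",
    "split_win_nonwin",
    "pair_adjacent_classes",
    "analyze_class",
    "run_analysis",
    "compare_with_wt",
    "descriptive_summary",
    "render_report",
]


class GroupingScheme(str, Enum):
    WIN_VS_NONWIN = "win_vs_nonwin"
    ADJACENT_CLASSES = "adjacent_classes"


class GapDirection(str, Enum):
    WT_HIGHER = "wt_higher"
    WT_LOWER = "wt_lower"
    EQUAL = "equal"


@dataclass(frozen=True)
class ClassResult:
    """Cut-score decision for one stratum (a class, or an adjacent pair)."""

    gender: Gender
    stratum: Union[WeightClass, tuple[WeightClass, WeightClass]]
    hi_stats: GroupStats
    lo_stats: GroupStats
    decision: LevelDecision
    wt_level: int
    gap: float  # wt_level - continuous cutoff, signed
    level_gap: int  # wt_level - selected integer level, signed

    @property
    def stratum_label(self) -> str:
        if isinstance(self.stratum, tuple):
            return f"{self.stratum[0].value}+{self.stratum[1].value}"
        return self.stratum.value


@dataclass(frozen=True)
class AnalysisReport:
    scheme: GroupingScheme
    results: tuple[ClassResult, ...]
    descriptives: dict
    composition: dict[str, MatchShareTable]
    provenance: str


def _impacts(
    dataset: ImpactDataset,
    gender: Gender,
    weight_class: WeightClass,
    role: Optional[AthleteRole] = None,
    hit_type: Optional[HitType] = None,
) -> list[float]:
    return [
        ev.impact
        for ev in dataset
        if ev.gender is gender
        and ev.weight_class is weight_class
        and (role is None or ev.athlete_role is role)
        and (hit_type is None or ev.hit_type is hit_type)
    ]


def split_win_nonwin(
    dataset: ImpactDataset,
    gender: Gender,
    weight_class: WeightClass,
    hit_type: Optional[HitType] = None,
) -> tuple[list[float], list[float]]:
    """Winner-role vs non-winner-role impacts for one stratum, hit types
    pooled unless ``hit_type`` filters them. Returns (hi, lo)."""
    dataset.require_non_empty()
    hi = _impacts(dataset, gender, weight_class, AthleteRole.WINNER, hit_type)
    lo = _impacts(dataset, gender, weight_class, AthleteRole.NON_WINNER, hit_type)
    label = f"{gender.value}/{weight_class.value}"
    if not hi:
        raise ValidationError(f"stratum {label} has no winner-role events")
    if not lo:
        raise ValidationError(f"stratum {label} has no non_winner-role events")
    return hi, lo


def pair_adjacent_classes(
    dataset: ImpactDataset,
    gender: Gender,
    hit_type: Optional[HitType] = None,
) -> list[tuple[WeightClass, WeightClass, list[float], list[float]]]:
    """Consecutive weight-class pairs for a gender, lightest pair first.

    Each element is ``(lighter, heavier, lo_impacts, hi_impacts)`` with the
    heavier class as the criterion ("hi") group and all athletes' kicks
    pooled within a class.
    """
    dataset.require_non_empty()
    classes = CLASSES_BY_GENDER[gender]
    per_class = {wc: _impacts(dataset, gender, wc, None, hit_type) for wc in classes}
    missing = [wc.value for wc in classes if not per_class[wc]]
    if missing:
        raise ValidationError(
            f"{gender.value} dataset missing weight class(es): {', '.join(missing)}"
        )
    return [
        (lighter, heavier, per_class[lighter], per_class[heavier])
        for lighter, heavier in zip(classes, classes[1:])
    ]


def analyze_class(
    hi_impacts: Sequence[float],
    lo_impacts: Sequence[float],
    wt_level: int,
    window: int = 1,
    *,
    gender: Gender = Gender.MEN,
    stratum: Union[WeightClass, tuple[WeightClass, WeightClass]] = WeightClass.U58,
) -> ClassResult:
    """Full per-stratum analysis: fit both groups, intersect their normal
    densities, validate candidate integer levels empirically, select one,
    and record gaps against the certified level."""
    hi_stats = fit_group_stats(hi_impacts)
    lo_stats = fit_group_stats(lo_impacts)
    # midpoint fallback: with near-equal fitted SDs the quadratic crossing
    # can fall outside the means; the equal-variance midpoint is its limit
    solution = gaussian_intersection(hi_stats, lo_stats, midpoint_fallback=True)
    candidates: list[tuple[int, ValidityIndices]] = [
        (lvl, empirical_validity(hi_impacts, lo_impacts, lvl))
        for lvl in candidate_levels(solution.cutoff, window)
    ]
    chosen: SelectionResult = select_level(candidates)
    decision = LevelDecision(
        continuous_cutoff=solution.cutoff,
        candidates=tuple(candidates),
        selected_level=chosen.selected_level,
        tie_broken=chosen.tie_broken,
    )
    return ClassResult(
        gender=gender,
        stratum=stratum,
        hi_stats=hi_stats,
        lo_stats=lo_stats,
        decision=decision,
        wt_level=wt_level,
        gap=wt_level - solution.cutoff,
        level_gap=wt_level - chosen.selected_level,
    )


def compare_with_wt(
    cutoff: Union[LevelDecision, float],
    wt_level: int,
) -> tuple[float, GapDirection]:
    """Absolute gap and direction between the certified level A and a
    study cutoff B (a continuous cutoff or a selected integer level)."""
    b = cutoff.selected_level if isinstance(cutoff, LevelDecision) else float(cutoff)
    diff = wt_level - b
    if diff > 0:
        direction = GapDirection.WT_HIGHER
    elif diff < 0:
        direction = GapDirection.WT_LOWER
    else:
        direction = GapDirection.EQUAL
    return abs(diff), direction


def descriptive_summary(dataset: ImpactDataset) -> dict:
    """Per-stratum (scoring, effective, overall) mean/SD cells.

    Cells with fewer than two events are reported as ``None`` rather than
    failing the whole summary.
    """
    dataset.require_non_empty()
    summary: dict[str, dict[str, Optional[tuple[int, float, float]]]] = {}
    for gender, wc in dataset.strata():
        cells: dict[str, Optional[tuple[int, float, float]]] = {}
        for label, hit_type in (
            ("scoring", HitType.SCORING),
            ("effective", HitType.EFFECTIVE),
            ("overall", None),
        ):
            values = _impacts(dataset, gender, wc, None, hit_type)
            if len(values) < 2:
                cells[label] = None
            else:
                stats = fit_group_stats(values)
                cells[label] = (stats.n, stats.mean, stats.sd)
        summary[f"{gender.value}/{wc.value}"] = cells
    return summary


def _composition(dataset: ImpactDataset) -> dict[str, MatchShareTable]:
    """Match-share tables per gender, counting distinct match ids."""
    out: dict[str, MatchShareTable] = {}
    for gender in Gender:
        counts: dict[WeightClass, int] = {}
        for wc in CLASSES_BY_GENDER[gender]:
            ids = {
                ev.match_id
                for ev in dataset
                if ev.gender is gender and ev.weight_class is wc
            }
            if ids:
                counts[wc] = len(ids)
        if counts:
            out[gender.value] = match_share_table(counts, gender)
    return out


def run_analysis(
    dataset: ImpactDataset,
    scheme: GroupingScheme,
    thresholds: ThresholdTable,
    window: int = 1,
    hit_type: Optional[HitType] = None,
) -> AnalysisReport:
    """Run one grouping scheme over every stratum present in the dataset.

    For ``win_vs_nonwin`` each (gender, class) stratum present yields one
    result; for ``adjacent_classes`` each gender with all five classes
    yields four ordered pairs, compared against the heavier class's
    certified level. Deterministic for a fixed dataset.
    """
    dataset.require_non_empty()
    results: list[ClassResult] = []
    if scheme is GroupingScheme.WIN_VS_NONWIN:
        for gender, wc in dataset.strata():
            hi, lo = split_win_nonwin(dataset, gender, wc, hit_type)
            results.append(
                analyze_class(
                    hi,
                    lo,
                    thresholds.level_for(gender, wc),
                    window,
                    gender=gender,
                    stratum=wc,
                )
            )
    elif scheme is GroupingScheme.ADJACENT_CLASSES:
        genders = {g for g, _ in dataset.strata()}
        for gender in Gender:
            if gender not in genders:
                continue
            for lighter, heavier, lo, hi in pair_adjacent_classes(
                dataset, gender, hit_type
            ):
                results.append(
                    analyze_class(
                        hi,
                        lo,
                        thresholds.level_for(gender, heavier),
                        window,
                        gender=gender,
                        stratum=(lighter, heavier),
                    )
                )
    else:  # pragma: no cover
        raise ValueError(f"unknown grouping scheme: {scheme}")
    return AnalysisReport(
        scheme=scheme,
        results=tuple(results),
        descriptives=descriptive_summary(dataset),
        composition=_composition(dataset),
        provenance=dataset.provenance,
    )


# ---------------------------------------------------------------------------
# rendering


def _result_to_dict(res: ClassResult) -> dict:
    return {
        "gender": res.gender.value,
        "stratum": res.stratum_label,
        "hi": {"n": res.hi_stats.n, "mean": res.hi_stats.mean, "sd": res.hi_stats.sd},
        "lo": {"n": res.lo_stats.n, "mean": res.lo_stats.mean, "sd": res.lo_stats.sd},
        "wt_level": res.wt_level,
        "continuous_cutoff": res.decision.continuous_cutoff,
        "selected_level": res.decision.selected_level,
        "tie_broken": res.decision.tie_broken,
        "gap": res.gap,
        "level_gap": res.level_gap,
        "candidates": [
            {
                "level": lvl,
                "accuracy": idx.accuracy,
                "sensitivity": idx.sensitivity,
                "specificity": idx.specificity,
            }
            for lvl, idx in res.decision.candidates
        ],
    }


def report_to_dict(report: AnalysisReport) -> dict:
    return {
        "scheme": report.scheme.value,
        "provenance": report.provenance,
        "results": [_result_to_dict(r) for r in report.results],
        "descriptives": report.descriptives,
        "composition": {
            gender: {
                "total": table.total,
                "shares": {
                    wc.value: {"count": count, "percent": percent}
                    for wc, (count, percent) in table.shares.items()
                },
            }
            for gender, table in report.composition.items()
        },
    }


_CSV_FIELDS = (
    "scheme",
    "gender",
    "stratum",
    "wt_level",
    "continuous_cutoff",
    "selected_level",
    "tie_broken",
    "gap",
    "level_gap",
    "hi_n",
    "hi_mean",
    "hi_sd",
    "lo_n",
    "lo_mean",
    "lo_sd",
)


def _render_csv(report: AnalysisReport) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_FIELDS)
    for r in report.results:
        writer.writerow(
            [
                report.scheme.value,
                r.gender.value,
                r.stratum_label,
                r.wt_level,
                repr(r.decision.continuous_cutoff),
                r.decision.selected_level,
                r.decision.tie_broken,
                repr(r.gap),
                r.level_gap,
                r.hi_stats.n,
                repr(r.hi_stats.mean),
                repr(r.hi_stats.sd),
                r.lo_stats.n,
                repr(r.lo_stats.mean),
                repr(r.lo_stats.sd),
            ]
        )
    return buf.getvalue()


def _render_text(report: AnalysisReport) -> str:
    lines = [
        f"Cut-score analysis ({report.scheme.value})",
        f"source: {report.provenance}",
        "",
        f"{'stratum':<14}{'A':>4}{'B':>8}{'level':>7}  candidates (level: acc/sens)",
    ]
    for r in report.results:
        cand = "  ".join(
            f"{lvl}: {idx.accuracy:.3f}/{idx.sensitivity:.3f}"
            for lvl, idx in r.decision.candidates
        )
        tag = " *" if r.decision.tie_broken else ""
        lines.append(
            f"{r.gender.value[0]} {r.stratum_label:<12}{r.wt_level:>4}"
            f"{r.decision.continuous_cutoff:>8.1f}"
            f"{r.decision.selected_level:>7}{tag}  {cand}"
        )
    lines.append("")
    lines.append("A: certified level; B: continuous cutoff; *: sensitivity tie-break")
    return "\n".join(lines) + "\n"


def render_report(report: AnalysisReport, format: str = "text") -> str:
    """Render a report as ``text``, ``csv`` or ``json`` file content.

    Field ordering is stable, CSV floats round-trip numerically, and the
    text layout mirrors the certified-vs-estimated threshold tables.
    """
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2) + "\n"
    if format == "csv":
        return _render_csv(report)
    if format == "text":
        return _render_text(report)
    raise ValueError(f"unknown report format: {format!r}")
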