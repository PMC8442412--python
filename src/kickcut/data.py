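"""Data model and validated I/O for kick-impact records and threshold tables.

This module owns the domain vocabulary (genders, weight classes, athlete
roles, hit types), the per-kick event record, CSV round-tripping, the
certified threshold table, and match-composition summaries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "Gender",
    "WeightClass",
    "AthleteRole",
    "HitType",
    "KickEvent",
    "ImpactDataset",
    "ThresholdTable",
    "MatchShareTable",
    "SchemaError",
    "ValidationError",
    "CLASSES_BY_GENDER",
    "DEFAULT_THRESHOLDS",
    "MAX_IMPACT_LEVEL",
    "normalize_weight_class",
    "read_events",
    "write_events",
    "load_thresholds",
    "match_share_table",
]

#: Validation ceiling for a single registered impact, in scoring-scale levels.
MAX_IMPACT_LEVEL = 100.0


class SchemaError(ValueError):
    """Raised when an input file is structurally unusable (e.g. missing columns)."""


class ValidationError(ValueError):
    """Raised when file content violates the event invariants."""


class Gender(str, Enum):
    MEN = "men"
    WOMEN = "women"


class WeightClass(str, Enum):
    # men
    U58 = "U58"
    U63 = "U63"
    U68 = "U68"
    U80 = "U80"
    O80 = "O80"
    # women
    U49 = "U49"
    U53 = "U53"
    U57 = "U57"
    U67 = "U67"
    O67 = "O67"


class AthleteRole(str, Enum):
    WINNER = "winner"
    NON_WINNER = "non_winner"


class HitType(str, Enum):
    SCORING = "scoring"
    EFFECTIVE = "effective"


#: Weight classes valid for each gender, lightest first.
CLASSES_BY_GENDER: dict[Gender, tuple[WeightClass, ...]] = {
    Gender.MEN: (
        WeightClass.U58,
        WeightClass.U63,
        WeightClass.U68,
        WeightClass.U80,
        WeightClass.O80,
    ),
    Gender.WOMEN: (
        WeightClass.U49,
        WeightClass.U53,
        WeightClass.U57,
        WeightClass.U67,
        WeightClass.O67,
    ),
}

# Free-text labels seen in source material normalise onto the U/O codes.
# "over 87 kg" and "+ 80 kg" are inconsistent labels for the same men's
# heavyweight stratum and both map to O80.
_WEIGHT_CLASS_ALIASES: dict[str, WeightClass] = {}
for _wc in WeightClass:
    _WEIGHT_CLASS_ALIASES[_wc.value.lower()] = _wc
    _kg = _wc.value[1:]
    _prefix = "under" if _wc.value[0] == "U" else "over"
    _WEIGHT_CLASS_ALIASES[f"{_prefix} {_kg} kg"] = _wc
    _WEIGHT_CLASS_ALIASES[f"{_prefix} {_kg}kg"] = _wc
    _WEIGHT_CLASS_ALIASES[f"{_prefix}{_kg}"] = _wc
    if _wc.value[0] == "U":
        _WEIGHT_CLASS_ALIASES[f"-{_kg} kg"] = _wc
        _WEIGHT_CLASS_ALIASES[f"- {_kg} kg"] = _wc
    else:
        _WEIGHT_CLASS_ALIASES[f"+{_kg} kg"] = _wc
        _WEIGHT_CLASS_ALIASES[f"+ {_kg} kg"] = _wc
_WEIGHT_CLASS_ALIASES["over 87 kg"] = WeightClass.O80
_WEIGHT_CLASS_ALIASES["over87"] = WeightClass.O80
_WEIGHT_CLASS_ALIASES["o87"] = WeightClass.O80


def normalize_weight_class(label: Union[str, WeightClass]) -> WeightClass:
    """Map a weight-class label (code or free text) to its canonical code.

    Accepts the U/O codes (``"U58"``), ``"under 58 kg"``-style text and the
    ``"+ 80 kg"`` / ``"over 87 kg"`` heavyweight variants.
    """
    if isinstance(label, WeightClass):
        return label
    key = str(label).strip().lower()
    try:
        return _WEIGHT_CLASS_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unknown weight class label: {label!r}") from None


@dataclass(frozen=True)
class KickEvent:
    """One registered trunk hit with its stratum labels and impact level."""

    match_id: str
    gender: Gender
    weight_class: WeightClass
    athlete_role: AthleteRole
    hit_type: HitType
    impact: float

    def __post_init__(self) -> None:
        if not (0.0 < self.impact <= MAX_IMPACT_LEVEL):
            raise ValidationError(
                f"impact must be in (0, {MAX_IMPACT_LEVEL}], got {self.impact}"
            )
        if self.weight_class not in CLASSES_BY_GENDER[self.gender]:
            raise ValidationError(
                f"weight class {self.weight_class.value} is not valid for "
                f"{self.gender.value}"
            )


@dataclass(frozen=True)
class ImpactDataset:
    """Ordered collection of :class:`KickEvent` with provenance metadata."""

    events: tuple[KickEvent, ...]
    provenance: str = ""
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[KickEvent]:
        return iter(self.events)

    def require_non_empty(self) -> None:
        if not self.events:
            raise ValidationError("dataset is empty; analysis requires events")

    def strata(self) -> list[tuple[Gender, WeightClass]]:
        """Distinct (gender, weight_class) pairs in first-seen order."""
        seen: dict[tuple[Gender, WeightClass], None] = {}
        for ev in self.events:
            seen.setdefault((ev.gender, ev.weight_class), None)
        return list(seen)


_EVENT_COLUMNS = (
    "match_id",
    "gender",
    "weight_class",
    "athlete_role",
    "hit_type",
    "impact",
)


def read_events(
    path: Union[str, Path],
    *,
    max_impact: float = MAX_IMPACT_LEVEL,
) -> ImpactDataset:
    """Read a CSV events file into a validated :class:`ImpactDataset`.

    The file must be UTF-8 comma-separated with a header naming the six
    event fields. Row order is preserved. All malformed rows are collected
    and reported together, numbered from 1 for the first data row.

    Raises
    ------
    SchemaError
        If any required column is missing from the header.
    ValidationError
        If any row has a non-numeric, non-positive or out-of-range impact,
        or an unknown categorical label.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _EVENT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        events: list[KickEvent] = []
        problems: list[str] = []
        for rownum, row in enumerate(reader, start=1):
            try:
                raw_impact = row["impact"]
                try:
                    impact = float(raw_impact)
                except (TypeError, ValueError):
                    raise ValidationError(f"non-numeric impact {raw_impact!r}")
                if not (0.0 < impact <= max_impact):
                    raise ValidationError(
                        f"impact {impact} outside (0, {max_impact}]"
                    )
                events.append(
                    KickEvent(
                        match_id=row["match_id"],
                        gender=Gender(row["gender"].strip().lower()),
                        weight_class=normalize_weight_class(row["weight_class"]),
                        athlete_role=AthleteRole(row["athlete_role"].strip()),
                        hit_type=HitType(row["hit_type"].strip()),
                        impact=impact,
                    )
                )
            except (ValidationError, ValueError) as exc:
                problems.append(f"row {rownum}: {exc}")
        if problems:
            raise ValidationError(
                f"{path}: {len(problems)} invalid row(s): " + "; ".join(problems)
            )
    return ImpactDataset(events=tuple(events), provenance=str(path))


def write_events(dataset: ImpactDataset, path: Union[str, Path]) -> None:
    """Write a dataset as CSV, re-readable by :func:`read_events`.

    Impacts are serialised with ``repr`` so the float round-trips exactly.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_COLUMNS)
        for ev in dataset.events:
            writer.writerow(
                [
                    ev.match_id,
                    ev.gender.value,
                    ev.weight_class.value,
                    ev.athlete_role.value,
                    ev.hit_type.value,
                    repr(ev.impact),
                ]
            )


#: Certified scoring-threshold levels (column "A") per gender and class.
DEFAULT_THRESHOLDS: dict[Gender, dict[WeightClass, int]] = {
    Gender.MEN: {
        WeightClass.U58: 18,
        WeightClass.U63: 20,
        WeightClass.U68: 21,
        WeightClass.U80: 23,
        WeightClass.O80: 25,
    },
    Gender.WOMEN: {
        WeightClass.U49: 16,
        WeightClass.U53: 17,
        WeightClass.U57: 18,
        WeightClass.U67: 20,
        WeightClass.O67: 22,
    },
}


@dataclass(frozen=True)
class ThresholdTable:
    """Certified integer scoring level per (gender, weight class) stratum."""

    entries: Mapping[tuple[Gender, WeightClass], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [
            f"{g.value}/{wc.value}"
            for g, classes in CLASSES_BY_GENDER.items()
            for wc in classes
            if (g, wc) not in self.entries
        ]
        if missing:
            raise ValidationError(
                "threshold table missing strata: " + ", ".join(missing)
            )
        for (g, wc), level in self.entries.items():
            if not isinstance(level, int) or isinstance(level, bool) or level <= 0:
                raise ValidationError(
                    f"threshold for {g.value}/{wc.value} must be a positive "
                    f"integer, got {level!r}"
                )

    def level_for(self, gender: Gender, weight_class: WeightClass) -> int:
        return self.entries[(gender, weight_class)]


def load_thresholds(
    path: Optional[Union[str, Path]] = None,
    *,
    use_defaults: bool = True,
) -> ThresholdTable:
    """Load a threshold table from YAML/JSON, or the bundled defaults.

    A file holds ``gender -> weight class -> level``. With ``use_defaults``
    (the default) file entries override the bundled table stratum by
    stratum; with ``use_defaults=False`` the file must itself cover all ten
    strata, and a partial file raises an error listing the missing ones.
    """
    entries: dict[tuple[Gender, WeightClass], int] = {}
    if use_defaults:
        for g, per_class in DEFAULT_THRESHOLDS.items():
            for wc, level in per_class.items():
                entries[(g, wc)] = level
    if path is not None:
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: expected a gender -> class mapping")
        for gender_key, per_class in raw.items():
            gender = Gender(str(gender_key).strip().lower())
            if not isinstance(per_class, dict):
                raise SchemaError(
                    f"{path}: expected a class -> level mapping for "
                    f"{gender.value}"
                )
            for class_key, level in per_class.items():
                wc = normalize_weight_class(str(class_key))
                entries[(gender, wc)] = level
    return ThresholdTable(entries=entries)


@dataclass(frozen=True)
class MatchShareTable:
    """Per-class match counts with their percentage shares, plus the total."""

    shares: Mapping[WeightClass, tuple[int, float]]
    total: int


def _percent_half_up(count: int, total: int) -> float:
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def match_share_table(
    match_counts: Mapping[Union[str, WeightClass], int],
    gender: Gender,
) -> MatchShareTable:
    """Composition summary: per-class match counts and percentage shares.

    Percentages are 100 x count / total, rounded half-up to one decimal.
    Counts must be non-negative with at least one positive.
    """
    normalized: dict[WeightClass, int] = {}
    for wc, count in match_counts.items():
        wc = normalize_weight_class(wc)
        if wc not in CLASSES_BY_GENDER[gender]:
            raise ValidationError(
                f"weight class {wc.value} is not valid for {gender.value}"
            )
        if count < 0:
            raise ValidationError(f"negative match count for {wc.value}: {count}")
        normalized[wc] = int(count)
    total = sum(normalized.values())
    if total <= 0:
        raise ValidationError("all match counts are zero")
    shares = {
        wc: (count, _percent_half_up(count, total))
        for wc, count in normalized.items()
    }
    return MatchShareTable(shares=shares, total=total)
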