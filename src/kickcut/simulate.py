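"""Stratified synthetic kick-impact data generator.

Draws per-stratum impacts from truncated normal distributions so the whole
analysis pipeline is testable without the (non-deposited) tournament data.
The bundled default parameterisation mirrors the published descriptive
statistics: per-class scoring-group and effective-hit-group means and SDs,
kick counts allocated in proportion to per-class match shares, and a
winner / non-winner mean separation exposed as a single free parameter.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.stats import norm

from .data import (
    CLASSES_BY_GENDER,
    AthleteRole,
    Gender,
    HitType,
    ImpactDataset,
    KickEvent,
    WeightClass,
)

__all__ = [
    "StratumSpec",
    "SimulationSpec",
    "GROUP_IMPACT_STATS",
    "DEFAULT_MATCH_COUNTS",
    "HIT_TOTALS",
    "default_spec",
    "generate_dataset",
    "perturb_spec",
    "load_spec",
    "save_spec",
]

#: Published per-group impact statistics: (gender, class, hit type) -> (mean, sd).
GROUP_IMPACT_STATS: dict[tuple[Gender, WeightClass, HitType], tuple[float, float]] = {
    (Gender.MEN, WeightClass.U58, HitType.SCORING): (24.6, 7.17),
    (Gender.MEN, WeightClass.U58, HitType.EFFECTIVE): (13.6, 1.88),
    (Gender.MEN, WeightClass.U63, HitType.SCORING): (28.3, 8.51),
    (Gender.MEN, WeightClass.U63, HitType.EFFECTIVE): (14.7, 2.40),
    (Gender.MEN, WeightClass.U68, HitType.SCORING): (27.4, 7.59),
    (Gender.MEN, WeightClass.U68, HitType.EFFECTIVE): (15.1, 2.65),
    (Gender.MEN, WeightClass.U80, HitType.SCORING): (32.2, 8.62),
    (Gender.MEN, WeightClass.U80, HitType.EFFECTIVE): (16.1, 3.39),
    (Gender.MEN, WeightClass.O80, HitType.SCORING): (30.9, 7.70),
    (Gender.MEN, WeightClass.O80, HitType.EFFECTIVE): (16.4, 3.68),
    (Gender.WOMEN, WeightClass.U49, HitType.SCORING): (19.9, 3.41),
    (Gender.WOMEN, WeightClass.U49, HitType.EFFECTIVE): (12.7, 1.39),
    (Gender.WOMEN, WeightClass.U53, HitType.SCORING): (21.2, 3.95),
    (Gender.WOMEN, WeightClass.U53, HitType.EFFECTIVE): (13.2, 1.73),
    (Gender.WOMEN, WeightClass.U57, HitType.SCORING): (25.4, 7.67),
    (Gender.WOMEN, WeightClass.U57, HitType.EFFECTIVE): (13.3, 1.71),
    (Gender.WOMEN, WeightClass.U67, HitType.SCORING): (25.5, 5.82),
    (Gender.WOMEN, WeightClass.U67, HitType.EFFECTIVE): (14.3, 2.59),
    (Gender.WOMEN, WeightClass.O67, HitType.SCORING): (27.3, 4.37),
    (Gender.WOMEN, WeightClass.O67, HitType.EFFECTIVE): (15.2, 3.29),
}

#: Published tournament composition: matches fought per gender and class.
DEFAULT_MATCH_COUNTS: dict[Gender, dict[WeightClass, int]] = {
    Gender.MEN: {
        WeightClass.U58: 24,
        WeightClass.U63: 25,
        WeightClass.U68: 21,
        WeightClass.U80: 20,
        WeightClass.O80: 14,
    },
    Gender.WOMEN: {
        WeightClass.U49: 16,
        WeightClass.U53: 17,
        WeightClass.U57: 19,
        WeightClass.U67: 15,
        WeightClass.O67: 17,
    },
}

#: Published registered-hit totals per gender and hit type.
HIT_TOTALS: dict[tuple[Gender, HitType], int] = {
    (Gender.MEN, HitType.SCORING): 814,
    (Gender.MEN, HitType.EFFECTIVE): 1430,
    (Gender.WOMEN, HitType.SCORING): 650,
    (Gender.WOMEN, HitType.EFFECTIVE): 688,
}

DEFAULT_SEED = 20180818
DEFAULT_TRUNCATION = (1.0, 60.0)
DEFAULT_WINNER_SHIFT = 2.0


class StratumSpec(BaseModel):
    """Generative description of one (gender, class, role, hit-type) stratum.

    ``mean`` is the role-neutral base mean; the winner / non-winner
    separation is applied at generation time via the simulation-level
    ``winner_shift`` knob.
    """

    model_config = ConfigDict(frozen=True)

    gender: Gender
    weight_class: WeightClass
    athlete_role: AthleteRole
    hit_type: HitType
    n: int = Field(ge=1)
    mean: float = Field(gt=0.0)
    sd: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _class_matches_gender(self) -> "StratumSpec":
        if self.weight_class not in CLASSES_BY_GENDER[self.gender]:
            raise ValueError(
                f"weight class {self.weight_class.value} invalid for "
                f"{self.gender.value}"
            )
        return self


class SimulationSpec(BaseModel):
    """Complete, seedable description of a synthetic dataset."""

    model_config = ConfigDict(frozen=True)

    strata: tuple[StratumSpec, ...]
    truncation: tuple[float, float] = DEFAULT_TRUNCATION
    round_to_integer_levels: bool = False
    winner_shift: float = DEFAULT_WINNER_SHIFT
    seed: int = DEFAULT_SEED

    @field_validator("truncation")
    @classmethod
    def _ordered_bounds(cls, v: tuple[float, float]) -> tuple[float, float]:
        lower, upper = v
        if not lower < upper:
            raise ValueError(f"truncation bounds must satisfy lower < upper, got {v}")
        return v

    def shifted_mean(self, stratum: StratumSpec) -> float:
        """Generation-time mean: winners are raised and non-winners lowered
        by half the configured separation, keeping the marginal mean at the
        stratum's base value."""
        half = 0.5 * self.winner_shift
        if stratum.athlete_role is AthleteRole.WINNER:
            return stratum.mean + half
        return stratum.mean - half


def default_spec(scale: float = 1.0) -> SimulationSpec:
    """Bundled default :class:`SimulationSpec`.

    Per-class scoring and effective-hit (mean, sd) follow the published
    descriptive table; per-class kick counts allocate the published hit
    totals proportionally to match shares and split them evenly between
    winner and non-winner roles. ``scale`` multiplies all stratum sizes
    (useful for quick tests).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    strata: list[StratumSpec] = []
    for gender, classes in CLASSES_BY_GENDER.items():
        counts = DEFAULT_MATCH_COUNTS[gender]
        total_matches = sum(counts.values())
        for wc in classes:
            share = counts[wc] / total_matches
            for hit_type in (HitType.SCORING, HitType.EFFECTIVE):
                mean, sd = GROUP_IMPACT_STATS[(gender, wc, hit_type)]
                n_class = max(2, round(HIT_TOTALS[(gender, hit_type)] * share * scale))
                n_non = n_class // 2
                n_win = n_class - n_non
                for role, n in (
                    (AthleteRole.WINNER, n_win),
                    (AthleteRole.NON_WINNER, n_non),
                ):
                    strata.append(
                        StratumSpec(
                            gender=gender,
                            weight_class=wc,
                            athlete_role=role,
                            hit_type=hit_type,
                            n=n,
                            mean=mean,
                            sd=sd,
                        )
                    )
    return SimulationSpec(strata=tuple(strata))


def _sample_truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float,
    upper: float,
    n: int,
) -> np.ndarray:
    """Rejection-sample n draws from Normal(mean, sd) restricted to
    [lower, upper]. Acceptance is high for all default strata (bounds sit
    well outside +/- 2 sd), so plain rejection is exact and cheap."""
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        batch = rng.normal(mean, sd, size=max(2 * (n - filled), 64))
        keep = batch[(batch >= lower) & (batch <= upper)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_dataset(spec: SimulationSpec) -> ImpactDataset:
    """Generate a validated :class:`ImpactDataset` from ``spec``.

    A single seeded generator stream drives all strata in declared order,
    so identical (spec, seed) pairs produce identical datasets regardless
    of anything environmental.

    Raises
    ------
    ValueError
        If the truncation bounds exclude more than 99% of a stratum's
        probability mass (which would silently distort its distribution).
    """
    lower, upper = spec.truncation
    rng = np.random.default_rng(spec.seed)
    events: list[KickEvent] = []
    for stratum in spec.strata:
        mean = spec.shifted_mean(stratum)
        mass = norm.cdf(upper, mean, stratum.sd) - norm.cdf(lower, mean, stratum.sd)
        if mass < 0.01:
            raise ValueError(
                f"truncation {spec.truncation} excludes >99% of stratum "
                f"{stratum.gender.value}/{stratum.weight_class.value}/"
                f"{stratum.athlete_role.value}/{stratum.hit_type.value} "
                f"(mean {mean}, sd {stratum.sd})"
            )
        draws = _sample_truncated_normal(
            rng, mean, stratum.sd, lower, upper, stratum.n
        )
        if spec.round_to_integer_levels:
            draws = np.clip(np.floor(draws + 0.5), max(lower, 1.0), upper)
        n_matches = DEFAULT_MATCH_COUNTS[stratum.gender].get(stratum.weight_class, 1)
        prefix = f"{stratum.gender.value[0]}-{stratum.weight_class.value}"
        for i, impact in enumerate(draws):
            events.append(
                KickEvent(
                    match_id=f"{prefix}-{(i % n_matches) + 1:03d}",
                    gender=stratum.gender,
                    weight_class=stratum.weight_class,
                    athlete_role=stratum.athlete_role,
                    hit_type=stratum.hit_type,
                    impact=float(impact),
                )
            )
    return ImpactDataset(
        events=tuple(events),
        provenance=f"synthetic:seed={spec.seed}",
        seed=spec.seed,
    )


def perturb_spec(spec: SimulationSpec, winner_shift: float) -> SimulationSpec:
    """Copy of ``spec`` with the winner / non-winner mean separation set to
    ``winner_shift``; setting it twice equals setting it once."""
    return spec.model_copy(update={"winner_shift": winner_shift})


def save_spec(spec: SimulationSpec, path: Union[str, Path]) -> None:
    """Serialise a spec to YAML (JSON-compatible structure)."""
    payload = spec.model_dump(mode="json")
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_spec(path: Union[str, Path]) -> SimulationSpec:
    """Load a spec written by :func:`save_spec` (YAML or JSON)."""
    with Path(path).open(encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return SimulationSpec.model_validate(payload)
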