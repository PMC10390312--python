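"""Domain types and validation for respondent drinking-survey records.

The modelling pipeline works on seven candidate items drawn from two
standard instruments: the first three AUDIT items (consumption frequency,
drinks per typical day, frequency of six-or-more-drink occasions; each an
ordinal 0-4 code) and four AUQ-derived quantities (consumption speed in
drinks/hour; number of drunkenness episodes in the previous six months;
drunkenness episodes per 10 drinking occasions; hangovers per 10 drinking
occasions).  Five of the seven survive item selection and feed the ordinal
classifier; the full seven feed the K-means derivation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

#: Canonical column order for the seven candidate clustering items.
ITEM_FIELDS: tuple[str, ...] = (
    "consumption_frequency",
    "drinks_typical_day",
    "six_drink_frequency",
    "consumption_speed",
    "drunkenness_frequency",
    "drunk_per_10",
    "hangover_per_10",
)

#: The five items retained by the published model, in classifier order.
RETAINED_ITEMS: tuple[str, ...] = (
    "six_drink_frequency",
    "consumption_speed",
    "drunkenness_frequency",
    "drunk_per_10",
    "hangover_per_10",
)

#: Ordinal AUDIT items coded 0..4.
ORDINAL_ITEMS: tuple[str, ...] = ITEM_FIELDS[:3]

#: Items bounded on the per-10-occasions scale.
PER10_ITEMS: tuple[str, ...] = ("drunk_per_10", "hangover_per_10")

#: Index of drunkenness_frequency in ITEM_FIELDS (severity tie-break item).
DRUNKENNESS_COL: int = ITEM_FIELDS.index("drunkenness_frequency")

GROUP_LABELS: dict[int, str] = {
    1: "low-risk",
    2: "hazardous",
    3: "binge",
    4: "high-intensity binge",
}

N_GROUPS: int = 4


class RecordValidationError(ValueError):
    """A raw record failed range or completeness checks for modelling."""


@dataclass(frozen=True)
class DrinkerGroup:
    """Ordinal severity group, 1 (low-risk) through 4 (high-intensity binge)."""

    index: int

    def __post_init__(self) -> None:
        if self.index not in GROUP_LABELS:
            raise ValueError(f"group index must be 1..{N_GROUPS}, got {self.index}")

    @property
    def label(self) -> str:
        return GROUP_LABELS[self.index]

    @classmethod
    def from_label(cls, label: str) -> "DrinkerGroup":
        for idx, name in GROUP_LABELS.items():
            if name == label:
                return cls(idx)
        raise ValueError(f"unknown group label {label!r}")


@dataclass(frozen=True)
class ItemVector:
    """One respondent's values on the seven candidate drinking items."""

    consumption_frequency: int
    drinks_typical_day: int
    six_drink_frequency: int
    consumption_speed: float
    drunkenness_frequency: int
    drunk_per_10: float
    hangover_per_10: float

    def __post_init__(self) -> None:
        for name in ORDINAL_ITEMS:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise RecordValidationError(
                    f"{name} must be an integer in 0..4, got {v!r}"
                )
        if not (self.consumption_speed >= 0 and np.isfinite(self.consumption_speed)):
            raise RecordValidationError(
                f"consumption_speed must be a nonnegative real, got "
                f"{self.consumption_speed!r}"
            )
        if not (
            isinstance(self.drunkenness_frequency, (int, np.integer))
            and self.drunkenness_frequency >= 0
        ):
            raise RecordValidationError(
                "drunkenness_frequency must be a nonnegative integer, got "
                f"{self.drunkenness_frequency!r}"
            )
        for name in PER10_ITEMS:
            v = getattr(self, name)
            if not (0 <= v <= 10 and np.isfinite(v)):
                raise RecordValidationError(f"{name} must lie in [0, 10], got {v!r}")

    def as_array(self, items: tuple[str, ...] = ITEM_FIELDS) -> np.ndarray:
        """Return the values of ``items`` as a float vector in that order."""
        return np.array([float(getattr(self, name)) for name in items])


@dataclass(frozen=True)
class Respondent:
    """A validated survey record admitted to modelling."""

    id: str
    items: ItemVector
    gender: str = "unspecified"  # "M", "F" or "unspecified"
    age: float | None = None
    audit_total: int | None = None
    binge_score: float | None = None
    apt: Any = None  # optional DemandCurve

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F", "unspecified"):
            raise RecordValidationError(f"gender must be M/F/unspecified, got {self.gender!r}")
        if self.age is not None and self.age < 0:
            raise RecordValidationError(f"age must be nonnegative, got {self.age!r}")
        if self.audit_total is not None and not 0 <= self.audit_total <= 40:
            raise RecordValidationError(
                f"audit_total must lie in [0, 40], got {self.audit_total!r}"
            )


def percent_to_tenths(pct: float) -> float:
    """Rescale a percentage of drinking occasions to the 10-occasion scale.

    Survey respondents report drunkenness/hangover frequency as a percentage
    of drinking occasions; the model works on a 0-10 "per 10 occasions"
    scale, i.e. ``pct / 10``.
    """
    if not (0 <= pct <= 100 and np.isfinite(pct)):
        raise RecordValidationError(f"percentage must lie in [0, 100], got {pct!r}")
    return pct / 10.0


def _coerce_ordinal(name: str, value: Any) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise RecordValidationError(f"{name}: cannot interpret {value!r} as a number")
    if not float(f).is_integer():
        raise RecordValidationError(f"{name} must be a whole 0..4 code, got {value!r}")
    return int(f)


def validate_record(
    raw: Mapping[str, Any], *, percent_scale: str = "tenths"
) -> Respondent:
    """Coerce and range-check a raw field map into a :class:`Respondent`.

    Records with any missing or out-of-range modelling item are rejected
    (listwise exclusion); optional fields (age, gender, AUDIT total, binge
    score) pass through when present.

    Parameters
    ----------
    raw
        Field map with at least the seven :data:`ITEM_FIELDS`.
    percent_scale
        Input dialect for the per-10-occasions items: ``"tenths"`` (native
        0-10 values, the default) or ``"percent"`` (0-100 values rescaled
        by :func:`percent_to_tenths`).
    """
    if percent_scale not in ("tenths", "percent"):
        raise ValueError(f"percent_scale must be 'tenths' or 'percent', got {percent_scale!r}")

    values: dict[str, Any] = {}
    for name in ITEM_FIELDS:
        if name not in raw or raw[name] is None or (
            isinstance(raw[name], float) and np.isnan(raw[name])
        ) or raw[name] == "":
            raise RecordValidationError(f"missing modelling item {name}")
        v = raw[name]
        if name in ORDINAL_ITEMS:
            values[name] = _coerce_ordinal(name, v)
        elif name == "drunkenness_frequency":
            values[name] = _coerce_ordinal(name, v)
        else:
            try:
                values[name] = float(v)
            except (TypeError, ValueError):
                raise RecordValidationError(f"{name}: cannot interpret {v!r} as a number")
    if percent_scale == "percent":
        for name in PER10_ITEMS:
            values[name] = percent_to_tenths(values[name])

    items = ItemVector(**values)

    def _opt(key: str, cast):
        v = raw.get(key)
        if v is None or v == "" or (isinstance(v, float) and np.isnan(v)):
            return None
        return cast(v)

    gender = raw.get("gender") or "unspecified"
    if gender not in ("M", "F", "unspecified"):
        raise RecordValidationError(f"gender must be M/F/unspecified, got {gender!r}")

    return Respondent(
        id=str(raw.get("id", "")),
        items=items,
        gender=gender,
        age=_opt("age", float),
        audit_total=_opt("audit_total", lambda v: _coerce_ordinal("audit_total", v)),
        binge_score=_opt("binge_score", float),
    )


def serialize(resp: Respondent) -> dict[str, Any]:
    """Flatten a Respondent back to a raw field map (inverse of validation)."""
    out: dict[str, Any] = {"id": resp.id, "gender": resp.gender}
    out.update(dataclasses.asdict(resp.items))
    for key in ("age", "audit_total", "binge_score"):
        v = getattr(resp, key)
        if v is not None:
            out[key] = v
    return out
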