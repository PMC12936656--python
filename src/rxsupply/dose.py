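"""Daily-dose parsing and drug-form stratification.

Prescribers write the amount taken at once either as a count of dosing
units ("2 tablets") or as an amount of active substance ("10 mg") — and for
combination products the substance-amount style is itself ambiguous: for a
5 mg + 10 mg product, "5 mg", "10 mg" and "15 mg" can all describe one
unit.  :func:`parse_dose_amount` resolves these notations into a canonical
units-per-dose figure; :func:`normalize_frequency` converts the dosing
frequency to a per-day rate, and their product is the canonical daily dose.

Prescriptions are also stratified by drug form into groups that each follow
their own days'-supply conventions (tablets vs creams vs eye drops ...).
:func:`classify_form` performs that mapping from free-text drug form plus
ATC code, driven by a configurable keyword/prefix rule list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .model import (DROPS, IU, MASS, UNIT, VOLUME, Component,
                    PrescriptionRecord)


class DoseParseError(ValueError):
    """Raised when a dose notation cannot be normalised."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


class UnparseableDose(DoseParseError):
    def __init__(self, message: str):
        super().__init__("UNPARSEABLE_DOSE", message)


# ---------------------------------------------------------------------------
# canonical dose

@dataclass(frozen=True)
class CanonicalDose:
    """Daily dose normalised to units (or measured amount) per day."""

    units_per_dose: float
    doses_per_day: float
    interpretation: str  # unit-count | single-component-mass | summed-component-mass | volume | drops
    confidence: str = "exact"  # exact | inferred

    @property
    def units_per_day(self) -> float:
        return self.units_per_dose * self.doses_per_day


def normalize_frequency(dose_times: float, dose_period: str) -> float:
    """Administrations per day from (count, period)."""
    if dose_times <= 0:
        raise DoseParseError("BAD_FREQUENCY", f"dose_times must be positive, got {dose_times}")
    if dose_period == "day":
        return float(dose_times)
    if dose_period == "week":
        return float(dose_times) / 7.0
    raise DoseParseError("BAD_PERIOD", f"unknown dose period {dose_period!r}")


def drops_to_volume(n_drops: float, substance_name: str = "",
                    drop_factor_table: Mapping[str, float] | None = None,
                    default_factor: float = 20.0) -> float:
    """Convert a drop count to millilitres.

    Drop size differs between substances (viscosity, dropper design), so a
    per-substance drops-per-mL table may be supplied; anything not listed
    falls back to the default factor of 20 drops/mL.
    """
    factor = default_factor
    if drop_factor_table:
        factor = drop_factor_table.get(substance_name.strip().lower(), default_factor) or default_factor
    return float(n_drops) / float(factor)


def _is_multiple(q: float, granularity: float, tol: float = 1e-9) -> bool:
    ratio = q / granularity
    return abs(ratio - round(ratio)) < tol


def parse_dose_amount(
    dose_amount: float,
    dose_amount_unit: str,
    components: Sequence[Component],
    plausible_range: tuple[float, float] = (0.25, 20.0),
    granularity: float = 0.25,
    drop_factor_table: Mapping[str, float] | None = None,
) -> tuple[float, str]:
    """Resolve the amount-per-dose notation to units per dose.

    unit-count amounts pass through unchanged.  Substance-amount (mass or
    volume) notations are divided by candidate strengths — the *summed*
    component strength first (for a combination product "15 mg" of a
    5 + 10 mg pill unambiguously means one unit), then each single component
    strength from largest down.  The first quotient inside the plausible
    units-per-dose range that lies on the dosing granularity grid wins.
    Amounts in drops are converted to millilitres via the drop-factor table.

    Returns ``(units_per_dose, interpretation)``; raises
    :class:`UnparseableDose` when no candidate is plausible (the record then
    falls through to imputation).
    """
    if dose_amount <= 0:
        raise DoseParseError("BAD_AMOUNT", f"dose_amount must be positive, got {dose_amount}")
    if not components:
        raise DoseParseError("NO_COMPONENTS", "components required to interpret dose amount")

    if dose_amount_unit == UNIT:
        return float(dose_amount), "unit-count"

    if dose_amount_unit == DROPS:
        name = components[0].substance if components else ""
        return drops_to_volume(dose_amount, name, drop_factor_table), "drops"

    if dose_amount_unit not in (MASS, VOLUME):
        raise DoseParseError("BAD_DOSE_AMOUNT_UNIT",
                             f"unknown dose amount unit {dose_amount_unit!r}")

    matching = [c for c in components if c.strength_unit == dose_amount_unit
                or (dose_amount_unit == MASS and c.strength_unit == IU)]
    if not matching:
        raise UnparseableDose(
            f"no component strength in unit {dose_amount_unit!r} to divide by")

    lo, hi = plausible_range
    candidates: list[tuple[float, str]] = []
    if len(matching) > 1:
        total = sum(c.strength_value for c in matching)
        candidates.append((total, "summed-component-mass"))
    single_tag = ("single-component-mass" if dose_amount_unit == MASS else "volume")
    for c in sorted(matching, key=lambda c: -c.strength_value):
        candidates.append((c.strength_value, single_tag))

    # two passes resolve combination-product ambiguity toward one unit per
    # dose: "5 mg" of a 5 + 10 mg product means one unit, not half a 10 mg
    for exact_only in (True, False):
        for strength, interpretation in candidates:
            q = float(dose_amount) / float(strength)
            if exact_only and q != 1.0:
                continue
            if lo <= q <= hi and _is_multiple(q, granularity):
                return q, interpretation
    raise UnparseableDose(
        f"amount {dose_amount} not a plausible multiple of any component strength")


def canonical_dose(record: PrescriptionRecord,
                   plausible_range: tuple[float, float] = (0.25, 20.0),
                   granularity: float = 0.25,
                   drop_factor_table: Mapping[str, float] | None = None) -> CanonicalDose:
    """Build the canonical daily dose for a record, or raise DoseParseError."""
    if record.dose_times is None or record.dose_amount is None:
        raise DoseParseError("DOSE_FIELDS_MISSING", "daily-dose fields absent")
    if record.dose_period is None:
        raise DoseParseError("DOSE_PERIOD_MISSING", "dose frequency period absent")
    if record.dose_amount_unit is None:
        raise DoseParseError("DOSE_AMOUNT_UNIT_MISSING", "dose amount unit absent")
    per_day = normalize_frequency(record.dose_times, record.dose_period)
    units, interpretation = parse_dose_amount(
        record.dose_amount, record.dose_amount_unit, record.components,
        plausible_range=plausible_range, granularity=granularity,
        drop_factor_table=drop_factor_table)
    return CanonicalDose(units_per_dose=units, doses_per_day=per_day,
                         interpretation=interpretation)


# ---------------------------------------------------------------------------
# drug-form groups

class FormGroup(str, Enum):
    SINGLE_DOSE = "single_dose"               # tablets, capsules, suppositories
    SEMISOLID = "semisolid"                   # creams, gels, ointments, shampoos
    NAIL_POLISH = "nail_polish"
    EAR_DROPS = "ear_drops"
    EYE_DROPS = "eye_drops"
    ORAL_DROPS = "oral_drops"
    INHALATION = "inhalation"
    NASAL_SPRAY = "nasal_spray"
    SYRUP = "syrup"
    TRANSDERMAL_PATCH = "transdermal_patch"
    INTRAVAGINAL = "intravaginal_contraceptive"
    IMPLANT_VACCINE = "implant_vaccine"
    INSULIN = "insulin_injection"
    OTHER = "other"


class Subgroup(str, Enum):
    EYE_SINGLE_DOSE = "eye_single_dose_container"
    EYE_ANTI_INFECTIVE = "eye_anti_infective"
    NASAL_ANTIFUNGAL = "nasal_antifungal"
    SYRUP_ANTIBIOTIC = "syrup_antibiotic"
    PATCH_HORMONAL = "patch_hormonal"
    PATCH_ANALGESIC = "patch_analgesic"


SUBGROUP_PARENT = {
    Subgroup.EYE_SINGLE_DOSE: FormGroup.EYE_DROPS,
    Subgroup.EYE_ANTI_INFECTIVE: FormGroup.EYE_DROPS,
    Subgroup.NASAL_ANTIFUNGAL: FormGroup.NASAL_SPRAY,
    Subgroup.SYRUP_ANTIBIOTIC: FormGroup.SYRUP,
    Subgroup.PATCH_HORMONAL: FormGroup.TRANSDERMAL_PATCH,
    Subgroup.PATCH_ANALGESIC: FormGroup.TRANSDERMAL_PATCH,
}


@dataclass(frozen=True)
class FormAssignment:
    group: FormGroup
    subgroup: Subgroup | None = None


# keyword rules are ordered: first match wins (most specific first)
DEFAULT_KEYWORD_RULES: tuple[tuple[str, FormGroup], ...] = (
    ("insulin", FormGroup.INSULIN),
    ("nail", FormGroup.NAIL_POLISH),
    ("ear drop", FormGroup.EAR_DROPS),
    ("eye drop", FormGroup.EYE_DROPS),
    ("oral drop", FormGroup.ORAL_DROPS),
    ("nasal spray", FormGroup.NASAL_SPRAY),
    ("nasal drop", FormGroup.NASAL_SPRAY),
    ("inhal", FormGroup.INHALATION),
    ("syrup", FormGroup.SYRUP),
    ("oral suspension", FormGroup.SYRUP),
    ("transdermal", FormGroup.TRANSDERMAL_PATCH),
    ("patch", FormGroup.TRANSDERMAL_PATCH),
    ("vaginal", FormGroup.INTRAVAGINAL),
    ("implant", FormGroup.IMPLANT_VACCINE),
    ("vaccine", FormGroup.IMPLANT_VACCINE),
    ("cream", FormGroup.SEMISOLID),
    ("gel", FormGroup.SEMISOLID),
    ("ointment", FormGroup.SEMISOLID),
    ("shampoo", FormGroup.SEMISOLID),
    ("liniment", FormGroup.SEMISOLID),
    ("tablet", FormGroup.SINGLE_DOSE),
    ("capsule", FormGroup.SINGLE_DOSE),
    ("suppositor", FormGroup.SINGLE_DOSE),
)

# ATC fallbacks for forms whose free text is uninformative ("solution for
# injection" covers both insulins and vaccines)
DEFAULT_ATC_RULES: tuple[tuple[str, FormGroup], ...] = (
    ("A10A", FormGroup.INSULIN),
    ("J07", FormGroup.IMPLANT_VACCINE),
)

# ATC prefixes assigning reporting/imputation subgroups; configuration, since
# the subgroup definitions name therapeutic classes rather than prefix lists
DEFAULT_SUBGROUP_ATC: dict[Subgroup, tuple[str, ...]] = {
    Subgroup.EYE_ANTI_INFECTIVE: ("S01A", "S01B", "S01C"),
    Subgroup.NASAL_ANTIFUNGAL: ("R01AX",),
    Subgroup.SYRUP_ANTIBIOTIC: ("J01",),
    Subgroup.PATCH_HORMONAL: ("G03",),
    Subgroup.PATCH_ANALGESIC: ("N02",),
}

DEFAULT_SINGLE_DOSE_CONTAINER_KEYWORDS = ("single-dose", "single dose", "unit dose")


@dataclass
class FormClassifier:
    """Configurable drug-form → group/subgroup mapping.

    Deterministic and total: unmatched records land in ``other``.
    """

    keyword_rules: tuple[tuple[str, FormGroup], ...] = DEFAULT_KEYWORD_RULES
    atc_rules: tuple[tuple[str, FormGroup], ...] = DEFAULT_ATC_RULES
    subgroup_atc: Mapping[Subgroup, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_ATC))
    single_dose_container_keywords: tuple[str, ...] = DEFAULT_SINGLE_DOSE_CONTAINER_KEYWORDS

    def classify(self, record: PrescriptionRecord) -> FormAssignment:
        form = (record.drug_form or "").strip().lower()
        atc = (record.atc_code or "").strip().upper()

        group = None
        for keyword, g in self.keyword_rules:
            if keyword in form:
                group = g
                break
        if group is None:
            for prefix, g in self.atc_rules:
                if atc.startswith(prefix):
                    group = g
                    break
        if group is None:
            group = FormGroup.OTHER

        subgroup = None
        if group is FormGroup.EYE_DROPS:
            if any(k in form for k in self.single_dose_container_keywords):
                subgroup = Subgroup.EYE_SINGLE_DOSE
            elif any(atc.startswith(p) for p in self.subgroup_atc.get(Subgroup.EYE_ANTI_INFECTIVE, ())):
                subgroup = Subgroup.EYE_ANTI_INFECTIVE
        elif group is FormGroup.NASAL_SPRAY:
            if any(atc.startswith(p) for p in self.subgroup_atc.get(Subgroup.NASAL_ANTIFUNGAL, ())):
                subgroup = Subgroup.NASAL_ANTIFUNGAL
        elif group is FormGroup.SYRUP:
            if any(atc.startswith(p) for p in self.subgroup_atc.get(Subgroup.SYRUP_ANTIBIOTIC, ())):
                subgroup = Subgroup.SYRUP_ANTIBIOTIC
        elif group is FormGroup.TRANSDERMAL_PATCH:
            if any(atc.startswith(p) for p in self.subgroup_atc.get(Subgroup.PATCH_HORMONAL, ())):
                subgroup = Subgroup.PATCH_HORMONAL
            elif any(atc.startswith(p) for p in self.subgroup_atc.get(Subgroup.PATCH_ANALGESIC, ())):
                subgroup = Subgroup.PATCH_ANALGESIC
        return FormAssignment(group, subgroup)

    # -- config round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "keyword_rules": [[k, g.value] for k, g in self.keyword_rules],
            "atc_rules": [[p, g.value] for p, g in self.atc_rules],
            "subgroup_atc": {s.value: list(p) for s, p in self.subgroup_atc.items()},
            "single_dose_container_keywords": list(self.single_dose_container_keywords),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FormClassifier":
        return cls(
            keyword_rules=tuple((k, FormGroup(g)) for k, g in d.get(
                "keyword_rules", [[k, g.value] for k, g in DEFAULT_KEYWORD_RULES])),
            atc_rules=tuple((p, FormGroup(g)) for p, g in d.get(
                "atc_rules", [[p, g.value] for p, g in DEFAULT_ATC_RULES])),
            subgroup_atc={Subgroup(s): tuple(p) for s, p in d.get(
                "subgroup_atc", {s.value: list(p) for s, p in DEFAULT_SUBGROUP_ATC.items()}).items()},
            single_dose_container_keywords=tuple(d.get(
                "single_dose_container_keywords", DEFAULT_SINGLE_DOSE_CONTAINER_KEYWORDS)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FormClassifier":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


DEFAULT_CLASSIFIER = FormClassifier()


def classify_form(record: PrescriptionRecord,
                  classifier: FormClassifier | None = None) -> FormAssignment:
    """Assign a record to its drug-form group (and subgroup where defined)."""
    return (classifier or DEFAULT_CLASSIFIER).classify(record)
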