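"""Days'-supply resolution: calculation, reconciliation and imputation.

The resolution order for a dispensed prescription is:

1. classify the drug form;
2. for single-dose forms (tablets, capsules, suppositories): compute
   DS = dispensed units / canonical daily dose, then take the *minimum* of
   the calculated and prescriber-provided DS when both exist (a pharmacist
   may dispense a larger package than the course needs, so the smaller
   figure is the better course-length estimate);
3. when the daily dose is missing, impute it from a mode table — the
   strictly most frequent daily dose observed for the same active substance
   at the same strength; keys whose top frequencies tie are excluded and
   their prescriptions stay unimputed;
4. for every other drug form, run that form's ordered rule chain
   (calculate where a quantitative dose exists, use the provided DS, else a
   form-specific constant sourced from product-characteristics summaries);
5. anything left is reported as unresolved — a valid, tagged outcome.

Every result carries a method tag and a human-readable trace so the final
method accounting (the per-group report) can be audited.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .dose import (CanonicalDose, DoseParseError, FormAssignment,
                   FormClassifier, FormGroup, Subgroup, canonical_dose,
                   classify_form)
from .model import PrescriptionRecord


class Method(str, Enum):
    CALCULATED = "calculated"
    PROVIDED = "provided"
    MIN_OF_CALCULATED_AND_PROVIDED = "min_of_calculated_and_provided"
    MODE_IMPUTED = "mode_imputed"
    FORM_IMPUTED = "form_imputed"
    BASELINE_IMPUTED = "baseline_imputed"
    UNRESOLVED = "unresolved"


class MissingQuantity(ValueError):
    """Neither units-per-package nor item-size available for the record."""


@dataclass(frozen=True)
class DSResult:
    prescription_id: str
    ds_days: int | None
    method: Method
    form_group: FormGroup
    subgroup: Subgroup | None = None
    detail: str = ""

    @property
    def resolved(self) -> bool:
        return self.method is not Method.UNRESOLVED


# ---------------------------------------------------------------------------
# elementary operations

def total_dispensed_units(record: PrescriptionRecord,
                          prefer: str = "units") -> float:
    """Total dispensed quantity: package count x package content.

    ``prefer="units"`` counts single-dose units (tablets, containers,
    patches); ``prefer="measured"`` uses the item size (grams, millilitres)
    of non-single-dose forms.  Falls back to the other basis when the
    preferred one is absent; raises :class:`MissingQuantity` when neither
    size field is present.
    """
    units = (record.n_packages * record.units_per_package
             if record.units_per_package else None)
    measured = (record.n_packages * record.item_size_value
                if record.item_size_value else None)
    first, second = (units, measured) if prefer == "units" else (measured, units)
    for total in (first, second):
        if total is not None:
            return float(total)
    raise MissingQuantity(
        f"{record.prescription_id}: neither units_per_package nor item_size present")


def calculate_ds(total_units: float, units_per_day: float,
                 rounding: str = "floor") -> int:
    """DS in whole days from dispensed quantity and daily dose.

    Floor (default) counts full days of coverage; a minimum of one day
    prevents zero-day supplies.  ``rounding`` may be floor|round|ceil.
    """
    if total_units <= 0 or units_per_day <= 0:
        raise ValueError("total_units and units_per_day must be positive")
    q = total_units / units_per_day
    if rounding == "floor":
        days = math.floor(q)
    elif rounding == "ceil":
        days = math.ceil(q)
    elif rounding == "round":
        days = round(q)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return max(1, int(days))


def reconcile(calculated: int | None,
              provided: int | None) -> tuple[int | None, Method | None, str]:
    """Combine calculated and provided DS: the smaller of the two wins."""
    if calculated is not None and provided is not None:
        winner = "provided" if provided < calculated else "calculated"
        if provided == calculated:
            winner = "equal"
        return (min(calculated, provided), Method.MIN_OF_CALCULATED_AND_PROVIDED,
                f"min(calculated={calculated}, provided={provided}); {winner} side used")
    if calculated is not None:
        return calculated, Method.CALCULATED, f"calculated={calculated}"
    if provided is not None:
        return provided, Method.PROVIDED, f"provided={provided}"
    return None, None, "neither calculated nor provided"


# ---------------------------------------------------------------------------
# mode table

ModeKey = tuple[tuple[str, ...], tuple[tuple[float, str], ...]]


def mode_key(record: PrescriptionRecord) -> ModeKey:
    """(sorted substance names, sorted strength signature) lookup key."""
    names = tuple(sorted(c.substance.strip().lower() for c in record.components))
    strengths = tuple(sorted((float(c.strength_value), c.strength_unit)
                             for c in record.components))
    return names, strengths


@dataclass(frozen=True)
class ModeEntry:
    modal_daily_dose: float
    support: int
    counts: Mapping[float, int]


@dataclass
class ModeTable:
    """Most common daily dose per (substance set, strength signature).

    Only keys with a *strictly* most frequent daily dose are usable for
    imputation; keys whose top frequencies tie (or fall below the support
    floor) are recorded in ``excluded_keys`` and never imputed from.
    """

    entries: dict[ModeKey, ModeEntry] = field(default_factory=dict)
    excluded_keys: dict[ModeKey, str] = field(default_factory=dict)

    def lookup(self, record: PrescriptionRecord) -> ModeEntry | None:
        return self.entries.get(mode_key(record))

    def __len__(self) -> int:
        return len(self.entries)


def build_mode_table(records: Iterable[PrescriptionRecord],
                     min_support: int = 1,
                     classifier: FormClassifier | None = None,
                     dose_options: Mapping | None = None) -> ModeTable:
    """Build the daily-dose mode table from single-dose prescriptions.

    Records whose dose fields do not parse contribute nothing.  When a
    classifier is supplied, non-single-dose records are skipped; otherwise
    the caller is trusted to pass single-dose records only.  Counting is
    order-invariant, so the table is too.
    """
    opts = dict(dose_options or {})
    counts: dict[ModeKey, Counter] = defaultdict(Counter)
    for record in records:
        if classifier is not None:
            if classifier.classify(record).group is not FormGroup.SINGLE_DOSE:
                continue
        try:
            dose = canonical_dose(record, **opts)
        except DoseParseError:
            continue
        counts[mode_key(record)][round(dose.units_per_day, 6)] += 1

    table = ModeTable()
    for key, counter in counts.items():
        support = sum(counter.values())
        if support < min_support:
            table.excluded_keys[key] = "low_support"
            continue
        top = counter.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            table.excluded_keys[key] = "tie"
            continue
        table.entries[key] = ModeEntry(modal_daily_dose=top[0][0], support=support,
                                       counts=dict(counter))
    return table


def impute_from_mode(record: PrescriptionRecord, table: ModeTable,
                     rounding: str = "floor") -> tuple[int | None, str]:
    """DS from the modal daily dose of the record's substance-strength key.

    Returns ``(None, reason)`` for keys that are absent, tie-excluded or
    when the dispensed quantity is unavailable — those prescriptions stay
    unimputed.
    """
    key = mode_key(record)
    if key in table.excluded_keys:
        return None, f"mode key excluded ({table.excluded_keys[key]})"
    entry = table.entries.get(key)
    if entry is None:
        return None, "mode key absent from table"
    try:
        total = total_dispensed_units(record, prefer="units")
    except MissingQuantity:
        return None, "MISSING_QUANTITY"
    ds = calculate_ds(total, entry.modal_daily_dose, rounding=rounding)
    return ds, (f"modal dose {entry.modal_daily_dose}/day "
                f"(support {entry.support}) x {total} units -> {ds}d")


# ---------------------------------------------------------------------------
# drug-form rule engine

@dataclass(frozen=True)
class Strategy:
    """One step of a form-group rule chain.

    kinds: ``calculate`` (daily-dose calculation), ``provided`` (use the
    prescriber's DS), ``constant`` (fixed days per prescription),
    ``per_package`` (days x packages), ``per_unit`` (days x dispensed items
    + plus_days, e.g. patches), ``package_type`` (choose large_days vs
    small_days on package size), ``unresolved`` (terminal give-up).
    """

    kind: str
    days: float | None = None
    plus_days: float = 0.0
    large_days: float | None = None
    small_days: float | None = None
    size_threshold: float | None = None

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        for k in ("days", "plus_days", "large_days", "small_days", "size_threshold"):
            v = getattr(self, k)
            if v not in (None, 0.0) or (k == "plus_days" and v != 0.0):
                d[k] = v
        return d


Chain = tuple[Strategy, ...]
ChainKey = tuple[FormGroup, Subgroup | None]


def _s(kind: str, **kw) -> Strategy:
    return Strategy(kind=kind, **kw)


def default_rules() -> "FormRuleSet":
    """The shipped rule chains: form-specific course-length conventions.

    Constants come from regulatory product-characteristics summaries and
    prescribing practice: short anti-infective courses (7 d ear drops,
    14 d anti-infective eye drops and antibiotic syrups, 7 d antifungal
    nasal spray), shelf-life-limited 30 d multi-dose containers, 2-month
    chronic-prescription conventions (60 d inhalation and insulin), patch
    wear times (7 d hormonal + 1 patch-free week, 3 d analgesic), 30 d per
    intravaginal item, 1 d for implants and vaccines, and 210/180 d nail
    polish by package type.
    """
    c: dict[ChainKey, Chain] = {
        (FormGroup.SINGLE_DOSE, None): (_s("calculate"), _s("provided")),
        (FormGroup.SEMISOLID, None): (_s("provided"), _s("per_package", days=30)),
        (FormGroup.NAIL_POLISH, None): (
            _s("provided"),
            _s("package_type", large_days=210, small_days=180, size_threshold=3.0)),
        (FormGroup.EAR_DROPS, None): (_s("provided"), _s("constant", days=7)),
        (FormGroup.EYE_DROPS, None): (_s("provided"), _s("per_package", days=30)),
        (FormGroup.EYE_DROPS, Subgroup.EYE_ANTI_INFECTIVE): (
            _s("provided"), _s("per_package", days=14)),
        (FormGroup.EYE_DROPS, Subgroup.EYE_SINGLE_DOSE): (
            _s("calculate"), _s("provided"), _s("constant", days=30)),
        (FormGroup.ORAL_DROPS, None): (
            _s("calculate"), _s("provided"), _s("constant", days=30)),
        (FormGroup.INHALATION, None): (
            _s("calculate"), _s("provided"), _s("constant", days=60)),
        (FormGroup.NASAL_SPRAY, None): (
            _s("calculate"), _s("provided"), _s("constant", days=30)),
        (FormGroup.NASAL_SPRAY, Subgroup.NASAL_ANTIFUNGAL): (
            _s("calculate"), _s("provided"), _s("constant", days=7)),
        (FormGroup.SYRUP, None): (
            _s("calculate"), _s("provided"), _s("per_package", days=30)),
        (FormGroup.SYRUP, Subgroup.SYRUP_ANTIBIOTIC): (
            _s("provided"), _s("constant", days=14)),
        (FormGroup.TRANSDERMAL_PATCH, None): (
            _s("provided"), _s("per_unit", days=7)),
        (FormGroup.TRANSDERMAL_PATCH, Subgroup.PATCH_HORMONAL): (
            _s("provided"), _s("per_unit", days=7, plus_days=7)),
        (FormGroup.TRANSDERMAL_PATCH, Subgroup.PATCH_ANALGESIC): (
            _s("provided"), _s("per_unit", days=3)),
        (FormGroup.INTRAVAGINAL, None): (_s("provided"), _s("per_unit", days=30)),
        # no standard way to write a DS for implants/vaccines, so the
        # provided value is deliberately ignored
        (FormGroup.IMPLANT_VACCINE, None): (_s("constant", days=1),),
        (FormGroup.INSULIN, None): (_s("provided"), _s("constant", days=60)),
        (FormGroup.OTHER, None): (_s("provided"), _s("unresolved")),
    }
    return FormRuleSet(chains=c)


@dataclass
class FormRuleSet:
    """Ordered imputation strategy chains per drug-form group/subgroup."""

    chains: dict[ChainKey, Chain] = field(default_factory=dict)

    def chain_for(self, group: FormGroup, subgroup: Subgroup | None = None) -> Chain:
        if subgroup is not None and (group, subgroup) in self.chains:
            return self.chains[(group, subgroup)]
        return self.chains.get((group, None),
                               (_s("provided"), _s("unresolved")))

    # -- config round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for (group, subgroup), chain in self.chains.items():
            key = group.value if subgroup is None else f"{group.value}:{subgroup.value}"
            out[key] = [s.to_dict() for s in chain]
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "FormRuleSet":
        chains: dict[ChainKey, Chain] = {}
        for key, steps in d.items():
            if ":" in key:
                g, sg = key.split(":", 1)
                ck: ChainKey = (FormGroup(g), Subgroup(sg))
            else:
                ck = (FormGroup(key), None)
            chains[ck] = tuple(Strategy(**step) for step in steps)
        return cls(chains=chains)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FormRuleSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


DEFAULT_RULES = default_rules()


def _try_calculate(record: PrescriptionRecord,
                   rounding: str = "floor",
                   dose_options: Mapping | None = None) -> tuple[int | None, str]:
    """Calculated DS from the record's own daily-dose fields, or None."""
    try:
        dose = canonical_dose(record, **dict(dose_options or {}))
    except DoseParseError as exc:
        return None, f"dose not parseable ({exc.code})"
    prefer = "measured" if dose.interpretation in ("volume", "drops") else "units"
    try:
        total = total_dispensed_units(record, prefer=prefer)
    except MissingQuantity:
        return None, "MISSING_QUANTITY"
    ds = calculate_ds(total, dose.units_per_day, rounding=rounding)
    return ds, (f"{total} {prefer} / {dose.units_per_day:g} per day -> {ds}d "
                f"({dose.interpretation})")


def _effective_provided(record: PrescriptionRecord, provided_cap: int,
                        trace: list[str]) -> int | None:
    provided = record.provided_ds
    if provided is not None and provided_cap and provided > provided_cap:
        trace.append(f"provided DS {provided}d exceeds plausibility cap "
                     f"{provided_cap}d (kept; warn-only)")
    return provided


def apply_form_rule(record: PrescriptionRecord,
                    rules: FormRuleSet | None = None,
                    assignment: FormAssignment | None = None,
                    classifier: FormClassifier | None = None,
                    rounding: str = "floor",
                    provided_cap: int = 365,
                    reconcile_in_chains: bool = True,
                    dose_options: Mapping | None = None) -> DSResult:
    """Run the drug-form rule chain for a non-single-dose record."""
    rules = rules or DEFAULT_RULES
    fa = assignment or classify_form(record, classifier)
    chain = rules.chain_for(fa.group, fa.subgroup)
    kinds = [s.kind for s in chain]
    trace: list[str] = [f"chain {kinds} for {fa.group.value}"
                        + (f":{fa.subgroup.value}" if fa.subgroup else "")]

    provided = _effective_provided(record, provided_cap, trace)
    calc: int | None = None
    if "calculate" in kinds:
        calc, why = _try_calculate(record, rounding=rounding, dose_options=dose_options)
        trace.append(f"calculate: {why}")

    def result(ds: int | None, method: Method) -> DSResult:
        return DSResult(record.prescription_id, ds, method, fa.group, fa.subgroup,
                        "; ".join(trace))

    # the smaller-of-the-two comparison applies wherever a chain both
    # calculates and consults the provided DS
    if (reconcile_in_chains and calc is not None and provided is not None
            and "calculate" in kinds and "provided" in kinds):
        ds, method, why = reconcile(calc, provided)
        trace.append(why)
        return result(ds, method)

    for s in chain:
        if s.kind == "calculate":
            if calc is not None:
                trace.append("calculated value used")
                return result(calc, Method.CALCULATED)
        elif s.kind == "provided":
            if provided is not None:
                trace.append(f"provided DS {provided}d used")
                return result(provided, Method.PROVIDED)
        elif s.kind == "constant":
            trace.append(f"imputed constant {s.days:g}d")
            return result(int(s.days), Method.FORM_IMPUTED)
        elif s.kind == "per_package":
            days = int(s.days * record.n_packages + s.plus_days)
            trace.append(f"imputed {s.days:g}d x {record.n_packages} package(s) -> {days}d")
            return result(max(1, days), Method.FORM_IMPUTED)
        elif s.kind == "per_unit":
            if record.units_per_package is None:
                trace.append("per-unit rule skipped (units_per_package absent)")
                continue
            n_items = record.n_packages * record.units_per_package
            days = int(s.days * n_items + s.plus_days)
            trace.append(f"imputed {s.days:g}d x {n_items} item(s)"
                         + (f" + {s.plus_days:g}d" if s.plus_days else "")
                         + f" -> {days}d")
            return result(max(1, days), Method.FORM_IMPUTED)
        elif s.kind == "package_type":
            size = record.item_size_value or record.units_per_package or 0
            days = s.large_days if size >= (s.size_threshold or 0) else s.small_days
            trace.append(f"package size {size} -> imputed {days:g}d")
            return result(int(days), Method.FORM_IMPUTED)
        elif s.kind == "unresolved":
            break
        else:
            raise ValueError(f"unknown strategy kind {s.kind!r}")
    trace.append("chain exhausted")
    return result(None, Method.UNRESOLVED)


# ---------------------------------------------------------------------------
# full resolution

def resolve_ds(record: PrescriptionRecord,
               mode_table: ModeTable | None = None,
               rules: FormRuleSet | None = None,
               classifier: FormClassifier | None = None,
               rounding: str = "floor",
               provided_cap: int = 365,
               provided_only_groups: frozenset[FormGroup] | set[FormGroup] = frozenset(),
               reconcile_in_chains: bool = True,
               dose_options: Mapping | None = None) -> DSResult:
    """Resolve one prescription's days' supply; always returns a result.

    ``provided_only_groups`` lists form groups restricted by the small-group
    policy to the provided-DS strategy only.
    """
    fa = classify_form(record, classifier)
    trace: list[str] = []

    if fa.group in provided_only_groups:
        provided = _effective_provided(record, provided_cap, trace)
        trace.append("small-group policy: provided DS only")
        if provided is not None:
            return DSResult(record.prescription_id, provided, Method.PROVIDED,
                            fa.group, fa.subgroup, "; ".join(trace))
        return DSResult(record.prescription_id, None, Method.UNRESOLVED,
                        fa.group, fa.subgroup, "; ".join(trace))

    if fa.group is FormGroup.SINGLE_DOSE:
        provided = _effective_provided(record, provided_cap, trace)
        calc, why = _try_calculate(record, rounding=rounding, dose_options=dose_options)
        trace.append(f"calculate: {why}")
        ds, method, rec_why = reconcile(calc, provided)
        trace.append(rec_why)
        if ds is not None:
            return DSResult(record.prescription_id, ds, method, fa.group, fa.subgroup,
                            "; ".join(trace))
        if mode_table is not None:
            ds, mode_why = impute_from_mode(record, mode_table, rounding=rounding)
            trace.append(f"mode imputation: {mode_why}")
            if ds is not None:
                return DSResult(record.prescription_id, ds, Method.MODE_IMPUTED,
                                fa.group, fa.subgroup, "; ".join(trace))
        else:
            trace.append("no mode table available")
        return DSResult(record.prescription_id, None, Method.UNRESOLVED,
                        fa.group, fa.subgroup, "; ".join(trace))

    res = apply_form_rule(record, rules=rules, assignment=fa,
                          rounding=rounding, provided_cap=provided_cap,
                          reconcile_in_chains=reconcile_in_chains,
                          dose_options=dose_options)
    if trace:
        res = replace(res, detail="; ".join(trace + [res.detail]))
    return res


def small_group_policy(records: Sequence[PrescriptionRecord],
                       classifier: FormClassifier | None = None,
                       threshold: int = 1000) -> set[FormGroup]:
    """Form groups with fewer than ``threshold`` prescriptions in the batch.

    Such groups are too small for reliable imputation and are restricted to
    the provided-DS strategy only.
    """
    counts: Counter = Counter(classify_form(r, classifier).group for r in records)
    return {g for g, n in counts.items() if n < threshold}


def resolve_baseline(record: PrescriptionRecord,
                     classifier: FormClassifier | None = None,
                     rounding: str = "floor",
                     default_days: int = 30,
                     dose_options: Mapping | None = None) -> DSResult:
    """Simplified comparator resolution.

    Single-dose prescriptions with a parseable daily dose get a calculated
    DS; everything else gets a flat default (30 days).  This is the cheap
    baseline the full pipeline is evaluated against.
    """
    fa = classify_form(record, classifier)
    if fa.group is FormGroup.SINGLE_DOSE:
        calc, why = _try_calculate(record, rounding=rounding, dose_options=dose_options)
        if calc is not None:
            return DSResult(record.prescription_id, calc, Method.CALCULATED,
                            fa.group, fa.subgroup, f"baseline: {why}")
    return DSResult(record.prescription_id, default_days, Method.BASELINE_IMPUTED,
                    fa.group, fa.subgroup, f"baseline: flat {default_days}d")
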