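"""Domain model, tabular I/O, validation and record-level cleaning.

A :class:`PrescriptionRecord` mirrors one dispensed prescription as it
appears in a national e-prescription extract: administrative identifiers,
issue/dispense dates, the active-substance components with strengths, the
drug form, the (optional and frequently missing) daily-dose fields, the
optional prescriber-entered treatment-course length ("provided DS") and
the dispensed-package quantities.  Everything downstream — dose parsing,
days'-supply resolution, adherence — consumes these records.

Files are plain delimited text (comma or tab, UTF-8, header row, ISO-8601
dates).  Because e-prescription exports have no standard schema, readers
accept a *dialect*: a mapping from the canonical column names used here to
whatever the source file calls them.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

# strength / amount unit vocabulary
MASS = "mass"
VOLUME = "volume"
UNIT = "unit"
IU = "iu"
DROPS = "drops"

STRENGTH_UNITS = frozenset({MASS, VOLUME, UNIT, IU})
DOSE_AMOUNT_UNITS = frozenset({UNIT, MASS, VOLUME, DROPS})
DOSE_PERIODS = frozenset({"day", "week"})
PRESCRIPTION_TYPES = frozenset({"initial", "refill", "narcotic", "device"})


@dataclass(frozen=True)
class Component:
    """One active-substance component with its strength per dispensing unit."""

    substance: str
    strength_value: float
    strength_unit: str = MASS

    def key(self) -> tuple[str, float, str]:
        return (self.substance.strip().lower(), float(self.strength_value), self.strength_unit)


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensed prescription (whole-day date resolution throughout)."""

    patient_id: str
    prescription_id: str
    issue_date: dt.date
    dispense_date: dt.date
    atc_code: str
    components: tuple[Component, ...]
    drug_form: str
    package_id: str
    n_packages: int = 1
    dose_times: float | None = None
    dose_period: str | None = None  # day | week
    dose_amount: float | None = None
    dose_amount_unit: str | None = None  # unit | mass | volume | drops
    dose_free_text: str | None = None
    provided_ds: int | None = None  # prescriber-entered treatment course, days
    units_per_package: int | None = None
    item_size_value: float | None = None
    item_size_unit: str | None = None
    prescription_type: str = "initial"
    notes: tuple[str, ...] = ()

    def with_note(self, note: str) -> "PrescriptionRecord":
        if note in self.notes:
            return self
        return replace(self, notes=self.notes + (note,))

    def substance_key(self) -> tuple[str, ...]:
        return tuple(sorted(c.substance.strip().lower() for c in self.components))


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Issue:
    code: str
    severity: str  # error | warning
    message: str


@dataclass
class ValidationReport:
    record_id: str
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]


def validate_record(record: PrescriptionRecord) -> ValidationReport:
    """Check record invariants; never raises.

    Severity policy: only violations that make days'-supply resolution
    impossible are ``error``; everything else is a ``warning``, because the
    pipeline exists to salvage incomplete records.
    """
    rep = ValidationReport(record_id=record.prescription_id)

    def err(code: str, msg: str) -> None:
        rep.issues.append(Issue(code, "error", msg))

    def warn(code: str, msg: str) -> None:
        rep.issues.append(Issue(code, "warning", msg))

    if record.dispense_date < record.issue_date:
        err("DATE_ORDER", "dispense_date precedes issue_date")
    if record.n_packages < 1:
        err("PKG_COUNT", f"n_packages must be >= 1, got {record.n_packages}")
    if not record.components:
        err("NO_COMPONENTS", "record has no active-substance components")
    for c in record.components:
        if c.strength_value <= 0:
            err("BAD_STRENGTH", f"non-positive strength for {c.substance!r}")
        if c.strength_unit not in STRENGTH_UNITS:
            warn("BAD_STRENGTH_UNIT", f"unknown strength unit {c.strength_unit!r}")
    if len(record.components) > 3:
        warn("TOO_MANY_COMPONENTS", "more than 3 components")
    if record.units_per_package is not None and record.units_per_package < 1:
        warn("BAD_UNITS_PER_PACKAGE", "units_per_package must be >= 1 when present")
    if record.provided_ds is not None and record.provided_ds < 1:
        warn("BAD_PROVIDED_DS", "provided_ds must be >= 1 when present")
    if record.dose_times is not None and record.dose_period is None:
        warn("DOSE_PERIOD_MISSING", "dose_times present but dose_period absent")
    if record.dose_period is not None and record.dose_period not in DOSE_PERIODS:
        warn("BAD_DOSE_PERIOD", f"unknown dose period {record.dose_period!r}")
    if record.dose_amount is not None and record.dose_amount_unit is None:
        warn("DOSE_AMOUNT_UNIT_MISSING", "dose_amount present but its unit absent")
    if record.dose_amount_unit is not None and record.dose_amount_unit not in DOSE_AMOUNT_UNITS:
        warn("BAD_DOSE_AMOUNT_UNIT", f"unknown dose amount unit {record.dose_amount_unit!r}")
    return rep


# ---------------------------------------------------------------------------
# package registry

@dataclass(frozen=True)
class PackageEntry:
    package_id: str
    components: tuple[Component, ...]
    drug_form: str = ""
    units_per_package: int | None = None
    item_size_value: float | None = None
    item_size_unit: str | None = None


@dataclass
class PackageRegistry:
    """Package master data keyed by package_id.

    The registry is the ground truth for active-substance composition: where
    a prescription disagrees with its dispensed package, the package wins.
    """

    entries: dict[str, PackageEntry] = field(default_factory=dict)

    def get(self, package_id: str) -> PackageEntry | None:
        return self.entries.get(package_id)

    def __contains__(self, package_id: str) -> bool:
        return package_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, entry: PackageEntry) -> None:
        self.entries[entry.package_id] = entry

    @classmethod
    def from_csv(cls, path: str | Path) -> "PackageRegistry":
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
        reg = cls()
        for _, row in df.iterrows():
            comps = _row_components(row)
            reg.add(PackageEntry(
                package_id=row["package_id"],
                components=comps,
                drug_form=row.get("drug_form", ""),
                units_per_package=_opt_int(row.get("units_per_package", "")),
                item_size_value=_opt_float(row.get("item_size_value", "")),
                item_size_unit=row.get("item_size_unit", "") or None,
            ))
        return reg

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for e in self.entries.values():
            row: dict[str, object] = {
                "package_id": e.package_id,
                "drug_form": e.drug_form,
                "units_per_package": _fmt_opt(e.units_per_package),
                "item_size_value": _fmt_opt(e.item_size_value),
                "item_size_unit": e.item_size_unit or "",
            }
            for i, c in enumerate(e.components, start=1):
                row[f"substance_{i}"] = c.substance
                row[f"strength_{i}"] = _fmt_num(c.strength_value)
                row[f"strength_unit_{i}"] = c.strength_unit
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def correct_active_substance(record: PrescriptionRecord,
                             registry: PackageRegistry) -> PrescriptionRecord:
    """Replace the record's components with the dispensed package's components.

    Early extracts carried false active-substance data on some prescriptions
    while the package reference was reliable, so wherever the registry entry
    for the dispensed package disagrees with the record, the registry version
    is substituted and a provenance note appended.  Idempotent; unknown
    packages leave the record unchanged apart from a warning note.
    """
    entry = registry.get(record.package_id)
    if entry is None:
        return record.with_note("PKG_UNKNOWN")
    rec_key = sorted(c.key() for c in record.components)
    reg_key = sorted(c.key() for c in entry.components)
    if rec_key == reg_key:
        return record
    old = "+".join(c.substance for c in record.components)
    new = "+".join(c.substance for c in entry.components)
    return replace(record, components=tuple(entry.components)).with_note(
        f"SUBSTANCE_CORRECTED:{old}->{new}")


# ---------------------------------------------------------------------------
# refill-series days'-supply artifact

@dataclass(frozen=True)
class RefillFlag:
    prescription_id: str
    flagged: bool


def flag_refill_ds_artifact(
    records: Sequence[PrescriptionRecord],
    artifact_value: int = 180,
    suppress: bool = False,
) -> tuple[list[RefillFlag], list[PrescriptionRecord]]:
    """Flag same-day refill series that all carry the combined course length.

    A known entry error: a doctor issues several refill prescriptions on the
    same day and stamps *each* with the full combined treatment length
    (typically 180 days for a 3 x 60-day series).  A series is flagged when
    two or more prescriptions share patient, substance set and issue date and
    every member's provided DS equals ``artifact_value``.  Singleton series
    are never flagged.  With ``suppress=True`` flagged records get their
    provided DS cleared (treated as absent) — the value is never rewritten to
    a guess.
    """
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, r in enumerate(records):
        groups[(r.patient_id, r.substance_key(), r.issue_date)].append(i)

    flagged_idx: set[int] = set()
    for idx in groups.values():
        if len(idx) < 2:
            continue
        if all(records[i].provided_ds == artifact_value for i in idx):
            flagged_idx.update(idx)

    flags = [RefillFlag(r.prescription_id, i in flagged_idx)
             for i, r in enumerate(records)]
    out: list[PrescriptionRecord] = []
    for i, r in enumerate(records):
        if suppress and i in flagged_idx:
            out.append(replace(r, provided_ds=None).with_note("REFILL_DS_ARTIFACT"))
        else:
            out.append(r)
    return flags, out


# ---------------------------------------------------------------------------
# delimited-text I/O

CANONICAL_COLUMNS = [
    "patient_id", "prescription_id", "issue_date", "dispense_date",
    "atc_code", "drug_form", "prescription_type",
    "substance_1", "strength_1", "strength_unit_1",
    "substance_2", "strength_2", "strength_unit_2",
    "substance_3", "strength_3", "strength_unit_3",
    "dose_times", "dose_period", "dose_amount", "dose_amount_unit",
    "dose_free_text", "provided_ds", "package_id", "n_packages",
    "units_per_package", "item_size_value", "item_size_unit",
]

MANDATORY_COLUMNS = [
    "patient_id", "prescription_id", "issue_date", "dispense_date",
    "atc_code", "drug_form", "substance_1", "strength_1",
    "package_id", "n_packages",
]


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    prescription_id: str
    code: str
    message: str


@dataclass
class LoadResult(Sequence):
    """Records plus the load report (rejections and parse warnings)."""

    records: list[PrescriptionRecord] = field(default_factory=list)
    rejected: list[RejectedRow] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):  # type: ignore[override]
        return self.records[i]

    def __iter__(self) -> Iterator[PrescriptionRecord]:
        return iter(self.records)


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _opt_float(value: object) -> float | None:
    s = str(value).strip()
    if not s:
        return None
    return float(s)


def _opt_int(value: object) -> int | None:
    f = _opt_float(value)
    if f is None:
        return None
    return int(round(f))


def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v) == int(v) else repr(float(v))


def _fmt_opt(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return _fmt_num(v)
    return str(v)


def _row_components(row: Mapping[str, object]) -> tuple[Component, ...]:
    comps = []
    for i in (1, 2, 3):
        name = str(row.get(f"substance_{i}", "") or "").strip()
        if not name:
            continue
        strength = _opt_float(row.get(f"strength_{i}", ""))
        unit = str(row.get(f"strength_unit_{i}", "") or "").strip() or MASS
        comps.append(Component(name, strength if strength is not None else 0.0, unit))
    return tuple(comps)


def read_prescriptions(path: str | Path,
                       dialect: Mapping[str, str] | None = None) -> LoadResult:
    """Read a delimited prescription file into records.

    ``dialect`` maps canonical column names (see :data:`CANONICAL_COLUMNS`)
    to the column names in the source file; identity by default.  Missing
    mandatory columns are a hard error.  Rows with unparseable mandatory
    dates or a dispense date before the issue date are rejected with a
    reason; unparseable *optional* fields merely become absent, with a
    warning in the load report.  Row order is preserved.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mapping = dict(dialect) if dialect else {}
    # rename source columns to canonical
    rename = {src: canon for canon, src in mapping.items() if src in df.columns}
    df = df.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    result = LoadResult()
    for i, row in enumerate(df.to_dict(orient="records")):
        rx_id = str(row.get("prescription_id", "")).strip()
        try:
            issue = dt.date.fromisoformat(str(row["issue_date"]).strip())
            disp = dt.date.fromisoformat(str(row["dispense_date"]).strip())
        except ValueError as exc:
            result.rejected.append(RejectedRow(i, rx_id, "BAD_DATE", str(exc)))
            continue
        if disp < issue:
            result.rejected.append(RejectedRow(
                i, rx_id, "DATE_ORDER", "dispense_date precedes issue_date"))
            continue

        def opt_num(col: str, kind: str = "float"):
            raw = str(row.get(col, "") or "").strip()
            if not raw:
                return None
            try:
                return float(raw) if kind == "float" else int(round(float(raw)))
            except ValueError:
                result.warnings.append(
                    f"row {i} ({rx_id}): unparseable {col} {raw!r}; treated as absent")
                return None

        try:
            n_packages = int(round(float(str(row["n_packages"]).strip())))
        except ValueError:
            result.rejected.append(RejectedRow(i, rx_id, "BAD_PKG_COUNT",
                                               f"unparseable n_packages {row['n_packages']!r}"))
            continue

        comps = _row_components(row)
        record = PrescriptionRecord(
            patient_id=str(row["patient_id"]).strip(),
            prescription_id=rx_id,
            issue_date=issue,
            dispense_date=disp,
            atc_code=str(row["atc_code"]).strip(),
            components=comps,
            drug_form=str(row["drug_form"]).strip(),
            package_id=str(row["package_id"]).strip(),
            n_packages=n_packages,
            dose_times=opt_num("dose_times"),
            dose_period=(str(row.get("dose_period", "") or "").strip() or None),
            dose_amount=opt_num("dose_amount"),
            dose_amount_unit=(str(row.get("dose_amount_unit", "") or "").strip() or None),
            dose_free_text=(str(row.get("dose_free_text", "") or "").strip() or None),
            provided_ds=opt_num("provided_ds", "int"),
            units_per_package=opt_num("units_per_package", "int"),
            item_size_value=opt_num("item_size_value"),
            item_size_unit=(str(row.get("item_size_unit", "") or "").strip() or None),
            prescription_type=(str(row.get("prescription_type", "") or "").strip() or "initial"),
        )
        result.records.append(record)
    return result


def record_to_row(record: PrescriptionRecord) -> dict[str, str]:
    row = {c: "" for c in CANONICAL_COLUMNS}
    row.update({
        "patient_id": record.patient_id,
        "prescription_id": record.prescription_id,
        "issue_date": record.issue_date.isoformat(),
        "dispense_date": record.dispense_date.isoformat(),
        "atc_code": record.atc_code,
        "drug_form": record.drug_form,
        "prescription_type": record.prescription_type,
        "dose_times": _fmt_opt(record.dose_times),
        "dose_period": record.dose_period or "",
        "dose_amount": _fmt_opt(record.dose_amount),
        "dose_amount_unit": record.dose_amount_unit or "",
        "dose_free_text": record.dose_free_text or "",
        "provided_ds": _fmt_opt(record.provided_ds),
        "package_id": record.package_id,
        "n_packages": str(record.n_packages),
        "units_per_package": _fmt_opt(record.units_per_package),
        "item_size_value": _fmt_opt(record.item_size_value),
        "item_size_unit": record.item_size_unit or "",
    })
    for i, c in enumerate(record.components[:3], start=1):
        row[f"substance_{i}"] = c.substance
        row[f"strength_{i}"] = _fmt_num(c.strength_value)
        row[f"strength_unit_{i}"] = c.strength_unit
    return row


def write_prescriptions(records: Sequence[PrescriptionRecord],
                        path: str | Path,
                        dialect: Mapping[str, str] | None = None) -> None:
    """Write records as delimited text (inverse of :func:`read_prescriptions`)."""
    rows = [record_to_row(r) for r in records]
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    if dialect:
        df = df.rename(columns=dict(dialect))
    df.to_csv(path, sep=_sep_for(path), index=False)
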